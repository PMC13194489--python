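"""Superposition, TM-score, secondary-structure and heme statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from geoevo import (
    StructureModel,
    content_change,
    deviation_bins,
    helix_content,
    heme_distance_stats,
    kabsch_superpose,
    segment_stats,
    ss_diff,
    tm_score,
)
from geoevo.simulate import generate_structure_pair
from geoevo.structure import (
    read_model_pdb,
    read_ss_string,
    reduce_dssp,
    segment_lengths,
    write_model_pdb,
    write_ss_string,
)


def random_rigid(rng):
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return rot, rng.normal(0, 10, 3)


# ------------------------------------------------------------ superposition


def test_identity_and_isometry_give_zero_rmsd():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(25, 3))
    res = kabsch_superpose(a, a)
    assert res.global_rmsd == pytest.approx(0.0, abs=1e-10)
    assert res.rotation == pytest.approx(np.eye(3), abs=1e-8)

    rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    b = a @ rot.T + np.array([1.0, -2.0, 3.0])
    res = kabsch_superpose(a, b)
    assert res.global_rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


def test_kabsch_beats_random_rigid_motions():
    """Fitted RMSD is minimal over 1,000 random rigid motions, every instance."""
    rng = np.random.default_rng(1)
    for trial in range(5):
        a = rng.normal(size=(10, 3)) * 5
        b = a + rng.normal(0, 1.0, size=a.shape)
        fitted = kabsch_superpose(a, b).global_rmsd
        for _ in range(1000):
            rot, t = random_rigid(rng)
            rmsd = np.sqrt(((a - (b @ rot.T + t)) ** 2).sum(axis=1).mean())
            assert fitted <= rmsd + 1e-12


def test_kabsch_agrees_with_scipy_align_vectors():
    """Independent cross-check of the fitted rotation against scipy."""
    rng = np.random.default_rng(3)
    a = rng.normal(size=(40, 3)) * 4
    b = a + rng.normal(0, 0.8, size=a.shape)
    res = kabsch_superpose(a, b)
    rot_scipy, _ = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
    assert res.rotation == pytest.approx(rot_scipy.as_matrix(), abs=1e-6)


def test_kabsch_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="at least 3"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="degenerate"):
        kabsch_superpose(line, line)


def test_rmsd_is_symmetric():
    rng = np.random.default_rng(9)
    a = rng.normal(size=(30, 3)) * 3
    b = a + rng.normal(0, 0.5, size=a.shape)
    assert kabsch_superpose(a, b).global_rmsd == pytest.approx(
        kabsch_superpose(b, a).global_rmsd)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_rigid_motion_invariance(seed):
    """RMSD, TM-score and heme stats are unchanged by proper rigid transforms."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(20, 3)) * 6
    b = a + rng.normal(0, 1.0, size=a.shape)
    base = kabsch_superpose(a, b)
    rot, t = random_rigid(rng)
    moved = kabsch_superpose(a, b @ rot.T + t)
    assert moved.global_rmsd == pytest.approx(base.global_rmsd, abs=1e-8)
    assert moved.tm_score == pytest.approx(base.tm_score, abs=1e-8)


# ----------------------------------------------------------------- TM-score


def test_tm_score_closed_forms():
    assert tm_score(np.zeros(407), 407) == 1.0
    assert tm_score(np.full(407, 1e9), 407) == pytest.approx(0.0, abs=1e-12)
    d0 = 1.24 * (407 - 15) ** (1 / 3) - 1.8
    assert tm_score(np.full(407, d0), 407) == pytest.approx(0.5)
    # short targets floor d0 at 0.5 A
    assert tm_score(np.full(10, 0.5), 10) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        tm_score(np.array([]), 10)


def test_deviation_bins_partition():
    assert deviation_bins(np.zeros(5)) == ["blue"] * 5
    assert deviation_bins(np.array([0.1, 1.0, 3.0])) == ["blue", "white", "red"]
    rng = np.random.default_rng(4)
    bins = deviation_bins(rng.exponential(1.0, size=200))
    assert len(bins) == 200 and set(bins) <= {"blue", "white", "red"}
    with pytest.raises(ValueError):
        deviation_bins(np.array([-0.1]))


# ---------------------------------------------------- secondary structure


def test_ss_diff_counts_and_paper_fraction():
    assert ss_diff("HHEE", "HHEE").n_diff == 0
    rng = np.random.default_rng(5)
    a = "".join(rng.choice(list("HEC"), size=407))
    b = list(a)
    for i in rng.choice(407, size=11, replace=False):
        b[i] = {"H": "E", "E": "C", "C": "H"}[a[i]]
    comp = ss_diff(a, "".join(b))
    assert comp.n_diff == 11
    assert round(100 * comp.fraction_diff, 1) == 2.7
    assert sum(comp.transition_counts.values()) == comp.n_diff
    # oracle: brute-force positionwise comparison
    assert comp.n_diff == sum(x != y for x, y in zip(a, "".join(b)))
    with pytest.raises(ValueError):
        ss_diff("HE", "H")


def test_reduce_dssp_mapping():
    assert reduce_dssp("HGIEB TS-") == "HHHEECCCC"


def test_segment_stats_counting_and_identity():
    la, lb, p, flag = segment_stats("EEECEEE", "EEEECEEEE", "E")
    assert (np.mean(la), np.mean(lb)) == (3.0, 4.0)
    la, lb, p, _ = segment_stats("EEECEE", "EEECEE", "E")
    assert p == 1.0  # identical strings: no evidence of change
    _, _, p, flag = segment_stats("CCCC", "CCCC", "E")
    assert np.isnan(p) and flag == "no-segments"
    assert segment_lengths("HHCHHHC", "H") == [2, 3]


def test_segment_stats_detects_planted_strand_elongation():
    """Paired test on rank-matched strand lengths: power > 0.8 at +0.5 residues."""
    rng = np.random.default_rng(6)
    rejections = 0
    trials = 200
    for _ in range(trials):
        lengths_a = rng.integers(3, 9, size=20)
        # +0.5 mean elongation: half the strands gain one residue
        gain = rng.permutation([1] * 10 + [0] * 10)
        lengths_b = lengths_a + gain
        ss_a = "C".join("E" * L for L in lengths_a)
        ss_b = "C".join("E" * L for L in lengths_b)
        pad = len(ss_b) - len(ss_a)
        _, _, p, _ = segment_stats(ss_a + "C" * pad, ss_b, "E")
        if p < 0.05:
            rejections += 1
    assert rejections / trials > 0.8


def test_helix_content_and_change():
    assert helix_content("HHHH") == 100.0
    d, _ = content_change("HHCC", "HCCC")
    assert helix_content("HHCC") == 50.0 and helix_content("HCCC") == 25.0
    assert d == pytest.approx(-25.0)
    with pytest.raises(ValueError):
        helix_content("")


def test_planted_helix_reduction_recovered_in_expectation():
    """A planted -2.4-point helix change is recovered on average over seeds."""
    deltas = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("HEC"), p=[0.4, 0.2, 0.4], size=400))
        b = list(a)
        h_idx = [i for i, c in enumerate(a) if c == "H"]
        k = round(0.024 * 400)  # ~2.4 points of 400 residues
        for i in rng.choice(h_idx, size=k, replace=False):
            b[i] = "C"
        d, _ = content_change(a, "".join(b))
        deltas.append(d)
    assert np.mean(deltas) == pytest.approx(-2.4, abs=0.15)


# -------------------------------------------------------------------- hemes


def _chain_models(n_hemes=6, spacing=11.0):
    fe = np.column_stack([np.arange(n_hemes) * spacing,
                          np.zeros(n_hemes), np.zeros(n_hemes)])
    coords = np.random.default_rng(8).normal(size=(30, 3)) * 5
    a = StructureModel("a", coords, heme_fe=fe)
    return a, fe


def test_heme_identical_and_constructed_shift():
    a, fe = _chain_models()
    b = StructureModel("b", a.ca_coords, heme_fe=fe.copy())
    res = heme_distance_stats(a, b)
    assert res.mean_difference == 0.0
    # stretch every consecutive iron-iron distance by exactly +0.1 A
    fe_b = fe.copy()
    for i in range(1, len(fe_b)):
        fe_b[i:, 0] += 0.1
    res = heme_distance_stats(a, StructureModel("b", a.ca_coords, heme_fe=fe_b))
    assert res.mean_difference == pytest.approx(0.1)
    assert np.all(res.distances_b - res.distances_a == pytest.approx(0.1))


def test_heme_all_pairs_count_and_errors():
    a, fe = _chain_models(n_hemes=5)
    b = StructureModel("b", a.ca_coords, heme_fe=fe + 0.01)
    res = heme_distance_stats(a, b, mode="all-pairs")
    assert len(res.distances_a) == 5 * 4 // 2
    with pytest.raises(ValueError, match="equal heme counts"):
        heme_distance_stats(a, StructureModel("x", a.ca_coords,
                                              heme_fe=fe[:3]))
    with pytest.raises(ValueError, match="mode"):
        heme_distance_stats(a, b, mode="nearest")


# ------------------------------------------------------ generated pairs + IO


def test_generated_pair_localizes_planted_deviations():
    """Post-fit deviation concentrates on the 20 perturbed residues."""
    a, b = generate_structure_pair(200, n_perturbed=20, displacement=3.0, seed=13)
    res = kabsch_superpose(a.ca_coords, b.ca_coords)
    dev = np.sort(res.per_residue_dev)
    # the 180 untouched residues barely move; the 20 perturbed ones dominate
    assert dev[179] < dev[-20] / 3
    assert np.median(dev[-20:]) > 2.0
    assert np.median(dev[:180]) < 0.5


def test_pure_rigid_pair_and_ss_contract():
    a, b = generate_structure_pair(407, n_perturbed=0, n_ss_changes=11,
                                   n_hemes=4, heme_shift=0.0, seed=2)
    res = kabsch_superpose(a.ca_coords, b.ca_coords)
    assert res.global_rmsd == pytest.approx(0.0, abs=1e-8)
    assert ss_diff(a.ss_string, b.ss_string).n_diff == 11
    with pytest.raises(ValueError):
        generate_structure_pair(2)


def test_pdb_and_ss_round_trip(tmp_path):
    a, _ = generate_structure_pair(50, n_hemes=3, seed=4)
    pdb, ssf = tmp_path / "a.pdb", tmp_path / "a.ss"
    write_model_pdb(a, pdb)
    write_ss_string(a.ss_string, ssf)
    back = read_model_pdb(pdb, ss_string=read_ss_string(ssf))
    assert len(back) == 50 and len(back.heme_fe) == 3
    assert back.ca_coords == pytest.approx(a.ca_coords, abs=1e-2)  # PDB precision
    assert back.ss_string == a.ss_string
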