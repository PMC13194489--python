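"""Quantitative divergence between two predicted structures of one protein.

Consumes pre-computed coordinates (Calpha traces), per-residue secondary-
structure strings (3-state H/E/C, reduced from 8-state DSSP as H={H,G,I},
E={E,B}, C=rest) and heme iron coordinates.  Provides optimal rigid-body
superposition (Kabsch), global and per-residue RMSD, TM-score with the
Zhang–Skolnick length normalization, secondary-structure difference
statistics, segment-length and content comparisons, and inter-heme
distance changes.  Residues are matched by index: both models must be
predictions of the same mature sequence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

SS_ALPHABET = frozenset("HEC")

_DSSP_TO_3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def reduce_dssp(ss8: str) -> str:
    """Reduce an 8-state DSSP string to the 3-state H/E/C alphabet."""
    return "".join(_DSSP_TO_3.get(c, "C") for c in ss8.upper())


@dataclass
class StructureModel:
    """A predicted protein model: Calpha trace, SS string, heme irons."""

    id: str
    ca_coords: np.ndarray  # (n_residues, 3), Angstroms
    ss_string: str = ""
    heme_fe: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.heme_fe = np.asarray(self.heme_fe, dtype=float).reshape(-1, 3)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must be (n, 3)")
        if not np.isfinite(self.ca_coords).all() or not np.isfinite(self.heme_fe).all():
            raise ValueError("coordinates must be finite")
        if self.ss_string:
            if len(self.ss_string) != len(self.ca_coords):
                raise ValueError("ss_string length must equal residue count")
            if set(self.ss_string) - SS_ALPHABET:
                raise ValueError("ss_string must be over H/E/C")

    def __len__(self) -> int:
        return len(self.ca_coords)


# ------------------------------------------------------------ superposition


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of matched Calpha sets (B onto A)."""

    rotation: np.ndarray  # (3,3) proper rotation, det = +1
    translation: np.ndarray  # (3,)
    global_rmsd: float
    per_residue_dev: np.ndarray  # (n_aligned,) Angstroms
    tm_score: float
    n_aligned: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted motion to coordinates in B's frame."""
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray,
                     l_target: int | None = None) -> SuperpositionResult:
    """Least-squares optimal superposition of B onto A (Kabsch algorithm).

    Finds the proper rotation R (reflections excluded) and translation t
    minimizing RMSD between A and R·B + t over index-matched points.
    Degenerate (collinear or coincident) inputs raise, since the optimal
    rotation is then not unique.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3) with equal n")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 matched points to superpose")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    spread = np.linalg.svd(a0, compute_uv=False)
    if spread[1] < 1e-9 * max(spread[0], 1.0):
        raise ValueError(
            "degenerate (collinear/coincident) points: rotation not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb

    b_fit = b @ rot.T + trans
    dev = np.linalg.norm(a - b_fit, axis=1)
    rmsd = float(np.sqrt((dev**2).mean()))
    lt = l_target if l_target is not None else n
    return SuperpositionResult(rot, trans, rmsd, dev, tm_score(dev, lt), n)


def tm_score(per_residue_dev: np.ndarray, l_target: int) -> float:
    """Template-modeling score from post-superposition deviations.

    score = (1/L) * sum_i 1/(1 + (d_i/d0)^2) with
    d0 = 1.24*(L-15)^(1/3) - 1.8 Angstroms, clamped to >= 0.5 for short
    targets.  Normalization length L defaults (upstream) to the reference
    model, making the score mildly asymmetric in the usual way.
    """
    dev = np.asarray(per_residue_dev, dtype=float)
    if dev.size == 0:
        raise ValueError("empty deviation list")
    if l_target < 1:
        raise ValueError("l_target must be positive")
    d0 = 1.24 * max(l_target - 15, 0) ** (1.0 / 3.0) - 1.8
    d0 = max(d0, 0.5)
    return float(np.sum(1.0 / (1.0 + (dev / d0) ** 2)) / l_target)


def deviation_bins(per_residue_dev: np.ndarray,
                   thresholds: tuple[float, float] = (0.5, 2.0)) -> list[str]:
    """Classify per-residue deviations into blue/white/red similarity bins.

    Defaults follow the common superposition-coloring convention:
    blue < 0.5 A (highest similarity), white 0.5-2 A, red > 2 A.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must be increasing")
    dev = np.asarray(per_residue_dev, dtype=float)
    if (dev < 0).any():
        raise ValueError("deviations must be non-negative")
    return ["blue" if d < lo else "white" if d <= hi else "red" for d in dev]


# ------------------------------------------------------ secondary structure


@dataclass
class SSComparison:
    n_positions: int
    n_diff: int
    transition_counts: dict[tuple[str, str], int]
    mean_strand_len: tuple[float, float] | None = None
    mean_helix_content: tuple[float, float] | None = None
    strand_len_p: float | None = None
    helix_content_p: float | None = None

    @property
    def fraction_diff(self) -> float:
        return self.n_diff / self.n_positions


def ss_diff(ss_a: str, ss_b: str) -> SSComparison:
    """Position-wise secondary-structure differences between two models.

    Returns the count and fraction of differing positions plus a tally of
    (class_a -> class_b) transitions at those positions, and the per-model
    mean strand length and helix content.
    """
    if len(ss_a) != len(ss_b):
        raise ValueError("SS strings must have equal length")
    if not ss_a:
        raise ValueError("empty SS strings")
    for s in (ss_a, ss_b):
        if set(s) - SS_ALPHABET:
            raise ValueError("SS strings must be over H/E/C")
    transitions: dict[tuple[str, str], int] = {}
    n_diff = 0
    for x, y in zip(ss_a, ss_b):
        if x != y:
            n_diff += 1
            transitions[(x, y)] = transitions.get((x, y), 0) + 1
    mean_strand = tuple(
        float(np.mean(L)) if (L := segment_lengths(s, "E")) else 0.0
        for s in (ss_a, ss_b)
    )
    return SSComparison(
        n_positions=len(ss_a),
        n_diff=n_diff,
        transition_counts=transitions,
        mean_strand_len=mean_strand,
        mean_helix_content=(helix_content(ss_a), helix_content(ss_b)),
    )


def segment_lengths(ss: str, cls: str) -> list[int]:
    """Lengths of maximal runs of one SS class, N- to C-terminal order."""
    return [len(list(g)) for k, g in itertools.groupby(ss) if k == cls]


def segment_stats(ss_a: str, ss_b: str, cls: str = "E"):
    """Segment-length comparison for one SS class between two models.

    Runs of ``cls`` are extracted per model and paired by rank order after
    equalizing counts (longest with longest, ...); a paired t-test is run
    on the matched lengths.  When segment counts differ the extra segments
    are dropped and the result is flagged ('rank-paired-truncated'); with
    no segments in either model the p-value is undefined (nan).

    Returns (lengths_a, lengths_b, p_value, pairing_flag).
    """
    if cls not in ("H", "E"):
        raise ValueError("segment class must be 'H' or 'E'")
    la, lb = segment_lengths(ss_a, cls), segment_lengths(ss_b, cls)
    if not la and not lb:
        return la, lb, float("nan"), "no-segments"
    k = min(len(la), len(lb))
    flag = "rank-paired" if len(la) == len(lb) else "rank-paired-truncated"
    if k < 2:
        return la, lb, float("nan"), flag + "-too-few"
    xa = sorted(la, reverse=True)[:k]
    xb = sorted(lb, reverse=True)[:k]
    if xa == xb:
        return la, lb, 1.0, flag  # identical matched lengths: no evidence
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-tied lengths
        p = float(stats.ttest_rel(xa, xb).pvalue)
    return la, lb, p, flag


def helix_content(ss: str) -> float:
    """Percent of residues assigned helix (H)."""
    if not ss:
        raise ValueError("empty SS string")
    return 100.0 * ss.count("H") / len(ss)


def content_change(ss_a: str, ss_b: str, cls: str = "H",
                   window: int = 50) -> tuple[float, float]:
    """Change in SS-class content (b - a, percentage points) with a test.

    The test is a paired t-test on per-window class proportions over
    non-overlapping windows of ``window`` residues (same partition in both
    models).  Returns (delta_percent, p_value); p is nan when fewer than
    two windows or no variation.
    """
    if len(ss_a) != len(ss_b):
        raise ValueError("SS strings must have equal length")
    pa = 100.0 * ss_a.count(cls) / len(ss_a)
    pb = 100.0 * ss_b.count(cls) / len(ss_b)
    wa = [s.count(cls) / len(s) for s in _windows(ss_a, window)]
    wb = [s.count(cls) / len(s) for s in _windows(ss_b, window)]
    if len(wa) < 2 or wa == wb:
        return pb - pa, float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-identical windows
        p = float(stats.ttest_rel(wa, wb).pvalue)
    return pb - pa, p


def _windows(s: str, w: int) -> list[str]:
    if w < 1:
        raise ValueError("window must be >= 1")
    return [s[i : i + w] for i in range(0, len(s) - w + 1, w)] or [s]


# ------------------------------------------------------------------- hemes


@dataclass
class HemeComparison:
    """Inter-heme (iron-iron) distance comparison between two models."""

    distances_a: np.ndarray
    distances_b: np.ndarray
    mean_difference: float  # b - a, Angstroms (signed)
    p_value: float
    pairing_mode: str


def _heme_pair_distances(fe: np.ndarray, mode: str) -> np.ndarray:
    if mode == "consecutive":
        return np.linalg.norm(np.diff(fe, axis=0), axis=1)
    if mode == "all-pairs":
        idx = list(itertools.combinations(range(len(fe)), 2))
        return np.array([np.linalg.norm(fe[i] - fe[j]) for i, j in idx])
    raise ValueError("mode must be 'consecutive' or 'all-pairs'")


def heme_distance_stats(model_a: StructureModel, model_b: StructureModel,
                        mode: str = "consecutive") -> HemeComparison:
    """Compare inter-heme iron distances between index-matched heme sets.

    'consecutive' pairs sequence-adjacent hemes (the wire geometry);
    'all-pairs' compares the full distance matrix.  The signed mean
    difference is model_b - model_a, with a paired t-test across matched
    pairs (nan when fewer than two pairs or no variation).
    """
    if len(model_a.heme_fe) != len(model_b.heme_fe):
        raise ValueError("models must carry equal heme counts, index-matched")
    if len(model_a.heme_fe) < 2:
        raise ValueError("need at least two hemes for distance statistics")
    da = _heme_pair_distances(model_a.heme_fe, mode)
    db = _heme_pair_distances(model_b.heme_fe, mode)
    diff = db - da
    if len(diff) < 2 or np.allclose(diff.std(), 0):
        p = float("nan") if not np.allclose(diff, 0) else 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_rel(db, da).pvalue)
    return HemeComparison(da, db, float(diff.mean()), p, mode)


# --------------------------------------------------------------------- I/O


def write_model_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a Calpha-trace PDB with heme irons as HETATM FE (resname HEC)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_res, n_heme = len(model.ca_coords), len(model.heme_fe)
    arr = struc.AtomArray(n_res + n_heme)
    arr.coord = np.vstack([model.ca_coords, model.heme_fe]) if n_heme else \
        model.ca_coords.copy()
    arr.chain_id[:] = "A"
    arr.res_id[:n_res] = np.arange(1, n_res + 1)
    arr.res_name[:n_res] = "GLY"
    arr.atom_name[:n_res] = "CA"
    arr.element[:n_res] = "C"
    arr.hetero[:n_res] = False
    if n_heme:
        arr.res_id[n_res:] = np.arange(n_res + 1, n_res + n_heme + 1)
        arr.res_name[n_res:] = "HEC"
        arr.atom_name[n_res:] = "FE"
        arr.element[n_res:] = "FE"
        arr.hetero[n_res:] = True
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_model_pdb(path: str | Path, model_id: str | None = None,
                   ss_string: str = "") -> StructureModel:
    """Read a model back: CA atoms by residue order, HETATM FE of HEM/HEC."""
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    ca = arr[(arr.atom_name == "CA") & ~arr.hetero]
    fe = arr[(arr.atom_name == "FE") & np.isin(arr.res_name, ("HEM", "HEC"))]
    return StructureModel(
        id=model_id or Path(path).stem,
        ca_coords=ca.coord[np.argsort(ca.res_id, kind="stable")],
        ss_string=ss_string,
        heme_fe=fe.coord[np.argsort(fe.res_id, kind="stable")],
    )


def read_ss_string(path: str | Path) -> str:
    """Read a plain-text SS file (one letter per residue, whitespace ignored)."""
    text = "".join(Path(path).read_text().split()).upper()
    if set(text) - SS_ALPHABET:
        return reduce_dssp(text)
    return text


def write_ss_string(ss: str, path: str | Path) -> None:
    Path(path).write_text(ss + "\n")


def comparison_report(model_a: StructureModel, model_b: StructureModel,
                      heme_mode: str = "consecutive") -> dict:
    """All structure-divergence statistics for one model pair, one dict row each.

    Keys: rmsd, tm_score, n_aligned, ss_n_diff, ss_fraction_diff,
    mean_strand_len_{a,b}, strand_len_p, helix_content_{a,b},
    helix_content_change, helix_content_p, heme_mean_difference, heme_p.
    """
    if len(model_a) != len(model_b):
        raise ValueError("models must have equal residue counts")
    sup = kabsch_superpose(model_a.ca_coords, model_b.ca_coords)
    out = {
        "rmsd": sup.global_rmsd,
        "tm_score": sup.tm_score,
        "n_aligned": sup.n_aligned,
    }
    if model_a.ss_string and model_b.ss_string:
        comp = ss_diff(model_a.ss_string, model_b.ss_string)
        _, _, strand_p, _ = segment_stats(model_a.ss_string, model_b.ss_string, "E")
        delta, helix_p = content_change(model_a.ss_string, model_b.ss_string, "H")
        out.update({
            "ss_n_diff": comp.n_diff,
            "ss_fraction_diff": comp.fraction_diff,
            "mean_strand_len_a": comp.mean_strand_len[0],
            "mean_strand_len_b": comp.mean_strand_len[1],
            "strand_len_p": strand_p,
            "helix_content_a": comp.mean_helix_content[0],
            "helix_content_b": comp.mean_helix_content[1],
            "helix_content_change": delta,
            "helix_content_p": helix_p,
        })
    if len(model_a.heme_fe) >= 2 and len(model_a.heme_fe) == len(model_b.heme_fe):
        hc = heme_distance_stats(model_a, model_b, heme_mode)
        out.update({
            "heme_mean_difference": hc.mean_difference,
            "heme_p": hc.p_value,
        })
    return out
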