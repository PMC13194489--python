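"""Synthetic inputs with planted ground truth for every pipeline stage.

This module emulates the data regime of a long-term clonal anode-adaptation
experiment at desk scale: a small annotated bacterial genome; descendant
lineages carrying on the order of 10^2 SNPs with controlled
transition/transversion ratio (kappa), dN/dS (omega), nonsense fraction
(lof_rate) and planted hotspot genes and deletions; paired toy protein
models with localized coordinate and secondary-structure perturbations
plus heme pseudo-atoms; qRT-PCR CT tables with a housekeeping gene; and
exponential growth curves with multiplicative noise.

Substitutions are planted by accept/reject on the candidate change's
effect given the current codon (not by per-site rate matrices), so every
planted event has an exactly auditable class; the truth table records all
of them for oracle cross-checks downstream.

All randomness flows from one integer seed through named counter-based
substreams, so each generator is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, CDSFeature, revcomp
from .mutstats import AlignmentBlock, genome_site_totals
from .structure import StructureModel
from .variants import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, VariantRecord

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


class ScenarioError(ValueError):
    """A simulation scenario is internally inconsistent or unsatisfiable."""


def spawn_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, reproducible generator for one named substream."""
    key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,)))


# ------------------------------------------------------------------ scenario


@dataclass(frozen=True)
class EvolutionScenario:
    """Parameters of one ancestor -> descendant simulation.

    Defaults emulate the regime of a recently diverged anode-adapted
    lineage: ~120 SNPs against a parent of a few hundred genes, a
    transition-rich spectrum (kappa ~ 2.8), dN/dS below 1 but far above
    the deep-divergence purifying regime (omega ~ 0.78), and a marked
    nonsense load.  ``kappa`` is the target transition/transversion COUNT
    ratio; ``lof_rate`` the fraction of coding SNPs planted as nonsense;
    ``indel_rate`` adds 1-bp frameshift deletions (as a fraction of
    n_snps) on top of the SNP budget.
    """

    n_genes: int = 40
    mean_gene_len: int = 300  # codons, including start and stop
    len_sd: float = 0.0  # codon-count sd; 0 = constant gene length
    intergenic_frac: float = 0.12
    n_snps: int = 120
    kappa: float = 2.76
    omega: float = 0.776
    lof_rate: float = 0.10
    indel_rate: float = 0.0
    hotspot_loci: tuple = ()  # ((locus_id_or_index, multiplier), ...)
    deletion_spans: tuple = ()  # lengths in bp, planted in intergenic spacers
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 0:
            raise ScenarioError("n_snps must be >= 0")
        if not 0 <= self.lof_rate <= 1:
            raise ScenarioError("lof_rate must be in [0, 1]")
        if not 0 <= self.indel_rate <= 1:
            raise ScenarioError("indel_rate must be in [0, 1]")
        if self.kappa <= 0 or self.omega <= 0:
            raise ScenarioError("kappa and omega must be positive")
        if not 0 <= self.intergenic_frac < 1:
            raise ScenarioError("intergenic_frac must be in [0, 1)")
        for _, mult in self.hotspot_loci:
            if mult < 1:
                raise ScenarioError("hotspot multipliers must be >= 1")
        if any(s < 1 for s in self.deletion_spans):
            raise ScenarioError("deletion spans must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """One planted variant with its ground-truth classification."""

    position: int  # 1-based, ancestor coordinates
    ref_allele: str
    alt_allele: str
    locus_id: str | None
    effect: str
    is_transition: bool | None  # None for indels

    def to_variant(self) -> VariantRecord:
        return VariantRecord(self.position, self.ref_allele, self.alt_allele)


@dataclass
class TruthTable:
    """Planted ground truth of one evolved lineage."""

    records: list[TruthRecord] = field(default_factory=list)
    deleted_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return sum(1 for r in self.records if r.is_transition is not None)

    @property
    def n_indels(self) -> int:
        return sum(1 for r in self.records if r.is_transition is None)

    @property
    def n_transitions(self) -> int:
        return sum(1 for r in self.records if r.is_transition)

    @property
    def n_transversions(self) -> int:
        return sum(1 for r in self.records if r.is_transition is False)

    def count(self, effect: str) -> int:
        return sum(1 for r in self.records if r.effect == effect)

    @property
    def n_functional(self) -> int:
        return sum(1 for r in self.records
                   if r.effect not in ("synonymous", "intergenic"))

    @property
    def n_lof(self) -> int:
        return sum(1 for r in self.records
                   if r.effect in ("nonsense", "frameshift", "start_loss"))

    def per_gene_functional(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            if r.locus_id and r.effect not in ("synonymous", "intergenic"):
                out[r.locus_id] = out.get(r.locus_id, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"position": r.position, "ref": r.ref_allele, "alt": r.alt_allele,
                 "locus_id": r.locus_id or "intergenic", "effect": r.effect,
                 "is_transition": r.is_transition} for r in self.records]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- ancestor genome


def generate_ancestral_genome(scenario: EvolutionScenario) -> AnnotatedGenome:
    """A random annotated genome matching the scenario's gene geometry.

    Genes start with ATG, end with a stop codon, have length = 0 mod 3,
    sit on both strands with internal codons drawn uniformly over the 61
    sense codons, and are separated by random intergenic spacers summing
    to the requested fraction of the genome.  Deterministic for a fixed
    scenario seed.
    """
    if scenario.n_genes < 1:
        raise ScenarioError("need at least one gene")
    if scenario.mean_gene_len < 3:
        raise ScenarioError("genes need >= 3 codons (start, sense, stop)")
    rng = spawn_rng(scenario.seed, "ancestor")

    if scenario.len_sd > 0:
        codons = np.maximum(
            4, np.rint(rng.normal(scenario.mean_gene_len, scenario.len_sd,
                                  scenario.n_genes)).astype(int))
    else:
        codons = np.full(scenario.n_genes, scenario.mean_gene_len, dtype=int)

    coding_total = int(3 * codons.sum())
    frac = scenario.intergenic_frac
    intergenic_total = int(round(coding_total * frac / (1.0 - frac)))
    n_spacers = scenario.n_genes + 1

    # reserve room so every requested deletion span fits inside one spacer
    reserved = np.zeros(n_spacers, dtype=int)
    spans = sorted(scenario.deletion_spans, reverse=True)
    if spans:
        if len(spans) > n_spacers:
            raise ScenarioError("more deletion spans than intergenic spacers")
        need = [s + 10 for s in spans]
        if sum(need) > intergenic_total:
            raise ScenarioError(
                f"deletion spans total {sum(spans)} bp exceed the intergenic "
                f"budget {intergenic_total} bp; raise intergenic_frac")
        hosts = rng.choice(n_spacers, size=len(spans), replace=False)
        reserved[hosts] = need
    remaining = intergenic_total - int(reserved.sum())
    base, extra = divmod(remaining, n_spacers)
    spacer_lens = reserved + base
    if extra:
        spacer_lens[rng.choice(n_spacers, size=extra, replace=False)] += 1

    stop_codons = sorted(STOP_CODONS)
    parts: list[str] = []
    features: list[CDSFeature] = []
    pos = 0
    for i in range(scenario.n_genes):
        spacer = "".join(rng.choice(list(_BASES), size=spacer_lens[i]))
        parts.append(spacer)
        pos += spacer_lens[i]
        n_cod = int(codons[i])
        body = "".join(rng.choice(SENSE_CODONS, size=n_cod - 2))
        cds = "ATG" + body + stop_codons[rng.integers(len(stop_codons))]
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(cds if strand == "+" else revcomp(cds))
        features.append(CDSFeature(f"G{i:04d}", pos + 1, pos + len(cds), strand,
                                   "hypothetical protein"))
        pos += len(cds)
    parts.append("".join(rng.choice(list(_BASES), size=spacer_lens[-1])))
    return AnnotatedGenome("synthchr1", "".join(parts), features)


# ------------------------------------------------------------ lineage evolution


def _mutate_base(base: str, want_ts: bool, rng: np.random.Generator) -> str:
    if want_ts:
        return _TRANSITION[base]
    tv = _TRANSVERSIONS[base]
    return tv[rng.integers(2)]


def evolve_lineage(genome: AnnotatedGenome, scenario: EvolutionScenario,
                   max_tries: int = 4000):
    """Plant SNPs, frameshift indels and deletions into a descendant lineage.

    Substitution classes are planted so that the realized Ts/Tv count
    ratio ~ kappa and the realized genome-wide dN/dS ~ omega (within
    multinomial sampling error), hotspot loci draw functional SNPs at
    multiplier x their length-proportional share, and deletion spans are
    excised from intergenic spacers after substitution.  Genes hit by a
    frameshift are dropped from the descendant's annotation (pseudogenes).

    Returns (descendant AnnotatedGenome, list[VariantRecord], TruthTable).
    """
    rng = spawn_rng(scenario.seed, "lineage")
    seq = genome.sequence
    genes = list(genome.features)

    if scenario.n_snps > 0 and not genes and scenario.intergenic_frac < 1:
        raise ScenarioError("no coding sites: omega target unreachable")

    if genes:
        S, N = genome_site_totals(genome)
        f_nonsyn = scenario.omega * N / (scenario.omega * N + S)
    else:
        f_nonsyn = 0.0
    f_nonsense = scenario.lof_rate
    f_missense = f_nonsyn - f_nonsense
    if f_missense < 0:
        raise ScenarioError(
            f"lof_rate {scenario.lof_rate} exceeds the coding nonsynonymous "
            f"fraction {f_nonsyn:.3f} implied by omega={scenario.omega}")
    f_syn = 1.0 - f_nonsyn

    coding_len = sum(f.length for f in genes)
    genome_len = len(seq)
    p_coding = coding_len / genome_len

    multipliers = _resolve_hotspots(scenario.hotspot_loci, genes)
    w_syn = np.array([f.length for f in genes], dtype=float)
    w_func = np.array([f.length * multipliers.get(f.locus_id, 1.0) for f in genes])
    cds_cache = {f.locus_id: f.cds_sequence(seq) for f in genes}

    # deletions are excised from intergenic spacers; choose their intervals
    # first so no substitution lands inside a region absent from the descendant
    intergenic = genome.intergenic_intervals()
    deleted = _place_deletions(scenario, intergenic, rng)
    inter_keep = [
        np.arange(a, b + 1) for a, b in intergenic
    ]
    inter_pool = (np.concatenate(inter_keep) if inter_keep
                  else np.array([], dtype=int))
    if deleted:
        cut = np.concatenate([np.arange(a, b + 1) for a, b in deleted])
        inter_pool = np.setdiff1d(inter_pool, cut)

    p_ts = scenario.kappa / (1.0 + scenario.kappa)
    used_positions: set[int] = set()
    records: list[TruthRecord] = []

    def sample_coding(category: str, want_ts: bool) -> TruthRecord | None:
        weights = w_syn if category == "synonymous" else w_func
        probs = weights / weights.sum()
        for _ in range(max_tries):
            gi = rng.choice(len(genes), p=probs)
            f = genes[gi]
            cds = cds_cache[f.locus_id]
            n_cod = len(cds) // 3
            ci = int(rng.integers(1, n_cod - 1))  # exclude start & stop codons
            off = int(rng.integers(3))
            codon = cds[3 * ci : 3 * ci + 3]
            alt_base = _mutate_base(codon[off], want_ts, rng)
            alt_codon = codon[:off] + alt_base + codon[off + 1:]
            aa_ref, aa_alt = CODON_TO_AA[codon], CODON_TO_AA[alt_codon]
            effect = ("synonymous" if aa_ref == aa_alt
                      else "nonsense" if aa_alt == "*" else "missense")
            if effect != category:
                continue
            local = 3 * ci + off
            if f.strand == "+":
                pos = f.start + local
                ref_fwd, alt_fwd = codon[off], alt_base
            else:
                pos = f.end - local
                ref_fwd, alt_fwd = revcomp(codon[off]), revcomp(alt_base)
            if pos in used_positions:
                continue
            return TruthRecord(pos, ref_fwd, alt_fwd, f.locus_id, effect, want_ts)
        return None

    for _ in range(scenario.n_snps):
        want_ts = bool(rng.random() < p_ts)
        if rng.random() >= p_coding or not genes:
            # intergenic placement
            for _ in range(max_tries):
                pos = int(inter_pool[rng.integers(len(inter_pool))])
                if pos not in used_positions:
                    break
            else:
                raise ScenarioError("intergenic space exhausted")
            ref = seq[pos - 1]
            rec = TruthRecord(pos, ref, _mutate_base(ref, want_ts, rng),
                              None, "intergenic", want_ts)
        else:
            u = rng.random()
            category = ("nonsense" if u < f_nonsense
                        else "missense" if u < f_nonsense + f_missense
                        else "synonymous")
            rec = sample_coding(category, want_ts)
            if rec is None:  # the ts/tv constraint can rarely be unsatisfiable
                rec = sample_coding(category, not want_ts)
            if rec is None:
                raise ScenarioError(
                    f"could not place a {category} substitution; "
                    "genome too small for the requested scenario")
        used_positions.add(rec.position)
        records.append(rec)

    # 1-bp frameshift deletions in CDS interiors
    n_indels = int(round(scenario.indel_rate * scenario.n_snps))
    frameshifted: set[str] = set()
    for _ in range(n_indels):
        probs = w_func / w_func.sum()
        for _ in range(max_tries):
            gi = rng.choice(len(genes), p=probs)
            f = genes[gi]
            n_cod = f.length // 3
            ci = int(rng.integers(1, n_cod - 1))
            pos = f.start + 3 * ci + int(rng.integers(3))  # forward coordinate
            if pos in used_positions or (pos - 1) in used_positions or pos <= f.start:
                continue
            anchor = seq[pos - 2 : pos]  # REF = anchor+deleted, ALT = anchor
            records.append(TruthRecord(pos - 1, anchor, anchor[0],
                                       f.locus_id, "frameshift", None))
            used_positions.update({pos, pos - 1})
            frameshifted.add(f.locus_id)
            break
        else:
            raise ScenarioError("could not place a frameshift indel")

    descendant = _build_descendant(genome, records, deleted, frameshifted)
    records.sort(key=lambda r: r.position)
    truth = TruthTable(records, deleted)
    variants = [r.to_variant() for r in records]
    return descendant, variants, truth


def _resolve_hotspots(hotspot_loci, genes) -> dict[str, float]:
    by_id = {f.locus_id for f in genes}
    out: dict[str, float] = {}
    for locus, mult in hotspot_loci:
        if isinstance(locus, int):
            locus = genes[locus].locus_id
        if locus not in by_id:
            raise ScenarioError(f"hotspot locus {locus!r} not in genome")
        out[locus] = float(mult)
    return out


def _place_deletions(scenario, intergenic, rng):
    deleted: list[tuple[int, int]] = []
    free = list(intergenic)
    for span in sorted(scenario.deletion_spans, reverse=True):
        candidates = [iv for iv in free if iv[1] - iv[0] + 1 >= span]
        if not candidates:
            raise ScenarioError(
                f"deletion span {span} does not fit in intergenic sequence")
        a, b = candidates[int(rng.integers(len(candidates)))]
        slack = (b - a + 1) - span
        start = a + int(rng.integers(slack + 1))
        interval = (start, start + span - 1)
        deleted.append(interval)
        free.remove((a, b))
        if a < interval[0]:
            free.append((a, interval[0] - 1))
        if interval[1] < b:
            free.append((interval[1] + 1, b))
    return sorted(deleted)


def _build_descendant(genome, records, deleted, frameshifted):
    seq = list(genome.sequence)
    drop = np.zeros(len(seq) + 2, dtype=bool)
    for r in records:
        if r.is_transition is not None:  # SNP
            seq[r.position - 1] = r.alt_allele
        else:  # anchored 1-bp deletion: the base after the anchor is lost
            drop[r.position + 1] = True
    for a, b in deleted:
        drop[a : b + 1] = True
    kept = [s for i, s in enumerate(seq, start=1) if not drop[i]]
    shift = np.cumsum(drop[: len(seq) + 1])  # deletions at or before each position

    feats = []
    for f in genome.features:
        if f.locus_id in frameshifted:
            continue  # pseudogene in the descendant
        if drop[f.start : f.end + 1].any():
            continue  # partially deleted gene (not produced by default scenarios)
        feats.append(CDSFeature(f.locus_id, f.start - int(shift[f.start]),
                                f.end - int(shift[f.end]), f.strand, f.product))
    return AnnotatedGenome(genome.id + "_desc", "".join(kept), feats)


def alignment_blocks_from_deletions(deleted_intervals, ref_length: int
                                    ) -> list[AlignmentBlock]:
    """Colinear alignment blocks implied by a set of reference deletions.

    The descendant aligns to the reference in blocks separated by the
    deleted intervals; query coordinates shift left by the cumulative
    deleted length.  Small (e.g. 1-bp) indels are treated as within-block
    noise, as a whole-genome aligner would.
    """
    blocks = []
    cursor, removed = 1, 0
    for a, b in sorted(deleted_intervals):
        if a > cursor:
            blocks.append(AlignmentBlock(cursor, a - 1, cursor - removed,
                                         a - 1 - removed, "+"))
        removed += b - a + 1
        cursor = b + 1
    if cursor <= ref_length:
        blocks.append(AlignmentBlock(cursor, ref_length, cursor - removed,
                                     ref_length - removed, "+"))
    return blocks


# ------------------------------------------------------------- structure pair


def generate_structure_pair(length: int, n_perturbed: int = 0,
                            displacement: float = 0.0, n_ss_changes: int = 0,
                            n_hemes: int = 0, heme_shift: float = 0.0,
                            seed: int = 0) -> tuple[StructureModel, StructureModel]:
    """A matched pair of toy Calpha models with planted divergence.

    Model B is a random proper rigid transform of model A, plus Gaussian
    coordinate noise (per-component sd = ``displacement``) at exactly
    ``n_perturbed`` residues, a secondary-structure string differing at
    exactly ``n_ss_changes`` positions, and each heme iron displaced by
    exactly ``heme_shift`` Angstroms in a random direction.
    """
    if length < 3:
        raise ValueError("need at least 3 residues for a meaningful geometry")
    if n_perturbed > length or n_ss_changes > length:
        raise ValueError("perturbation counts cannot exceed the chain length")
    rng = spawn_rng(seed, "structure")

    # smooth random chain, 3.8 A virtual bonds with directional persistence
    coords = np.zeros((length, 3))
    direction = _unit(rng.normal(size=3))
    for i in range(1, length):
        direction = _unit(direction + 0.45 * rng.normal(size=3))
        coords[i] = coords[i - 1] + 3.8 * direction

    ss = _random_ss(length, rng)

    heme_a = np.zeros((n_hemes, 3))
    if n_hemes:
        anchors = np.sort(rng.choice(length, size=n_hemes, replace=False))
        heme_a = coords[anchors] + rng.normal(0, 2.0, size=(n_hemes, 3))

    coords_b = coords.copy()
    if n_perturbed:
        idx = rng.choice(length, size=n_perturbed, replace=False)
        coords_b[idx] += rng.normal(0, displacement, size=(n_perturbed, 3))
    ss_b = list(ss)
    if n_ss_changes:
        for i in rng.choice(length, size=n_ss_changes, replace=False):
            ss_b[i] = rng.choice([c for c in "HEC" if c != ss[i]])
    ss_b = "".join(ss_b)
    heme_b = heme_a.copy()
    if n_hemes and heme_shift:
        for i in range(n_hemes):
            heme_b[i] += heme_shift * _unit(rng.normal(size=3))

    rot = _random_rotation(rng)
    trans = rng.normal(0, 20.0, size=3)
    coords_b = coords_b @ rot.T + trans
    heme_b = heme_b @ rot.T + trans if n_hemes else heme_b

    return (StructureModel("model_a", coords, ss, heme_a),
            StructureModel("model_b", coords_b, ss_b, heme_b))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _random_ss(length: int, rng: np.random.Generator) -> str:
    out: list[str] = []
    while len(out) < length:
        cls = rng.choice(list("HEC"), p=[0.35, 0.25, 0.40])
        run = int(rng.integers(3, 11)) if cls in "HE" else int(rng.integers(1, 8))
        out.extend(cls * run)
    return "".join(out[:length])


# ------------------------------------------------------------------ CT tables


def generate_ct_table(strains: list[str], genes: list[str],
                      true_folds: dict, housekeeping_ct: float = 16.0,
                      noise_sd: float = 0.3, replicates: int = 3,
                      seed: int = 0, condition: str = "fumarate",
                      housekeeping_gene: str = "recA") -> pd.DataFrame:
    """A qRT-PCR CT table whose 2^-ddCT analysis recovers planted folds.

    ``true_folds`` maps (strain, gene) to the fold change relative to the
    first strain in ``strains`` (the reference; unlisted pairs default to
    1).  Each sample gets a common loading offset (so only CT differences
    are meaningful) and Gaussian cycle noise of sd ``noise_sd``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for key, fold in true_folds.items():
        if fold <= 0:
            raise ValueError(f"true fold for {key} must be positive")
    rng = spawn_rng(seed, "ct")
    base_ct = {g: float(rng.uniform(18, 26)) for g in genes}
    rows = []
    for strain in strains:
        for rep in range(1, replicates + 1):
            offset = float(rng.normal(0, 0.5))
            rows.append({"strain": strain, "condition": condition,
                         "gene": housekeeping_gene, "replicate": rep,
                         "ct": housekeeping_ct + offset + float(rng.normal(0, noise_sd))})
            for gene in genes:
                fold = float(true_folds.get((strain, gene), 1.0))
                ct = base_ct[gene] - np.log2(fold) + offset
                rows.append({"strain": strain, "condition": condition,
                             "gene": gene, "replicate": rep,
                             "ct": ct + float(rng.normal(0, noise_sd))})
    return pd.DataFrame(rows)


# --------------------------------------------------------------- growth curves


def generate_growth_curves(k_per_strain: dict[str, float], y0: float = 0.01,
                           t_grid=None, noise_sd: float = 0.0,
                           replicates: int = 3, seed: int = 0,
                           unit: str = "per-day",
                           acceptor: str = "Fe(III) oxide",
                           plateau: float | None = None) -> pd.DataFrame:
    """Exponential growth/reduction curves y0*exp(k t)*(1+eps) per strain.

    ``t_grid`` must be strictly increasing (default 0..10 in 11 steps).
    ``plateau`` caps the noiseless trajectory (late-phase saturation).
    Returns a long table (strain, acceptor, replicate, time, value, unit).
    """
    t = np.asarray([0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10] if t_grid is None else t_grid,
                   dtype=float)
    if t.size == 0:
        raise ValueError("t_grid must be nonempty")
    if t.size > 1 and (np.diff(t) <= 0).any():
        raise ValueError("t_grid must be strictly increasing")
    rng = spawn_rng(seed, "growth")
    rows = []
    for strain, k in k_per_strain.items():
        if not np.isfinite(k):
            raise ValueError(f"rate for {strain} must be finite")
        for rep in range(1, replicates + 1):
            y = y0 * np.exp(k * t)
            if plateau is not None:
                y = np.minimum(y, plateau)
            if noise_sd > 0:
                y = y * (1.0 + rng.normal(0, noise_sd, size=t.shape))
                y = np.maximum(y, 1e-12)
            for ti, yi in zip(t, y):
                rows.append({"strain": strain, "acceptor": acceptor,
                             "replicate": rep, "time": float(ti),
                             "value": float(yi), "unit": unit})
    return pd.DataFrame(rows)
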