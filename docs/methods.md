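# Methods

This note documents the models, conventions, defaults and numerical
choices behind each module, and what the synthetic-data generator does
and does not emulate.

## Coordinate and annotation conventions

All genomic coordinates are 1-based inclusive (GFF3/VCF convention);
variant alleles are given on the forward strand, indels VCF-anchored
(REF=`AC`, ALT=`A` deletes one base).  CDS features must have length
divisible by 3; translation uses NCBI table 11, with any annotated start
codon (ATG/GTG/TTG/…) read as Met.  A variant in the start codon that
leaves a valid initiator is called synonymous; one that destroys it is a
start-loss.  Multi-nucleotide same-length substitutions are classified
jointly from the composite codon(s), not per base.  Variants falling in
overlapping CDS are annotated once per locus but counted once in
genome-wide totals (the functional call wins when calls differ).

Effect classes partition exhaustively: synonymous, missense, nonsense,
start_loss, stop_loss, frameshift, inframe_indel, intergenic.
**Functional** = any class altering the protein (everything except
synonymous and intergenic).  **LOF** = nonsense + frameshift +
start_loss; stop-loss is functional but not LOF, following the
convention of standard prokaryotic annotators.  Amino-acid *category
changes* use a six-class physicochemical scheme — nonpolar-aliphatic
(AVLIM), aromatic (FYW), polar-uncharged (STNQ), positive (KRH),
negative (DE), special (CGP) — chosen so that, e.g., proline→alanine
counts as a category change; the scheme is a documented default, not a
universal standard, and is switchable by editing `AA_CATEGORIES`.

## Census statistics

**Ts/Tv** counts SNPs only (A↔G, C↔T transitions); the ratio is flagged
infinite when no transversion was observed.

**dN/dS** uses Nei–Gojobori equal-pathway site counting: each codon
position contributes (synonymous single-base neighbors)/3 synonymous
sites, mutations to stop counting as nonsynonymous, so every sense codon
carries exactly 3 sites.  N and S are summed over every sense codon of
every reference CDS (terminal stop codons carry no sense sites);
N_d and S_d are observed SNP counts (nonsynonymous = missense +
nonsense + stop-loss + start-loss).  No multiple-hit correction is
applied by default: at the divergences this package targets
(10⁻⁵–10⁻³ substitutions/site) the Jukes–Cantor correction is far below
counting noise; `jukes_cantor=True` enables it.  A set with no
synonymous substitutions yields an undefined (NaN) ratio, never a crash;
all-synonymous yields 0.

**Background density** is functional SNPs per kb of *coding* sequence by
default.  The denominator is a config option (`cds` or `genome`) and is
always echoed in the output row; the CDS default was chosen because
published per-kb backgrounds in this regime are consistent with a coding
denominator (≈ 3.3 Mb for a 3.7 Mb genome at ~90% coding).

**Hotspots** are genes with ≥ 1 functional variant whose per-gene
functional density (functional variants / gene kb) reaches
factor × background, factor defaulting to 3.  The rule is scale-invariant
and monotone: adding a functional variant never demotes a hotspot.

**LOF %** is 100 × LOF / functional.  Published tables in this domain
sometimes print LOF percentages that match no single obvious denominator
(e.g. 14.29% alongside 6 LOF of 41 functional, which is 14.6%); this
package always reports LOF/functional and leaves reconciliation to the
reader.

**Large gaps** are reference intervals ≥ `min_gap` (default 1000 bp, an
operational choice — multi-gene deletions are kilobases) between
consecutive colinear alignment blocks, with flanking query coordinates;
terminal gaps are reported when the reference length is supplied.

## Structure comparison

Residues are matched by index: both models must be predictions of the
same mature sequence, so no alignment stage exists (and the module
deliberately contains no structure prediction or DSSP assignment —
coordinates and secondary-structure strings are inputs).

Superposition is the closed-form Kabsch solution via SVD with the
determinant correction that excludes reflections; collinear or
coincident point sets raise, as the optimal rotation is then not unique.
RMSD is Cα-only.  TM-score uses the standard length normalization
d₀ = 1.24·(L−15)^⅓ − 1.8 Å clamped at 0.5 Å, with L defaulting to the
first (reference) model's length — the score's mild asymmetry enters
only through that choice.  Per-residue deviations are binned
blue/white/red at < 0.5 / 0.5–2 / > 2 Å, the common similarity-coloring
convention.

Secondary structure is 3-state over H/E/C; 8-state DSSP input is reduced
as H = {H,G,I}, E = {E,B}, C = rest.  β-strand (or helix) segment
lengths are compared by rank-order pairing after count equalization —
longest with longest — with a paired t-test; unequal counts truncate to
the smaller set and flag the result.  Identical matched lengths return
p = 1 by convention.  Content changes (e.g. helix percentage) are tested
by a paired t-test on per-window proportions over non-overlapping
windows (default 50 residues); the window size trades power against
locality and is configurable.

Heme comparisons use iron–iron Euclidean distances between
index-matched hemes, either sequence-consecutive pairs (default — the
nanowire geometry) or all pairs; the statistic is the signed mean
difference (second model minus first) with a paired t-test.

## Expression (2^−ΔΔCT)

ΔCT = CT_target − CT_housekeeping per replicate; ΔΔCT subtracts the
*mean* reference-strain ΔCT for the same gene and condition; fold =
2^−ΔΔCT with amplification efficiency fixed at 2 (no efficiency
correction).  Replicates aggregate on the log₂ scale, so the reported
fold is a geometric mean — under symmetric CT noise this is the unbiased
convention — and the reference strain's own mean fold is exactly 1.
Adding any constant to all CT values of one sample changes nothing
(housekeeping invariance).  Group contrasts run an independent t-test on
log₂ folds, which is symmetric under fold inversion.

## Phenotype

Growth rates come from ordinary least squares on ln(value) vs time.
The exponential window is user-fixable; the automatic policy scores
every contiguous window of ≥ 3 points and picks the longest whose R² is
within a small tolerance (2 × 10⁻³) of the best *after flooring* each
window's residual sum at the series' own noise level, estimated as the
median residual variance of the shortest windows.  The floor exists
because raw R² is not comparable across window lengths: short windows
reach spuriously high R² under noise, while long windows on shallow
exponentials look worse only because their signal variance is small.
Windows extending into lag or saturation accrue real model error above
the floor and are excluded.  On noiseless exponentials the fit is exact
for any k and y0 > 0; on logistic curves the automatic window recovers
the early-phase rate with a small (< 10%) downward bias from residual
curvature.

Rate contrasts compute mean(k_A)/mean(k_B) with an independent t-test on
the k values and refuse to mix time bases (per-hour vs per-day tags).
Ferrozine Fe(II) inverts a linear A562 calibration and multiplies by the
dilution factor (default 10, the 0.1 mL into 0.9 mL HCl protocol),
warning on extrapolation.  The attachment index is A580(solubilized
crystal violet)/A600(culture), with mean ± sd over replicates.

## Statistical tests

All tests (paired/independent t, Wilcoxon signed-rank, χ², McNemar)
delegate to scipy.stats / statsmodels through one shape-validating entry
point; identical paired vectors return (0, 1) rather than a degenerate
division.  Raw two-sided p-values are reported everywhere; a
Benjamini–Hochberg helper exists but no correction is applied by
default.

## Synthetic-data generator

The generator emulates the data regime of a recently diverged,
anode-adapted clonal lineage, at desk scale.  Defaults (the study
conditions): 40 genes × 300 codons, 12% intergenic, 120 SNPs,
Ts/Tv target κ = 2.76, dN/dS target ω = 0.776, 10% of coding SNPs
nonsense (which puts LOF at ~14% of functional variants), no indels or
deletions unless requested.

- **Ancestor.**  Genes start ATG, end at a random stop, internal codons
  uniform over the 61 sense codons (no real codon-usage bias — a neutral
  composition keeps the estimator tests clean), both strands, separated
  by random spacers; gene length is constant at `mean_gene_len` codons
  unless `len_sd` > 0.  Spacer capacity is reserved up front for any
  requested deletion spans.
- **Substitutions.**  κ parametrizes the transition *count* ratio
  directly (P(transition) = κ/(1+κ)); ω is enforced by drawing each
  coding SNP's class (nonsense / missense / synonymous) so that the
  expected nonsynonymous fraction is ωN/(ωN+S), then accept/reject
  sampling a site and allele of that class given the current codon —
  every planted event therefore has an exactly auditable class.  Two
  SNPs never share a codon, and annotated start/stop codons are not
  mutated (site totals still count all sense codons; the bias is two
  codons per gene).  Hotspot loci receive functional SNPs with
  probability weighted by multiplier × length.
- **Indels and deletions.**  Frameshifts are 1-bp anchored deletions in
  CDS interiors (genes hit become pseudogenes and are dropped from the
  descendant annotation).  Streaming deletions are excised whole from
  intergenic spacers — chosen *before* substitution placement so no
  variant lands in sequence absent from the descendant — which keeps the
  truth table exact and lets gap detection recover the intervals
  exactly.  Alignment blocks derived from the truth treat 1-bp indels as
  within-block noise, as a whole-genome aligner would.
- **Structures.**  Model chains are smooth random Cα walks (3.8 Å
  virtual bonds with directional persistence); model B is a random
  proper rigid transform of A plus per-component Gaussian noise at
  exactly `n_perturbed` residues, exactly `n_ss_changes` SS letter
  changes, and heme irons displaced by exactly `heme_shift` Å in random
  directions.
- **CT tables and growth curves.**  CT values embed planted folds as
  −log₂(fold) cycle shifts plus a per-sample loading offset and Gaussian
  cycle noise; growth curves are y0·e^{kt}·(1+ε) with optional plateau
  cap.

What the generator does *not* emulate — codon-usage and GC bias,
mutational context effects, recombination, population dynamics, read-level
sequencing error, real protein geometry (no excluded volume or native SS
coupling to coordinates), amplification-efficiency variation — bounds
what passing tests show: estimators are verified to be correct and
well-calibrated on data matching their model assumptions, not robust to
every artifact of real data.

All randomness flows from one integer seed through named, CRC-keyed
`SeedSequence` substreams, so each generator (ancestor, lineage,
structure, CT, growth) is independently reproducible and identical
scenario + seed reproduces every output byte for byte.

## Problem sizes used in verification

The test suite and the acceptance script run entirely on synthetic data:
parameter-recovery checks use 5,000 SNPs on a ~250-gene (~130 kb)
genome averaged over 10–20 seeds (Ts/Tv and dN/dS recover their targets
within a few percent); hotspot/deletion recovery uses 120-SNP lineages
over 30–50 seeds; expression recovery uses 100 simulated CT tables.
These sizes were chosen so the whole verification cycle completes in
about a minute while leaving Monte-Carlo error well inside the stated
tolerances.

## Known limitations

Single-pair comparisons only (no phylogenetic dN/dS, no significance
test against dN/dS = 1); no whole-genome alignment of megabase inputs
(gap detection consumes pre-computed blocks); Cα-only structural
comparison with index matching (no flexible or domain-wise fitting); no
qPCR efficiency estimation or absolute quantification; no lag/stationary
growth modelling beyond window exclusion.
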