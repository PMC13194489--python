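"""Shared fixtures: a hand-built two-gene genome and a simulated lineage."""

import pytest

from geoevo import AnnotatedGenome, CDSFeature, EvolutionScenario
from geoevo.simulate import evolve_lineage, generate_ancestral_genome

# layout (1-based): TTTT | +gene G_PLUS 5-19 | AAAA | -gene G_MINUS 24-35 | GG
# G_PLUS  codons: ATG GGA CCT TGG TAA
# G_MINUS codons: ATG AAA GAT TAA (genome carries the reverse complement)
TINY_SEQ = "TTTT" + "ATGGGACCTTGGTAA" + "AAAA" + "TTAATCTTTCAT" + "GG"


@pytest.fixture
def tiny_genome() -> AnnotatedGenome:
    return AnnotatedGenome(
        "tiny",
        TINY_SEQ,
        [
            CDSFeature("G_PLUS", 5, 19, "+", "toy plus-strand protein"),
            CDSFeature("G_MINUS", 24, 35, "-", "toy minus-strand protein"),
        ],
    )


@pytest.fixture(scope="session")
def lt_like_scenario() -> EvolutionScenario:
    """A small scenario in the anode-adaptation regime, with planted extras."""
    return EvolutionScenario(
        n_genes=30,
        mean_gene_len=150,
        intergenic_frac=0.25,
        n_snps=120,
        kappa=2.76,
        omega=0.776,
        lof_rate=0.08,
        indel_rate=0.02,
        hotspot_loci=(("G0005", 10.0),),
        deletion_spans=(800, 600),
        seed=11,
    )


@pytest.fixture(scope="session")
def lineage(lt_like_scenario):
    """(parent, descendant, variants, truth) for the session's test lineage."""
    parent = generate_ancestral_genome(lt_like_scenario)
    descendant, variants, truth = evolve_lineage(parent, lt_like_scenario)
    return parent, descendant, variants, truth
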