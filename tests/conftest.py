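import numpy as np
import pytest

from pharmscan.annotate import TranscriptModel
from pharmscan.phenotype import load_ade_codes
from pharmscan.simulate import CohortSpec, PlantedEffect, generate_cohort


@pytest.fixture(scope="session")
def codelist():
    return load_ade_codes()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with one planted effect, reused across tests."""
    spec = CohortSpec(
        n_persons=1500, n_variants=25, n_drugs=3, seed=7,
        prescription_rate=0.5, base_ade_rate=0.1,
        planted_effects=[PlantedEffect("v00003", "M01AC", np.log(2.5))],
        variant_mafs={"v00003": 0.25},
    )
    return spec, generate_cohort(spec)


def _build_refseq(rng, cds_codons, exons, cds, length=160):
    """Random genome with the given codon string laid into the CDS intervals."""
    seq = list(rng.choice(list("ACGT"), length))
    cds_bases = list("".join(cds_codons))
    i = 0
    for lo, hi in cds:
        for pos in range(lo, hi + 1):
            seq[pos - 1] = cds_bases[i]
            i += 1
    assert i == len(cds_bases)
    return "".join(seq)


@pytest.fixture(scope="session")
def toy_transcript():
    """Forward-strand two-exon transcript with a 51-bp CDS and its genome.

    CDS = ATG + 15 sense codons + TAA laid over genomic intervals
    (21, 40) and (61, 91); exons (11, 40) and (61, 100).
    """
    rng = np.random.default_rng(123)
    codons = ["ATG"] + ["CAA", "GCT", "TGG", "CTT", "AAA", "GAT", "TCA",
                        "CAA", "GCT", "CGT", "ATT", "CCA", "GGA", "CAC",
                        "AAA"] + ["TAA"]
    exons = [(11, 40), (61, 100)]
    cds = [(21, 40), (61, 91)]
    t = TranscriptModel(gene="TOY1", chrom="chr1", strand="+", exons=exons, cds=cds)
    refseq = _build_refseq(rng, codons, exons, cds)
    return t, refseq, codons
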