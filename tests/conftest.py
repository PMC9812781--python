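import numpy as np
import pandas as pd
import pytest

from treburden.annotate import GeneModel, Transcript
from treburden.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """One small cohort with a strong planted signal, shared across tests."""
    config = SimConfig.with_odds_ratio(
        5.0,
        control_carrier_freq=0.01,
        n_cases=150,
        n_controls=150,
        n_panel=100,
        n_loci=120,
        n_expansion_loci=15,
        n_decoy_loci=3,
        genome_length=4_000_000,
        n_chromosomes=2,
        seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture
def toy_gene_model():
    """Two-gene model on one contig: plus- and minus-strand transcripts.

    GENE_A (+): exons [1000,1200) [1500,1700) [2000,2300), CDS [1100,2200)
      -> utr5 = [1000,1100), utr3 = [2200,2300)
    GENE_B (-): exons [5000,5300) [5600,5900), CDS [5100,5800)
      -> utr5 = [5800,5900) (5' on minus strand), utr3 = [5000,5100)
    """
    txs = [
        Transcript(
            gene_id="GENE_A",
            transcript_id="TX_A",
            contig="chr1",
            strand="+",
            start=1000,
            end=2300,
            exons=[(1000, 1200), (1500, 1700), (2000, 2300)],
            cds_start=1100,
            cds_end=2200,
        ),
        Transcript(
            gene_id="GENE_B",
            transcript_id="TX_B",
            contig="chr1",
            strand="-",
            start=5000,
            end=5900,
            exons=[(5000, 5300), (5600, 5900)],
            cds_start=5100,
            cds_end=5800,
        ),
    ]
    return GeneModel(txs)


@pytest.fixture
def tiny_calls():
    rows = []
    for sid, length in [("s1", 10), ("s2", 11), ("s3", 10), ("s4", 12), ("s5", 11), ("s6", 55)]:
        rows.append(
            {
                "sample_id": sid,
                "contig": "chr1",
                "start": 100,
                "end": 160,
                "motif": "AGC",
                "length_bp": float(length),
                "anchored_irr": 0,
                "depth": 30.0,
            }
        )
    return pd.DataFrame(rows)
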