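import pandas as pd
import pytest

from tdrsv.genemodel import GeneModel, TpmMatrix, TranscriptModel
from tdrsv.model import GenomicInterval
from tdrsv.simulate import FixtureSpec, generate_annotation


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def annotation(spec):
    return generate_annotation(spec)


@pytest.fixture(scope="session")
def three_transcript_gene():
    """Hand-built gene: T1/T2 coding with disjoint CDS, T3 non-coding.

    Layout on chr9 (+ strand), private exons ordered T1, T3, T2 so a
    single deletion can take out T1 and T3 while sparing T2:
      T1: exons [1000,1400) [5000,5400); CDS [1100,1300)
      T3: exons [2000,2400) [5000,5400); no CDS (lncRNA)
      T2: exons [3000,3400) [5000,5400); CDS [3100,3300)
    The [4000,4900) stretch is intronic for every transcript.
    """
    def t(tid, x, coding, mane=False):
        return TranscriptModel(
            id=tid,
            gene_id="GX",
            biotype="protein_coding" if coding else "lncRNA",
            strand="+",
            exons=[
                GenomicInterval("chr9", x, x + 400),
                GenomicInterval("chr9", 5000, 5400),
            ],
            cds=[GenomicInterval("chr9", x + 100, x + 300)] if coding else [],
            is_mane=mane,
        )

    return GeneModel(
        id="GX",
        symbol="GX",
        transcripts=[
            t("T1", 1000, True, mane=True),
            t("T2", 3000, True),
            t("T3", 2000, False),
        ],
    )


@pytest.fixture(scope="session")
def tpm_10_30_60():
    """TPM table for the hand-built gene: T1=10, T2=30, T3=60 in 'brain'."""
    return TpmMatrix(
        pd.DataFrame(
            {"brain": [10.0, 30.0, 60.0], "silent": [0.0, 0.0, 0.0]},
            index=["T1", "T2", "T3"],
        )
    )
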