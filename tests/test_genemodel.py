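"""GTF parsing, SV-gene positional context and TSS geometry."""
import textwrap

import numpy as np
import pytest

from tdrsv.genemodel import (
    SVGeneContext,
    TpmMatrix,
    classify_context,
    read_gtf,
    tss_distance,
    write_gtf,
)
from tdrsv.model import Genotype, GenomicInterval, PointVariant, SVRecord, SVType


def sv(svtype, start, end, chrom="chr1", svlen=None):
    length = svlen if svlen is not None else end - start
    return SVRecord("sv", SVType(svtype), GenomicInterval(chrom, start, end),
                    length, {"S": Genotype.HET})


TOY_GTF = textwrap.dedent(
    """\
    chr5\tsrc\tgene\t101\t2000\t.\t+\t.\tgene_id "g1"; gene_name "G1";
    chr5\tsrc\ttranscript\t101\t2000\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_type "protein_coding"; tag "MANE_Select";
    chr5\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
    chr5\tsrc\texon\t1001\t2000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
    chr5\tsrc\tCDS\t121\t180\t.\t+\t0\tgene_id "g1"; transcript_id "t1";
    chr5\tsrc\ttranscript\t101\t2000\t.\t+\t.\tgene_id "g1"; transcript_id "t2"; transcript_type "lncRNA";
    chr5\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t2";
    """
)


def test_read_gtf_parses_coordinates_and_biotypes(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(TOY_GTF)
    genes = read_gtf(str(p))
    assert set(genes) == {"g1"}
    gene = genes["g1"]
    t1 = next(t for t in gene.transcripts if t.id == "t1")
    t2 = next(t for t in gene.transcripts if t.id == "t2")
    # 1-based inclusive 101..200 becomes [100, 200)
    assert t1.exons[0] == GenomicInterval("chr5", 100, 200)
    assert t1.cds == [GenomicInterval("chr5", 120, 180)]
    assert t1.is_mane and t1.is_coding
    assert not t2.is_mane and not t2.is_coding and t2.biotype == "lncRNA"
    assert gene.span == GenomicInterval("chr5", 100, 2000)


def test_write_read_gtf_round_trip(annotation, tmp_path):
    path = str(tmp_path / "sim.gtf")
    write_gtf(annotation.genes, path)
    back = read_gtf(path)
    assert set(back) == set(annotation.genes)
    for gid, gene in annotation.genes.items():
        b = back[gid]
        assert [t.id for t in b.transcripts] == [t.id for t in gene.transcripts]
        for t, bt in zip(gene.transcripts, b.transcripts):
            assert bt.exons == t.exons
            assert bt.cds == t.cds
            assert bt.is_mane == t.is_mane
            assert bt.biotype == t.biotype


def test_context_classes(three_transcript_gene):
    gene = three_transcript_gene
    g = lambda *a: sv(*a, chrom="chr9")
    assert classify_context(g("DEL", 0, 6000), gene) is SVGeneContext.WHOLE_GENE
    assert classify_context(g("DEL", 4000, 4900), gene) is SVGeneContext.INTRONIC
    assert classify_context(g("DEL", 3100, 3200), gene) is SVGeneContext.EXONIC
    assert classify_context(g("DEL", 8000, 9000), gene) is SVGeneContext.INTERGENIC
    assert classify_context(sv("DEL", 0, 100, chrom="chr2"), gene) is SVGeneContext.INTERGENIC
    # a deletion touching one exon of one transcript is exonic, not whole-gene
    assert classify_context(g("DEL", 1390, 1450), gene) is SVGeneContext.EXONIC


def test_context_insertion_uses_anchor_point(three_transcript_gene):
    gene = three_transcript_gene
    ins_exonic = SVRecord("i", SVType.INS, GenomicInterval("chr9", 1100, 1100), 300)
    ins_intronic = SVRecord("i", SVType.INS, GenomicInterval("chr9", 4500, 4500), 300)
    assert classify_context(ins_exonic, gene) is SVGeneContext.EXONIC
    assert classify_context(ins_intronic, gene) is SVGeneContext.INTRONIC


def test_context_matches_per_base_oracle(annotation):
    """Random SVs: context agrees with per-base exon/span membership."""
    rng = np.random.default_rng(23)
    genes = list(annotation.genes.values())
    for _ in range(400):
        gene = genes[int(rng.integers(len(genes)))]
        span = gene.span
        start = int(rng.integers(span.start - 2000, span.end + 2000))
        length = int(rng.integers(1, 4000))
        record = sv("DEL", start, start + length)
        bases = set(range(start, start + length))
        exon_bases = set()
        for t in gene.transcripts:
            for e in t.exons:
                exon_bases.update(range(e.start, e.end))
        span_bases = set(range(span.start, span.end))
        if start <= span.start and start + length >= span.end:
            expected = SVGeneContext.WHOLE_GENE
        elif bases & exon_bases:
            expected = SVGeneContext.EXONIC
        elif bases & span_bases:
            expected = SVGeneContext.INTRONIC
        else:
            expected = SVGeneContext.INTERGENIC
        assert classify_context(record, gene) is expected


def test_tss_distance(three_transcript_gene):
    gene = three_transcript_gene  # every transcript TSS at its span start
    g = lambda *a: sv(*a, chrom="chr9")
    assert tss_distance(g("DEL", 900, 1100), gene) == 0  # covers T1's TSS
    # minimum over transcripts: TSSs at 1000 (T1), 2000 (T3), 3000 (T2)
    assert tss_distance(g("DEL", 2100, 2200), gene) == 100
    assert tss_distance(g("DEL", 1400, 1450), gene) == 400  # T1 side wins
    assert tss_distance(sv("DEL", 0, 100, chrom="chr2"), gene) is None


def test_tss_distance_downstream_gap():
    from tdrsv.genemodel import GeneModel, TranscriptModel

    single = GeneModel(
        id="gs", symbol="gs",
        transcripts=[TranscriptModel(
            id="ts", gene_id="gs", biotype="protein_coding", strand="+",
            exons=[GenomicInterval("chr1", 1000, 1400)],
            cds=[GenomicInterval("chr1", 1100, 1300)],
        )],
    )
    # deletion starting 500 bp downstream of the sole TSS (at 1000)
    assert tss_distance(sv("DEL", 1500, 1800), single) == 500


def test_tss_strand_awareness():
    from tdrsv.genemodel import GeneModel, TranscriptModel

    minus = GeneModel(
        id="gm", symbol="gm",
        transcripts=[TranscriptModel(
            id="tm", gene_id="gm", biotype="protein_coding", strand="-",
            exons=[GenomicInterval("chr1", 1000, 2000)],
            cds=[GenomicInterval("chr1", 1100, 1900)],
        )],
    )
    # TSS of a minus-strand transcript is its rightmost base (1999)
    assert tss_distance(sv("DEL", 2100, 2200), minus) == 101
    assert tss_distance(sv("DEL", 900, 950), minus) == 1050


def test_tpm_matrix_lookup(tpm_10_30_60):
    assert tpm_10_30_60.get("T2", "brain") == 30.0
    assert tpm_10_30_60.get("nonexistent", "brain") == 0.0  # logged, not fatal
    with pytest.raises(KeyError, match="brain"):
        tpm_10_30_60.get("T1", "kidney")


def test_tpm_matrix_tsv_round_trip(tpm_10_30_60, tmp_path):
    p = str(tmp_path / "tpm.tsv")
    tpm_10_30_60.to_tsv(p)
    back = TpmMatrix.from_tsv(p)
    assert back.frame.equals(tpm_10_30_60.frame)


def test_point_variant_context(three_transcript_gene):
    pv_exonic = PointVariant("chr9", 1150)
    pv_outside = PointVariant("chr9", 9000)
    assert classify_context(pv_exonic, three_transcript_gene) is SVGeneContext.EXONIC
    assert classify_context(pv_outside, three_transcript_gene) is SVGeneContext.INTERGENIC
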