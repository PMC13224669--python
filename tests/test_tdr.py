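"""Transcript disruption ratio: analytic cases, variant-class rules, invariants."""
import numpy as np
import pandas as pd
import pytest

from tdrsv.genemodel import TpmMatrix
from tdrsv.model import Genotype, GenomicInterval, PointVariant, SVRecord, SVType
from tdrsv.tdr import (
    compute_tdr,
    compute_tdr_stopgain,
    disrupted_transcripts,
    mane_tdr_comparison,
    protein_coding_ratio,
)


def sv(svtype, start, end, chrom="chr9", svlen=None, sid="sv"):
    length = svlen if svlen is not None else end - start
    return SVRecord(sid, SVType(svtype), GenomicInterval(chrom, start, end),
                    length, {"S": Genotype.HET})


def test_three_transcript_example(three_transcript_gene, tpm_10_30_60):
    """DEL over T1 (CDS) and T3 (exon) but not T2: TDR = (10+60)/100 = 0.7."""
    record = sv("DEL", 1000, 2400)
    assert disrupted_transcripts(record, three_transcript_gene) == {"T1", "T3"}
    res = compute_tdr(record, three_transcript_gene, "brain", tpm_10_30_60)
    assert res.tdr == pytest.approx(0.7)
    assert res.tpm_disrupted == 70.0 and res.tpm_total == 100.0
    assert res.disrupts_mane  # T1 carries the MANE tag


def test_whole_gene_deletion_tdr_one(three_transcript_gene, tpm_10_30_60):
    res = compute_tdr(sv("DEL", 0, 6000), three_transcript_gene, "brain", tpm_10_30_60)
    assert res.tdr == 1.0


def test_intronic_deletion_tdr_zero(three_transcript_gene, tpm_10_30_60):
    res = compute_tdr(sv("DEL", 4000, 4900), three_transcript_gene, "brain", tpm_10_30_60)
    assert res.disrupted == frozenset()
    assert res.tdr == 0.0


def test_silent_gene_is_undefined(three_transcript_gene, tpm_10_30_60):
    res = compute_tdr(sv("DEL", 0, 6000), three_transcript_gene, "silent", tpm_10_30_60)
    assert res.tdr is None and not res.defined


def test_unknown_tissue_raises(three_transcript_gene, tpm_10_30_60):
    with pytest.raises(KeyError, match="brain"):
        compute_tdr(sv("DEL", 0, 6000), three_transcript_gene, "kidney", tpm_10_30_60)


def test_utr_only_deletion_spares_coding_transcript(three_transcript_gene, tpm_10_30_60):
    """T1's exon [1000,1400) is UTR outside CDS [1100,1300): a deletion of
    [1320,1390) touches the exon but no CDS base, so T1 is not disrupted."""
    record = sv("DEL", 1320, 1390)
    assert disrupted_transcripts(record, three_transcript_gene) == frozenset()


def test_noncoding_transcript_uses_exon_overlap(three_transcript_gene, tpm_10_30_60):
    """T3 (lncRNA, no CDS) is disrupted through exon overlap."""
    record = sv("DEL", 2050, 2080)
    assert disrupted_transcripts(record, three_transcript_gene) == {"T3"}
    res = compute_tdr(record, three_transcript_gene, "brain", tpm_10_30_60)
    assert res.tdr == pytest.approx(0.6)


def test_insertion_anchor_rule(three_transcript_gene):
    ins_in_cds = SVRecord("i1", SVType.INS, GenomicInterval("chr9", 1150, 1150), 500)
    ins_in_utr = SVRecord("i2", SVType.INS, GenomicInterval("chr9", 1050, 1050), 500)
    assert disrupted_transcripts(ins_in_cds, three_transcript_gene) == {"T1"}
    assert disrupted_transcripts(ins_in_utr, three_transcript_gene) == frozenset()


def test_inversion_containing_whole_gene_disrupts_nothing(three_transcript_gene):
    """Both breakpoints outside the span: the gene is relocated intact."""
    inv = sv("INV", 0, 10_000)
    assert disrupted_transcripts(inv, three_transcript_gene) == frozenset()


def test_inversion_breakpoint_inside_disrupts(three_transcript_gene):
    inv = sv("INV", 1200, 10_000)  # left breakpoint inside T1's CDS
    assert "T1" in disrupted_transcripts(inv, three_transcript_gene)


def test_stopgain_cds_containment(three_transcript_gene, tpm_10_30_60):
    v = PointVariant("chr9", 3200)  # inside T2's CDS only
    res = compute_tdr_stopgain(v, three_transcript_gene, "brain", tpm_10_30_60)
    assert res.disrupted == {"T2"}
    assert res.tdr == pytest.approx(0.3)


def test_stopgain_in_utr_is_zero(three_transcript_gene, tpm_10_30_60):
    v = PointVariant("chr9", 1050)  # exon of T1, but UTR for every CDS
    res = compute_tdr_stopgain(v, three_transcript_gene, "brain", tpm_10_30_60)
    assert res.tdr == 0.0


def test_stopgain_outside_span_flagged(three_transcript_gene, tpm_10_30_60):
    v = PointVariant("chr9", 50_000)
    res = compute_tdr_stopgain(v, three_transcript_gene, "brain", tpm_10_30_60)
    assert res.tdr == 0.0 and "outside_gene_span" in res.flags


def test_stopgain_shared_cds_position():
    """A site in every coding CDS yields TDR = coding TPM / total TPM."""
    from tdrsv.genemodel import GeneModel, TranscriptModel

    shared_cds = GenomicInterval("chr1", 1100, 1200)
    def t(tid, coding):
        return TranscriptModel(
            id=tid, gene_id="g", biotype="protein_coding" if coding else "lncRNA",
            strand="+", exons=[GenomicInterval("chr1", 1000, 1400)],
            cds=[shared_cds] if coding else [],
        )
    gene = GeneModel(id="g", symbol="g", transcripts=[t("a", True), t("b", True), t("c", False)])
    tpm = TpmMatrix(pd.DataFrame({"ts": [40.0, 40.0, 20.0]}, index=["a", "b", "c"]))
    res = compute_tdr_stopgain(PointVariant("chr1", 1150), gene, "ts", tpm)
    assert res.tdr == pytest.approx(0.8)


def test_protein_coding_ratio(three_transcript_gene, tpm_10_30_60):
    # coding T1+T2 = 40 of 100 total
    assert protein_coding_ratio(three_transcript_gene, "brain", tpm_10_30_60) == pytest.approx(0.4)
    assert protein_coding_ratio(three_transcript_gene, "silent", tpm_10_30_60) is None


def test_tdr_monotone_in_disrupted_set(three_transcript_gene, tpm_10_30_60):
    """Growing the physical extent of a deletion never lowers TDR."""
    small = compute_tdr(sv("DEL", 1000, 1400), three_transcript_gene, "brain", tpm_10_30_60)
    bigger = compute_tdr(sv("DEL", 1000, 2400), three_transcript_gene, "brain", tpm_10_30_60)
    whole = compute_tdr(sv("DEL", 0, 6000), three_transcript_gene, "brain", tpm_10_30_60)
    assert small.disrupted <= bigger.disrupted <= whole.disrupted
    assert small.tdr <= bigger.tdr <= whole.tdr


def test_tdr_invariant_to_tpm_rescaling(three_transcript_gene, tpm_10_30_60):
    record = sv("DEL", 1000, 2400)
    scaled = TpmMatrix(tpm_10_30_60.frame * 37.5)
    a = compute_tdr(record, three_transcript_gene, "brain", tpm_10_30_60)
    b = compute_tdr(record, three_transcript_gene, "brain", scaled)
    assert a.tdr == pytest.approx(b.tdr)


def test_dup_and_del_share_disruption_rule(three_transcript_gene, tpm_10_30_60):
    d = compute_tdr(sv("DEL", 1000, 2400), three_transcript_gene, "brain", tpm_10_30_60)
    u = compute_tdr(sv("DUP", 1000, 2400), three_transcript_gene, "brain", tpm_10_30_60)
    assert d.disrupted == u.disrupted and d.tdr == u.tdr


def test_whole_gene_del_is_one_wherever_expressed(annotation):
    """Property: a whole-gene deletion has TDR 1.0 in every expressed tissue."""
    for gid, gene in list(annotation.genes.items())[:10]:
        span = gene.span
        record = sv("DEL", span.start - 100, span.end + 100, chrom=gene.chrom)
        for tissue in annotation.tissues:
            res = compute_tdr(record, gene, tissue, annotation.tpm)
            if res.defined:
                assert res.tdr == 1.0


def test_mane_comparison_fractions(annotation):
    """Planted partition: slot-0 deletions disrupt the MANE transcript, later
    slots do not; fractions above threshold follow the engineered shares."""
    svs = []
    gids = list(annotation.genes)
    for gid in (gids[1], gids[2]):  # first-transcript share 0.8 everywhere
        svs.append((sv("DEL", *_slot(annotation, gid, 0), chrom="chr1", sid=f"m_{gid}"),
                    annotation.genes[gid]))
    for gid in (gids[3],):  # share 0.1: non-MANE slots carry 0.9
        svs.append((sv("DEL", *_slot(annotation, gid, 1), chrom="chr1", sid=f"n_{gid}"),
                    annotation.genes[gid]))
    tissue_a, tissue_b = annotation.tissues[0], annotation.tissues[1]
    per_sv, summary = mane_tdr_comparison(svs, annotation.tpm, tissue_a, tissue_b)
    mane_rows = summary[summary["disrupts_mane"]]
    assert (mane_rows["frac_high_tdr"] == 1.0).all()  # share 0.8 > 0.25
    non_mane = per_sv[~per_sv["disrupts_mane"]]
    assert len(non_mane) == 1


def test_mane_comparison_empty_partition_is_nan(three_transcript_gene, tpm_10_30_60):
    svs = [(sv("DEL", 1000, 1400), three_transcript_gene)]  # disrupts MANE T1
    _, summary = mane_tdr_comparison(svs, tpm_10_30_60, "brain", "silent")
    empty = summary[~summary["disrupts_mane"]]
    assert empty["frac_high_tdr"].isna().all()


def _slot(annotation, gid, k):
    s = annotation.layout[gid].slots[k]
    return s.start - 10, s.end + 10


def test_tdr_matches_per_base_oracle_small(annotation):
    """Spot-check against per-base enumeration (full-scale run lives in the
    acceptance suite)."""
    _oracle_check(annotation, n_pairs=100, seed=3)


def _oracle_check(annotation, n_pairs, seed):
    rng = np.random.default_rng(seed)
    genes = list(annotation.genes.values())
    tissues = annotation.tissues
    for _ in range(n_pairs):
        gene = genes[int(rng.integers(len(genes)))]
        span = gene.span
        svtype = ["DEL", "DUP", "INV", "INS"][int(rng.integers(4))]
        if svtype == "INS":
            pos = int(rng.integers(span.start - 500, span.end + 500))
            record = SVRecord("o", SVType.INS, GenomicInterval("chr1", pos, pos), 200)
        else:
            start = int(rng.integers(span.start - 2000, span.end + 2000))
            length = int(rng.integers(1, 6000))
            record = sv(svtype, start, start + length, chrom="chr1")
        got = disrupted_transcripts(record, gene)
        expected = _per_base_oracle(record, gene)
        assert got == expected
        tissue = tissues[int(rng.integers(len(tissues)))]
        res = compute_tdr(record, gene, tissue, annotation.tpm)
        total = sum(annotation.tpm.get(t, tissue) for t in sorted(gene.transcript_ids))
        if total == 0:
            assert res.tdr is None
        else:
            dis = sum(annotation.tpm.get(t, tissue) for t in sorted(expected))
            assert res.tdr == dis / total


def _per_base_oracle(record, gene):
    """Independent rule evaluation via explicit per-base sets."""
    out = set()
    for t in gene.transcripts:
        targets = t.cds if t.cds else t.exons
        target_bases = set()
        for ivl in targets:
            target_bases.update(range(ivl.start, ivl.end))
        if record.svtype is SVType.INS:
            hit = record.interval.start in target_bases
        else:
            bases = set(range(record.interval.start, record.interval.end))
            if record.svtype is SVType.INV:
                span = t.span
                bps_inside = any(
                    span.start < bp < span.end
                    for bp in (record.interval.start, record.interval.end)
                )
                hit = bps_inside and bool(bases & target_bases)
            else:
                hit = bool(bases & target_bases)
        if hit:
            out.add(t.id)
    return frozenset(out)
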