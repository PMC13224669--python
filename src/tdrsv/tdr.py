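"""Transcript disruption ratio (TDR).

For a variant, a gene and a tissue, TDR is the fraction of the gene's
total expression (summed median TPM over all annotated isoforms, coding
and non-coding) contributed by the transcripts the variant disrupts:

    TDR(gene, tissue) = sum TPM(disrupted transcripts)
                      / sum TPM(all transcripts)

A transcript counts as disrupted when the variant physically breaks its
translated structure: DEL/DUP overlap ≥ 1 bp of the CDS (coding) or of
the exons (non-coding isoforms, which have no CDS); an insertion lands
inside such an interval; an inversion has a breakpoint strictly inside
the transcript span *and* overlaps a qualifying base — an inversion that
contains a whole gene relocates it intact and disrupts nothing.

TDR is UNDEFINED (None) when the gene is silent in the tissue (total
TPM = 0); such rows propagate as missing, never as 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import pandas as pd

from .genemodel import GeneModel, SVGeneContext, TpmMatrix, classify_context
from .model import GenomicInterval, PointVariant, SVRecord, SVType

TDR_THRESHOLD = 0.25  # empirical threshold for potentially pathogenic SVs


@dataclass
class TdrResult:
    variant_id: str
    gene_id: str
    tissue: str
    disrupted: frozenset[str]
    tpm_disrupted: float
    tpm_total: float
    tdr: Optional[float]  # None = UNDEFINED (gene silent in tissue)
    disrupts_mane: bool
    context: Optional[SVGeneContext] = None
    flags: set[str] = field(default_factory=set)

    @property
    def defined(self) -> bool:
        return self.tdr is not None


def disrupted_transcripts(sv: SVRecord, gene: GeneModel) -> frozenset[str]:
    """Transcripts whose qualifying intervals the SV disrupts."""
    if sv.chrom != gene.chrom:
        return frozenset()
    out = set()
    for t in gene.transcripts:
        targets = t.disruption_targets()
        if not targets:
            continue
        if sv.svtype is SVType.INS:
            anchor = sv.interval.start
            if any(iv.contains_point(anchor) for iv in targets):
                out.add(t.id)
        elif sv.svtype is SVType.INV:
            span = t.span
            bp_inside = any(
                span.start < bp < span.end
                for bp in (sv.interval.start, sv.interval.end)
            )
            if bp_inside and any(sv.interval.overlaps(iv) for iv in targets):
                out.add(t.id)
        else:  # DEL / DUP: any coding-structure overlap
            if any(sv.interval.overlaps(iv) for iv in targets):
                out.add(t.id)
    return frozenset(out)


def _tdr_from_set(
    variant_id: str,
    gene: GeneModel,
    tissue: str,
    tpm: TpmMatrix,
    disrupted: frozenset[str],
    context: Optional[SVGeneContext],
    flags: Optional[set[str]] = None,
) -> TdrResult:
    total = sum(tpm.get(tid, tissue) for tid in sorted(gene.transcript_ids))
    dis = sum(tpm.get(tid, tissue) for tid in sorted(disrupted))
    tdr = dis / total if total > 0 else None
    return TdrResult(
        variant_id=variant_id,
        gene_id=gene.id,
        tissue=tissue,
        disrupted=disrupted,
        tpm_disrupted=dis,
        tpm_total=total,
        tdr=tdr,
        disrupts_mane=any(tid in disrupted for tid in gene.mane_transcripts),
        context=context,
        flags=flags or set(),
    )


def compute_tdr(
    variant: Union[SVRecord, PointVariant],
    gene: GeneModel,
    tissue: str,
    tpm: TpmMatrix,
) -> TdrResult:
    """TDR of a structural or stop-gain point variant for one gene/tissue."""
    if tissue not in tpm.tissues:
        raise KeyError(
            f"unknown tissue {tissue!r}; available: {', '.join(tpm.tissues)}"
        )
    if isinstance(variant, PointVariant):
        return compute_tdr_stopgain(variant, gene, tissue, tpm)
    disrupted = disrupted_transcripts(variant, gene)
    context = classify_context(variant, gene)
    return _tdr_from_set(variant.id, gene, tissue, tpm, disrupted, context)


def compute_tdr_stopgain(
    v: PointVariant, gene: GeneModel, tissue: str, tpm: TpmMatrix
) -> TdrResult:
    """Stop-gain TDR: disrupted = transcripts whose CDS contains the site.

    NMD degrades the transcripts actually translated in the tissue, so
    only CDS containment counts; a position outside the gene span yields
    TDR 0 with an ``outside_gene_span`` flag.
    """
    variant_id = f"{v.chrom}:{v.pos}:{v.consequence}"
    flags: set[str] = set()
    if v.chrom != gene.chrom or not gene.span.contains_point(v.pos):
        flags.add("outside_gene_span")
        disrupted: frozenset[str] = frozenset()
    else:
        disrupted = frozenset(
            t.id
            for t in gene.transcripts
            if any(c.contains_point(v.pos) for c in t.cds)
        )
    res = _tdr_from_set(
        variant_id, gene, tissue, tpm, disrupted, classify_context(v, gene), flags
    )
    if "outside_gene_span" in flags and res.tpm_total > 0:
        res.tdr = 0.0
    return res


def protein_coding_ratio(
    gene: GeneModel, tissue: str, tpm: TpmMatrix
) -> Optional[float]:
    """Fraction of the gene's expression carried by protein-coding isoforms."""
    total = sum(tpm.get(t.id, tissue) for t in gene.transcripts)
    if total == 0:
        return None
    coding = sum(
        tpm.get(t.id, tissue)
        for t in gene.transcripts
        if t.biotype == "protein_coding"
    )
    return coding / total


def mane_tdr_comparison(
    svs: Iterable[tuple[SVRecord, GeneModel]],
    tpm: TpmMatrix,
    tissue_a: str,
    tissue_b: str,
    threshold: float = TDR_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare TDR behaviour of MANE-disrupting versus non-MANE SVs.

    Returns (per-SV table of TDR pairs, summary).  The summary reports,
    for each partition (disrupts_mane true/false) and tissue, the
    fraction of SVs with defined TDR above the threshold; an empty
    partition reports NaN (UNDEFINED), not 0.
    """
    rows = []
    for sv, gene in svs:
        ra = compute_tdr(sv, gene, tissue_a, tpm)
        rb = compute_tdr(sv, gene, tissue_b, tpm)
        rows.append(
            {
                "variant_id": sv.id,
                "gene_id": gene.id,
                "disrupts_mane": ra.disrupts_mane,
                f"tdr_{tissue_a}": ra.tdr,
                f"tdr_{tissue_b}": rb.tdr,
            }
        )
    per_sv = pd.DataFrame(rows)
    summary_rows = []
    for mane_flag in (True, False):
        part = per_sv[per_sv["disrupts_mane"] == mane_flag] if len(per_sv) else per_sv
        for tissue in (tissue_a, tissue_b):
            col = part[f"tdr_{tissue}"].dropna() if len(part) else pd.Series(dtype=float)
            frac = float((col > threshold).mean()) if len(col) else float("nan")
            summary_rows.append(
                {
                    "disrupts_mane": mane_flag,
                    "tissue": tissue,
                    "n": int(len(col)),
                    "frac_high_tdr": frac,
                }
            )
    return per_sv, pd.DataFrame(summary_rows)


def compute_tdr_results(
    svs: Iterable[SVRecord],
    genes: dict[str, GeneModel],
    tpm: TpmMatrix,
    tissues: Iterable[str],
) -> list[TdrResult]:
    """TDR for every SV against every same-chromosome gene it touches."""
    tissues = list(tissues)
    out: list[TdrResult] = []
    for sv in svs:
        for gene in genes.values():
            if gene.chrom != sv.chrom:
                continue
            ctx = classify_context(sv, gene)
            if ctx is SVGeneContext.INTERGENIC:
                continue
            disrupted = disrupted_transcripts(sv, gene)
            for tissue in tissues:
                out.append(_tdr_from_set(sv.id, gene, tissue, tpm, disrupted, ctx))
    return out


def tdr_table(
    svs: Iterable[SVRecord],
    genes: dict[str, GeneModel],
    tpm: TpmMatrix,
    tissues: Iterable[str],
) -> pd.DataFrame:
    """All-pairs TDR table for SVs against every same-chromosome gene they touch."""
    tissues = list(tissues)
    rows = []
    for sv in svs:
        for gene in genes.values():
            if gene.chrom != sv.chrom:
                continue
            ctx = classify_context(sv, gene)
            if ctx is SVGeneContext.INTERGENIC:
                continue
            disrupted = disrupted_transcripts(sv, gene)
            for tissue in tissues:
                res = _tdr_from_set(sv.id, gene, tissue, tpm, disrupted, ctx)
                rows.append(
                    {
                        "variant_id": res.variant_id,
                        "gene_id": res.gene_id,
                        "tissue": tissue,
                        "n_disrupted": len(res.disrupted),
                        "tpm_disrupted": res.tpm_disrupted,
                        "tpm_total": res.tpm_total,
                        "tdr": res.tdr,
                        "disrupts_mane": res.disrupts_mane,
                        "context_class": ctx.value,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "gene_id",
            "tissue",
            "n_disrupted",
            "tpm_disrupted",
            "tpm_total",
            "tdr",
            "disrupts_mane",
            "context_class",
        ],
    )
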