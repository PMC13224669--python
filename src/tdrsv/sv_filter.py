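"""Tiered SV quality-control workflow.

Breakpoint calls are the primary input; corroborating read-depth and
re-genotyping evidence gates them by size tier:

* SHORT  (< 200 bp)                  — retained only with a confident
  re-genotyped call (HET/HOM) in at least one carrier sample;
* MEDIUM (200 bp ≤ len < 100 kb, DEL/DUP) — needs a same-type support
  interval from either read-depth caller at > 80% reciprocal overlap;
* LONG   (≥ 100 kb, DEL/DUP)         — needs the read-depth (CNVnator-
  style) support at > 80% reciprocal overlap;
* OTHER  (INV, INS ≥ 200 bp)         — passes without overlap filtering.

Inversions shorter than 200 bp fall outside every tier and pass through
flagged ``untested_tier``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import pandas as pd
from intervaltree import IntervalTree

from .model import Genotype, GenomicInterval, SVRecord, SVType

log = logging.getLogger(__name__)

SHORT_MAX_BP = 200
LONG_MIN_BP = 100_000
RO_THRESHOLD = 0.8  # strict: support must exceed this


class SizeTier(str, Enum):
    SHORT = "SHORT"
    MEDIUM = "MEDIUM"
    LONG = "LONG"
    OTHER = "OTHER"
    UNTESTED = "UNTESTED"  # INV < 200 bp: no tier defined


def size_tier(sv: SVRecord) -> SizeTier:
    if sv.svtype is SVType.INV:
        return SizeTier.OTHER if sv.svlen >= SHORT_MAX_BP else SizeTier.UNTESTED
    if sv.svlen < SHORT_MAX_BP:
        return SizeTier.SHORT
    if sv.svtype is SVType.INS:
        return SizeTier.OTHER
    return SizeTier.MEDIUM if sv.svlen < LONG_MIN_BP else SizeTier.LONG


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 across chromosomes."""
    if a.length == 0 or b.length == 0:
        raise ValueError("reciprocal overlap undefined for zero-length intervals")
    if a.chrom != b.chrom:
        return 0.0
    ov = a.overlap_len(b)
    return min(ov / a.length, ov / b.length)


class _TypedIntervalIndex:
    """Per-chromosome interval tree of (svtype, interval) support calls."""

    def __init__(self, entries: Iterable[tuple[str, GenomicInterval]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for svtype, iv in entries:
            self.add(svtype, iv)

    def add(self, svtype: str, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, str(svtype)
        )

    def best_ro(self, sv: SVRecord) -> float:
        """Best reciprocal overlap among same-type support intervals."""
        tree = self._trees.get(sv.chrom)
        if tree is None:
            return 0.0
        best = 0.0
        for hit in tree.overlap(sv.interval.start, sv.interval.end):
            if hit.data != sv.svtype.value:
                continue
            ro = reciprocal_overlap(
                sv.interval, GenomicInterval(sv.chrom, hit.begin, hit.end)
            )
            best = max(best, ro)
        return best


@dataclass
class SupportEvidence:
    """Corroborating evidence for the QC workflow.

    ``lumpy_intervals`` / ``cnvnator_intervals`` are typed interval sets so
    a DEL is only corroborated by DEL evidence; ``paragraph_genotypes``
    maps (sv id, sample) to the re-genotyped call for short SVs.
    """

    lumpy: _TypedIntervalIndex = field(default_factory=_TypedIntervalIndex)
    cnvnator: _TypedIntervalIndex = field(default_factory=_TypedIntervalIndex)
    paragraph_genotypes: dict[tuple[str, str], Genotype] = field(default_factory=dict)

    @classmethod
    def from_lists(
        cls,
        lumpy: Iterable[tuple[str, GenomicInterval]] = (),
        cnvnator: Iterable[tuple[str, GenomicInterval]] = (),
        paragraph: Optional[dict[tuple[str, str], Genotype]] = None,
    ) -> "SupportEvidence":
        return cls(
            lumpy=_TypedIntervalIndex(lumpy),
            cnvnator=_TypedIntervalIndex(cnvnator),
            paragraph_genotypes=dict(paragraph or {}),
        )


def build_exclusion_index(regions: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    idx: dict[str, IntervalTree] = {}
    for iv in regions:
        idx.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return idx


def exclude_regions(
    svs: Iterable[SVRecord], exclusion: dict[str, IntervalTree] | Iterable[GenomicInterval]
) -> list[SVRecord]:
    """Drop any SV overlapping a problematic region by ≥ 1 bp."""
    if not isinstance(exclusion, dict):
        exclusion = build_exclusion_index(exclusion)
    kept: list[SVRecord] = []
    n_removed = 0
    for sv in svs:
        tree = exclusion.get(sv.chrom)
        start, end = sv.interval.start, sv.interval.end
        if end == start:  # INS anchor: treat as the single anchored base
            end = start + 1
        if tree is not None and tree.overlap(start, end):
            n_removed += 1
            continue
        kept.append(sv)
    if n_removed:
        log.info("exclude_regions: removed %d SVs in problematic regions", n_removed)
    return kept


def apply_qc_workflow(
    svs: Iterable[SVRecord], evidence: SupportEvidence
) -> tuple[list[SVRecord], pd.DataFrame]:
    """Run the tiered retention rules; returns (passed, per-SV audit trace).

    Exactly one tier rule fires per SV; the audit records which, the
    evidence value it saw, and the verdict.
    """
    passed: list[SVRecord] = []
    audit_rows = []
    for sv in svs:
        tier = size_tier(sv)
        ok: bool
        rule: str
        detail: str
        if tier is SizeTier.SHORT:
            rule = "short_regenotype_confident"
            confident = [
                s
                for s in sv.genotypes
                if evidence.paragraph_genotypes.get((sv.id, s))
                in (Genotype.HET, Genotype.HOM)
            ]
            ok = bool(confident)
            detail = f"confident_carriers={len(confident)}"
        elif tier is SizeTier.MEDIUM:
            rule = "medium_ro_lumpy_or_cnvnator"
            ro = max(evidence.lumpy.best_ro(sv), evidence.cnvnator.best_ro(sv))
            ok = ro > RO_THRESHOLD
            detail = f"best_ro={ro:.4f}"
        elif tier is SizeTier.LONG:
            rule = "long_ro_cnvnator"
            ro = evidence.cnvnator.best_ro(sv)
            ok = ro > RO_THRESHOLD
            detail = f"best_ro={ro:.4f}"
        elif tier is SizeTier.OTHER:
            rule = "other_pass_through"
            ok = True
            detail = "INV/INS not overlap-filtered"
        else:  # UNTESTED: INV < 200 bp
            rule = "untested_tier_pass_through"
            ok = True
            sv.qc_flags.add("untested_tier")
            detail = "no tier defined for short INV"
        audit_rows.append(
            {
                "sv_id": sv.id,
                "svtype": sv.svtype.value,
                "svlen": sv.svlen,
                "tier": tier.value,
                "rule": rule,
                "passed": ok,
                "detail": detail,
            }
        )
        if ok:
            passed.append(sv)
    audit = pd.DataFrame(
        audit_rows,
        columns=["sv_id", "svtype", "svlen", "tier", "rule", "passed", "detail"],
    )
    return passed, audit


# sample-level BAM QC thresholds (strict inequalities)
MIN_COVERAGE = 15.0
MAX_CHIMERIC = 0.0005
MAX_CONTAMINATION = 0.05


def bam_qc_gate(metrics: pd.DataFrame) -> pd.Series:
    """Per-sample pass/fail/'UNEVALUATED' from alignment QC metrics.

    Requires columns mean_coverage, chimeric_fraction, contamination; an
    optional boolean ``insert_size_normal`` column is honoured when present.
    """
    required = ["mean_coverage", "chimeric_fraction", "contamination"]
    verdicts = {}
    for sample, row in metrics.iterrows():
        if any(col not in metrics.columns or pd.isna(row[col]) for col in required):
            verdicts[sample] = "UNEVALUATED"
            continue
        ok = (
            row["mean_coverage"] > MIN_COVERAGE
            and row["chimeric_fraction"] < MAX_CHIMERIC
            and row["contamination"] < MAX_CONTAMINATION
        )
        if "insert_size_normal" in metrics.columns and not pd.isna(
            row["insert_size_normal"]
        ):
            ok = ok and bool(row["insert_size_normal"])
        verdicts[sample] = "PASS" if ok else "FAIL"
    return pd.Series(verdicts, name="bam_qc")
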