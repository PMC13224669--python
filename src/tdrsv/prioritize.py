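"""Candidate-pathogenic-SV prioritization cascade.

Per patient, SVs flow through ordered stages and the first failure
terminates evaluation of that SV:

    RAW -> QC -> RARE -> DOSAGE_CLASS -> TDR_GENELIST -> INHERITANCE -> REPORT

* QC            — tiered quality-control verdict (from the filter module);
* RARE          — background AF < 0.01 across the multi-ancestry cohorts;
* DOSAGE_CLASS  — exonic/whole-gene DEL or DUP, or exonic INV;
* TDR_GENELIST  — TDR > 0.25 in the disease tissue for a gene on the
  curated disease gene list;
* INHERITANCE   — zygosity consistent with the gene's mode of inheritance
  (OMIM-style) or its tissue-specific dosage sensitivity (MoDs < 0.3);
* REPORT        — survivors, annotated (known-pathogenic overlap is an
  annotation only, never a gate: final calls stay manual).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .genemodel import GeneModel, SVGeneContext, classify_context
from .model import Genotype, SVRecord, SVType
from .popfreq import RARE_AF_THRESHOLD, merge_compatible
from .tdr import TDR_THRESHOLD, TdrResult

MODS_SENSITIVE_THRESHOLD = 0.3  # strict: MoDs < 0.3 = dosage sensitive

STAGES = [
    "RAW",
    "QC",
    "RARE",
    "DOSAGE_CLASS",
    "TDR_GENELIST",
    "INHERITANCE",
    "REPORT",
]


@dataclass
class GeneAnnotations:
    """Per-gene annotation tables consumed by the cascade.

    ``mods`` holds tissue-specific dosage-sensitivity percentiles in
    [0, 1] (0 = most constrained); ``inheritance`` holds OMIM-style mode
    sets (subsets of {AD, AR, XL}); ``known_pathogenic`` is a ClinVar-style
    list of SVs used for annotation only.
    """

    constraint: dict[str, float] = field(default_factory=dict)
    mods: dict[str, dict[str, float]] = field(default_factory=dict)
    inheritance: dict[str, frozenset[str]] = field(default_factory=dict)
    known_pathogenic: list[SVRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene, per_tissue in self.mods.items():
            for tissue, v in per_tissue.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"MoDs[{gene}][{tissue}]={v} outside [0,1]")

    def is_annotated(self, gene: str) -> bool:
        return gene in self.inheritance or gene in self.mods

    def known_overlap(self, sv: SVRecord) -> Optional[str]:
        """Id of a same-type known-pathogenic SV at > 80% reciprocal overlap."""
        for known in self.known_pathogenic:
            if merge_compatible(sv, known):
                return known.id
        return None


@dataclass
class CascadeConfig:
    tissue: str
    gene_list: frozenset[str]
    tdr_threshold: float = TDR_THRESHOLD
    af_threshold: float = RARE_AF_THRESHOLD
    mods_threshold: float = MODS_SENSITIVE_THRESHOLD


def dosage_class_filter(
    sv: SVRecord, contexts: Mapping[str, SVGeneContext]
) -> tuple[bool, str]:
    """Stage 4: keep dosage-disrupting categories only.

    Exonic/whole-gene deletions and duplications, or exonic inversions;
    insertions and purely intronic/intergenic SVs fail.
    """
    if sv.svtype in (SVType.DEL, SVType.DUP):
        hits = [
            g
            for g, c in contexts.items()
            if c in (SVGeneContext.EXONIC, SVGeneContext.WHOLE_GENE)
        ]
        if hits:
            return True, f"{sv.svtype.value} exonic/whole-gene in {','.join(sorted(hits))}"
        return False, "no exonic/whole-gene context"
    if sv.svtype is SVType.INV:
        hits = [g for g, c in contexts.items() if c is SVGeneContext.EXONIC]
        if hits:
            return True, f"INV exonic in {','.join(sorted(hits))}"
        return False, "inversion without exonic context"
    return False, f"{sv.svtype.value} not a dosage-disrupting category"


def tdr_genelist_filter(
    sv_id: str,
    tdr_results: Iterable[TdrResult],
    gene_list: frozenset[str],
    tissue: str,
    threshold: float = TDR_THRESHOLD,
) -> tuple[bool, list[str], str]:
    """Stage 5: defined TDR > threshold in the disease tissue, listed gene."""
    rows = [
        r
        for r in tdr_results
        if r.variant_id == sv_id and r.tissue == tissue and r.defined
    ]
    if not rows:
        return False, [], "no expressed gene"
    passing = sorted(
        {r.gene_id for r in rows if r.gene_id in gene_list and r.tdr > threshold}
    )
    if passing:
        return True, passing, f"TDR>{threshold} in {','.join(passing)}"
    listed = [r for r in rows if r.gene_id in gene_list]
    if listed:
        best = max(r.tdr for r in listed)
        return False, [], f"best TDR in listed genes {best:.3f} <= {threshold}"
    return False, [], "no listed gene affected"


def inheritance_consistency(
    sv: SVRecord,
    gene: str,
    annotations: GeneAnnotations,
    tissue: str,
    carrier_genotype: Genotype,
    second_hits: Iterable[str] = (),
    mods_threshold: float = MODS_SENSITIVE_THRESHOLD,
) -> tuple[bool, str]:
    """Stage 6: zygosity versus mode of inheritance / dosage sensitivity.

    Genes missing from every annotation table pass with an ``unannotated``
    rationale so novel candidate genes are not silently dropped.
    """
    if not annotations.is_annotated(gene):
        return True, "unannotated gene (flagged, not dropped)"
    modes = annotations.inheritance.get(gene, frozenset())
    mods_val = annotations.mods.get(gene, {}).get(tissue)
    dominant_like = "AD" in modes or (
        mods_val is not None and mods_val < mods_threshold
    )
    if dominant_like and carrier_genotype in (Genotype.HET, Genotype.HOM):
        why = "AD inheritance" if "AD" in modes else f"MoDs {mods_val:.2f} < {mods_threshold}"
        return True, why
    if modes == frozenset({"AR"}):
        if carrier_genotype is Genotype.HOM:
            return True, "biallelic loss in recessive gene"
        if gene in set(second_hits):
            return True, "heterozygous hit with second hit in recessive gene"
        return False, "single heterozygous hit in recessive gene"
    if carrier_genotype not in (Genotype.HET, Genotype.HOM):
        return False, "no confident carrier genotype"
    return False, (
        f"modes {sorted(modes) or 'none'} with MoDs "
        f"{'n/a' if mods_val is None else f'{mods_val:.2f}'} not consistent with zygosity"
    )


def run_cascade(
    svs: list[SVRecord],
    sample: str,
    genes: dict[str, GeneModel],
    tdr_results: list[TdrResult],
    annotations: GeneAnnotations,
    config: CascadeConfig,
    qc_passed: Optional[set[str]] = None,
    second_hits: Iterable[str] = (),
    segregation: Optional[Mapping[str, bool]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Run the full cascade for one patient.

    Returns (report, trace, per-stage surviving counts).  ``qc_passed``
    is the id set surviving the tiered QC workflow (None = all pass);
    ``segregation`` is an optional external per-SV verdict that decides
    the INHERITANCE stage when supplied (pedigree evidence hook).
    """
    tdr_by_variant: dict[str, list[TdrResult]] = {}
    for r in tdr_results:
        tdr_by_variant.setdefault(r.variant_id, []).append(r)

    trace_rows = []
    report_rows = []
    counts = {s: 0 for s in STAGES}

    def record(sv_id: str, stage: str, ok: bool, reason: str) -> None:
        trace_rows.append(
            {"sv_id": sv_id, "stage": stage, "passed": ok, "reason": reason}
        )

    for sv in svs:
        counts["RAW"] += 1
        record(sv.id, "RAW", True, "input")

        ok = qc_passed is None or sv.id in qc_passed
        record(sv.id, "QC", ok, "tiered QC" if ok else "failed tiered QC")
        if not ok:
            continue
        counts["QC"] += 1

        af = sv.background_af if sv.background_af is not None else 0.0
        ok = af < config.af_threshold
        record(
            sv.id,
            "RARE",
            ok,
            f"background AF {af:.4g} {'<' if ok else '>='} {config.af_threshold}",
        )
        if not ok:
            continue
        counts["RARE"] += 1

        contexts = {
            g.id: classify_context(sv, g)
            for g in genes.values()
            if g.chrom == sv.chrom
        }
        ok, reason = dosage_class_filter(sv, contexts)
        record(sv.id, "DOSAGE_CLASS", ok, reason)
        if not ok:
            continue
        counts["DOSAGE_CLASS"] += 1

        ok, passing_genes, reason = tdr_genelist_filter(
            sv.id,
            tdr_by_variant.get(sv.id, []),
            config.gene_list,
            config.tissue,
            config.tdr_threshold,
        )
        record(sv.id, "TDR_GENELIST", ok, reason)
        if not ok:
            continue
        counts["TDR_GENELIST"] += 1

        gt = sv.genotypes.get(sample, Genotype.MISSING)
        if segregation is not None and sv.id in segregation:
            ok = bool(segregation[sv.id])
            reason = "external segregation verdict"
            consistent_genes = passing_genes if ok else []
        else:
            consistent_genes = []
            reasons = []
            for g in passing_genes:
                g_ok, g_reason = inheritance_consistency(
                    sv,
                    g,
                    annotations,
                    config.tissue,
                    gt,
                    second_hits,
                    config.mods_threshold,
                )
                if g_ok:
                    consistent_genes.append(g)
                reasons.append(f"{g}: {g_reason}")
            ok = bool(consistent_genes)
            reason = "; ".join(reasons)
        record(sv.id, "INHERITANCE", ok, reason)
        if not ok:
            continue
        counts["INHERITANCE"] += 1

        counts["REPORT"] += 1
        record(sv.id, "REPORT", True, "candidate for manual review")
        tdrs = {
            r.gene_id: r.tdr
            for r in tdr_by_variant.get(sv.id, [])
            if r.tissue == config.tissue and r.defined
        }
        for g in consistent_genes:
            report_rows.append(
                {
                    "sample": sample,
                    "sv_id": sv.id,
                    "svtype": sv.svtype.value,
                    "chrom": sv.chrom,
                    "start": sv.interval.start,
                    "end": sv.interval.end,
                    "gene_id": g,
                    "context": contexts.get(g, SVGeneContext.INTERGENIC).value,
                    "tissue": config.tissue,
                    "tdr": tdrs.get(g),
                    "genotype": gt.value,
                    "background_af": af,
                    "constraint": annotations.constraint.get(g),
                    "mods": annotations.mods.get(g, {}).get(config.tissue),
                    "inheritance": ",".join(sorted(annotations.inheritance.get(g, ()))),
                    "known_pathogenic_overlap": annotations.known_overlap(sv),
                }
            )

    report = pd.DataFrame(
        report_rows,
        columns=[
            "sample",
            "sv_id",
            "svtype",
            "chrom",
            "start",
            "end",
            "gene_id",
            "context",
            "tissue",
            "tdr",
            "genotype",
            "background_af",
            "constraint",
            "mods",
            "inheritance",
            "known_pathogenic_overlap",
        ],
    )
    trace = pd.DataFrame(trace_rows, columns=["sv_id", "stage", "passed", "reason"])
    return report, trace, counts
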