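"""Multi-ancestry background allele-frequency database.

QC-passed callsets from several ancestry cohorts are merged by
single-linkage clustering of same-type SVs at > 80% reciprocal overlap
(Jasmine-like).  Each cluster gets a per-population allele frequency and
a background AF equal to the maximum across populations; SVs with
background AF < 0.01 are flagged rare.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .model import ALT_DOSE, Genotype, SVRecord, SVType, merge_genotypes
from .sv_filter import RO_THRESHOLD, reciprocal_overlap

log = logging.getLogger(__name__)

RARE_AF_THRESHOLD = 0.01  # strict: AF < 0.01 is rare

# insertion merging (interval RO is undefined for zero-width anchors)
INS_MAX_ANCHOR_DIST = 100
INS_MIN_LEN_RATIO = 0.8


@dataclass
class Cohort:
    """One ancestry cohort: population label, QC-passed SVs, sample list."""

    population: str
    svs: list[SVRecord]
    samples: list[str]


@dataclass
class SVCluster:
    members: list[tuple[str, SVRecord]]  # (population, record)
    representative: SVRecord
    per_pop_af: dict[str, float] = field(default_factory=dict)
    background_af: Optional[float] = None
    flags: set[str] = field(default_factory=set)

    @property
    def svtype(self) -> SVType:
        return self.representative.svtype

    @property
    def is_rare(self) -> Optional[bool]:
        if self.background_af is None:
            return None
        return self.background_af < RARE_AF_THRESHOLD


def compute_pop_af(sv: SVRecord, samples: list[str]) -> Optional[float]:
    """Alternate-allele frequency over a cohort's sample list.

    HET contributes 1 allele, HOM 2; the denominator counts only samples
    with a non-MISSING genotype (samples absent from the genotype map are
    reference).  Returns None when every genotype is MISSING.
    """
    alt = 0
    n_called = 0
    for s in samples:
        g = sv.genotypes.get(s, Genotype.HOMREF)
        if g is Genotype.MISSING:
            continue
        n_called += 1
        alt += ALT_DOSE[g]
    if n_called == 0:
        return None
    return alt / (2 * n_called)


def merge_compatible(a: SVRecord, b: SVRecord) -> bool:
    """Edge predicate for cross-cohort consolidation (same type required)."""
    if a.svtype is not b.svtype:
        return False
    if a.svtype is SVType.INS:
        if a.chrom != b.chrom:
            return False
        if abs(a.interval.start - b.interval.start) > INS_MAX_ANCHOR_DIST:
            return False
        ratio = min(a.svlen, b.svlen) / max(a.svlen, b.svlen)
        return ratio > INS_MIN_LEN_RATIO
    return reciprocal_overlap(a.interval, b.interval) > RO_THRESHOLD


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_svs(cohorts: Iterable[Cohort]) -> list[SVCluster]:
    """Single-linkage clustering of same-type SVs across cohorts.

    The representative of each cluster is the member with the largest
    carrier count (ties: smallest start, then smallest end, then id).
    The result is independent of cohort input order: members are sorted
    canonically before linkage.
    """
    entries: list[tuple[str, SVRecord]] = []
    for cohort in cohorts:
        entries.extend((cohort.population, sv) for sv in cohort.svs)
    # canonical order makes clustering independent of input order
    entries.sort(
        key=lambda e: (
            e[1].svtype.value,
            e[1].chrom,
            e[1].interval.start,
            e[1].interval.end,
            e[0],
            e[1].id,
        )
    )
    uf = _UnionFind(len(entries))
    # sweep within (svtype, chrom) groups; candidate pairs must be near
    # enough that RO > 0.8 (or the INS anchor rule) is possible
    by_group: dict[tuple[str, str], list[int]] = {}
    for i, (_, sv) in enumerate(entries):
        by_group.setdefault((sv.svtype.value, sv.chrom), []).append(i)
    for idxs in by_group.values():
        active: list[int] = []
        for i in idxs:
            sv_i = entries[i][1]
            lo = sv_i.interval.start - INS_MAX_ANCHOR_DIST
            active = [
                j
                for j in active
                if entries[j][1].interval.end >= lo
                or entries[j][1].svtype is SVType.INS
            ]
            for j in active:
                if merge_compatible(entries[j][1], sv_i):
                    uf.union(i, j)
            active.append(i)
    groups: dict[int, list[int]] = {}
    for i in range(len(entries)):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for idxs in sorted(groups):
        members = [entries[i] for i in groups[idxs]]
        rep = min(
            (sv for _, sv in members),
            key=lambda sv: (
                -sv.carrier_count,
                sv.interval.start,
                sv.interval.end,
                sv.id,
            ),
        )
        clusters.append(SVCluster(members=members, representative=rep))
    clusters.sort(
        key=lambda c: (
            c.representative.chrom,
            c.representative.interval.start,
            c.representative.interval.end,
            c.representative.id,
        )
    )
    return clusters


def assign_background_af(
    cluster: SVCluster, cohorts: Iterable[Cohort]
) -> SVCluster:
    """Fill per-population AFs and the max-across-populations background AF.

    Populations with no member in the cluster contribute AF 0 (an SV
    unseen across a genotyped cohort is evidence of rarity there).
    """
    per_pop: dict[str, float] = {}
    undefined = False
    for cohort in cohorts:
        gmaps = [sv.genotypes for pop, sv in cluster.members if pop == cohort.population]
        if not gmaps:
            per_pop[cohort.population] = 0.0
            continue
        merged = merge_genotypes(gmaps, cohort.samples)
        probe = SVRecord(
            id=cluster.representative.id,
            svtype=cluster.representative.svtype,
            interval=cluster.representative.interval,
            svlen=cluster.representative.svlen,
            genotypes=merged,
        )
        af = compute_pop_af(probe, cohort.samples)
        if af is None:
            undefined = True
            cluster.flags.add(f"all_missing:{cohort.population}")
            continue
        per_pop[cohort.population] = af
    cluster.per_pop_af = per_pop
    cluster.background_af = max(per_pop.values()) if per_pop else None
    if undefined and not per_pop:
        cluster.background_af = None
    return cluster


def build_background_db(cohorts: list[Cohort]) -> pd.DataFrame:
    """Cluster all cohorts and emit the background-AF database table."""
    clusters = cluster_svs(cohorts)
    rows = []
    for k, cl in enumerate(clusters):
        assign_background_af(cl, cohorts)
        rep = cl.representative
        row = {
            "cluster_id": f"BG{k:06d}",
            "svtype": rep.svtype.value,
            "chrom": rep.chrom,
            "start": rep.interval.start,
            "end": rep.interval.end,
            "svlen": rep.svlen,
            "n_members": len(cl.members),
            "background_af": cl.background_af,
            "rare": cl.is_rare,
        }
        for pop, af in sorted(cl.per_pop_af.items()):
            row[f"af_{pop}"] = af
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_background_af(
    svs: Iterable[SVRecord], db: pd.DataFrame
) -> list[SVRecord]:
    """Annotate patient SVs with the background AF of their matching cluster.

    A patient SV matches a database entry of the same type under the same
    merge predicate used to build the database; unmatched SVs get AF 0.
    """
    from .model import GenomicInterval  # local to avoid cycle at import time

    db_records = [
        SVRecord(
            id=str(r.cluster_id),
            svtype=SVType(r.svtype),
            interval=GenomicInterval(
                r.chrom, int(r.start), int(r.start) if r.svtype == "INS" else int(r.end)
            ),
            svlen=int(r.svlen),
        )
        for r in db.itertuples(index=False)
    ]
    afs = [float(a) if not pd.isna(a) else 0.0 for a in db["background_af"]]
    out = []
    for sv in svs:
        best = 0.0
        for rec, af in zip(db_records, afs):
            if merge_compatible(sv, rec):
                best = max(best, af)
        sv.background_af = best
        out.append(sv)
    return out
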