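"""Gene annotation, transcript expression lookup, and SV-gene geometry.

GTF input follows the Gencode dialect (gene/transcript/exon/CDS features
with gene_id/transcript_id/transcript_type attributes and an optional
MANE_Select tag); coordinates convert from 1-based inclusive to the
internal 0-based half-open convention on read.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

import gffutils
import pandas as pd

from .model import GenomicInterval, PointVariant, SVRecord, SVType

log = logging.getLogger(__name__)


@dataclass
class TranscriptModel:
    id: str
    gene_id: str
    biotype: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    is_mane: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.id}: overlapping exons")
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise ValueError(f"{self.id}: CDS segment outside exons")

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom, self.exons[0].start, self.exons[-1].end
        )

    @property
    def tss(self) -> int:
        """Strand-aware transcription start coordinate."""
        return self.span.start if self.strand == "+" else self.span.end - 1

    def disruption_targets(self) -> list[GenomicInterval]:
        """Intervals whose disruption knocks the transcript out.

        CDS for coding transcripts; exons for non-coding transcripts,
        which carry no CDS but still contribute to the expression
        denominator.
        """
        return self.cds if self.is_coding else self.exons


@dataclass
class GeneModel:
    id: str
    symbol: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.id}: gene without transcripts")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].span.chrom

    @property
    def span(self) -> GenomicInterval:
        """Union of all transcript spans."""
        return GenomicInterval(
            self.chrom,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
        )

    @property
    def transcript_ids(self) -> list[str]:
        return [t.id for t in self.transcripts]

    @property
    def mane_transcripts(self) -> list[str]:
        return [t.id for t in self.transcripts if t.is_mane]


class GtfParseError(ValueError):
    pass


def read_gtf(path: str) -> dict[str, GeneModel]:
    """Parse a Gencode-style GTF into gene models keyed by gene id."""
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise GtfParseError(f"{path}: cannot parse GTF ({exc})") from None

    transcripts: dict[str, dict] = {}
    for feat in db.features_of_type("transcript"):
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise GtfParseError(
                f"{path}: transcript at {feat.seqid}:{feat.start} missing {exc}"
            ) from None
        biotype = (feat.attributes.get("transcript_type") or ["protein_coding"])[0]
        tags = feat.attributes.get("tag") or []
        transcripts[tid] = {
            "id": tid,
            "gene_id": gid,
            "biotype": biotype,
            "strand": feat.strand,
            "is_mane": "MANE_Select" in tags,
            "exons": [],
            "cds": [],
            "symbol": (feat.attributes.get("gene_name") or [gid])[0],
        }
    for ftype, key in (("exon", "exons"), ("CDS", "cds")):
        for feat in db.features_of_type(ftype):
            try:
                tid = feat.attributes["transcript_id"][0]
            except KeyError:
                raise GtfParseError(
                    f"{path}: {ftype} at {feat.seqid}:{feat.start} missing transcript_id"
                ) from None
            if tid in transcripts:
                transcripts[tid][key].append(
                    GenomicInterval(feat.seqid, feat.start - 1, feat.end)
                )

    genes: dict[str, GeneModel] = {}
    by_gene: dict[str, list[TranscriptModel]] = {}
    symbols: dict[str, str] = {}
    for tid, spec in transcripts.items():
        if not spec["exons"]:
            log.warning("transcript %s has no exons; dropped", tid)
            continue
        tm = TranscriptModel(
            id=spec["id"],
            gene_id=spec["gene_id"],
            biotype=spec["biotype"],
            strand=spec["strand"],
            exons=spec["exons"],
            cds=spec["cds"],
            is_mane=spec["is_mane"],
        )
        by_gene.setdefault(spec["gene_id"], []).append(tm)
        symbols[spec["gene_id"]] = spec["symbol"]
    for gid, tms in by_gene.items():
        genes[gid] = GeneModel(id=gid, symbol=symbols[gid], transcripts=tms)
    return genes


def write_gtf(genes: dict[str, GeneModel], path: str) -> None:
    """Emit gene models back to Gencode-style GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for gene in sorted(genes.values(), key=lambda g: (g.chrom, g.span.start)):
            span = gene.span
            attrs = f'gene_id "{gene.id}"; gene_name "{gene.symbol}";'
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{gene.transcripts[0].strand}\t.\t{attrs}\n"
            )
            for t in gene.transcripts:
                tattrs = (
                    f'gene_id "{gene.id}"; transcript_id "{t.id}"; '
                    f'gene_name "{gene.symbol}"; transcript_type "{t.biotype}";'
                )
                if t.is_mane:
                    tattrs += ' tag "MANE_Select";'
                ts = t.span
                fh.write(
                    f"{gene.chrom}\tsim\ttranscript\t{ts.start + 1}\t{ts.end}\t.\t"
                    f"{t.strand}\t.\t{tattrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{gene.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\t{tattrs}\n"
                    )
                for c in t.cds:
                    fh.write(
                        f"{gene.chrom}\tsim\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                        f"{t.strand}\t0\t{tattrs}\n"
                    )


class TpmMatrix:
    """Transcript × tissue median-TPM lookup backed by a DataFrame.

    Unknown transcripts look up as 0 with a logged warning (annotation /
    expression table mismatches should be visible, not fatal).
    """

    def __init__(self, values: pd.DataFrame):
        if (values.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        self._df = values.astype(float)

    @property
    def tissues(self) -> list[str]:
        return list(self._df.columns)

    @property
    def transcripts(self) -> list[str]:
        return list(self._df.index)

    def get(self, transcript_id: str, tissue: str) -> float:
        if tissue not in self._df.columns:
            raise KeyError(
                f"unknown tissue {tissue!r}; available: {', '.join(self.tissues)}"
            )
        if transcript_id not in self._df.index:
            log.warning("transcript %s absent from TPM table; using 0", transcript_id)
            return 0.0
        return float(self._df.at[transcript_id, tissue])

    def to_tsv(self, path: str) -> None:
        self._df.to_csv(path, sep="\t", index_label="transcript_id")

    @classmethod
    def from_tsv(cls, path: str) -> "TpmMatrix":
        df = pd.read_csv(path, sep="\t", index_col="transcript_id")
        return cls(df)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df


class SVGeneContext(str, Enum):
    """Positional class of an SV relative to one gene.

    Mutually exclusive and exhaustive: WHOLE_GENE (contains the full gene
    span) > EXONIC (touches ≥1 exon of any transcript) > INTRONIC
    (inside the span but exon-free) > INTERGENIC.
    """

    INTERGENIC = "INTERGENIC"
    INTRONIC = "INTRONIC"
    EXONIC = "EXONIC"
    WHOLE_GENE = "WHOLE_GENE"


def classify_context(sv: Union[SVRecord, PointVariant], gene: GeneModel) -> SVGeneContext:
    if isinstance(sv, PointVariant):
        iv = GenomicInterval(sv.chrom, sv.pos, sv.pos + 1)
        whole_gene_possible = False
    else:
        iv = sv.interval
        if sv.svtype is SVType.INS:
            # insertions are classified by their anchor point
            iv = GenomicInterval(iv.chrom, iv.start, iv.start + 1)
            whole_gene_possible = False
        else:
            whole_gene_possible = True
    span = gene.span
    if iv.chrom != span.chrom:
        return SVGeneContext.INTERGENIC
    if whole_gene_possible and iv.contains(span):
        return SVGeneContext.WHOLE_GENE
    if any(iv.overlaps(e) for t in gene.transcripts for e in t.exons):
        return SVGeneContext.EXONIC
    if iv.overlaps(span):
        return SVGeneContext.INTRONIC
    return SVGeneContext.INTERGENIC


def tss_distance(sv: Union[SVRecord, PointVariant], gene: GeneModel) -> Optional[int]:
    """Minimum over transcripts of the gap between the SV and the TSS.

    0 when the SV covers a TSS; distances are measured to the nearest
    covered base.  None when the SV is on another chromosome.
    """
    if isinstance(sv, PointVariant):
        start, end, chrom = sv.pos, sv.pos + 1, sv.chrom
    else:
        start, end, chrom = sv.interval.start, sv.interval.end, sv.chrom
        if end == start:  # INS anchor
            end = start + 1
    if chrom != gene.chrom:
        return None
    best = None
    for t in gene.transcripts:
        tss = t.tss
        if start <= tss < end:
            d = 0
        elif tss < start:
            d = start - tss
        else:
            d = tss - (end - 1)
        best = d if best is None else min(best, d)
    return best
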