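"""Read and write SV call sets and interval files.

VCF records use 1-based inclusive POS/END; they are converted to the
internal 0-based half-open convention on read (POS-1, END) and back on
write.  BED files are already half-open and pass through unchanged.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
import pysam

from .model import Genotype, GenomicInterval, SVRecord, SVType, classify_gt_tuple

log = logging.getLogger(__name__)

SUPPORTED_SVTYPES = {"DEL", "DUP", "INV", "INS", "BND"}

_BND_ALT_RE = re.compile(
    r"^(?P<t1>[A-Za-z.*]*)(?P<b1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)"
    r"(?P<b2>[\[\]])(?P<t2>[A-Za-z.*]*)$"
)


class SVParseError(ValueError):
    """Malformed SV input; the message names the offending file/line."""


@dataclass
class BreakendRecord:
    """One half of a BND mate pair, kept until mates are resolved."""

    id: str
    chrom: str
    pos: int  # 0-based
    alt: str
    mate_id: Optional[str] = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    source: str = ""

    def junction_class(self) -> Optional[str]:
        """'RR' for t]p] alts, 'LL' for [p[t alts, else None.

        Inversion junctions join two same-orientation breakends, so an
        intra-chromosomal mate pair is inversion-compatible only when
        both alts fall in the same class.
        """
        m = _BND_ALT_RE.match(self.alt)
        if not m:
            return None
        b1, b2, t1, t2 = m.group("b1"), m.group("b2"), m.group("t1"), m.group("t2")
        if b1 != b2:
            return None
        if b1 == "]" and t1 and not t2:
            return "RR"
        if b1 == "[" and t2 and not t1:
            return "LL"
        return None

    def mate_locus(self) -> Optional[tuple[str, int]]:
        m = _BND_ALT_RE.match(self.alt)
        if not m:
            return None
        return m.group("chrom"), int(m.group("pos")) - 1


def convert_bnd_to_inv(
    a: BreakendRecord, b: BreakendRecord
) -> Optional[SVRecord]:
    """Convert a mated BND pair into a single INV record.

    Returns None (with a logged warning) for inter-chromosomal pairs,
    orientation-incompatible pairs, self-mated or degenerate pairs.
    """
    if a.chrom != b.chrom:
        log.warning("BND pair %s/%s is inter-chromosomal; dropped", a.id, b.id)
        return None
    ca, cb = a.junction_class(), b.junction_class()
    if ca is None or cb is None or ca != cb:
        log.warning("BND pair %s/%s orientation-incompatible; dropped", a.id, b.id)
        return None
    lo, hi = min(a.pos, b.pos), max(a.pos, b.pos)
    if hi <= lo:
        log.warning("BND pair %s/%s spans nothing; dropped", a.id, b.id)
        return None
    genotypes = dict(b.genotypes)
    genotypes.update(a.genotypes)
    return SVRecord(
        id=f"{a.id}_INV",
        svtype=SVType.INV,
        interval=GenomicInterval(a.chrom, lo, hi),
        svlen=hi - lo,
        genotypes=genotypes,
        source=a.source,
        qc_flags={"from_bnd"},
    )


def _pair_breakends(bnds: list[BreakendRecord]) -> list[SVRecord]:
    by_id = {b.id: b for b in bnds}
    used: set[str] = set()
    out: list[SVRecord] = []
    for b in bnds:
        if b.id in used:
            continue
        mate = None
        if b.mate_id and b.mate_id in by_id and b.mate_id != b.id:
            mate = by_id[b.mate_id]
        else:
            locus = b.mate_locus()
            if locus is not None:
                for cand in bnds:
                    if cand.id != b.id and cand.id not in used and (
                        cand.chrom,
                        cand.pos,
                    ) == locus:
                        mate = cand
                        break
        if mate is None:
            log.warning("unmated BND %s; dropped", b.id)
            used.add(b.id)
            continue
        used.add(b.id)
        used.add(mate.id)
        inv = convert_bnd_to_inv(b, mate)
        if inv is not None:
            out.append(inv)
    return out


def read_sv_vcf(path: str, dialect: str = "manta") -> list[SVRecord]:
    """Read a Manta-style SV VCF into normalized :class:`SVRecord` objects.

    Multi-allelic lines are split into one record per ALT.  BND mates are
    paired and converted to INV; records of unsupported SVTYPE are skipped
    with a logged count.
    """
    records: list[SVRecord] = []
    bnds: list[BreakendRecord] = []
    n_skipped_type = 0
    n_skipped_flag = 0
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise SVParseError(f"{path}: cannot parse VCF header ({exc})") from None
    try:
        iterator = enumerate(vf.fetch() if vf.index is not None else vf, start=1)
        for i, rec in iterator:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                n_skipped_flag += 1
                continue
            if svtype not in SUPPORTED_SVTYPES:
                n_skipped_type += 1
                continue
            alts = rec.alts or ()
            for ai in range(1, len(alts) + 1):
                genotypes = {
                    s: classify_gt_tuple(rec.samples[s].get("GT"), ai)
                    for s in rec.samples
                }
                rid = rec.id or f"{rec.chrom}_{rec.pos}_{svtype}"
                if len(alts) > 1:
                    rid = f"{rid}_alt{ai}"
                if svtype == "BND":
                    bnds.append(
                        BreakendRecord(
                            id=rid,
                            chrom=rec.chrom,
                            pos=rec.pos - 1,
                            alt=alts[ai - 1],
                            mate_id=_first(rec.info.get("MATEID")),
                            genotypes=genotypes,
                            source=dialect,
                        )
                    )
                    continue
                start = rec.start  # POS - 1
                if svtype == "INS":
                    svlen = abs(_first(rec.info.get("SVLEN"), 0) or 0)
                    if svlen <= 0:
                        n_skipped_flag += 1
                        continue
                    interval = GenomicInterval(rec.chrom, start, start)
                else:
                    # prefer SVLEN when present: htslib rewrites rec.stop
                    # from SVLEN with a different off-by-one convention
                    svlen_info = _first(rec.info.get("SVLEN"))
                    if svlen_info:
                        end = start + abs(int(svlen_info))
                    else:
                        end = rec.stop  # END, or POS + len(REF) - 1
                    if end <= start:
                        raise SVParseError(
                            f"{path}: record {rec.id or i} ({rec.chrom}:{rec.pos}) "
                            f"has END <= POS"
                        )
                    interval = GenomicInterval(rec.chrom, start, end)
                    svlen = end - start
                records.append(
                    SVRecord(
                        id=rid,
                        svtype=SVType(svtype),
                        interval=interval,
                        svlen=svlen,
                        genotypes=genotypes,
                        source=dialect,
                    )
                )
    except SVParseError:
        raise
    except Exception as exc:  # pysam raises assorted errors on malformed bodies
        raise SVParseError(f"{path}: malformed VCF record ({exc})") from None
    records.extend(_pair_breakends(bnds))
    if n_skipped_type:
        log.info("%s: skipped %d records with unsupported SVTYPE", path, n_skipped_type)
    if n_skipped_flag:
        log.info("%s: skipped %d records lacking SVTYPE/SVLEN", path, n_skipped_flag)
    return records


def _first(val, default=None):
    if val is None:
        return default
    if isinstance(val, (tuple, list)):
        return val[0] if val else default
    return val


def write_sv_vcf(
    records: Iterable[SVRecord], path: str, samples: Optional[list[str]] = None
) -> None:
    """Write records as a minimal VCF 4.2 with SVTYPE/END/SVLEN and GT."""
    records = list(records)
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.genotypes:
                seen.setdefault(s)
        samples = list(seen)
    contigs: dict[str, int] = {}
    for r in records:
        hi = max(r.interval.end, r.interval.start + r.svlen) + 10_000
        contigs[r.chrom] = max(contigs.get(r.chrom, 0), hi)
    gt_str = {
        Genotype.HOMREF: "0/0",
        Genotype.HET: "0/1",
        Genotype.HOM: "1/1",
        Genotype.MISSING: "./.",
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in sorted(contigs.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write(
            '##INFO=<ID=BACKGROUND_AF,Number=1,Type=Float,'
            'Description="Max allele frequency across background populations">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + samples) + "\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.interval.start, r.id)):
            pos = r.interval.start + 1
            end = pos if r.svtype is SVType.INS else r.interval.end
            svlen = -r.svlen if r.svtype is SVType.DEL else r.svlen
            info = f"SVTYPE={r.svtype.value};END={end};SVLEN={svlen}"
            if r.background_af is not None:
                info += f";BACKGROUND_AF={r.background_af:.6g}"
            gts = [gt_str[r.genotypes.get(s, Genotype.MISSING)] for s in samples]
            row = [
                r.chrom,
                str(pos),
                r.id,
                "N",
                f"<{r.svtype.value}>",
                ".",
                "PASS",
                info,
                "GT",
            ] + gts
            fh.write("\t".join(row) + "\n")


def read_interval_bed(path: str) -> list[GenomicInterval]:
    """Read a 3+ column BED; comment/track lines skipped, coordinates kept as-is."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise SVParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise SVParseError(
                    f"{path}:{lineno}: non-numeric BED coordinates"
                ) from None
            if end <= start or start < 0:
                raise SVParseError(f"{path}:{lineno}: invalid interval [{start},{end})")
            out.append(GenomicInterval(chrom, start, end))
    return out


def read_support_bed(path: str) -> list[tuple[str, GenomicInterval]]:
    """Read a BED whose 4th column carries the SV type of each support call."""
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise SVParseError(f"{path}:{lineno}: support BED needs 4 columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError:
                raise SVParseError(f"{path}:{lineno}: invalid support interval") from None
            out.append((parts[3], iv))
    return out


def records_to_table(records: Iterable[SVRecord]) -> pd.DataFrame:
    """Flat one-row-per-SV table (genotypes serialized as sample:GT pairs)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "svtype": r.svtype.value,
                "chrom": r.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "svlen": r.svlen,
                "source": r.source,
                "qc_flags": ",".join(sorted(r.qc_flags)),
                "background_af": r.background_af,
                "genotypes": ";".join(
                    f"{s}:{g.value}" for s, g in sorted(r.genotypes.items())
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "svtype",
            "chrom",
            "start",
            "end",
            "svlen",
            "source",
            "qc_flags",
            "background_af",
            "genotypes",
        ],
    )


def records_from_table(df: pd.DataFrame) -> list[SVRecord]:
    out = []
    for row in df.itertuples(index=False):
        genotypes = {}
        if isinstance(row.genotypes, str) and row.genotypes:
            for pair in row.genotypes.split(";"):
                s, g = pair.split(":")
                genotypes[s] = Genotype(g)
        af = row.background_af
        if pd.isna(af):
            af = None
        out.append(
            SVRecord(
                id=row.id,
                svtype=SVType(row.svtype),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                svlen=int(row.svlen),
                genotypes=genotypes,
                source=row.source if isinstance(row.source, str) else "",
                qc_flags=set(row.qc_flags.split(","))
                if isinstance(row.qc_flags, str) and row.qc_flags
                else set(),
                background_af=af,
            )
        )
    return out
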