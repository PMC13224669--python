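"""Deterministic synthetic-data generator.

Produces every input the toolkit consumes — toy gene annotation with
multi-isoform genes, transcript × tissue TPM tables, cohort callsets
with planted common/rare SVs, support evidence, patient cohorts with a
known pathogenic SV, and expression matrices with TDR-proportional
dosage effects — together with truth tables sufficient to score every
downstream module without any external data.

Gene layout: every gene owns a shared 5' exon, one private exon per
transcript in its own 2 kb slot, and a shared 3' exon; the coding
sequence lives only in the private exon, so a deletion over a contiguous
run of slots disrupts exactly that run of transcripts.  TPM shares per
transcript are constructed directly, which makes each planted SV's TDR
exact by construction rather than approximated by breakpoint sampling.

All randomness derives from ``FixtureSpec.seed``; the same seed and spec
produce byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genemodel import GeneModel, TpmMatrix, TranscriptModel, write_gtf
from .model import Genotype, GenomicInterval, SVRecord, SVType
from .outlier_stats import ExpressionMatrix
from .popfreq import Cohort
from .prioritize import GeneAnnotations
from .sv_filter import SupportEvidence

DEFAULT_TISSUES = ("Retina", "Cerebellum", "Testis", "Liver", "Heart", "Lung")

# gene layout constants (bp)
_GENE0 = 100_000
_GENE_SPACING = 50_000
_SHARED_EXON = 300
_SLOT_OFFSET = 1_000
_SLOT_PITCH = 2_000
_PRIVATE_EXON = 500
_CDS_LO, _CDS_HI = 100, 400  # CDS within the private exon


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic data.

    Defaults are the desk-scale conditions used throughout the test
    suite: 40 genes with 2-4 transcripts over 3 tissues, two background
    cohorts of 60 and 75 genotyped samples, log2-scale expression noise
    of 0.5 and a confounder loading of 0.5.
    """

    seed: int = 0
    n_genes: int = 40
    transcripts_per_gene: tuple[int, int] = (2, 4)
    n_tissues: int = 3
    cohorts: dict[str, int] = field(default_factory=lambda: {"EAS": 60, "EUR": 75})
    noise_sd: float = 0.5
    confounder_loading: float = 0.5
    common_af: float = 0.05
    het_del_factor: float = 0.5  # dosage lost per unit TDR for a HET DEL
    dup_gain_factor: float = 0.5  # dosage gained per unit TDR per extra copy

    @property
    def tissues(self) -> list[str]:
        base = list(DEFAULT_TISSUES)
        while len(base) < self.n_tissues:
            base.append(f"Tissue{len(base)}")
        return base[: self.n_tissues]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GeneLayout:
    gene_id: str
    slots: list[GenomicInterval]  # private exon per transcript, 5'->3'
    intron_gap: GenomicInterval  # guaranteed exon-free interval in the gene
    span: GenomicInterval


@dataclass
class Annotation:
    genes: dict[str, GeneModel]
    tpm: TpmMatrix
    tissues: list[str]
    layout: dict[str, GeneLayout]
    shares: pd.DataFrame  # (gene × tissue) TPM share of transcript 0

    def prefix_fraction(self, gene_id: str, tissue: str, k: int) -> float:
        """Exact TPM fraction of the first k transcripts of a gene."""
        gene = self.genes[gene_id]
        total = sum(self.tpm.get(t.id, tissue) for t in gene.transcripts)
        if total == 0:
            return float("nan")
        head = sum(self.tpm.get(t.id, tissue) for t in gene.transcripts[:k])
        return head / total

    def del_over_slots(self, gene_id: str, k0: int, k1: int, pad: int = 20) -> GenomicInterval:
        """Interval covering private slots k0..k1 (inclusive) and nothing else."""
        slots = self.layout[gene_id].slots
        return GenomicInterval(
            slots[k0].chrom, slots[k0].start - pad, slots[k1].end + pad
        )


def generate_annotation(spec: FixtureSpec) -> Annotation:
    """Build the toy genome annotation and its transcript × tissue TPMs.

    Deterministic role genes anchor downstream studies: gene 0 switches
    dominant isoform between the first two tissues, genes 1-2 carry a
    high (0.8) first-transcript share, gene 3 a low (0.1) share, gene 4
    a high (0.85) share, and the last gene is silent in the first
    tissue.  All other shares are drawn uniformly.
    """
    rng = spec.rng(1)
    tissues = spec.tissues
    lo, hi = spec.transcripts_per_gene
    genes: dict[str, GeneModel] = {}
    layout: dict[str, GeneLayout] = {}
    tpm_rows: dict[str, list[float]] = {}
    share_rows = {}
    for g in range(spec.n_genes):
        gid = f"G{g:03d}"
        n_t = int(rng.integers(lo, hi + 1))
        if g <= 4:
            n_t = max(n_t, 2)  # role genes need >= 2 isoforms
        start = _GENE0 + g * _GENE_SPACING
        shared_a = GenomicInterval("chr1", start, start + _SHARED_EXON)
        slots = []
        transcripts = []
        for k in range(n_t):
            s = start + _SLOT_OFFSET + k * _SLOT_PITCH
            slots.append(GenomicInterval("chr1", s, s + _PRIVATE_EXON))
        tail = start + _SLOT_OFFSET + n_t * _SLOT_PITCH
        shared_b = GenomicInterval("chr1", tail, tail + _SHARED_EXON)
        noncoding_idx = n_t - 1 if n_t >= 3 else None
        for k in range(n_t):
            tid = f"{gid}T{k}"
            coding = k != noncoding_idx
            transcripts.append(
                TranscriptModel(
                    id=tid,
                    gene_id=gid,
                    biotype="protein_coding" if coding else "lncRNA",
                    strand="+",
                    exons=[shared_a, slots[k], shared_b],
                    cds=[
                        GenomicInterval(
                            "chr1", slots[k].start + _CDS_LO, slots[k].start + _CDS_HI
                        )
                    ]
                    if coding
                    else [],
                    is_mane=(k == 0),
                )
            )
        gene = GeneModel(id=gid, symbol=f"SYM{g:03d}", transcripts=transcripts)
        genes[gid] = gene
        gap = GenomicInterval(
            "chr1", slots[0].end + 200, slots[0].end + 200 + 600
        )  # inside the inter-slot intron, exon-free by construction
        layout[gid] = GeneLayout(gene_id=gid, slots=slots, intron_gap=gap, span=gene.span)

        # per-tissue TPMs: engineered first-transcript share, rest Dirichlet
        shares_g = []
        for ti, tissue in enumerate(tissues):
            total = float(np.round(10 ** rng.normal(1.2, 0.4), 3))
            if g == spec.n_genes - 1 and ti == 0:
                total = 0.0  # silent gene/tissue: exercises UNDEFINED TDR
            if g == 0:
                s0 = 0.8 if ti == 0 else 0.1
            elif g in (1, 2):
                s0 = 0.8
            elif g == 3:
                s0 = 0.1
            elif g == 4:
                s0 = 0.85
            else:
                s0 = float(rng.uniform(0.05, 0.95))
            rest = rng.dirichlet(np.ones(n_t - 1)) * (1 - s0) if n_t > 1 else []
            if g == 0 and ti == 1:
                # isoform switch: transcript 1 dominates in the second tissue
                rest = np.asarray(rest, dtype=float)
                if len(rest):
                    rest[:] = (1 - s0 - 0.8) / max(len(rest) - 1, 1)
                    rest[0] = 0.8
            parts = np.concatenate([[s0], np.asarray(rest, dtype=float)])
            for k in range(n_t):
                tpm_rows.setdefault(f"{gid}T{k}", [0.0] * len(tissues))[ti] = float(
                    np.round(total * parts[k], 6)
                )
            shares_g.append(s0 if total > 0 else np.nan)
        share_rows[gid] = shares_g
    tpm = TpmMatrix(
        pd.DataFrame.from_dict(tpm_rows, orient="index", columns=tissues)
    )
    shares = pd.DataFrame.from_dict(share_rows, orient="index", columns=tissues)
    return Annotation(genes=genes, tpm=tpm, tissues=tissues, layout=layout, shares=shares)


# ---------------------------------------------------------------------------
# QC benchmark cohort: validated SVs vs decoys with engineered support


def _support_interval(iv: GenomicInterval, ro: float) -> GenomicInterval:
    """Same-length interval shifted so its reciprocal overlap with iv is ~ro."""
    shift = int(round(iv.length * (1 - ro)))
    return GenomicInterval(iv.chrom, iv.start + shift, iv.end + shift)


@dataclass
class QcCohort:
    svs: list[SVRecord]
    evidence: SupportEvidence
    truth: pd.DataFrame  # sv_id, tier, category, validated
    samples: list[str]


def generate_qc_cohort(
    spec: FixtureSpec, n_validated: int = 100, n_decoys: int = 100
) -> QcCohort:
    """Planted validated SVs and decoys for the tiered QC workflow.

    Validated SVs carry support with reciprocal overlap > 0.8 from the
    tier-appropriate caller (or a confident re-genotyped call for short
    SVs); decoys carry support at RO ≤ 0.8, support from the wrong
    caller, or a non-confident re-genotyped call.
    """
    rng = spec.rng(2)
    samples = [f"Q{i:02d}" for i in range(10)]
    validated_templates = [
        ("short_del_confident", "DEL", 150, None),
        ("medium_del_lumpy", "DEL", 5_000, ("lumpy", 0.95)),
        ("medium_dup_cnvnator", "DUP", 30_000, ("cnvnator", 0.9)),
        ("long_del_cnvnator", "DEL", 150_000, ("cnvnator", 0.93)),
        ("inv_passthrough", "INV", 5_000, None),
        ("ins_passthrough", "INS", 300, None),
    ]
    decoy_templates = [
        ("short_del_homref", "DEL", 150, None),
        ("short_ins_missing", "INS", 120, None),
        ("medium_del_low_ro", "DEL", 5_000, ("lumpy", 0.7)),
        ("medium_dup_low_ro", "DUP", 30_000, ("cnvnator", 0.75)),
        ("long_del_wrong_caller", "DEL", 150_000, ("lumpy", 0.95)),
        ("long_dup_low_ro", "DUP", 150_000, ("cnvnator", 0.6)),
    ]
    svs: list[SVRecord] = []
    lumpy: list[tuple[str, GenomicInterval]] = []
    cnvnator: list[tuple[str, GenomicInterval]] = []
    paragraph: dict[tuple[str, str], Genotype] = {}
    truth_rows = []
    slot_pitch = 400_000  # keeps support evidence from leaking across SVs
    idx = 0
    for validated, n, templates in (
        (True, n_validated, validated_templates),
        (False, n_decoys, decoy_templates),
    ):
        for i in range(n):
            cat, svtype, length, support = templates[i % len(templates)]
            start = 10_000 + idx * slot_pitch
            idx += 1
            carrier = samples[int(rng.integers(len(samples)))]
            genotypes = {carrier: Genotype.HET}
            if svtype == "INS":
                interval = GenomicInterval("chr2", start, start)
            else:
                interval = GenomicInterval("chr2", start, start + length)
            sv = SVRecord(
                id=f"QC{idx:05d}",
                svtype=SVType(svtype),
                interval=interval,
                svlen=length,
                genotypes=genotypes,
                source="manta",
            )
            svs.append(sv)
            if support is not None:
                caller, ro = support
                si = _support_interval(
                    GenomicInterval("chr2", start, start + length), ro
                )
                (lumpy if caller == "lumpy" else cnvnator).append((svtype, si))
            if cat == "short_del_confident":
                paragraph[(sv.id, carrier)] = Genotype.HET
            elif cat == "short_del_homref":
                paragraph[(sv.id, carrier)] = Genotype.HOMREF
            # short_ins_missing: deliberately absent from the re-genotyped set
            truth_rows.append(
                {"sv_id": sv.id, "category": cat, "validated": validated}
            )
    evidence = SupportEvidence.from_lists(
        lumpy=lumpy, cnvnator=cnvnator, paragraph=paragraph
    )
    return QcCohort(
        svs=svs,
        evidence=evidence,
        truth=pd.DataFrame(truth_rows),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Background cohorts with planted allele frequencies


@dataclass
class AfStudy:
    cohorts: list[Cohort]
    truth: pd.DataFrame  # sv_id, target AFs, realized AFs, rare flag


def _genotypes_for_af(
    samples: list[str], af: float, rng: np.random.Generator
) -> tuple[dict[str, Genotype], float]:
    """Exact-count HET genotypes realizing the requested AF."""
    n_alt = int(round(af * 2 * len(samples)))
    n_alt = min(n_alt, len(samples))
    chosen = rng.choice(len(samples), size=n_alt, replace=False) if n_alt else []
    gts = {samples[int(i)]: Genotype.HET for i in chosen}
    return gts, n_alt / (2 * len(samples))


def generate_af_cohorts(
    spec: FixtureSpec,
    planted: Optional[list[dict]] = None,
    n_common: int = 20,
    n_rare: int = 20,
) -> AfStudy:
    """Background cohorts with SVs planted at known per-population AFs.

    Each planted SV appears in every population where its target AF is
    positive, as a slightly jittered copy (so cross-cohort merging is
    exercised); common SVs target ``spec.common_af`` in one population,
    rare SVs a single alternate allele in one population.
    """
    rng = spec.rng(3)
    pops = list(spec.cohorts)
    pop_samples = {
        p: [f"{p}{i:03d}" for i in range(n)] for p, n in spec.cohorts.items()
    }
    if planted is None:
        planted = []
        for i in range(n_common):
            pop = pops[i % len(pops)]
            afs = {pop: spec.common_af}
            # half the common SVs also segregate at low AF elsewhere
            if i % 2 == 0 and len(pops) > 1:
                other = pops[(i + 1) % len(pops)]
                afs[other] = 0.004
            planted.append({"svtype": "DEL" if i % 3 else "DUP", "afs": afs})
        for i in range(n_rare):
            pop = pops[i % len(pops)]
            n2 = 2 * spec.cohorts[pop]
            planted.append({"svtype": "DEL", "afs": {pop: 1.0 / n2}})
    cohort_svs: dict[str, list[SVRecord]] = {p: [] for p in pops}
    truth_rows = []
    for i, plant in enumerate(planted):
        length = int(rng.integers(1_000, 20_000))
        start = 5_000_000 + i * 100_000
        realized = {}
        for pop, af in plant["afs"].items():
            jitter = int(rng.integers(0, max(1, length // 50)))
            iv = GenomicInterval("chr3", start + jitter, start + jitter + length)
            gts, real_af = _genotypes_for_af(pop_samples[pop], af, rng)
            realized[pop] = real_af
            cohort_svs[pop].append(
                SVRecord(
                    id=f"AF{i:04d}_{pop}",
                    svtype=SVType(plant["svtype"]),
                    interval=iv,
                    svlen=length,
                    genotypes=gts,
                    source="manta",
                )
            )
        max_af = max(realized.values())
        truth_rows.append(
            {
                "plant_id": f"AF{i:04d}",
                "svtype": plant["svtype"],
                "chrom": "chr3",
                "start": start,
                "length": length,
                "max_realized_af": max_af,
                "rare": max_af < 0.01,
            }
        )
    cohorts = [Cohort(p, cohort_svs[p], pop_samples[p]) for p in pops]
    return AfStudy(cohorts=cohorts, truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Patient cohort with one planted pathogenic SV per patient


@dataclass
class PatientStudy:
    patients: dict[str, list[SVRecord]]
    qc_passed: dict[str, set[str]]
    truth: pd.DataFrame  # patient, sv_id, category, pathogenic
    annotations: GeneAnnotations
    gene_list: frozenset[str]
    tissue: str
    background: AfStudy
    annotation: Annotation


def generate_patient_cohort(
    spec: FixtureSpec,
    ann: Optional[Annotation] = None,
    n_patients: int = 50,
    n_qc_fail: int = 6,
) -> PatientStudy:
    """End-to-end patient study with planted ground truth per cascade stage.

    Each patient carries one pathogenic SV (rare, exonic, high TDR in the
    disease tissue, listed gene, dominant-consistent) among ~100 benign
    SVs engineered to fail at a known stage: common polymorphisms present
    in the background cohorts, rare intronic/intergenic SVs, exonic SVs
    in unlisted genes, low-TDR SVs in listed genes, and heterozygous hits
    in recessive-only listed genes, plus a few QC failures.
    """
    if ann is None:
        ann = generate_annotation(spec)
    rng = spec.rng(4)
    tissue = ann.tissues[1]  # disease tissue; tissue 0 hosts the silent gene
    gids = list(ann.genes)
    hi_genes = [gids[1], gids[2]]  # engineered share 0.8
    low_gene = gids[3]  # engineered share 0.1
    ar_gene = gids[4]  # engineered share 0.85
    reserved = set(gids[:5]) | {gids[-1]}
    unlisted_genes = [g for g in gids if g not in reserved]
    gene_list = frozenset(hi_genes + [low_gene, ar_gene])

    annotations = GeneAnnotations(
        constraint={g: float(np.round(rng.uniform(0, 1), 3)) for g in gids},
        mods={
            **{g: {t: 0.1 for t in ann.tissues} for g in hi_genes},
            low_gene: {t: 0.15 for t in ann.tissues},
            ar_gene: {t: 0.6 for t in ann.tissues},
        },
        inheritance={
            **{g: frozenset({"AD"}) for g in hi_genes},
            low_gene: frozenset({"AD"}),
            ar_gene: frozenset({"AR"}),
        },
    )

    # shared benign templates: (category, interval factory per replicate)
    def cds_subinterval(gene_id: str, j: int) -> GenomicInterval:
        slot = ann.layout[gene_id].slots[0]
        off = _CDS_LO + 10 + (j * 17) % (_CDS_HI - _CDS_LO - 40)
        return GenomicInterval(slot.chrom, slot.start + off, slot.start + off + 15)

    common_loci = []
    for j in range(30):
        base = _GENE0 - 60_000 + j * 1_500  # intergenic stretch left of gene 0
        common_loci.append(GenomicInterval("chr1", base, base + 800))
    background = generate_af_cohorts(
        spec,
        planted=[
            {"svtype": "DEL", "afs": {list(spec.cohorts)[j % len(spec.cohorts)]: spec.common_af}}
            for j in range(30)
        ],
    )
    # re-anchor the background plants onto the common benign loci so that
    # patient copies merge with the database at > 80% reciprocal overlap
    for pop_cohort in background.cohorts:
        for sv in pop_cohort.svs:
            j = int(sv.id[2:6])
            locus = common_loci[j]
            jitter = int(rng.integers(0, 40))
            sv.interval = GenomicInterval(
                locus.chrom, locus.start + jitter, locus.end + jitter
            )
            sv.svlen = sv.interval.length
    background.truth["chrom"] = "chr1"
    background.truth["start"] = [iv.start for iv in common_loci]
    background.truth["length"] = [iv.length for iv in common_loci]

    patients: dict[str, list[SVRecord]] = {}
    qc_passed: dict[str, set[str]] = {}
    truth_rows = []
    for p in range(n_patients):
        pid = f"PT{p:03d}"
        svs: list[SVRecord] = []
        categories: list[tuple[str, bool]] = []

        def add(category: str, svtype: str, iv: GenomicInterval, pathogenic: bool = False, qc_ok: bool = True):
            sv = SVRecord(
                id=f"{pid}_SV{len(svs):03d}",
                svtype=SVType(svtype),
                interval=iv,
                svlen=max(iv.length, 1),
                genotypes={pid: Genotype.HET},
                source="manta",
            )
            svs.append(sv)
            categories.append((category, qc_ok))
            truth_rows.append(
                {
                    "patient": pid,
                    "sv_id": sv.id,
                    "category": category,
                    "pathogenic": pathogenic,
                }
            )

        # 30 common polymorphisms (eliminated at RARE)
        for j in range(30):
            add("common_background", "DEL", common_loci[j])
        # 25 rare intronic + 10 rare intergenic (eliminated at DOSAGE_CLASS)
        for j in range(25):
            g = unlisted_genes[j % len(unlisted_genes)]
            add("rare_intronic", "DEL", ann.layout[g].intron_gap)
        for j in range(10):
            base = _GENE0 + spec.n_genes * _GENE_SPACING + 20_000 + j * 2_000
            add("rare_intergenic", "DEL", GenomicInterval("chr1", base, base + 900))
        # 15 rare exonic in unlisted genes (eliminated at TDR_GENELIST)
        for j in range(15):
            g = unlisted_genes[(j * 3 + 1) % len(unlisted_genes)]
            add("rare_exonic_unlisted", "DEL", cds_subinterval(g, j))
        # 10 low-TDR hits in a listed gene (eliminated at TDR_GENELIST)
        for j in range(10):
            add("rare_low_tdr_listed", "DEL", cds_subinterval(low_gene, j))
        # 10 heterozygous hits in the recessive-only listed gene
        for j in range(10):
            add("rare_ar_het", "DEL", cds_subinterval(ar_gene, j))
        # QC failures (eliminated at QC)
        for j in range(n_qc_fail):
            g = unlisted_genes[(j * 5 + 2) % len(unlisted_genes)]
            add("qc_fail", "DEL", cds_subinterval(g, j + 20), qc_ok=False)
        # the planted pathogenic SV: exonic over the first-transcript slot
        patho_gene = hi_genes[p % len(hi_genes)]
        patho_type = "DEL" if p % 2 == 0 else "DUP"
        add(
            "pathogenic",
            patho_type,
            ann.del_over_slots(patho_gene, 0, 0),
            pathogenic=True,
        )
        patients[pid] = svs
        qc_passed[pid] = {
            sv.id for sv, (_, qc_ok) in zip(svs, categories) if qc_ok
        }
    return PatientStudy(
        patients=patients,
        qc_passed=qc_passed,
        truth=pd.DataFrame(truth_rows),
        annotations=annotations,
        gene_list=gene_list,
        tissue=tissue,
        background=background,
        annotation=ann,
    )


def score_patient_study(study: PatientStudy) -> dict:
    """Run the full prioritization pipeline over a generated patient study.

    Builds the background AF database from the study's cohorts, annotates
    every patient's SVs, computes TDR in the disease tissue and runs the
    cascade; returns recall/false-positive counts against the planted
    truth plus the median per-stage survivor counts.
    """
    from .popfreq import annotate_background_af, build_background_db
    from .prioritize import STAGES, CascadeConfig, run_cascade
    from .tdr import compute_tdr_results

    ann = study.annotation
    db = build_background_db(study.background.cohorts)
    cfg = CascadeConfig(tissue=study.tissue, gene_list=study.gene_list)
    truth = study.truth.set_index("sv_id")
    n_recall = n_patho = n_fp = 0
    stage_counts: list[dict[str, int]] = []
    for pid, svs in study.patients.items():
        annotate_background_af(svs, db)
        results = compute_tdr_results(svs, ann.genes, ann.tpm, [study.tissue])
        report, _, counts = run_cascade(
            svs,
            pid,
            ann.genes,
            results,
            study.annotations,
            cfg,
            qc_passed=study.qc_passed[pid],
        )
        reported = set(report["sv_id"])
        patho = set(truth[(truth["patient"] == pid) & truth["pathogenic"]].index)
        n_patho += len(patho)
        n_recall += len(reported & patho)
        n_fp += len(reported - patho)
        stage_counts.append(counts)
    medians = {
        s: float(np.median([c[s] for c in stage_counts])) for s in STAGES
    }
    return {
        "n_patients": len(study.patients),
        "n_pathogenic": n_patho,
        "n_recalled": n_recall,
        "n_false_positive": n_fp,
        "median_stage_counts": medians,
    }


# ---------------------------------------------------------------------------
# Expression with TDR-proportional dosage effects


def generate_expression(
    spec: FixtureSpec,
    carriers: pd.DataFrame,
    genes: list[str],
    samples: list[str],
    tissue: str = "Tissue",
) -> ExpressionMatrix:
    """Sample × gene log2 expression with planted dosage effects.

    Baseline log2 abundance is Gaussian per gene plus a shared confounder
    with loading ``spec.confounder_loading`` and i.i.d. noise of sd
    ``spec.noise_sd``.  A heterozygous DEL carrier loses a fraction
    0.5·TDR of dosage, a homozygous DEL the full TDR fraction; DUP
    carriers gain 0.5·TDR per extra copy.  A TDR of 0 leaves the carrier
    distribution identical to non-carriers.
    """
    rng = spec.rng(5)
    n, m = len(samples), len(genes)
    mu = rng.normal(5.0, 1.0, size=m)
    conf = rng.normal(0.0, 1.0, size=n)
    noise = rng.normal(0.0, spec.noise_sd, size=(n, m))
    vals = mu[None, :] + spec.confounder_loading * conf[:, None] + noise
    s_index = {s: i for i, s in enumerate(samples)}
    g_index = {g: j for j, g in enumerate(genes)}
    for row in carriers.itertuples(index=False):
        i, j = s_index[row.sample], g_index[row.gene]
        tdr = float(row.tdr)
        gt = Genotype(row.genotype)
        if SVType(row.svtype) is SVType.DEL:
            frac = spec.het_del_factor * tdr if gt is Genotype.HET else tdr
            factor = max(1.0 - frac, 1e-3)
        elif SVType(row.svtype) is SVType.DUP:
            copies = 1 if gt is Genotype.HET else 2
            factor = 1.0 + spec.dup_gain_factor * tdr * copies
        else:
            factor = 1.0
        vals[i, j] += np.log2(factor)
    values = pd.DataFrame(vals, index=samples, columns=genes)
    covariates = pd.DataFrame({"conf": conf}, index=samples)
    return ExpressionMatrix(values={tissue: values}, covariates=covariates)


def dosage_effect_study(
    spec: FixtureSpec,
    svtype: str = "DEL",
    n_events: int = 500,
    n_genes: int = 100,
    n_samples: int = 300,
    tissue: str = "Tissue",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Carrier events with uniform TDR plus the matching expression matrix.

    The returned carriers table holds one (sample, gene, svtype, genotype,
    tdr) row per planted event; events occupy distinct sample-gene cells.
    """
    rng = spec.rng(6)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    genes = [f"EG{j:03d}" for j in range(n_genes)]
    cells = rng.choice(n_samples * n_genes, size=n_events, replace=False)
    rows = []
    for c in cells:
        i, j = divmod(int(c), n_genes)
        rows.append(
            {
                "sample": samples[i],
                "gene": genes[j],
                "svtype": svtype,
                "genotype": "HET",
                "tdr": float(np.round(rng.uniform(0.0, 1.0), 6)),
            }
        )
    carriers = pd.DataFrame(rows)
    expr = generate_expression(spec, carriers, genes, samples, tissue)
    return expr, carriers


# ---------------------------------------------------------------------------
# File emission (CLI `tdrsv simulate`)


def write_fixture_files(spec: FixtureSpec, outdir: str) -> dict[str, str]:
    """Write the standard-format fixture set to a directory.

    Emits the toy GTF and TPM TSV, per-cohort background VCFs, the QC
    benchmark VCF with its support BEDs and re-genotyped VCF, and truth
    tables; returns the path of every file written.
    """
    from . import sv_io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    ann = generate_annotation(spec)
    write_gtf(ann.genes, str(out / "annotation.gtf"))
    ann.tpm.to_tsv(str(out / "tpm.tsv"))
    paths["gtf"] = str(out / "annotation.gtf")
    paths["tpm"] = str(out / "tpm.tsv")

    qc = generate_qc_cohort(spec)
    sv_io.write_sv_vcf(qc.svs, str(out / "qc_calls.vcf"), samples=qc.samples)
    paths["qc_vcf"] = str(out / "qc_calls.vcf")
    # support BEDs carry the sv type in column 4
    for name in ("lumpy", "cnvnator"):
        idx = getattr(qc.evidence, name)
        with open(out / f"{name}.bed", "w") as fh:
            for chrom, tree in sorted(idx._trees.items()):
                for hit in sorted(tree):
                    fh.write(f"{chrom}\t{hit.begin}\t{hit.end}\t{hit.data}\n")
        paths[f"{name}_bed"] = str(out / f"{name}.bed")
    para_records = []
    for (sv_id, sample), gt in sorted(qc.evidence.paragraph_genotypes.items()):
        sv = next(s for s in qc.svs if s.id == sv_id)
        para_records.append(
            SVRecord(
                id=sv.id,
                svtype=sv.svtype,
                interval=sv.interval,
                svlen=sv.svlen,
                genotypes={sample: gt},
                source="paragraph",
            )
        )
    sv_io.write_sv_vcf(para_records, str(out / "paragraph.vcf"), samples=qc.samples)
    paths["paragraph_vcf"] = str(out / "paragraph.vcf")
    qc.truth.to_csv(out / "qc_truth.tsv", sep="\t", index=False)
    paths["qc_truth"] = str(out / "qc_truth.tsv")

    af = generate_af_cohorts(spec)
    for cohort in af.cohorts:
        p = out / f"background_{cohort.population}.vcf"
        sv_io.write_sv_vcf(cohort.svs, str(p), samples=cohort.samples)
        paths[f"background_{cohort.population}"] = str(p)
    af.truth.to_csv(out / "af_truth.tsv", sep="\t", index=False)
    paths["af_truth"] = str(out / "af_truth.tsv")
    return paths


def paragraph_from_vcf(path: str) -> dict[tuple[str, str], Genotype]:
    """Load a re-genotyped (Paragraph-style) VCF into the QC evidence map."""
    from . import sv_io

    out: dict[tuple[str, str], Genotype] = {}
    for rec in sv_io.read_sv_vcf(path, dialect="paragraph"):
        for sample, gt in rec.genotypes.items():
            out[(rec.id, sample)] = gt
    return out
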