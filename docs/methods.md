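# Methods

## The transcript disruption ratio

For a variant *v*, gene *g* and tissue *t*,

TDR(g, t) = Σ<sub>i ∈ D(v,g)</sub> TPM<sub>i,t</sub> / Σ<sub>i ∈ g</sub> TPM<sub>i,t</sub>

where the sums run over the gene's annotated transcripts (coding and
non-coding — short-read quantification cannot reliably separate them,
so the denominator keeps both) and D(v,g) is the disrupted set:

* **DEL/DUP** — transcript disrupted iff the variant overlaps ≥ 1 bp of
  its CDS; non-coding isoforms have no CDS, so exon overlap is used for
  them. Deletions and duplications share one rule: a partial tandem
  duplication breaks the transcript's structure just as a deletion does.
* **INS** — the zero-width anchor point must lie inside a qualifying
  interval.
* **INV** — at least one breakpoint strictly inside the transcript span
  *and* overlap with a qualifying base. An inversion containing the
  whole gene relocates it intact and disrupts nothing.
* **Stop-gain SNV** — disrupted iff the position is inside the CDS
  (the transcripts actually translated, hence exposed to
  nonsense-mediated decay). No 50-nt last-exon NMD-escape rule is
  applied; disruption is CDS containment only.

TDR is **undefined** when the gene is silent in the tissue
(denominator 0). Undefined values propagate as missing and such rows
are excluded from prioritization rather than scored 0: a silent gene
cannot be dosage-disrupted in that tissue, but a silent 0 would mask
annotation/expression-table mismatches.

Invariants: 0 ≤ TDR ≤ 1 where defined; monotone non-decreasing as the
disrupted set grows; invariant to uniform rescaling of a tissue's TPM
column; whole-gene CNVs score 1.0 in every expressed tissue.

## Tiered SV quality control

Breakpoint-based calls are the primary input; orthogonal evidence gates
them by size tier. Thresholds are applied with the stated inequality
verbatim — strict where the rule says "greater than":

| tier | definition | retention rule |
|---|---|---|
| SHORT | length < 200 bp | re-genotyped call HET/HOM in ≥ 1 carrier |
| MEDIUM | 200 bp ≤ length < 100 kb, DEL/DUP | same-type support (either read-depth caller) RO > 0.8 |
| LONG | length ≥ 100 kb, DEL/DUP | same-type read-depth (CNVnator-style) support RO > 0.8 |
| OTHER | INV, INS ≥ 200 bp | pass (no reliable orthogonal validation) |

Reciprocal overlap RO(a,b) = min(|a∩b|/|a|, |a∩b|/|b|). Evidence is
type-matched (a DUP call never corroborates a DEL) — the tier rules
name DEL/DUP jointly but cross-type corroboration would let one
miscalled event validate another. Inversions shorter than 200 bp fall
in no tier; they pass flagged `untested_tier` rather than being dropped
silently. Exclusion regions remove any SV overlapping by ≥ 1 bp.
Sample gates: mean coverage > 15×, chimeric reads < 0.05%, contamination
< 5% (all strict); insert-size normality enters as an upstream boolean.

## Background allele frequencies

Same-type SVs from all cohorts are merged by **single-linkage**
clustering with RO > 0.8 as the edge predicate (clique merging would
make results order-dependent and split chains the merging tool keeps
together). Insertions are zero-width, so RO is replaced by anchor
distance ≤ 100 bp plus inserted-length ratio > 0.8 (both configurable
module constants). The cluster representative is the member with the
most carriers (ties: smallest start, end, id); clustering is invariant
to cohort input order by canonical pre-sorting.

Per-population AF = alt alleles (HET = 1, HOM = 2) over 2 × samples with
a non-MISSING genotype; half-calls are MISSING and leave the
denominator. A population with no member in a cluster contributes AF 0
— absence across a genotyped cohort is evidence of rarity, not missing
data. Background AF = max over populations; **rare** means background
AF < 0.01 (strict).

## Prioritization cascade

Stages run in order per SV, first failure terminates: QC → RARE →
DOSAGE_CLASS (exonic/whole-gene DEL/DUP or exonic INV; insertions are
not in the dosage-disrupting class) → TDR > 0.25 in the disease tissue
for a gene on the curated list → inheritance consistency → report.

Inheritance passes when (AD mode or tissue MoDs < 0.3) with a confident
carrier genotype, or for AR-only genes with homozygosity or a supplied
second hit. MoDs is a per-gene, per-tissue dosage-sensitivity
percentile (0 = most constrained); < 0.3 marks likely
haploinsufficiency. XL-only genes with a heterozygous carrier and
non-sensitive MoDs fail this stage — the rule enumerates only the
dominant-like and AR-only arms, applied literally. Genes absent from
every annotation table pass *flagged* `unannotated`: curated candidate
lists legitimately contain genes without OMIM entries, and dropping
them silently would hide exactly the novel cases the cascade exists to
find. Known-pathogenic overlap (same type, RO > 0.8) is annotation
only, never a gate — final calls are manual. True pedigree segregation
needs family genotypes and is out of scope; an external per-SV verdict
hook decides the stage when supplied.

## Outlier statistics

Log-scale expression is residualized per gene by OLS against supplied
covariates (hidden-factor estimation such as PEER is an external
preprocessing step; its output enters as covariates), then standardized
(ddof = 1). Outliers: |Z| > 2 single-tissue, |median Z across tissues| >
2 multi-tissue, strict. Enrichment: 2×2 carrier × outlier table, OR =
ad/bc with Haldane +0.5 when a cell is empty, Woolf 95% CI, two-sided
Fisher exact p. The Fisher test is conservative at discrete counts, so
null rejection runs somewhat below nominal — the calibration test
bounds it in [0.01, 0.08] at its simulated scale and the CI-coverage
check requires ≥ 90/100. Correlation defaults to Spearman (robust to
the nonlinear TDR→fold-change map); Pearson is available. TSS-distance
enrichment bins default to edges 0 / 2 kb / 10 kb / 100 kb / 1 Mb
(config-exposed; the binning is this package's choice).

## Synthetic data generator

`tdrsv.simulate` emulates callset-level inputs only (no reads). Genes
are laid out with a shared 5′ exon, one private CDS-bearing exon per
transcript in its own 2 kb slot, and a shared 3′ exon, so a deletion
over a contiguous run of slots disrupts exactly that run. Per-tissue
TPM shares are constructed directly — a planted SV's TDR is exact by
construction (the first-transcript share), which we prefer over
rejection-sampling breakpoints toward a target: it is deterministic and
leaves no tolerance band in the truth table. Deterministic role genes
anchor the studies: an isoform-switch gene (dominant transcript differs
between tissues), high-share (0.8/0.85) and low-share (0.1) genes for
the cascade's listed/unlisted × high/low-TDR cells, and one
gene/tissue silent to exercise undefined TDR.

Default study conditions (desk scale): 40 genes × 2–4 transcripts × 3
tissues; background cohorts of 60 and 75 samples with planted AFs
realized as exact carrier counts; QC benchmarks of 100 validated + 100
decoy SVs cycling all tiers; patient cohorts of 50 patients × ~107 SVs
(one planted pathogenic, benign categories engineered to fail at each
named stage); expression studies of 300 samples × 100 genes with 500
planted events. Dosage model (log2 scale): baseline N(5, 1) per gene,
shared confounder loading 0.5, noise sd 0.5; HET DEL multiplies dosage
by (1 − 0.5·TDR) — one of two copies lost over the disrupted fraction —
HOM by (1 − TDR) floored at 10⁻³, DUP by (1 + 0.5·TDR) per extra copy.
With noise sd 0.5, a full-TDR heterozygous deletion shifts expression
by about −2 Z, matching the planted-effect scale the statistics module
is validated against.

What the generator does **not** emulate: read-level artifacts and
breakpoint uncertainty, overlapping genes and shared exons between
genes, linkage between variants, population structure beyond discrete
cohort labels, and non-coding regulatory effects on expression. Passing
tests therefore demonstrate correctness of the rules and statistics,
not calling accuracy on sequencing data.

## Numerical choices

Internal coordinates are 0-based half-open everywhere; conversion
happens only at I/O boundaries (VCF/GTF are 1-based inclusive; the
deleted segment of a VCF SV is POS..END, so start = POS − 1, end = END).
Insertions are zero-width anchors whose size-tier length is the
inserted length. When both END and SVLEN are present on a VCF record,
SVLEN wins (htslib rewrites the stop coordinate from SVLEN with a
different off-by-one convention than the END field). Multi-allelic
lines split into one record per ALT. TDR numerator/denominator sums run
in sorted-transcript order so results are bit-reproducible. Gene span =
union of transcript spans. TSS distance is the gap to the nearest
covered base, minimized over transcripts. Cluster and representative
tie-breaks are lexicographic as listed above.
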