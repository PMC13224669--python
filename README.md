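# tdrsv

Tissue-specific gene-dosage interpretation of structural variants (SVs).

Whether a deletion, duplication, insertion or inversion matters for a
patient depends on *which transcripts it breaks in the tissue where the
disease lives*. A gene can express different isoforms in retina and
cerebellum; an SV that ablates the testis-dominant isoform may be
harmless in the brain. `tdrsv` quantifies this with the **transcript
disruption ratio**:

```
TDR(gene, tissue) = Σ TPM(disrupted transcripts) / Σ TPM(all transcripts)
```

where a transcript is *disrupted* when the variant overlaps its coding
sequence (exons, for non-coding isoforms), an insertion lands inside
it, or an inversion breakpoint falls within it, and TPMs are
tissue-specific median expression over all annotated isoforms, coding
and non-coding. TDR = 1 means the variant removes essentially all of
the gene's functional output in that tissue; TDR = 0 means the
expressed isoforms escape. The same rule applied to stop-gain SNVs
captures nonsense-mediated decay exposure.

Around the metric, the package implements the full interpretation
workflow used for rare-disease cohorts:

* **`tdrsv.sv_io`** — Manta-style SV VCF and BED I/O, breakend-pair →
  inversion conversion, 0-based half-open internal coordinates.
* **`tdrsv.sv_filter`** — tiered quality control: exclusion regions;
  short SVs (< 200 bp) kept only with a confident re-genotyped call;
  medium CNVs (200 bp – 100 kb) and long CNVs (≥ 100 kb) kept only with
  same-type read-depth support at > 80% reciprocal overlap; sample-level
  alignment QC gates.
* **`tdrsv.popfreq`** — multi-ancestry background allele frequencies:
  Jasmine-style single-linkage merging of same-type SVs at > 80%
  reciprocal overlap across cohorts, per-population AFs, background AF =
  max across populations, rare = background AF < 0.01.
* **`tdrsv.genemodel`** — Gencode-style GTF parsing, SV–gene context
  (intergenic / intronic / exonic / whole-gene), TSS distances,
  transcript × tissue TPM lookup.
* **`tdrsv.tdr`** — TDR for SVs and stop-gain variants, MANE-Select
  comparison, protein-coding expression ratio.
* **`tdrsv.prioritize`** — the candidate cascade: QC → rare → dosage
  class (exonic/whole-gene DEL/DUP, exonic INV) → TDR > 0.25 in a listed
  disease gene → inheritance/dosage-sensitivity consistency (OMIM modes,
  MoDs < 0.3) → report with full per-stage audit trace.
* **`tdrsv.outlier_stats`** — covariate residualization, per-gene
  Z-scores, single-/multi-tissue outlier calls (|Z| > 2), carrier-outlier
  odds ratios with Woolf CIs and Fisher exact p-values, TDR–expression
  correlations, TSS-distance enrichment.
* **`tdrsv.simulate`** — a deterministic synthetic-data generator that
  produces every input above with planted ground truth (it backs the
  whole test suite; no external data needed).

## Worked example

`examples/01_transcript_disruption_ratio.py` builds a toy annotation in
which gene `G000` switches dominant isoform between tissues, then scores
one deletion of the first transcript's private exon:

```
    Retina: TDR = 0.80  (disrupted ['G000T0'], TPM 39.81 of 49.76)
Cerebellum: TDR = 0.10  (disrupted ['G000T0'], TPM 2.67 of 26.74)
```

The identical variant removes 80% of the gene's expressed output in
retina but only 10% in cerebellum — above and below the pathogenicity
threshold (TDR > 0.25) respectively. `examples/03_prioritize_patient.py`
runs the full cascade for a synthetic patient (~107 raw SVs):

```
  RAW            107 SVs remain
  QC             101 SVs remain
  RARE            71 SVs remain
  DOSAGE_CLASS    36 SVs remain
  TDR_GENELIST    11 SVs remain
  INHERITANCE      1 SVs remain
  REPORT           1 SVs remain
```

leaving exactly the planted pathogenic deletion (rare, exonic, TDR 0.8
in the disease tissue, dominant-consistent gene).
`examples/04_dosage_effect_statistics.py` validates the metric's
direction of effect on simulated expression (Spearman r = −0.55 for
deletions, +0.31 for duplications, both p ≪ 0.01).

## Command line

```bash
tdrsv simulate --seed 3 --out fixtures/        # synthetic inputs + truth
tdrsv convert  --vcf calls.vcf --out svs.tsv
tdrsv filter   --svs calls.vcf --paragraph pg.vcf --lumpy lumpy.bed \
               --cnvnator cnv.bed --out passed.vcf --audit audit.tsv
tdrsv popfreq build    --cohort EAS=eas.vcf --cohort EUR=eur.vcf --out bg.tsv
tdrsv popfreq annotate --svs passed.vcf --db bg.tsv --out annotated.vcf
tdrsv tdr      --svs annotated.vcf --gtf anno.gtf --tpm tpm.tsv \
               --tissue Cerebellum --out tdr.tsv
```

## Limitations

TDR scores physical transcript disruption only: promoter/enhancer loss
(TDR = 0 by construction) is surfaced separately through the
TSS-distance enrichment statistics, not by the metric itself. See
`docs/methods.md` for the model, parameter defaults and the design
decisions behind edge-case handling.
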