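"""Run the candidate-pathogenic-SV cascade for one synthetic patient.

Each patient carries ~100 benign SVs (common polymorphisms, intronic or
intergenic events, hits in unlisted or low-TDR genes, heterozygous hits
in recessive genes) plus one planted pathogenic SV: rare, exonic, high
TDR in the disease tissue, in a listed dominant-consistent gene.  The
cascade should surface exactly that one.
"""
from tdrsv import FixtureSpec, generate_patient_cohort
from tdrsv.popfreq import annotate_background_af, build_background_db
from tdrsv.prioritize import STAGES, CascadeConfig, run_cascade
from tdrsv.tdr import compute_tdr_results

study = generate_patient_cohort(FixtureSpec(seed=1), n_patients=1)
ann = study.annotation
db = build_background_db(study.background.cohorts)

pid, svs = next(iter(study.patients.items()))
annotate_background_af(svs, db)
results = compute_tdr_results(svs, ann.genes, ann.tpm, [study.tissue])
report, trace, counts = run_cascade(
    svs, pid, ann.genes, results, study.annotations,
    CascadeConfig(tissue=study.tissue, gene_list=study.gene_list),
    qc_passed=study.qc_passed[pid],
)

print(f"patient {pid}, disease tissue {study.tissue}")
for stage in STAGES:
    print(f"  {stage:<13} {counts[stage]:>4} SVs remain")
print("\nfinal report:")
print(report[["sv_id", "svtype", "gene_id", "context", "tdr",
              "genotype", "inheritance", "mods"]].to_string(index=False))

truth = study.truth
planted = truth[(truth["patient"] == pid) & truth["pathogenic"]]["sv_id"].iloc[0]
print(f"\nplanted pathogenic SV: {planted} -> "
      f"{'recovered' if planted in set(report['sv_id']) else 'MISSED'}")
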