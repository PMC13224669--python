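"""Synthetic-data generator: determinism, planted truths, dosage model."""
import numpy as np
import pandas as pd
import pytest

from tdrsv.genemodel import SVGeneContext, classify_context, read_gtf, write_gtf
from tdrsv.model import Genotype, GenomicInterval, SVRecord, SVType
from tdrsv.simulate import (
    FixtureSpec,
    dosage_effect_study,
    generate_af_cohorts,
    generate_annotation,
    generate_expression,
    generate_patient_cohort,
    generate_qc_cohort,
    write_fixture_files,
)
from tdrsv.tdr import compute_tdr


def test_same_seed_identical_outputs(tmp_path):
    spec = FixtureSpec(seed=42, n_genes=8)
    a, b = generate_annotation(spec), generate_annotation(spec)
    assert a.tpm.frame.equals(b.tpm.frame)
    p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
    write_gtf(a.genes, str(p1)); write_gtf(b.genes, str(p2))
    assert p1.read_text() == p2.read_text()
    qa, qb = generate_qc_cohort(spec), generate_qc_cohort(spec)
    assert qa.truth.equals(qb.truth)
    assert [s.interval for s in qa.svs] == [s.interval for s in qb.svs]


def test_different_seed_differs():
    a = generate_annotation(FixtureSpec(seed=1, n_genes=8))
    b = generate_annotation(FixtureSpec(seed=2, n_genes=8))
    assert not a.tpm.frame.equals(b.tpm.frame)


def test_annotation_round_trips_through_gtf(tmp_path):
    spec = FixtureSpec(seed=3, n_genes=5)
    ann = generate_annotation(spec)
    path = str(tmp_path / "five.gtf")
    write_gtf(ann.genes, path)
    assert len(read_gtf(path)) == 5


def test_isoform_switch_gene_changes_dominant_transcript():
    ann = generate_annotation(FixtureSpec(seed=5))
    gid = list(ann.genes)[0]
    tids = ann.genes[gid].transcript_ids
    t0, t1 = ann.tissues[0], ann.tissues[1]
    top0 = max(tids, key=lambda t: ann.tpm.get(t, t0))
    top1 = max(tids, key=lambda t: ann.tpm.get(t, t1))
    assert top0 != top1


def test_one_mane_per_coding_gene():
    ann = generate_annotation(FixtureSpec(seed=5, n_genes=10))
    for gene in ann.genes.values():
        assert len(gene.mane_transcripts) == 1


def test_engineered_prefix_shares_give_exact_tdr():
    ann = generate_annotation(FixtureSpec(seed=5))
    gid = list(ann.genes)[1]  # engineered first-transcript share 0.8
    record = SVRecord("p", SVType.DEL, ann.del_over_slots(gid, 0, 0),
                      ann.del_over_slots(gid, 0, 0).length, {"S": Genotype.HET})
    for tissue in ann.tissues:
        res = compute_tdr(record, ann.genes[gid], tissue, ann.tpm)
        assert res.tdr == pytest.approx(0.8, abs=1e-9)


def test_whole_gene_deletion_truth(spec, annotation):
    gid = list(annotation.genes)[2]
    span = annotation.genes[gid].span
    record = SVRecord("wg", SVType.DEL,
                      GenomicInterval("chr1", span.start - 500, span.end + 500),
                      span.length + 1000, {"S": Genotype.HET})
    assert classify_context(record, annotation.genes[gid]) is SVGeneContext.WHOLE_GENE
    res = compute_tdr(record, annotation.genes[gid], annotation.tissues[1],
                      annotation.tpm)
    assert res.tdr == 1.0


def test_qc_decoys_fail_and_validated_pass(spec):
    from tdrsv.sv_filter import apply_qc_workflow

    qc = generate_qc_cohort(spec, n_validated=24, n_decoys=24)
    passed, _ = apply_qc_workflow(qc.svs, qc.evidence)
    got = {s.id for s in passed}
    expected = set(qc.truth[qc.truth["validated"]]["sv_id"])
    assert got == expected


def test_af_plants_realize_target_category(spec):
    study = generate_af_cohorts(spec)
    # planted common entries reach AF >= 0.01 somewhere; rare ones never do
    assert study.truth["rare"].value_counts().to_dict() == {False: 20, True: 20}
    for cohort in study.cohorts:
        for record in cohort.svs:
            assert all(g in (Genotype.HET,) for g in record.genotypes.values())


def test_patient_truth_covers_every_stage(spec, annotation):
    study = generate_patient_cohort(spec, ann=annotation, n_patients=2)
    cats = set(study.truth["category"])
    assert {"common_background", "rare_intronic", "rare_intergenic",
            "rare_exonic_unlisted", "rare_low_tdr_listed", "rare_ar_het",
            "qc_fail", "pathogenic"} <= cats
    per_patient = study.truth.groupby("patient")["pathogenic"].sum()
    assert (per_patient == 1).all()


def test_expression_tdr_zero_identical_to_no_carriers():
    spec = FixtureSpec(seed=9)
    genes = [f"g{i}" for i in range(5)]
    samples = [f"s{i}" for i in range(20)]
    carriers = pd.DataFrame(
        [{"sample": "s0", "gene": "g0", "svtype": "DEL",
          "genotype": "HET", "tdr": 0.0}]
    )
    empty = pd.DataFrame(columns=["sample", "gene", "svtype", "genotype", "tdr"])
    with_c = generate_expression(spec, carriers, genes, samples)
    without = generate_expression(spec, empty, genes, samples)
    assert with_c.values["Tissue"].equals(without.values["Tissue"])


def test_expression_hom_del_full_tdr_ablates():
    spec = FixtureSpec(seed=9, noise_sd=0.01)
    genes, samples = ["g0"], ["s0", "s1"]
    carriers = pd.DataFrame(
        [{"sample": "s0", "gene": "g0", "svtype": "DEL",
          "genotype": "HOM", "tdr": 1.0}]
    )
    mat = generate_expression(spec, carriers, genes, samples)
    v = mat.values["Tissue"]
    assert v.at["s0", "g0"] < v.at["s1", "g0"] - 5  # ~ -log2(1000)


def test_dosage_study_plants_unique_cells():
    expr, carriers = dosage_effect_study(FixtureSpec(seed=4), n_events=100,
                                         n_genes=20, n_samples=50)
    assert len(carriers) == 100
    assert not carriers.duplicated(["sample", "gene"]).any()
    assert carriers["tdr"].between(0, 1).all()


def test_fixture_files_written_and_parseable(tmp_path):
    from tdrsv import sv_io

    spec = FixtureSpec(seed=6, n_genes=6)
    paths = write_fixture_files(spec, str(tmp_path / "fx"))
    genes = read_gtf(paths["gtf"])
    assert len(genes) == 6
    svs = sv_io.read_sv_vcf(paths["qc_vcf"])
    assert len(svs) == 200
    support = sv_io.read_support_bed(paths["cnvnator_bed"])
    assert all(t in {"DEL", "DUP"} for t, _ in support)


def test_cli_filter_popfreq_tdr_pipeline(tmp_path):
    """Shell pipeline over generated fixture files: filter -> popfreq -> tdr."""
    from click.testing import CliRunner

    from tdrsv.cli import main

    runner = CliRunner()
    fx = tmp_path / "fx"
    assert runner.invoke(main, ["simulate", "--seed", "3", "--out", str(fx)]).exit_code == 0
    res = runner.invoke(main, [
        "filter", "--svs", str(fx / "qc_calls.vcf"),
        "--paragraph", str(fx / "paragraph.vcf"),
        "--lumpy", str(fx / "lumpy.bed"),
        "--cnvnator", str(fx / "cnvnator.bed"),
        "--out", str(tmp_path / "passed.vcf"),
        "--audit", str(tmp_path / "audit.tsv")])
    assert res.exit_code == 0, res.output
    assert "100/200" in res.output
    res = runner.invoke(main, [
        "popfreq", "build",
        "--cohort", f"EAS={fx / 'background_EAS.vcf'}",
        "--cohort", f"EUR={fx / 'background_EUR.vcf'}",
        "--out", str(tmp_path / "bg.tsv")])
    assert res.exit_code == 0, res.output
    db = pd.read_csv(tmp_path / "bg.tsv", sep="\t")
    assert {"background_af", "rare"} <= set(db.columns)
    res = runner.invoke(main, [
        "popfreq", "annotate", "--svs", str(tmp_path / "passed.vcf"),
        "--db", str(tmp_path / "bg.tsv"),
        "--out", str(tmp_path / "annotated.vcf")])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, [
        "tdr", "--svs", str(tmp_path / "annotated.vcf"),
        "--gtf", str(fx / "annotation.gtf"), "--tpm", str(fx / "tpm.tsv"),
        "--tissue", "Retina", "--out", str(tmp_path / "tdr.tsv")])
    assert res.exit_code == 0, res.output


def test_cli_simulate_and_convert(tmp_path):
    from click.testing import CliRunner

    from tdrsv.cli import main

    runner = CliRunner()
    out = tmp_path / "fx"
    res = runner.invoke(main, ["simulate", "--seed", "3", "--out", str(out)])
    assert res.exit_code == 0, res.output
    res2 = runner.invoke(
        main,
        ["convert", "--vcf", str(out / "qc_calls.vcf"),
         "--out", str(tmp_path / "svs.tsv")],
    )
    assert res2.exit_code == 0, res2.output
    table = pd.read_csv(tmp_path / "svs.tsv", sep="\t")
    assert len(table) == 200
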