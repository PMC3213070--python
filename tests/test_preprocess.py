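"""Pre-analytic pipeline: missing-value rules, imputation, filtering, transform."""

import numpy as np
import pandas as pd
import pytest

from refgene_screen.preprocess import (
    BIOLOGICAL,
    TECHNICAL,
    MissingPolicy,
    UnrecoverableCellError,
    classify_missing,
    clean_ct,
    filter_genes,
    impute_and_flag,
    preprocess_pipeline,
    qc_reference_vs_array_mean,
    transform,
)
from refgene_screen.simdata import StudyDesign, simulate_ct
from refgene_screen.stability import mad
from refgene_screen.tables import ASSIGNED_CT40, IMPUTED_MEAN, MEASURED

from conftest import SMALL_DESIGN, build_ct, flat_gene

M = None  # missing marker in fixture rows


class TestClassifyMissing:
    def test_all_replicate_absence_at_leading_edge_is_biological(self):
        # undetected in every replicate at t=0 and t=4, detected at t=18
        table = build_ct({"G": [M, M, M, M, M, M, 30, 31, 30]})
        cls = classify_missing(table)
        row = cls.loc["G"]
        assert (row[:6] == BIOLOGICAL).all() and row[6:].isna().all()

    def test_single_replicate_failure_is_technical(self):
        table = build_ct({"G": [25, 24, 25, M, 24, 25, 24, 25, 24]})
        cls = classify_missing(table)
        assert cls.loc["G"].dropna().tolist() == [TECHNICAL]

    def test_interior_all_replicate_absence_is_technical(self):
        # fully missing mid-course: not contiguous with either edge
        table = build_ct({"G": [25, 24, 25, M, M, M, 24, 25, 24]})
        cls = classify_missing(table)
        assert (cls.loc["G"].dropna() == TECHNICAL).all()

    def test_gene_without_missing_yields_empty_classification(self):
        table = build_ct({"G": [25, 24, 25, 24, 25, 24, 25, 24, 25]})
        assert classify_missing(table).loc["G"].isna().all()

    def test_edge_rule_can_be_disabled(self):
        table = build_ct({"G": [M, M, M, 24, 25, 24, 25, 24, 25]})
        cls = classify_missing(table, MissingPolicy(biological_edge_rule=False))
        assert (cls.loc["G"].dropna() == TECHNICAL).all()

    def test_sidecar_override_reclassifies_a_cell(self, tmp_path):
        from refgene_screen.preprocess import read_overrides

        table = build_ct({"G": [25, 24, 25, M, 24, 25, 24, 25, 24]})
        sample = table.sample_ids[3]
        sidecar = tmp_path / "overrides.tsv"
        sidecar.write_text(f"gene\tsample\tclass\nG\t{sample}\t{BIOLOGICAL}\n")
        cls = classify_missing(table, overrides=read_overrides(sidecar))
        assert cls.loc["G", sample] == BIOLOGICAL

    def test_override_of_non_missing_cell_rejected(self):
        table = build_ct({"G": [25, 24, 25, 24, 25, 24, 25, 24, 25]})
        with pytest.raises(ValueError, match="non-missing"):
            classify_missing(table, overrides={("G", table.sample_ids[0]): TECHNICAL})


class TestImputeAndFlag:
    def test_biological_cell_assigned_ct40(self):
        table = build_ct({"G": [M, M, M, 24, 25, 24, 25, 24, 25]})
        out, prov = impute_and_flag(table, classify_missing(table))
        assert (out.values.loc["G"][:3] == 40.0).all()
        assert (prov.loc["G"][:3] == ASSIGNED_CT40).all()

    def test_technical_cell_gets_time_point_mean(self):
        table = build_ct({"G": [25, 24, 25, M, 24.0, 26.0, 25, 24, 25]})
        out, prov = impute_and_flag(table, classify_missing(table))
        sample = table.sample_ids[3]
        assert out.values.loc["G", sample] == 25.0  # mean of {24, 26}
        assert prov.loc["G", sample] == IMPUTED_MEAN

    def test_complete_table_returned_unchanged(self):
        table = build_ct({"G": [25, 24, 25, 24, 25, 24, 25, 24, 25]})
        out, prov = impute_and_flag(table, classify_missing(table))
        assert out.values.equals(table.values)
        assert (prov == MEASURED).all().all()

    def test_technical_cell_without_detected_replicate_raises(self):
        table = build_ct({"G": [25, 24, 25, M, M, M, 24, 25, 24]})
        with pytest.raises(UnrecoverableCellError):
            impute_and_flag(table, classify_missing(table))


class TestFilterGenes:
    def test_one_technical_missing_is_retained(self):
        table = build_ct(
            {"G": [25, 24, 25, M, 24, 25, 24, 25, 24], "H": [20] * 9}
        )
        kept, removed = filter_genes(table, classify_missing(table))
        assert "G" in kept.gene_ids and removed == []

    def test_two_technical_missing_is_removed_with_reason(self):
        table = build_ct(
            {"G": [25, M, 25, M, 24, 25, 24, 25, 24], "H": [20] * 9}
        )
        kept, removed = filter_genes(table, classify_missing(table))
        assert kept.gene_ids == ["H"]
        assert removed[0].gene == "G" and "2 unexplained" in removed[0].reason

    def test_biological_edge_missing_never_triggers_removal(self):
        # six biological (edge-run) cells, zero technical
        table = build_ct(
            {"G": [M, M, M, M, M, M, 25, 24, 25], "H": [20] * 9}
        )
        cls = classify_missing(table)
        assert (cls.loc["G"].dropna() == BIOLOGICAL).all()
        kept, removed = filter_genes(table, cls)
        assert "G" in kept.gene_ids and removed == []

    def test_all_genes_removed_raises_degenerate(self):
        from refgene_screen.preprocess import DegenerateInputError

        table = build_ct({"G": [M, 24, 25, M, 24, 25, 24, 25, 24]})
        with pytest.raises(DegenerateInputError):
            filter_genes(table, classify_missing(table))

    def test_planted_96_gene_panel_removes_exactly_the_dropout_genes(self):
        """Genes planted with >= 2 unexplained missing cells are the ones removed."""
        from refgene_screen.pipeline import PipelineConfig
        from refgene_screen.simdata import DEFAULT_DESIGN

        panel = PipelineConfig().gene_panel()
        table, truth = simulate_ct(DEFAULT_DESIGN, panel, 0.0, seed=101)
        cls = classify_missing(table)
        kept, removed = filter_genes(table, cls)
        planted = {
            g
            for g in table.gene_ids
            if int((cls.loc[g] == TECHNICAL).sum()) >= 2
        }
        assert {r.gene for r in removed} == planted
        assert planted <= set(truth.genes_of_kind("dropout"))


class TestTransform:
    def test_ct40_maps_to_one_and_ct25_to_sixteen(self):
        table = build_ct({"G": [40, 25, 30, 40, 25, 30, 40, 25, 30]})
        expr = transform(table)
        assert expr.values.loc["G"].tolist()[:3] == [1.0, 16.0, 11.0]

    def test_round_trip_recovers_ct_exactly(self, rng):
        ct = 5 + 30 * rng.random(9)
        table = build_ct({"G": ct.tolist()})
        expr = transform(table)
        np.testing.assert_allclose(41.0 - expr.values.loc["G"], ct, rtol=0, atol=1e-12)

    def test_mad_invariant_under_reflection(self, rng):
        ct = 20 + 10 * rng.random(9)
        table = build_ct({"G": ct.tolist()})
        expr = transform(table)
        assert mad(expr.values.loc["G"]) == pytest.approx(mad(ct), abs=1e-12)

    def test_missing_cells_rejected(self):
        table = build_ct({"G": [M, 24, 25, 24, 25, 24, 25, 24, 25]})
        with pytest.raises(ValueError, match="complete"):
            transform(table)


class TestCleanPipeline:
    def test_clean_is_idempotent(self):
        table = build_ct(
            {
                "BIO": [M, M, M, 24, 25, 24, 25, 24, 25],
                "TECH1": [25, 24, 25, M, 24, 26, 24, 25, 24],
                "OK": [20] * 9,
            }
        )
        once, prov1, removed1 = clean_ct(table)
        twice, prov2, removed2 = clean_ct(once)
        assert once.values.equals(twice.values)
        assert removed2 == []

    def test_pipeline_output_has_no_missing_and_positive_x(self):
        table = build_ct(
            {
                "BIO": [M, M, M, 24, 25, 24, 25, 24, 25],
                "OK": [20] * 9,
            }
        )
        expr = preprocess_pipeline(table)
        assert not expr.values.isna().any().any()
        assert (expr.values > 0).all().all()
        assert (expr.values.loc["BIO"][:3] == 1.0).all()  # assigned Ct 40 -> x = 1


class TestQcCorrelation:
    def test_gene_tracking_array_mean_has_r_one(self):
        base = [20, 21, 22, 23, 24, 25, 26, 27, 28]
        table = build_ct({"A": base, "B": [v + 2.0 for v in base]})
        assert qc_reference_vs_array_mean(table, "A") == pytest.approx(1.0)

    def test_gene_anti_tracking_the_mean_has_r_minus_one(self):
        up = [20.0, 21, 22, 23, 24, 25, 26, 27, 28]
        down = [36.0 - v for v in up]  # mean still varies; gene moves opposite
        table = build_ct({"A": up, "B": up, "C": up, "D": down})
        assert qc_reference_vs_array_mean(table, "D") == pytest.approx(-1.0)

    def test_constant_gene_raises_undefined_correlation(self):
        table = build_ct({"A": [20] * 9, "B": list(range(20, 29))})
        with pytest.raises(ValueError, match="variance"):
            qc_reference_vs_array_mean(table, "A")

    def test_batch_artifact_gene_decorrelates_from_array_mean(self):
        """Monte Carlo: |r| < 0.5 for an array-specific-shift gene in >= 95% of seeds."""
        from refgene_screen.simdata import DEFAULT_DESIGN

        design = DEFAULT_DESIGN
        nulls = [
            flat_gene(f"N{i}", 22.0 + 0.1 * i, noise=0.5, kind="null", design=design)
            for i in range(85)
        ]
        batch = flat_gene("BAT", 12.0, noise=0.3, kind="batch_artifact", design=design)
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            table, _ = simulate_ct(design, nulls + [batch], 0.0, seed=seed)
            if abs(qc_reference_vs_array_mean(table, "BAT")) < 0.5:
                hits += 1
        assert hits / n_seeds >= 0.95
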