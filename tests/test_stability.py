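"""MAD and geNorm stability statistics vs brute-force oracles."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refgene_screen.stability import (
    EmptyScreenWarning,
    candidate_screen,
    genorm_m,
    genorm_rank,
    m_cutoff_filter,
    mad,
)
from refgene_screen.tables import ASSIGNED_CT40, MEASURED

from conftest import SMALL_DESIGN, build_expr


def brute_force_m(table, candidates):
    """Independent oracle: materialize every pairwise difference vector."""
    out = {}
    for gi in candidates:
        sds = []
        for gj in candidates:
            if gj == gi:
                continue
            diff = (table.values.loc[gi] - table.values.loc[gj]).tolist()
            sds.append(statistics.stdev(diff))  # n-1 denominator
        out[gi] = sum(sds) / len(sds)
    return out


class TestMad:
    def test_constant_vector_is_zero(self):
        assert mad([1, 1, 1]) == 0.0

    def test_outlier_resistant_enumeration_example(self):
        # median 3; |deviations| {2,1,0,1,97}; median of those is 1
        assert mad([1, 2, 3, 4, 100]) == 1.0

    def test_reflection_invariance(self, rng):
        ct = 20 + 10 * rng.random(23)
        assert mad(41 - ct) == pytest.approx(mad(ct), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad([])


class TestGenormM:
    def test_profiles_differing_by_constant_have_m_zero(self):
        expr = build_expr({"A": [1, 2, 3, 4, 3, 2, 1, 2, 3],
                           "B": [3, 4, 5, 6, 5, 4, 3, 4, 5]})
        m = genorm_m(expr, ["A", "B"])
        assert m["A"] == 0.0 and m["B"] == 0.0

    def test_three_gene_hand_example(self):
        from refgene_screen.simdata import StudyDesign

        design = StudyDesign((0.0, 4.0), (2, 2))
        expr = build_expr(
            {"A": [1, 2, 3, 4], "B": [1, 2, 3, 4], "C": [1, 3, 2, 4]}, design
        )
        m = genorm_m(expr, ["A", "B", "C"])
        # M(A) = mean(SD(A-B), SD(A-C)) = mean(0, SD(0,-1,1,0)) = 0.8165/2
        assert m["A"] == pytest.approx(np.sqrt(2 / 3) / 2, abs=1e-12)
        assert m["A"] == pytest.approx(0.408, abs=1e-3)

    def test_shift_invariance_per_gene(self, rng):
        vals = {f"G{i}": (10 + rng.normal(0, 1, 9)).tolist() for i in range(4)}
        expr = build_expr(vals)
        shifted = dict(vals)
        shifted["G2"] = [v + 5.0 for v in vals["G2"]]
        expr2 = build_expr(shifted)
        m1 = genorm_m(expr, list(vals))
        m2 = genorm_m(expr2, list(vals))
        np.testing.assert_allclose(m1, m2, atol=1e-12)

    def test_agrees_with_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 10))
            vals = {f"G{i}": (15 + rng.normal(0, 1, 9)).tolist() for i in range(k)}
            expr = build_expr(vals)
            m = genorm_m(expr, list(vals))
            oracle = brute_force_m(expr, list(vals))
            for g in vals:
                assert m[g] == pytest.approx(oracle[g], abs=1e-10)

    def test_fewer_than_two_candidates_rejected(self):
        expr = build_expr({"A": [1, 2, 3, 4, 3, 2, 1, 2, 3]})
        with pytest.raises(ValueError):
            genorm_m(expr, ["A"])

    def test_expected_m_monotone_in_gene_noise(self):
        """Spearman rho > 0.9 between planted noise sd and M (50 genes, 1000 samples)."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        sds = np.linspace(0.1, 1.5, 50)
        X = 20 + rng.normal(0, 1, (50, 1000)) * sds[:, None]
        values = pd.DataFrame(X, index=[f"G{i}" for i in range(50)],
                              columns=[f"t0h_r{j + 1}" for j in range(1000)])
        times = pd.Series(0.0, index=values.columns)
        from refgene_screen.tables import ExpressionTable

        expr = ExpressionTable(values=values, sample_time_h=times)
        m = genorm_m(expr, list(values.index))
        rho = spearmanr(sds, m.to_numpy()).statistic
        assert rho > 0.9


class TestCandidateScreen:
    def _results(self, p_by_gene):
        return pd.DataFrame({"anova_p_bh": pd.Series(p_by_gene)})

    def test_gene_below_p_floor_excluded_regardless_of_mad(self):
        expr = build_expr({"A": [5.0, 5.1, 4.9, 5.0, 5.1, 4.9, 5.0, 5.1, 4.9],
                           "B": [9, 5, 1, 9, 5, 1, 9, 5, 1]})
        screen = candidate_screen(expr, self._results({"A": 0.04, "B": 0.9}))
        assert list(screen.index) == ["B"]

    def test_single_passing_gene_ranked_first(self):
        expr = build_expr({"A": [5.0, 5.1, 4.9, 5.0, 5.1, 4.9, 5.0, 5.1, 4.9]})
        screen = candidate_screen(expr, self._results({"A": 0.5}))
        assert list(screen.index) == ["A"]

    def test_no_passing_gene_warns_and_returns_empty(self):
        expr = build_expr({"A": [5.0, 5.1, 4.9, 5.0, 5.1, 4.9, 5.0, 5.1, 4.9]})
        with pytest.warns(EmptyScreenWarning):
            screen = candidate_screen(expr, self._results({"A": 0.01}))
        assert screen.empty

    def test_sorted_by_mad_then_p_descending(self):
        expr = build_expr({
            "TIGHT": [5.0, 5.01, 4.99, 5.0, 5.01, 4.99, 5.0, 5.01, 4.99],
            "LOOSE": [5.0, 6.0, 4.0, 5.0, 6.0, 4.0, 5.0, 6.0, 4.0],
        })
        screen = candidate_screen(expr, self._results({"TIGHT": 0.3, "LOOSE": 0.8}))
        assert list(screen.index) == ["TIGHT", "LOOSE"]


class TestGenormRank:
    def test_two_gene_base_case_shares_rank_one(self):
        expr = build_expr({"A": [1, 2, 3, 4, 3, 2, 1, 2, 3],
                           "B": [1, 2, 4, 4, 3, 1, 1, 2, 3]})
        report = genorm_rank(expr, ["A", "B"])
        assert report["stepwise_rank"].tolist() == [1, 1]
        sd_ab = statistics.stdev(
            (expr.values.loc["A"] - expr.values.loc["B"]).tolist()
        )
        np.testing.assert_allclose(report["m_value"], [sd_ab, sd_ab], atol=1e-12)

    def test_candidate_with_excess_imputed_cells_excluded_by_name(self, rng):
        vals = {f"G{i}": (15 + rng.normal(0, 0.3, 9)).tolist() for i in range(23)}
        expr = build_expr(vals)
        # plant 3 imputed/assigned cells on one gene (tolerance is 2)
        prov = expr.provenance.copy()
        prov.loc["G7", prov.columns[:3]] = ASSIGNED_CT40
        expr.provenance = prov
        report = genorm_rank(expr, list(vals), missing_tolerance=2)
        assert not report.loc["G7", "included"]
        assert "excess missing" in report.loc["G7", "exclusion_reason"]
        assert report["included"].sum() == 22

    def test_stepwise_ranks_are_one_one_then_three_to_k(self, rng):
        vals = {f"G{i}": (15 + rng.normal(0, 0.5, 9)).tolist() for i in range(6)}
        expr = build_expr(vals)
        report = genorm_rank(expr, list(vals))
        assert sorted(report["stepwise_rank"]) == [1, 1, 3, 4, 5, 6]

    def test_noisiest_gene_gets_worst_rank(self, rng):
        vals = {f"G{i}": (15 + rng.normal(0, 0.2, 23)).tolist() for i in range(5)}
        vals["NOISY"] = (15 + rng.normal(0, 3.0, 23)).tolist()
        expr = build_expr(vals, design=_design23())
        report = genorm_rank(expr, list(vals))
        assert report.loc["NOISY", "stepwise_rank"] == 6


def _design23():
    from refgene_screen.simdata import DEFAULT_DESIGN

    return DEFAULT_DESIGN


class TestMCutoff:
    def _report(self, m_by_gene):
        return pd.DataFrame(
            {
                "m_value": pd.Series(m_by_gene),
                "included": True,
            }
        )

    def test_exact_boundary_excluded(self):
        assert m_cutoff_filter(self._report({"A": 0.5, "B": 0.49})) == ["B"]

    def test_offset_only_genes_all_pass(self):
        expr = build_expr({"A": [1, 2, 3, 4, 3, 2, 1, 2, 3],
                           "B": [2, 3, 4, 5, 4, 3, 2, 3, 4],
                           "C": [5, 6, 7, 8, 7, 6, 5, 6, 7]})
        report = genorm_rank(expr, ["A", "B", "C"])
        assert m_cutoff_filter(report) == ["A", "B", "C"]

    def test_planted_low_and_high_noise_split_recovered(self):
        """13 tight genes vs 10 loose ones: exactly the tight ones pass M < 0.5
        in >= 90% of 100 seeded runs."""
        from refgene_screen.tables import ExpressionTable

        design = _design23()
        cols = design.sample_ids()
        times = pd.Series(design.sample_times(), index=cols, dtype=float)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            tight = rng.normal(0, 0.12, (13, 23))  # within-group pairwise SD ~ 0.17
            loose = rng.normal(0, 0.65, (10, 23))  # within-group pairwise SD ~ 0.92
            X = 15 + np.vstack([tight, loose])
            names = [f"T{i}" for i in range(13)] + [f"L{i}" for i in range(10)]
            expr = ExpressionTable(
                values=pd.DataFrame(X, index=names, columns=cols),
                sample_time_h=times,
            )
            report = genorm_rank(expr, names)
            if set(m_cutoff_filter(report)) == {f"T{i}" for i in range(13)}:
                hits += 1
        assert hits / n_seeds >= 0.90
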