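"""Per-gene time-course differential-regulation testing.

Time points are treated as independent groups.  For every gene the module
computes a one-way ANOVA and a Kruskal-Wallis p-value across all time
points, BH-adjusts the ANOVA p-values across genes (one family per
normalization condition), computes the fold-change trajectory relative to
the earliest time point, locates the time point of greatest change in
either direction (maximizing max(FC, 1/FC), ties broken toward the earlier
point), runs a two-sided two-sample t-test between baseline and that
point, and calls a gene *regulated* when max fold change >= 1.5 and
BH-adjusted ANOVA p < 0.05.

All statistics operate on the log2-like x = 41 - Ct scale, where residuals
are closest to Gaussian and one unit is one PCR cycle (a doubling).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import ExpressionTable

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05


class DegenerateStatisticError(ValueError):
    """The requested statistic is undefined on this input (zero variance)."""


def _groups_for(table: ExpressionTable, gene: str) -> list[np.ndarray]:
    if gene not in table.values.index:
        raise KeyError(f"gene {gene!r} not in table")
    row = table.values.loc[gene]
    return [row[table.samples_at(t)].to_numpy() for t in table.time_points_h]


def _check_group_sizes(groups: list[np.ndarray]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two time points")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each time point needs at least two samples")


def anova_per_gene(table: ExpressionTable, gene: str) -> float:
    """Classical one-way fixed-effects ANOVA p-value across time points."""
    groups = _groups_for(table, gene)
    _check_group_sizes(groups)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.f_oneway(*groups).pvalue)
    if np.isnan(p):
        raise DegenerateStatisticError("all values identical: F undefined")
    return p


def kruskal_wallis_per_gene(table: ExpressionTable, gene: str) -> float:
    """Kruskal-Wallis rank-test p-value across time points (tie-corrected)."""
    groups = _groups_for(table, gene)
    _check_group_sizes(groups)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.kruskal(*groups).pvalue)
    except ValueError as exc:  # older scipy raises when all values are tied
        raise DegenerateStatisticError(str(exc)) from exc
    if np.isnan(p):
        raise DegenerateStatisticError("all values tied: H undefined")
    return p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _max_change(fc_row: pd.Series, baseline_t: float) -> tuple[float, float]:
    """(time, max(FC, 1/FC)) over non-baseline points; earlier time wins ties."""
    best_t, best = None, -np.inf
    for t in sorted(fc_row.index):
        if t == baseline_t:
            continue
        change = max(fc_row[t], 1.0 / fc_row[t])
        if change > best + 1e-12:
            best_t, best = t, change
    if best_t is None:  # single-time-point table
        return baseline_t, 1.0
    return best_t, float(best)


def ttest_at_max(
    table: ExpressionTable, gene: str, welch: bool = False
) -> tuple[float, float]:
    """Locate the time of greatest change and t-test it against baseline.

    Returns ``(max_fc_time, p)``; two-sided, pooled variance by default
    (Welch optional).  Degenerate (zero-variance) comparisons raise.
    """
    from .normalize import fold_change

    base_t = table.baseline_time_h
    fc_row = pd.Series(
        {t: fold_change(table, gene, t) for t in table.time_points_h}
    )
    max_t, _ = _max_change(fc_row, base_t)
    a = table.values.loc[gene, table.samples_at(base_t)].to_numpy()
    b = table.values.loc[gene, table.samples_at(max_t)].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs >= 2 samples in both groups")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateStatisticError("zero variance in both groups")
    p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
    return max_t, p


def overall_mean_by_time(table: ExpressionTable) -> pd.Series:
    """Grand mean x over all genes and samples, per time point.

    Used to check that one gene's kinetics (e.g. a drifting reference)
    differ from global transcription drift.
    """
    if table.values.empty:
        raise ValueError("empty table")
    return pd.Series(
        {
            t: float(table.values[table.samples_at(t)].to_numpy().mean())
            for t in table.time_points_h
        }
    ).sort_index()


def test_table(
    table: ExpressionTable,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> pd.DataFrame:
    """Run the whole per-gene testing battery on one expression table.

    Returns a DataFrame indexed by gene with columns ``anova_p``, ``kw_p``,
    ``anova_p_bh``, ``max_fc_time_h``, ``max_fc``, ``ttest_p_at_max``,
    ``regulated`` plus one ``fc_t<h>h`` column per time point.  ANOVA and
    Kruskal-Wallis are vectorized across genes; genes whose statistic is
    undefined (zero spread) get NaN p-values and are never called
    regulated.  BH adjustment spans all genes of this table — one family
    per normalization condition.
    """
    time_points = table.time_points_h
    if len(time_points) < 2:
        raise ValueError("need at least two time points")
    base_t = table.baseline_time_h
    group_mats = [table.values[table.samples_at(t)].to_numpy() for t in time_points]
    _check_group_sizes([g[0] for g in group_mats])

    with np.errstate(invalid="ignore", divide="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova_p = stats.f_oneway(*group_mats, axis=1).pvalue
            kw_p = stats.kruskal(*group_mats, axis=1).pvalue

    # fold-change trajectories vs baseline
    from .normalize import fold_change_table

    fc = fold_change_table(table)  # genes x time points

    max_fc_time = np.empty(len(fc))
    max_fc = np.empty(len(fc))
    ttest_p = np.full(len(fc), np.nan)
    base_mat = table.values[table.samples_at(base_t)].to_numpy()
    samples_by_t = {t: table.samples_at(t) for t in time_points}
    for i, gene in enumerate(fc.index):
        t_max, change = _max_change(fc.loc[gene], base_t)
        max_fc_time[i] = t_max
        max_fc[i] = change
        a = base_mat[i]
        b = table.values.loc[gene, samples_by_t[t_max]].to_numpy()
        if np.ptp(a) > 0 or np.ptp(b) > 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                ttest_p[i] = stats.ttest_ind(a, b, equal_var=not welch).pvalue

    # BH across genes; undefined ANOVA p-values stay NaN and fail the call
    p_bh = np.full(len(fc), np.nan)
    ok = ~np.isnan(anova_p)
    if ok.any():
        p_bh[ok] = bh_adjust(anova_p[ok])

    regulated = (max_fc >= fc_threshold) & (p_bh < alpha)
    out = pd.DataFrame(
        {
            "anova_p": anova_p,
            "kw_p": kw_p,
            "anova_p_bh": p_bh,
            "max_fc_time_h": max_fc_time,
            "max_fc": max_fc,
            "ttest_p_at_max": ttest_p,
            "regulated": regulated,
        },
        index=fc.index,
    )
    for t in time_points:
        out[f"fc_t{t:g}h"] = fc[t]
    out.index.name = "gene"
    return out


def call_regulated(
    results: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> set[str]:
    """Genes with max fold change >= threshold and BH-adjusted p < alpha."""
    mask = (results["max_fc"] >= fc_threshold) & (results["anova_p_bh"] < alpha)
    return set(results.index[mask.fillna(False)])
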