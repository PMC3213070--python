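"""Reference-gene stability screening: MAD/p plane and geNorm M values.

Two independent screens identify candidate reference genes among the genes
a time-course ANOVA did not call regulated:

* the **MAD screen** ranks candidates by the median absolute deviation
  from the median (raw, no 1.4826 consistency factor) of each gene's
  x = 41 - Ct values across all samples — a robust spread measure on the
  cycle scale, insensitive to the 41 - Ct reflection;

* the **geNorm screen** ranks candidates by the M value: for gene i,
  M(i) is the mean over the other candidates j of the sample standard
  deviation (n-1 denominator) of the pairwise log-expression difference
  x(i, s) - x(j, s).  A gene tracking the common signal has small pairwise
  difference SDs, hence a small M.  The stepwise ranking repeatedly drops
  the highest-M gene and recomputes M on the remainder; the final pair is
  indistinguishable by construction (their M values are equal) and shares
  rank 1.

Agreement between the two screens' top candidates is itself a check of
the procedure and is asserted by the simulation-based tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ExpressionTable

DEFAULT_P_FLOOR = 0.05
DEFAULT_M_CUTOFF = 0.5
DEFAULT_MISSING_TOLERANCE = 2


class EmptyScreenWarning(UserWarning):
    """No gene passed the not-regulated p-value floor."""


def mad(values) -> float:
    """Raw median absolute deviation from the median (no scaling factor)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    return float(stats.median_abs_deviation(v, scale=1.0))


def candidate_screen(
    table: ExpressionTable,
    test_results: pd.DataFrame,
    p_floor: float = DEFAULT_P_FLOOR,
) -> pd.DataFrame:
    """Rank not-regulated genes by expression spread (MAD), ascending.

    ``test_results`` must come from :func:`refgene_screen.diffexpr.test_table`
    run on the NON-normalized table — screening after normalization would
    circularly favour genes resembling the chosen reference.  Genes with
    BH-adjusted ANOVA p >= ``p_floor`` are retained, ranked by MAD
    ascending with ties broken by p descending (flatter evidence first).
    """
    common = [g for g in test_results.index if g in table.values.index]
    res = test_results.loc[common]
    candidates = res.index[res["anova_p_bh"] >= p_floor]
    if len(candidates) == 0:
        warnings.warn("no gene passed the p-value floor", EmptyScreenWarning)
        return pd.DataFrame(columns=["mad", "anova_p_bh"]).rename_axis("gene")

    mads = {g: mad(table.values.loc[g]) for g in candidates}
    out = pd.DataFrame(
        {
            "mad": pd.Series(mads),
            "anova_p_bh": res.loc[candidates, "anova_p_bh"],
        }
    )
    out = out.sort_values(["mad", "anova_p_bh"], ascending=[True, False])
    out.index.name = "gene"
    return out


def genorm_m(table: ExpressionTable, candidates: list[str]) -> pd.Series:
    """geNorm M value per candidate: mean pairwise-difference SD.

    M(i) = mean over j != i of SD_s(x(i, s) - x(j, s)), sample SD with the
    n-1 denominator, over the table's shared samples.
    """
    if len(candidates) < 2:
        raise ValueError("geNorm needs at least two candidate genes")
    missing = [g for g in candidates if g not in table.values.index]
    if missing:
        raise KeyError(f"candidate gene(s) not in table: {', '.join(missing)}")
    X = table.values.loc[list(candidates)].to_numpy()
    diffs = X[:, None, :] - X[None, :, :]
    sds = diffs.std(axis=2, ddof=1)  # diagonal is exactly 0
    m = sds.sum(axis=1) / (len(candidates) - 1)
    return pd.Series(m, index=list(candidates), name="m_value")


def genorm_rank(
    table: ExpressionTable,
    candidates: list[str],
    missing_tolerance: int = DEFAULT_MISSING_TOLERANCE,
) -> pd.DataFrame:
    """Full geNorm report: exclusion, full-set M values, stepwise ranks.

    Candidates with more than ``missing_tolerance`` imputed or assigned
    cells (per the table's provenance flags) are excluded first, mirroring
    geNorm's refusal to rank genes with excess missing data.  The stepwise
    ranking then repeatedly removes the highest-M gene from the remaining
    set (rank = current set size); the final two genes share rank 1.

    Returns a DataFrame indexed by gene with ``m_value`` (computed once on
    the full included set), ``stepwise_rank`` (NaN for excluded genes),
    ``included`` and ``exclusion_reason``.
    """
    imputed = table.imputed_cell_counts()
    excluded = {}
    included = []
    for g in candidates:
        n_bad = int(imputed.get(g, 0))
        if n_bad > missing_tolerance:
            excluded[g] = f"excess missing values ({n_bad} imputed/assigned cells)"
        else:
            included.append(g)
    if len(included) < 2:
        raise ValueError(
            f"geNorm needs >= 2 included candidates, got {len(included)}"
        )

    full_m = genorm_m(table, included)

    ranks: dict[str, int] = {}
    current = list(included)
    while len(current) > 2:
        m = genorm_m(table, current)
        worst = m.sort_values(kind="stable").index[-1]
        ranks[worst] = len(current)
        current.remove(worst)
    for g in current:  # the indistinguishable final pair
        ranks[g] = 1

    rows = []
    for g in candidates:
        if g in excluded:
            rows.append((g, np.nan, np.nan, False, excluded[g]))
        else:
            rows.append((g, full_m[g], ranks[g], True, ""))
    out = pd.DataFrame(
        rows,
        columns=["gene", "m_value", "stepwise_rank", "included", "exclusion_reason"],
    ).set_index("gene")
    return out.sort_values(
        ["included", "stepwise_rank", "m_value"], ascending=[False, True, True]
    )


def m_cutoff_filter(
    report: pd.DataFrame, cutoff: float = DEFAULT_M_CUTOFF
) -> list[str]:
    """Genes whose full-set M value is strictly below the cutoff (default 0.5)."""
    ok = report["included"] & (report["m_value"] < cutoff)
    return list(report.index[ok.fillna(False)])
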