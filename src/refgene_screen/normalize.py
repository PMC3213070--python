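"""Normalization schemes for expression tables on the x = 41 - Ct scale.

Three classes of scheme are supported, matching common qPCR practice:
no normalization, a single reference gene (the classic delta-Ct), and the
geometric mean of several reference genes.  Because x is log2-like,
subtracting the arithmetic mean of the reference x values is exactly
division by the geometric mean of the linear reference abundances.

Every scheme is a per-sample shift: within any sample, differences between
genes (hence gene rank order) are untouched.  A re-centering constant — the
across-sample mean of the subtracted reference signal — is added back so
that normalized tables keep positive, comparable magnitudes; it cancels in
every fold change and test statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CT_MAX, ExpressionTable

MODES = ("none", "single", "geometric_mean")


@dataclass(frozen=True)
class NormalizationScheme:
    """Declarative description of one normalization condition."""

    mode: str
    reference_genes: tuple[str, ...] = ()
    literal_ct_geomean: bool = False
    name: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        refs = tuple(self.reference_genes)
        object.__setattr__(self, "reference_genes", refs)
        if len(set(refs)) != len(refs):
            raise ValueError("duplicate reference genes")
        if self.mode == "none" and refs:
            raise ValueError("mode 'none' takes no reference genes")
        if self.mode == "single" and len(refs) != 1:
            raise ValueError("mode 'single' takes exactly one reference gene")
        if self.mode == "geometric_mean" and len(refs) < 1:
            raise ValueError("mode 'geometric_mean' takes at least one reference gene")
        if self.name is None:
            object.__setattr__(self, "name", self._default_name())

    def _default_name(self) -> str:
        if self.mode == "none":
            return "none"
        if self.mode == "single":
            return f"single:{self.reference_genes[0]}"
        return "geomean:" + "+".join(self.reference_genes)


def normalize(table: ExpressionTable, scheme: NormalizationScheme) -> ExpressionTable:
    """Apply a normalization scheme; returns a new table, input untouched.

    For a reference signal r(s) (one gene's x, or the mean x of several),
    x'(g, s) = x(g, s) - r(s) + mean_s r(s).  With ``literal_ct_geomean``
    the multi-reference signal is instead built from the geometric mean of
    the raw Ct numbers, a numerically eccentric but occasionally reported
    variant.
    """
    if scheme.mode == "none":
        return table.with_values(table.values.copy())

    missing = [g for g in scheme.reference_genes if g not in table.values.index]
    if missing:
        raise KeyError(
            f"reference gene(s) not in table (removed or never present): "
            f"{', '.join(missing)}"
        )

    refs = table.values.loc[list(scheme.reference_genes)]
    if scheme.literal_ct_geomean and scheme.mode == "geometric_mean":
        ct = (CT_MAX + 1.0) - refs  # back to the Ct scale
        ref_signal = (CT_MAX + 1.0) - np.exp(np.log(ct).mean(axis=0))
    else:
        ref_signal = refs.mean(axis=0)

    centering = float(ref_signal.mean())
    shifted = table.values.sub(ref_signal, axis=1) + centering
    return table.with_values(shifted)


def fold_change(
    table: ExpressionTable,
    gene: str,
    t: float,
    baseline_t: float | None = None,
) -> float:
    """Fold change of ``gene`` at time ``t`` relative to baseline.

    FC = 2^(mean x at t - mean x at baseline); the baseline defaults to the
    earliest time point and has FC = 1 by construction.
    """
    if gene not in table.values.index:
        raise KeyError(f"gene {gene!r} not in table")
    if baseline_t is None:
        baseline_t = table.baseline_time_h
    base_samples = table.samples_at(baseline_t)
    t_samples = table.samples_at(t)
    if not base_samples:
        raise ValueError(f"no samples at baseline t={baseline_t:g}h")
    if not t_samples:
        raise ValueError(f"no samples at t={t:g}h")
    row = table.values.loc[gene]
    return float(2.0 ** (row[t_samples].mean() - row[base_samples].mean()))


def fold_change_table(table: ExpressionTable):
    """Genes x time-points DataFrame of fold changes vs the earliest point."""
    groups = {
        t: table.values[table.samples_at(t)].mean(axis=1)
        for t in table.time_points_h
    }
    base = groups[table.baseline_time_h]
    return pd.DataFrame(
        {t: 2.0 ** (m - base) for t, m in groups.items()}
    )
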