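"""Pre-analytic processing of raw Ct matrices.

The cleaning pipeline mirrors standard qPCR array practice:

1. **classify** every missing cell as *biological* (the transcript is
   plausibly absent: the gene is undetected in all replicates of a
   contiguous run of time points touching the start or end of the time
   course) or *technical* (unexplained non-detection);
2. **filter** out genes accumulating two or more technical missing cells;
3. **impute** the survivors — biological cells get the instrument maximum
   Ct 40, technical cells the mean Ct of the detected replicates at the
   same time point;
4. **transform** to the expression scale x = 41 - Ct, i.e. reflect so that
   larger means more expressed and add a one-cycle pseudocount so that
   Ct = 40 maps to x = 1 rather than 0.

An optional sidecar annotation (gene, sample, class) can override the
rule-based classification cell by cell, standing in for expert judgment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    ASSIGNED_CT40,
    CT_MAX,
    IMPUTED_MEAN,
    MEASURED,
    CtTable,
    ExpressionTable,
    RemovedGene,
)

BIOLOGICAL = "biological"
TECHNICAL = "technical"


class UnrecoverableCellError(ValueError):
    """A technical missing cell has no detected replicate to impute from."""


class DegenerateInputError(ValueError):
    """Input left no usable data (e.g. all genes filtered out)."""


@dataclass(frozen=True)
class MissingPolicy:
    """How missing Ct values are explained and when a gene is dropped.

    ``max_unexplained_missing``: a gene with at least this many technical
    (unexplained) missing cells is removed; default 2 ("two or more").
    ``biological_edge_rule``: whether all-replicate absence in a contiguous
    run touching the first or last time point counts as biological.
    """

    max_unexplained_missing: int = 2
    biological_edge_rule: bool = True

    def __post_init__(self) -> None:
        if self.max_unexplained_missing < 1:
            raise ValueError("max_unexplained_missing must be >= 1")


def read_overrides(path) -> dict[tuple[str, str], str]:
    """Read a sidecar TSV with columns gene, sample, class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"gene", "sample", "class"}
    if not expected <= set(df.columns):
        raise ValueError(f"override sidecar needs columns {sorted(expected)}")
    out = {}
    for _, row in df.iterrows():
        cls = row["class"]
        if cls not in (BIOLOGICAL, TECHNICAL):
            raise ValueError(f"override class must be biological/technical, got {cls!r}")
        out[(row["gene"], row["sample"])] = cls
    return out


def classify_missing(
    table: CtTable,
    policy: MissingPolicy = MissingPolicy(),
    overrides: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Label every missing cell ``biological`` or ``technical``.

    Returns an object DataFrame with the table's axes; non-missing cells
    hold None.  A missing cell is biological iff its gene is undetected in
    ALL replicates at a contiguous run of time points that includes the
    first or the last time point (and the edge rule is enabled); every
    other missing cell is technical.
    """
    time_points = table.time_points_h
    samples_by_t = {t: table.samples_at(t) for t in time_points}
    cls = pd.DataFrame(None, index=table.values.index, columns=table.values.columns, dtype=object)

    missing = table.values.isna()
    for gene in table.gene_ids:
        row = missing.loc[gene]
        if not row.any():
            continue
        all_missing = {t: bool(row[samples_by_t[t]].all()) for t in time_points}
        edge_ts: set[float] = set()
        if policy.biological_edge_rule:
            for t in time_points:  # run from the start
                if all_missing[t]:
                    edge_ts.add(t)
                else:
                    break
            for t in reversed(time_points):  # run from the end
                if all_missing[t]:
                    edge_ts.add(t)
                else:
                    break
        for s in table.sample_ids:
            if row[s]:
                cls.loc[gene, s] = (
                    BIOLOGICAL if table.sample_time_h[s] in edge_ts else TECHNICAL
                )

    if overrides:
        for (gene, sample), label in overrides.items():
            if gene not in table.values.index or sample not in table.values.columns:
                raise ValueError(f"override targets unknown cell ({gene}, {sample})")
            if pd.isna(cls.loc[gene, sample]):
                raise ValueError(
                    f"override targets non-missing cell ({gene}, {sample})"
                )
            cls.loc[gene, sample] = label
    return cls


def impute_and_flag(
    table: CtTable, classification: pd.DataFrame
) -> tuple[CtTable, pd.DataFrame]:
    """Fill every missing cell and record per-cell provenance.

    Biological cells become Ct 40 (flag ``assigned_ct40``); technical cells
    become the mean Ct of the detected replicates of the same gene at the
    same time point (flag ``imputed_mean``).  Raises
    :class:`UnrecoverableCellError` for a technical cell with no detected
    replicate at its time point — such a gene should have been filtered.
    """
    values = table.values.copy()
    prov = pd.DataFrame(MEASURED, index=values.index, columns=values.columns)
    missing = table.values.isna()
    if bool((missing & classification.isna()).to_numpy().any()):
        raise ValueError("every missing cell must be classified")

    for gene in table.gene_ids:
        row = missing.loc[gene]
        if not row.any():
            continue
        for s in table.sample_ids:
            if not row[s]:
                continue
            if classification.loc[gene, s] == BIOLOGICAL:
                values.loc[gene, s] = CT_MAX
                prov.loc[gene, s] = ASSIGNED_CT40
            else:
                peers = table.samples_at(table.sample_time_h[s])
                detected = table.values.loc[gene, peers].dropna()
                if detected.empty:
                    raise UnrecoverableCellError(
                        f"gene {gene}, sample {s}: no detected replicate at "
                        f"t={table.sample_time_h[s]:g}h to impute from"
                    )
                values.loc[gene, s] = float(detected.mean())
                prov.loc[gene, s] = IMPUTED_MEAN
    return CtTable(values=values, sample_time_h=table.sample_time_h.copy()), prov


def filter_genes(
    table: CtTable,
    classification: pd.DataFrame,
    policy: MissingPolicy = MissingPolicy(),
) -> tuple[CtTable, list[RemovedGene]]:
    """Drop genes with too many unexplained (technical) missing cells.

    Biological missing cells never count toward removal.
    """
    tech_counts = (classification == TECHNICAL).sum(axis=1)
    removed = [
        RemovedGene(
            gene=g,
            reason=f"{int(n)} unexplained missing values",
        )
        for g, n in tech_counts.items()
        if n >= policy.max_unexplained_missing
    ]
    keep = [g for g in table.gene_ids if g not in {r.gene for r in removed}]
    if not keep:
        raise DegenerateInputError("no genes left after missing-value filtering")
    kept = CtTable(
        values=table.values.loc[keep].copy(),
        sample_time_h=table.sample_time_h.copy(),
    )
    return kept, removed


def transform(
    table: CtTable,
    provenance: pd.DataFrame | None = None,
    removed: list[RemovedGene] | None = None,
) -> ExpressionTable:
    """Map a complete Ct matrix to the expression scale x = 41 - Ct.

    The reflection makes larger x mean higher expression; the extra cycle
    is a pseudocount so that the instrument ceiling Ct = 40 maps to x = 1.
    Rejects tables that still contain missing cells or Ct >= 41.
    """
    vals = table.values
    if vals.isna().to_numpy().any():
        raise ValueError("transform requires a complete table; impute first")
    if (vals.to_numpy() >= CT_MAX + 1.0).any():
        raise ValueError("Ct >= 41 would give non-positive expression")
    return ExpressionTable(
        values=(CT_MAX + 1.0) - vals,
        sample_time_h=table.sample_time_h.copy(),
        provenance=None if provenance is None else provenance.copy(),
        removed=list(removed or []),
    )


def clean_ct(
    table: CtTable,
    policy: MissingPolicy = MissingPolicy(),
    overrides: dict[tuple[str, str], str] | None = None,
) -> tuple[CtTable, pd.DataFrame, list[RemovedGene]]:
    """classify -> filter -> impute; returns (complete CtTable, provenance, removed).

    Idempotent: running it again on its own output changes nothing.
    """
    classification = classify_missing(table, policy, overrides)
    kept, removed = filter_genes(table, classification, policy)
    complete, prov = impute_and_flag(kept, classification.loc[kept.gene_ids])
    return complete, prov, removed


def preprocess_pipeline(
    table: CtTable,
    policy: MissingPolicy = MissingPolicy(),
    overrides: dict[tuple[str, str], str] | None = None,
) -> ExpressionTable:
    """Full pre-analytic pipeline: clean then transform to x = 41 - Ct."""
    complete, prov, removed = clean_ct(table, policy, overrides)
    return transform(complete, prov, removed)


def qc_reference_vs_array_mean(table: CtTable, gene: str) -> float:
    """Pearson correlation of one gene's Ct with the per-sample mean Ct.

    A gene tracking global signal (RNA input, cDNA quality) correlates
    strongly with the array mean; a batch-artifact gene whose shifts are
    array-specific does not.  The mean excludes the queried gene itself so
    its own excursions cannot manufacture correlation.  Samples where the
    gene is undetected are dropped; requires >= 3 usable samples and
    non-degenerate variance.
    """
    if gene not in table.values.index:
        raise KeyError(f"gene {gene!r} not in table")
    if len(table.gene_ids) < 2:
        raise ValueError("need at least one other gene for the array mean")
    gene_ct = table.values.loc[gene]
    mean_ct = table.values.drop(index=gene).mean(axis=0, skipna=True)
    mask = gene_ct.notna() & mean_ct.notna()
    if int(mask.sum()) < 3:
        raise ValueError("need at least 3 samples with the gene detected")
    x = gene_ct[mask].to_numpy()
    y = mean_ct[mask].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
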