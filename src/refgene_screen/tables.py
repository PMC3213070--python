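"""Tabular containers for qPCR cycle-threshold (Ct) data and transformed expression.

Two containers move through the analysis:

``CtTable``
    raw genes x samples Ct values (cycles) with an explicit missing marker
    (NaN in memory, the literal token ``NA`` on disk) and per-sample time
    annotation.  Lower Ct means more transcript.

``ExpressionTable``
    the filtered, imputed, transformed matrix x = 41 - Ct, on which every
    downstream statistic operates.  The 41 - Ct transform reverses the
    ordering (higher x = higher expression) and the built-in pseudocount of
    one cycle keeps x >= 1 for any recorded Ct <= 40.  Each cell carries a
    provenance flag.

Sample identifiers encode the design: ``t<hours>h_r<replicate>``, e.g.
``t4h_r2`` is the second replicate taken 4 hours after challenge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: token written for a missing Ct value in TSV files
MISSING_TOKEN = "NA"

#: maximum cycle number the instrument reports
CT_MAX = 40.0

# per-cell provenance flags
MEASURED = "measured"
IMPUTED_MEAN = "imputed_mean"
ASSIGNED_CT40 = "assigned_ct40"
PROVENANCE_FLAGS = frozenset({MEASURED, IMPUTED_MEAN, ASSIGNED_CT40})

_SAMPLE_ID_RE = re.compile(r"^t(?P<hours>[0-9]+(?:\.[0-9]+)?)h_r(?P<rep>[0-9]+)$")


def make_sample_id(hours: float, replicate: int) -> str:
    """Build the canonical ``t<hours>h_r<rep>`` sample identifier."""
    return f"t{hours:g}h_r{replicate}"


def parse_sample_id(sample_id: str) -> tuple[float, int]:
    """Extract (hours, replicate) from a canonical sample identifier."""
    m = _SAMPLE_ID_RE.match(sample_id)
    if m is None:
        raise ValueError(
            f"sample id {sample_id!r} does not match the t<hours>h_r<rep> pattern"
        )
    return float(m.group("hours")), int(m.group("rep"))


@dataclass
class RemovedGene:
    """A gene dropped before analysis, with the reason it was dropped."""

    gene: str
    reason: str


def _check_axes(values: pd.DataFrame, sample_time_h: pd.Series) -> None:
    if values.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    if values.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    if list(sample_time_h.index) != list(values.columns):
        raise ValueError("sample_time_h index must match the table's sample ids")
    if (np.asarray(sample_time_h, dtype=float) < 0).any():
        raise ValueError("time points must be non-negative")


@dataclass
class CtTable:
    """Raw genes x samples Ct matrix with sample time metadata.

    ``values`` is a float DataFrame (rows = gene symbols, columns = sample
    ids); missing measurements are NaN.  Recorded Ct values must lie in
    (0, 40].
    """

    values: pd.DataFrame
    sample_time_h: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.sample_time_h = self.sample_time_h.astype(float)
        _check_axes(self.values, self.sample_time_h)
        present = self.values.to_numpy()
        present = present[~np.isnan(present)]
        if present.size and ((present <= 0).any() or (present > CT_MAX + 1e-9).any()):
            raise ValueError(f"recorded Ct values must lie in (0, {CT_MAX:g}]")

    # -- axes -----------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def time_points_h(self) -> list[float]:
        """Distinct time points, ascending."""
        return sorted(set(self.sample_time_h))

    def samples_at(self, t: float) -> list[str]:
        return list(self.sample_time_h.index[self.sample_time_h == t])

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    # -- I/O ------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "CtTable":
        values = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=[MISSING_TOKEN],
            keep_default_na=False,
        )
        values.index = values.index.astype(str)
        times = pd.Series(
            [parse_sample_id(s)[0] for s in values.columns],
            index=values.columns,
            dtype=float,
        )
        return cls(values=values, sample_time_h=times)

    def copy(self) -> "CtTable":
        return CtTable(self.values.copy(), self.sample_time_h.copy())


@dataclass
class ExpressionTable:
    """Complete (no missing cells) expression matrix on the x = 41 - Ct scale.

    ``provenance`` mirrors ``values`` cell-for-cell with one of the flags
    ``measured``, ``imputed_mean`` or ``assigned_ct40``; ``removed`` lists
    genes dropped before the transform together with the reason.
    """

    values: pd.DataFrame
    sample_time_h: pd.Series
    provenance: pd.DataFrame | None = None
    removed: list[RemovedGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.sample_time_h = self.sample_time_h.astype(float)
        _check_axes(self.values, self.sample_time_h)
        if self.values.isna().to_numpy().any():
            raise ValueError("ExpressionTable must not contain missing cells")
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                MEASURED, index=self.values.index, columns=self.values.columns
            )
        if self.provenance.shape != self.values.shape or not (
            self.provenance.index.equals(self.values.index)
            and self.provenance.columns.equals(self.values.columns)
        ):
            raise ValueError("provenance axes must match values")
        flags = set(np.unique(self.provenance.to_numpy().astype(str)))
        if not flags <= PROVENANCE_FLAGS:
            raise ValueError(f"unknown provenance flags: {flags - PROVENANCE_FLAGS}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def time_points_h(self) -> list[float]:
        return sorted(set(self.sample_time_h))

    @property
    def baseline_time_h(self) -> float:
        return self.time_points_h[0]

    def samples_at(self, t: float) -> list[str]:
        return list(self.sample_time_h.index[self.sample_time_h == t])

    def imputed_cell_counts(self) -> pd.Series:
        """Per-gene count of cells that are not direct measurements."""
        return (self.provenance != MEASURED).sum(axis=1)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")

    def with_values(self, values: pd.DataFrame) -> "ExpressionTable":
        """Same metadata, new matrix (used by normalization)."""
        return ExpressionTable(
            values=values,
            sample_time_h=self.sample_time_h.copy(),
            provenance=self.provenance.copy(),
            removed=list(self.removed),
        )
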