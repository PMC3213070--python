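import numpy as np
import pandas as pd
import pytest

from refgene_screen.simdata import DEFAULT_DESIGN, GeneArchetype, StudyDesign
from refgene_screen.tables import CtTable, ExpressionTable, make_sample_id

SMALL_DESIGN = StudyDesign(
    time_points_h=(0.0, 4.0, 18.0),
    replicates_per_point=(3, 3, 3),
)


def build_ct(values_by_gene: dict, design: StudyDesign = SMALL_DESIGN) -> CtTable:
    """CtTable from {gene: [ct per sample]} lists (None = missing)."""
    sample_ids = design.sample_ids()
    values = pd.DataFrame(
        {g: [np.nan if v is None else float(v) for v in row] for g, row in values_by_gene.items()},
        index=sample_ids,
    ).T
    times = pd.Series(design.sample_times(), index=sample_ids, dtype=float)
    return CtTable(values=values, sample_time_h=times)


def build_expr(values_by_gene: dict, design: StudyDesign = SMALL_DESIGN) -> ExpressionTable:
    """ExpressionTable directly from {gene: [x per sample]} lists."""
    sample_ids = design.sample_ids()
    values = pd.DataFrame(
        {g: [float(v) for v in row] for g, row in values_by_gene.items()},
        index=sample_ids,
    ).T
    times = pd.Series(design.sample_times(), index=sample_ids, dtype=float)
    return ExpressionTable(values=values, sample_time_h=times)


def flat_gene(name: str, baseline: float, noise: float = 0.0, kind: str = "stable",
              design: StudyDesign = SMALL_DESIGN, threshold: float | None = None) -> GeneArchetype:
    return GeneArchetype(
        name=name,
        kind=kind,
        baseline_ct=baseline,
        log2_trajectory=(0.0,) * len(design.time_points_h),
        noise_sd=noise,
        dropout_ct_threshold=threshold,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One full default pipeline run shared by read-only tests."""
    from refgene_screen.pipeline import PipelineConfig, run_all

    return run_all(PipelineConfig(), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_design():
    return SMALL_DESIGN


@pytest.fixture
def full_design():
    return DEFAULT_DESIGN
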