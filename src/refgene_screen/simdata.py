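"""Synthetic Ct-matrix generator with known ground truth.

Emulates a microfluidic qPCR array time-course experiment: 96 assays
measured on one array per animal, 7 time points spanning initiation, peak
and resolution of an acute inflammatory response, 3-4 animals per point.
Genes are drawn from a small set of archetypes:

``stable``
    flat trajectory, low noise — the planted reference-gene candidates
    (PPIA-like).
``spike``
    transiently induced gene; the default big spike reaches ~208-fold
    (+7.70 log2) at 4 h, an IL-1beta-like response.  Smaller spike
    archetypes model the bulk of regulated inflammatory genes.
``drift``
    slowly rising gene peaking late (+1.49 log2 ~ 2.8-fold at 18 h), the
    GAPDH-like unstable reference whose use as a normalizer plants
    artifacts downstream.
``null``
    flat trajectory, ordinary noise — unregulated targets.
``dropout``
    expressed near the detection limit; measurements beyond the dropout
    threshold are recorded as missing.
``batch_artifact``
    a gene carrying large array-specific shifts on a few arrays
    (an 18S-rRNA-like manufacturing defect), unrelated to global signal.

The generative model for gene g on sample s taken at time t is

    Ct(g, s) = baseline_ct(g) - log2_trajectory(g, t) - array_effect(s)
               + batch_shift(g, s) + Normal(0, noise_sd(g))

so a positive log2 fold change LOWERS Ct (more template, earlier
detection), with amplification efficiency fixed at 2 (one cycle = 2-fold).
Values above a gene's dropout threshold become missing; values between the
threshold and the instrument maximum of 40 cycles are clipped to 40.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CT_MAX, CtTable, make_sample_id

GENE_KINDS = ("stable", "spike", "drift", "null", "dropout", "batch_artifact")

# batch_artifact behaviour: large positive Ct shift (low detection) on a few
# randomly chosen arrays, independent of the shared array effect
BATCH_N_AFFECTED_ARRAYS = 3
BATCH_SHIFT_CT = 4.0


@dataclass(frozen=True)
class StudyDesign:
    """Time points (hours) and replicate counts of the sampling design."""

    time_points_h: tuple[float, ...]
    replicates_per_point: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.time_points_h) != len(self.replicates_per_point):
            raise ValueError("time_points_h and replicates_per_point lengths differ")
        if not self.time_points_h:
            raise ValueError("design needs at least one time point")
        if any(t < 0 for t in self.time_points_h):
            raise ValueError("time points must be non-negative")
        if any(b <= a for a, b in zip(self.time_points_h, self.time_points_h[1:])):
            raise ValueError("time points must be strictly increasing")
        if any(r < 1 for r in self.replicates_per_point):
            raise ValueError("replicate counts must be positive")

    @property
    def n_samples(self) -> int:
        return sum(self.replicates_per_point)

    def sample_ids(self) -> list[str]:
        return [
            make_sample_id(t, r + 1)
            for t, n in zip(self.time_points_h, self.replicates_per_point)
            for r in range(n)
        ]

    def sample_times(self) -> list[float]:
        return [
            t
            for t, n in zip(self.time_points_h, self.replicates_per_point)
            for _ in range(n)
        ]


#: the default design: 7 points, 4 animals at 1 h and 4 h, 3 elsewhere (23 arrays)
DEFAULT_DESIGN = StudyDesign(
    time_points_h=(0.0, 1.0, 4.0, 9.0, 18.0, 27.0, 50.0),
    replicates_per_point=(3, 4, 4, 3, 3, 3, 3),
)


@dataclass(frozen=True)
class GeneArchetype:
    """Generative parameters for one simulated gene."""

    name: str
    kind: str
    baseline_ct: float
    log2_trajectory: tuple[float, ...]
    noise_sd: float = 0.3
    dropout_ct_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown gene kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kind in ("stable", "null") and any(
            v != 0 for v in self.log2_trajectory
        ):
            raise ValueError(f"{self.kind} archetype must have an all-zero trajectory")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated table."""

    archetypes: dict[str, GeneArchetype]
    array_effect: pd.Series
    batch_affected_samples: dict[str, list[str]]
    rng_seed: int

    def genes_of_kind(self, *kinds: str) -> list[str]:
        return [g for g, a in self.archetypes.items() if a.kind in kinds]

    def to_json(self, path) -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "array_effect": {s: float(v) for s, v in self.array_effect.items()},
            "batch_affected_samples": self.batch_affected_samples,
            "genes": {
                g: {
                    "kind": a.kind,
                    "baseline_ct": a.baseline_ct,
                    "log2_trajectory": list(a.log2_trajectory),
                    "noise_sd": a.noise_sd,
                    "dropout_ct_threshold": a.dropout_ct_threshold,
                }
                for g, a in self.archetypes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_ct(
    design: StudyDesign,
    archetypes: list[GeneArchetype],
    array_effect_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CtTable, SimulationTruth]:
    """Draw one Ct matrix from the generative model.

    Identical (design, archetypes, array_effect_sd, seed) yield a
    bit-identical table.  Raises on duplicate gene names, mismatched
    trajectory lengths or negative noise.
    """
    if not archetypes:
        raise ValueError("need at least one gene archetype")
    names = [a.name for a in archetypes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names in archetype list")
    n_t = len(design.time_points_h)
    for a in archetypes:
        if len(a.log2_trajectory) != n_t:
            raise ValueError(
                f"gene {a.name}: trajectory length {len(a.log2_trajectory)} "
                f"does not match the {n_t} design time points"
            )
    if array_effect_sd < 0:
        raise ValueError("array_effect_sd must be non-negative")

    rng = np.random.default_rng(seed)
    sample_ids = design.sample_ids()
    sample_times = np.array(design.sample_times())
    t_index = np.searchsorted(np.array(design.time_points_h), sample_times)
    n_s = design.n_samples

    array_effect = rng.normal(0.0, array_effect_sd, size=n_s)

    rows = np.empty((len(archetypes), n_s))
    batch_affected: dict[str, list[str]] = {}
    for i, a in enumerate(archetypes):
        traj = np.asarray(a.log2_trajectory)[t_index]
        noise = rng.normal(0.0, a.noise_sd, size=n_s)
        ct = a.baseline_ct - traj - array_effect + noise
        if a.kind == "batch_artifact":
            hit = rng.choice(n_s, size=min(BATCH_N_AFFECTED_ARRAYS, n_s), replace=False)
            ct[hit] += BATCH_SHIFT_CT
            batch_affected[a.name] = [sample_ids[j] for j in sorted(hit)]
        if a.dropout_ct_threshold is not None:
            ct[ct > a.dropout_ct_threshold] = np.nan
        # instrument ceiling: detections between threshold and 40 read as 40
        ct = np.minimum(ct, CT_MAX)
        rows[i] = ct

    values = pd.DataFrame(rows, index=names, columns=sample_ids)
    times = pd.Series(sample_times, index=sample_ids, dtype=float)
    table = CtTable(values=values, sample_time_h=times)
    truth = SimulationTruth(
        archetypes={a.name: a for a in archetypes},
        array_effect=pd.Series(array_effect, index=sample_ids),
        batch_affected_samples=batch_affected,
        rng_seed=seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# default archetype mix
# ---------------------------------------------------------------------------

#: archetype counts emulating the study structure: of 96 assays, 10
#: detection-limit genes fail the missing-value screen and the batch gene is
#: excluded by QC, leaving 85 analyzable genes (3 planted stable candidates,
#: one big spike, one drifting pseudo-reference, remainder null).
DEFAULT_MIX = {
    "stable": 3,
    "spike": 1,
    "drift": 1,
    "batch_artifact": 1,
    "dropout": 10,
    "regulated": 0,
    "null": 80,
}

#: IL-1beta-like induction: ~208-fold (2^7.70) at 4 h, decaying thereafter
SPIKE_TRAJECTORY = (0.0, 4.0, 7.70, 5.0, 3.0, 1.5, 0.5)

#: GAPDH-like drift: slow rise to 2.8-fold (2^1.49) at 18 h, then decline
DRIFT_TRAJECTORY = (0.0, 0.0, 0.5, 1.0, 1.49, 1.0, 0.5)

# noise defaults (cycles): stable candidates are tight; regulated targets have
# moderate residual noise; flat "null" genes carry larger animal-to-animal
# variability not structured by time (what makes them poor reference genes
# despite non-significant ANOVA)
STABLE_NOISE_SD = 0.25
TARGET_NOISE_SD = 0.5
NULL_NOISE_SD = 1.0
DRIFT_NOISE_SD = 0.3
DROPOUT_BASELINE_CT = 39.8
DROPOUT_NOISE_SD = 0.6

# moderate regulated genes cycle through these log2 amplitudes / peak times
_REG_AMPLITUDES = (1.5, 2.0, 2.5, 3.0, 4.0)
_REG_SIGNS = (1.0, 1.0, 1.0, -1.0)  # mostly inductions, some repressions


def _regulated_trajectory(i: int, n_t: int) -> tuple[float, ...]:
    amp = _REG_AMPLITUDES[i % len(_REG_AMPLITUDES)] * _REG_SIGNS[i % len(_REG_SIGNS)]
    peak = 1 + (i % (n_t - 1))  # never the baseline point
    traj = [0.0] * n_t
    traj[peak] = amp
    # one-step shoulders give smoother, more realistic kinetics
    if peak - 1 >= 1:
        traj[peak - 1] = amp / 2
    if peak + 1 <= n_t - 1:
        traj[peak + 1] = amp / 2
    return tuple(traj)


def default_archetypes(
    mix: dict[str, int] | None = None,
    design: StudyDesign = DEFAULT_DESIGN,
) -> list[GeneArchetype]:
    """Build the deterministic default gene panel for a given design.

    ``mix`` maps archetype group names (keys of :data:`DEFAULT_MIX`) to
    counts; ``regulated`` genes are moderate spikes with log2 amplitudes
    >= 1.5 cycling through varied peak times and directions.
    """
    mix = dict(DEFAULT_MIX if mix is None else mix)
    n_t = len(design.time_points_h)
    flat = (0.0,) * n_t
    genes: list[GeneArchetype] = []

    for i in range(mix.get("stable", 0)):
        genes.append(
            GeneArchetype(
                name=f"STB{i + 1:02d}",
                kind="stable",
                baseline_ct=22.0 + 2.0 * i,
                log2_trajectory=flat,
                noise_sd=STABLE_NOISE_SD,
            )
        )
    for i in range(mix.get("spike", 0)):
        genes.append(
            GeneArchetype(
                name=f"SPK{i + 1:02d}",
                kind="spike",
                baseline_ct=30.0,
                log2_trajectory=SPIKE_TRAJECTORY[:n_t],
                noise_sd=TARGET_NOISE_SD,
            )
        )
    for i in range(mix.get("drift", 0)):
        genes.append(
            GeneArchetype(
                name=f"DRF{i + 1:02d}",
                kind="drift",
                baseline_ct=20.0,
                log2_trajectory=DRIFT_TRAJECTORY[:n_t],
                noise_sd=DRIFT_NOISE_SD,
            )
        )
    for i in range(mix.get("batch_artifact", 0)):
        genes.append(
            GeneArchetype(
                name=f"BAT{i + 1:02d}",
                kind="batch_artifact",
                baseline_ct=12.0,
                log2_trajectory=flat,
                noise_sd=DRIFT_NOISE_SD,
            )
        )
    for i in range(mix.get("dropout", 0)):
        genes.append(
            GeneArchetype(
                name=f"DRP{i + 1:02d}",
                kind="dropout",
                baseline_ct=DROPOUT_BASELINE_CT,
                log2_trajectory=flat,
                noise_sd=DROPOUT_NOISE_SD,
                dropout_ct_threshold=CT_MAX,
            )
        )
    for i in range(mix.get("regulated", 0)):
        genes.append(
            GeneArchetype(
                name=f"REG{i + 1:02d}",
                kind="spike",
                baseline_ct=24.0 + (i % 9),
                log2_trajectory=_regulated_trajectory(i, n_t),
                noise_sd=TARGET_NOISE_SD,
            )
        )
    for i in range(mix.get("null", 0)):
        genes.append(
            GeneArchetype(
                name=f"NUL{i + 1:02d}",
                kind="null",
                baseline_ct=23.0 + 0.5 * (i % 21),
                log2_trajectory=flat,
                noise_sd=NULL_NOISE_SD,
            )
        )
    return genes
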