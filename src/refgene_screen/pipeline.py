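"""End-to-end orchestration and cross-scheme comparison.

``run_all`` drives the full analysis: simulate (or ingest) a Ct matrix,
clean and transform it, test every gene under each configured
normalization scheme, screen for reference-gene candidates on the
non-normalized results, and compare the regulated-gene sets across
schemes.  Everything is deterministic given (config, seed), and every
filtering or imputation decision is logged with gene and sample ids.

The cross-scheme comparison is the analysis's punchline: a normalization
scheme built on an unstable reference manufactures "regulated" genes that
no other scheme sees, and flips the apparent direction of genuinely flat
genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, preprocess, stability
from .normalize import NormalizationScheme, normalize
from .simdata import (
    DEFAULT_DESIGN,
    GeneArchetype,
    SimulationTruth,
    StudyDesign,
    default_archetypes,
    simulate_ct,
)
from .tables import CtTable, ExpressionTable, RemovedGene

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything a run needs except the seed."""

    design: StudyDesign = DEFAULT_DESIGN
    mix: dict[str, int] | None = None
    archetypes: list[GeneArchetype] | None = None
    array_effect_sd: float = 0.0
    input_path: str | None = None  # read a Ct TSV instead of simulating
    missing_policy: preprocess.MissingPolicy = field(
        default_factory=preprocess.MissingPolicy
    )
    overrides_path: str | None = None
    exclude_genes: tuple[str, ...] = ("BAT01",)  # QC exclusions by name
    schemes: tuple[NormalizationScheme, ...] = (
        NormalizationScheme(mode="none", name="none"),
        NormalizationScheme(mode="single", reference_genes=("STB01",), name="stable_ref"),
        NormalizationScheme(mode="single", reference_genes=("DRF01",), name="drift_ref"),
    )
    fc_threshold: float = diffexpr.DEFAULT_FC_THRESHOLD
    alpha: float = diffexpr.DEFAULT_ALPHA
    p_floor: float = stability.DEFAULT_P_FLOOR
    m_cutoff: float = stability.DEFAULT_M_CUTOFF
    missing_tolerance: int = stability.DEFAULT_MISSING_TOLERANCE
    welch: bool = False
    focal_gene: str | None = "NUL01"

    def gene_panel(self) -> list[GeneArchetype]:
        if self.archetypes is not None:
            return self.archetypes
        return default_archetypes(self.mix, self.design)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "design" in raw:
            kwargs["design"] = StudyDesign(
                time_points_h=tuple(raw["design"]["time_points_h"]),
                replicates_per_point=tuple(raw["design"]["replicates_per_point"]),
            )
        sim = raw.get("simulate", {})
        if "mix" in sim:
            kwargs["mix"] = {str(k): int(v) for k, v in sim["mix"].items()}
        if "array_effect_sd" in sim:
            kwargs["array_effect_sd"] = float(sim["array_effect_sd"])
        if "input_path" in raw:
            kwargs["input_path"] = raw["input_path"]
        pre = raw.get("preprocess", {})
        kwargs["missing_policy"] = preprocess.MissingPolicy(
            max_unexplained_missing=int(pre.get("max_unexplained_missing", 2)),
            biological_edge_rule=bool(pre.get("biological_edge_rule", True)),
        )
        if "overrides_path" in pre:
            kwargs["overrides_path"] = pre["overrides_path"]
        if "exclude_genes" in raw:
            kwargs["exclude_genes"] = tuple(raw["exclude_genes"])
        if "schemes" in raw:
            kwargs["schemes"] = tuple(
                NormalizationScheme(
                    mode=s["mode"],
                    reference_genes=tuple(s.get("references", ())),
                    literal_ct_geomean=bool(s.get("literal_ct_geomean", False)),
                    name=s.get("name"),
                )
                for s in raw["schemes"]
            )
        thr = raw.get("thresholds", {})
        for yaml_key, attr in [
            ("fc", "fc_threshold"),
            ("alpha", "alpha"),
            ("p_floor", "p_floor"),
            ("m_cutoff", "m_cutoff"),
        ]:
            if yaml_key in thr:
                kwargs[attr] = float(thr[yaml_key])
        if "missing_tolerance" in thr:
            kwargs["missing_tolerance"] = int(thr["missing_tolerance"])
        if "welch" in thr:
            kwargs["welch"] = bool(thr["welch"])
        if "focal_gene" in raw:
            kwargs["focal_gene"] = raw["focal_gene"]
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# cross-scheme comparison
# ---------------------------------------------------------------------------


@dataclass
class SchemeComparison:
    """Regulated-gene sets per scheme plus exact Venn-region cardinalities."""

    schemes: tuple[str, ...]
    regulated: dict[str, set[str]]
    regions: dict[tuple[str, ...], set[str]]  # key = schemes containing the region

    @property
    def unique(self) -> dict[str, set[str]]:
        """Genes regulated under exactly one scheme — the artifact candidates."""
        return {s: set(self.regions.get((s,), set())) for s in self.schemes}

    def region_counts(self) -> dict[str, int]:
        return {"+".join(k): len(v) for k, v in sorted(self.regions.items())}

    def to_dict(self) -> dict:
        return {
            "schemes": list(self.schemes),
            "regulated_counts": {s: len(g) for s, g in self.regulated.items()},
            "regulated": {s: sorted(g) for s, g in self.regulated.items()},
            "venn_regions": {
                "+".join(k): sorted(v) for k, v in sorted(self.regions.items())
            },
            "unique": {s: sorted(g) for s, g in self.unique.items()},
        }


def compare_schemes(results_by_scheme: dict[str, pd.DataFrame]) -> SchemeComparison:
    """Exact set algebra over per-scheme regulated calls.

    All schemes must share one retained-gene universe.  Regions are keyed
    by the subset of schemes whose regulated sets contain them, so the
    disjoint region cardinalities sum to the union's cardinality.
    """
    labels = tuple(results_by_scheme)
    if len(labels) < 2:
        raise ValueError("need at least two schemes to compare")
    universes = [tuple(df.index) for df in results_by_scheme.values()]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("schemes were tested on different gene universes")

    regulated = {
        s: set(df.index[df["regulated"].astype(bool)])
        for s, df in results_by_scheme.items()
    }
    union = set().union(*regulated.values())
    regions: dict[tuple[str, ...], set[str]] = {}
    for gene in union:
        key = tuple(s for s in labels if gene in regulated[s])
        regions.setdefault(key, set()).add(gene)
    return SchemeComparison(schemes=labels, regulated=regulated, regions=regions)


@dataclass
class FocalGeneReport:
    """One gene's fold-change trajectory and calls under every scheme."""

    gene: str
    trajectories: pd.DataFrame  # schemes x time points, fold change
    anova_p: dict[str, float]
    ttest_p_at_max: dict[str, float]
    max_fc_time_h: dict[str, float]
    direction: dict[str, str]  # up / down / none per scheme
    sign_discordant: bool

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "fold_change_by_time": {
                s: {f"{t:g}": float(v) for t, v in row.items()}
                for s, row in self.trajectories.iterrows()
            },
            "anova_p": self.anova_p,
            "ttest_p_at_max": self.ttest_p_at_max,
            "max_fc_time_h": self.max_fc_time_h,
            "direction": self.direction,
            "sign_discordant": self.sign_discordant,
        }


def focal_gene_trajectories(
    results_by_scheme: dict[str, pd.DataFrame],
    gene: str,
    fc_threshold: float = diffexpr.DEFAULT_FC_THRESHOLD,
    alpha: float = diffexpr.DEFAULT_ALPHA,
) -> FocalGeneReport:
    """Align one gene's kinetics across schemes and flag sign discordance.

    Per scheme the gene's *direction* is ``up``/``down`` when that scheme
    calls it regulated (max fold change >= threshold, BH p < alpha) at its
    maximal-change point, else ``none``.  The report is flagged
    sign-discordant when the schemes disagree — at least one scheme sees a
    material change and the directions are not all identical (covers both
    up-vs-down flips and regulated-vs-flat disagreement).
    """
    for s, df in results_by_scheme.items():
        if gene not in df.index:
            raise KeyError(f"gene {gene!r} missing under scheme {s!r}")

    fc_cols = [c for c in next(iter(results_by_scheme.values())).columns if c.startswith("fc_t")]
    times = [float(c[4:-1]) for c in fc_cols]
    rows, anova_p, ttest_p, max_t, direction = {}, {}, {}, {}, {}
    for s, df in results_by_scheme.items():
        r = df.loc[gene]
        rows[s] = pd.Series([r[c] for c in fc_cols], index=times)
        anova_p[s] = float(r["anova_p"])
        ttest_p[s] = float(r["ttest_p_at_max"])
        max_t[s] = float(r["max_fc_time_h"])
        if bool(r["regulated"]):
            fc_at_max = rows[s][max_t[s]]
            direction[s] = DIRECTION_UP if fc_at_max > 1 else DIRECTION_DOWN
        else:
            direction[s] = DIRECTION_NONE
    dirs = set(direction.values())
    discordant = len(dirs) > 1 and dirs != {DIRECTION_NONE}
    return FocalGeneReport(
        gene=gene,
        trajectories=pd.DataFrame(rows).T,
        anova_p=anova_p,
        ttest_p_at_max=ttest_p,
        max_fc_time_h=max_t,
        direction=direction,
        sign_discordant=discordant,
    )


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """Everything one run produced."""

    ct_raw: CtTable
    truth: SimulationTruth | None
    expression: ExpressionTable  # non-normalized
    removed: list[RemovedGene]
    qc_correlations: pd.Series
    results_by_scheme: dict[str, pd.DataFrame]
    screen: pd.DataFrame
    genorm: pd.DataFrame | None
    m_passing: list[str]
    comparison: SchemeComparison | None
    focal: FocalGeneReport | None
    overall_mean: pd.Series
    log: list[str]


def run_all(
    config: PipelineConfig, seed: int, out_dir: str | Path | None = None
) -> ReportBundle:
    """Run the complete analysis; optionally write the report bundle.

    Deterministic given (config, seed): two invocations produce
    byte-identical output files.
    """
    log: list[str] = []

    # --- input -----------------------------------------------------------
    truth = None
    if config.input_path:
        ct_raw = CtTable.from_tsv(config.input_path)
        log.append(f"loaded Ct table from {config.input_path}")
    else:
        ct_raw, truth = simulate_ct(
            config.design, config.gene_panel(), config.array_effect_sd, seed
        )
        log.append(f"simulated {len(ct_raw.gene_ids)} genes, seed {seed}")

    # --- QC: correlation of each gene's Ct with the array mean ----------
    qc = {}
    for g in ct_raw.gene_ids:
        try:
            qc[g] = preprocess.qc_reference_vs_array_mean(ct_raw, g)
        except ValueError:
            qc[g] = np.nan
    qc_correlations = pd.Series(qc, name="qc_r")

    excluded = [g for g in config.exclude_genes if g in ct_raw.values.index]
    removed: list[RemovedGene] = [
        RemovedGene(gene=g, reason="excluded by QC configuration") for g in excluded
    ]
    for g in excluded:
        log.append(f"QC exclusion: {g} (r vs array mean = {qc_correlations[g]:.3f})")
    keep = [g for g in ct_raw.gene_ids if g not in set(excluded)]
    ct_qc = CtTable(ct_raw.values.loc[keep].copy(), ct_raw.sample_time_h.copy())

    # --- pre-analytic pipeline ------------------------------------------
    overrides = (
        preprocess.read_overrides(config.overrides_path)
        if config.overrides_path
        else None
    )
    complete, prov, filtered = preprocess.clean_ct(
        ct_qc, config.missing_policy, overrides
    )
    removed.extend(filtered)
    for r in filtered:
        log.append(f"filtered: {r.gene} ({r.reason})")
    n_imputed = int((prov != "measured").to_numpy().sum())
    log.append(
        f"retained {len(complete.gene_ids)} genes; imputed/assigned {n_imputed} cells"
    )
    expression = preprocess.transform(complete, prov, removed)

    # --- per-scheme testing ---------------------------------------------
    results_by_scheme: dict[str, pd.DataFrame] = {}
    for scheme in config.schemes:
        table_s = normalize(expression, scheme)
        results_by_scheme[scheme.name] = diffexpr.test_table(
            table_s, config.fc_threshold, config.alpha, config.welch
        )
        n_reg = int(results_by_scheme[scheme.name]["regulated"].sum())
        log.append(f"scheme {scheme.name}: {n_reg} regulated genes")

    # --- stability screening (non-normalized results) -------------------
    none_schemes = [s for s in config.schemes if s.mode == "none"]
    base_name = none_schemes[0].name if none_schemes else config.schemes[0].name
    if not none_schemes:
        log.append(
            f"warning: no mode-none scheme configured; screening on {base_name}"
        )
    screen = stability.candidate_screen(
        expression, results_by_scheme[base_name], config.p_floor
    )
    genorm = None
    m_passing: list[str] = []
    if len(screen) >= 2:
        genorm = stability.genorm_rank(
            expression, list(screen.index), config.missing_tolerance
        )
        m_passing = stability.m_cutoff_filter(genorm, config.m_cutoff)
        log.append(
            f"screen: {len(screen)} candidates, {len(m_passing)} with M < "
            f"{config.m_cutoff:g}"
        )

    # --- cross-scheme comparison ----------------------------------------
    comparison = (
        compare_schemes(results_by_scheme) if len(results_by_scheme) >= 2 else None
    )
    focal = None
    if config.focal_gene and all(
        config.focal_gene in df.index for df in results_by_scheme.values()
    ):
        focal = focal_gene_trajectories(
            results_by_scheme, config.focal_gene, config.fc_threshold, config.alpha
        )

    bundle = ReportBundle(
        ct_raw=ct_raw,
        truth=truth,
        expression=expression,
        removed=removed,
        qc_correlations=qc_correlations,
        results_by_scheme=results_by_scheme,
        screen=screen,
        genorm=genorm,
        m_passing=m_passing,
        comparison=comparison,
        focal=focal,
        overall_mean=diffexpr.overall_mean_by_time(expression),
        log=log,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _fmt_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write all per-stage TSVs, the comparison JSON and a summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle.ct_raw.to_tsv(out / "ct_raw.tsv")
    if bundle.truth is not None:
        bundle.truth.to_json(out / "simulation_truth.json")
    bundle.expression.to_tsv(out / "expression.tsv")
    bundle.expression.provenance.rename_axis("gene").to_csv(
        out / "provenance.tsv", sep="\t"
    )
    pd.DataFrame(
        [(r.gene, r.reason) for r in bundle.removed], columns=["gene", "reason"]
    ).to_csv(out / "removed_genes.tsv", sep="\t", index=False)
    _fmt_df(bundle.qc_correlations.rename_axis("gene").to_frame(), out / "qc.tsv")
    for name, df in bundle.results_by_scheme.items():
        _fmt_df(df, out / f"results_{name.replace(':', '_')}.tsv")
    _fmt_df(bundle.screen, out / "stability_screen.tsv")
    if bundle.genorm is not None:
        _fmt_df(bundle.genorm, out / "genorm.tsv")
    _fmt_df(
        bundle.overall_mean.rename_axis("time_h").to_frame("mean_x"),
        out / "overall_mean_by_time.tsv",
    )

    report: dict = {"m_passing": bundle.m_passing}
    if bundle.comparison is not None:
        report["comparison"] = bundle.comparison.to_dict()
    if bundle.focal is not None:
        report["focal_gene"] = bundle.focal.to_dict()
    with open(out / "comparison.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    lines = ["# Run summary", ""]
    lines += [f"- {entry}" for entry in bundle.log]
    if bundle.comparison is not None:
        lines += ["", "## Regulated genes per scheme", ""]
        for s, genes in bundle.comparison.regulated.items():
            lines.append(f"- {s}: {len(genes)}")
        lines += ["", "## Venn regions", ""]
        for k, n in bundle.comparison.region_counts().items():
            lines.append(f"- {k}: {n}")
    if bundle.focal is not None:
        lines += [
            "",
            f"## Focal gene {bundle.focal.gene}",
            "",
            f"- directions: {bundle.focal.direction}",
            f"- sign discordant: {bundle.focal.sign_discordant}",
        ]
    (out / "summary.md").write_text("\n".join(lines) + "\n")
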