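"""End-to-end orchestration of the cohort analysis.

One configured run reproduces the shape of the full analysis: generate (or
ingest) a cohort, complete-case filter, classical statistics, six role x
time mixed-graphical-model networks with predictability, centrality and its
bootstrap, walk-trap clusters, a shared average layout, node-size scaling
against the first assessment, and a machine-readable report.  All stage
seeds derive deterministically from one global seed, so a single integer
reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .classical_stats import (
    DegenerateDataError,
    PowerQuery,
    ReferenceNorm,
    compare_to_reference,
    ks_normality,
    one_way_anova,
    power_min_r,
    rm_anova,
    tukey_hsd,
)
from .data_model import (
    ROLES,
    SUBSCALES,
    TIME_POINTS,
    Stratum,
    complete_case_filter,
    export_network,
    read_cohort,
    stratify,
    write_cohort,
)
from .graph_structure import average_layout, node_size_scale, walktrap_cluster
from .mgm import MGMConfig, estimate_stratum_network, predictability
from .network_metrics import bootstrap_centrality, centrality_table
from .synthetic import SyntheticSpec, generate_cohort

logger = logging.getLogger("dyadnet")

#: Published Italian control norm for the Anxiety subscale (mean +- SD).
ANXIETY_CONTROL_NORM = ReferenceNorm("Anxiety", control_mean=4.25, control_sd=3.53)

STAGES = ("ingest", "filter", "stats", "networks", "metrics", "structure", "report")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_dyads: int = Field(23, gt=0)
    n_father_dropouts: int = Field(7, ge=0)
    dyad_rho: float = Field(0.3, ge=0, lt=1)
    time_rho: float = Field(0.5, ge=0, lt=1)


class MGMSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    folds: int = Field(10, gt=1)
    n_lambdas: int = Field(50, gt=1)
    lambda_min_ratio: float = Field(1e-3, gt=0, lt=1)
    rule: Literal["and", "or"] = "and"
    threshold_scale: float = Field(1.0, ge=0)
    min_n: int = Field(10, gt=0)


class BootstrapSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    B: int = Field(200, ge=1)


class LayoutSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    iterations: int = Field(500, gt=0)


class StructureSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    walk_length: int = Field(4, ge=1)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    mode: Literal["synthetic", "csv"] = "synthetic"
    input_csv: Optional[str] = None
    outdir: str = "dyadnet_run"
    seed: int = 0
    synthetic: SyntheticConfig = SyntheticConfig()
    mgm: MGMSection = MGMSection()
    bootstrap: BootstrapSection = BootstrapSection()
    layout: LayoutSection = LayoutSection()
    structure: StructureSection = StructureSection()

    def model_post_init(self, _ctx) -> None:
        if self.mode == "csv" and not self.input_csv:
            raise ValueError("mode 'csv' requires input_csv")


def validate_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return RunConfig(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([global_seed, stage_index])."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2**31))


def _synthetic_spec(config: RunConfig) -> SyntheticSpec:
    n = config.synthetic.n_dyads
    k = config.synthetic.n_father_dropouts
    return SyntheticSpec(
        n_dyads=n,
        dyad_rho=config.synthetic.dyad_rho,
        time_rho=config.synthetic.time_rho,
        dropout=frozenset(range(n - k, n)),
        seed=stage_seed(config.seed, "ingest"),
    )


def _classical_stats(strata: list[Stratum], n_complete: int) -> dict:
    """The questionnaire-level statistical arm, per subscale.

    Normality screening per stratum, repeated-measures ANOVA over the three
    assessments (all complete-case parents as subjects) with Tukey post
    hocs, mother-father one-way ANOVAs per time point, the control-norm
    classification of the T1 Anxiety mean, and the a priori power analysis
    at the complete-dyad count.
    """
    by_role_time = {(s.parent_role, s.time_point): s for s in strata}
    out: dict = {"normality": [], "rm_anova": [], "tukey": [], "role_anova": []}
    for sub_i, sub in enumerate(SUBSCALES):
        # subjects x time matrix stacking mothers and fathers
        cols = []
        for t in TIME_POINTS:
            col = np.concatenate(
                [by_role_time[(role, t)].data[:, sub_i] for role in ROLES]
            )
            cols.append(col)
        mat = np.column_stack(cols)
        for (role, t), s in by_role_time.items():
            x = s.data[:, sub_i]
            try:
                r = ks_normality(x)
                out["normality"].append(
                    {"subscale": sub, "role": role, "time": t,
                     "D": r.statistic, "p": r.p_value}
                )
            except (DegenerateDataError, ValueError):
                out["normality"].append(
                    {"subscale": sub, "role": role, "time": t, "D": None, "p": None}
                )
        if mat.shape[0] >= 2:
            try:
                r = rm_anova(mat)
                out["rm_anova"].append(
                    {"subscale": sub, "F": r.statistic, "df1": r.df[0],
                     "df2": r.df[1], "p": r.p_value}
                )
                n_subj, t_lev = mat.shape
                ms_err = _rm_ms_error(mat)
                for tr in tukey_hsd(
                    mat.mean(axis=0), ms_err, n_subj, (t_lev - 1) * (n_subj - 1),
                    labels=list(TIME_POINTS),
                ):
                    out["tukey"].append(
                        {"subscale": sub, "pair": tr.label.split(":")[1],
                         "q": tr.statistic, "p": tr.p_value}
                    )
            except DegenerateDataError:
                out["rm_anova"].append(
                    {"subscale": sub, "F": None, "df1": None, "df2": None, "p": None}
                )
        for t in TIME_POINTS:
            groups = [by_role_time[(role, t)].data[:, sub_i] for role in ROLES]
            if all(len(g) >= 2 for g in groups):
                try:
                    r = one_way_anova(groups)
                    out["role_anova"].append(
                        {"subscale": sub, "time": t, "F": r.statistic, "p": r.p_value}
                    )
                except DegenerateDataError:
                    out["role_anova"].append(
                        {"subscale": sub, "time": t, "F": None, "p": None}
                    )
    anx_i = SUBSCALES.index("Anxiety")
    t1_anx = np.concatenate(
        [by_role_time[(role, "t1")].data[:, anx_i] for role in ROLES]
    )
    out["anxiety_t1_vs_norm"] = {
        "sample_mean": float(t1_anx.mean()) if t1_anx.size else None,
        "control_mean": ANXIETY_CONTROL_NORM.control_mean,
        "control_sd": ANXIETY_CONTROL_NORM.control_sd,
        "band": compare_to_reference(float(t1_anx.mean()), ANXIETY_CONTROL_NORM).value
        if t1_anx.size
        else None,
    }
    if n_complete >= 4:
        out["power_min_r"] = {
            "n": n_complete,
            "alpha": 0.05,
            "power": 0.8,
            "r": power_min_r(PowerQuery(n=n_complete)),
        }
    return out


def _rm_ms_error(mat: np.ndarray) -> float:
    n, t = mat.shape
    grand = mat.mean()
    ss_time = n * np.sum((mat.mean(axis=0) - grand) ** 2)
    ss_subj = t * np.sum((mat.mean(axis=1) - grand) ** 2)
    ss_err = np.sum((mat - grand) ** 2) - ss_time - ss_subj
    return float(ss_err / ((t - 1) * (n - 1)))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts under ``config.outdir``.

    Returns the run report (also written as report.json / report.md).  An
    empty complete-case cohort yields a report with status
    ``"empty_cohort"`` and no network artifacts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "status": "ok",
    }
    t_start = time.time()

    def _stage(name):
        logger.info("stage %s", name)
        return time.time()

    try:
        t0 = _stage("ingest")
        if config.mode == "synthetic":
            spec = _synthetic_spec(config)
            cohort, truth = generate_cohort(spec)
            write_cohort(cohort, outdir / "cohort.csv")
            truth_json = {
                "community_partition": truth.community_partition,
                "adjacency_by_stratum": {
                    f"{role}_{t}": truth.adjacency_by_stratum[(role, t)].tolist()
                    for role in ROLES
                    for t in TIME_POINTS
                },
            }
            (outdir / "truth.json").write_text(
                json.dumps(truth_json, indent=2, sort_keys=True), encoding="utf-8"
            )
        else:
            cohort = read_cohort(config.input_csv)
        logger.info("ingest done in %.1fs", time.time() - t0)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageFailure("ingest", e) from e

    try:
        t0 = _stage("filter")
        complete, filt = complete_case_filter(cohort)
        report["cohort"] = {
            "n_enrolled": filt.n_enrolled,
            "n_complete": filt.n_retained,
            "n_dropped": filt.n_dropped,
            "dropped_ids": filt.dropped_ids,
        }
        logger.info("filter done in %.1fs", time.time() - t0)
    except Exception as e:
        raise StageFailure("filter", e) from e

    if filt.n_retained == 0:
        report["status"] = "empty_cohort"
        report["networks"] = []
        _write_report(report, outdir)
        return report

    try:
        t0 = _stage("stats")
        strata = stratify(complete)
        report["strata"] = [
            {"role": s.parent_role, "time": s.time_point, "n": s.n} for s in strata
        ]
        report["classical_stats"] = _classical_stats(strata, filt.n_retained)
        pd.DataFrame(report["classical_stats"]["rm_anova"]).to_csv(
            outdir / "stats_rm_anova.csv", index=False
        )
        pd.DataFrame(report["classical_stats"]["tukey"]).to_csv(
            outdir / "stats_tukey.csv", index=False
        )
        pd.DataFrame(report["classical_stats"]["role_anova"]).to_csv(
            outdir / "stats_role_anova.csv", index=False
        )
        logger.info("stats done in %.1fs", time.time() - t0)
    except Exception as e:
        raise StageFailure("stats", e) from e

    mgm_config = MGMConfig(
        folds=config.mgm.folds,
        n_lambdas=config.mgm.n_lambdas,
        lambda_min_ratio=config.mgm.lambda_min_ratio,
        rule=config.mgm.rule,
        threshold_scale=config.mgm.threshold_scale,
        min_n=config.mgm.min_n,
        seed=stage_seed(config.seed, "networks"),
    )
    nets, fits_by_stratum, pred_rows = [], {}, []
    try:
        t0 = _stage("networks")
        for s in strata:
            net, fits = estimate_stratum_network(s, mgm_config)
            nets.append(net)
            fits_by_stratum[s.label] = fits
            pred = predictability(fits, s)
            for node, row in pred.table.iterrows():
                pred_rows.append({"stratum": s.label, "node": node, **row.to_dict()})
        pd.DataFrame(pred_rows).to_csv(outdir / "predictability.csv", index=False)
        logger.info("networks done in %.1fs", time.time() - t0)
    except Exception as e:
        raise StageFailure("networks", e) from e

    try:
        t0 = _stage("metrics")
        metric_rows = []
        boot_seed = stage_seed(config.seed, "metrics")
        for s, net in zip(strata, nets):
            ct = centrality_table(net)
            if config.bootstrap.enabled:
                summ = bootstrap_centrality(
                    s, mgm_config, B=config.bootstrap.B,
                    seed=int(np.random.SeedSequence(
                        [boot_seed, ROLES.index(s.parent_role),
                         TIME_POINTS.index(s.time_point)]
                    ).generate_state(1)[0] % (2**31)),
                )
                net.edge_support = summ.edge_support
                for (metric, node), row in summ.table.iterrows():
                    metric_rows.append(
                        {"stratum": s.label, "metric": metric, "node": node,
                         **row.to_dict()}
                    )
            else:
                for node in ct.index:
                    for metric in ("strength", "betweenness"):
                        metric_rows.append(
                            {"stratum": s.label, "metric": metric, "node": node,
                             "point": float(ct.loc[node, metric]),
                             "boot_mean": None, "ci_lo": None, "ci_hi": None,
                             "rank_stability": None}
                        )
        pd.DataFrame(metric_rows).to_csv(outdir / "centrality.csv", index=False)
        report["centrality_file"] = "centrality.csv"
        logger.info("metrics done in %.1fs", time.time() - t0)
    except Exception as e:
        raise StageFailure("metrics", e) from e

    try:
        t0 = _stage("structure")
        layout = average_layout(
            nets,
            seed=stage_seed(config.seed, "structure"),
            iterations=config.layout.iterations,
        )
        layout_rows = [
            {"node": node, "x": xy[0], "y": xy[1]} for node, xy in layout.coords.items()
        ]
        pd.DataFrame(layout_rows).to_csv(outdir / "layout.csv", index=False)
        cluster_rows, net_summaries = [], []
        by_role_time = {(s.parent_role, s.time_point): s for s in strata}
        for s, net in zip(strata, nets):
            clusters = walktrap_cluster(net, t=config.structure.walk_length)
            for node, comm in clusters.membership.items():
                cluster_rows.append(
                    {"stratum": s.label, "node": node, "community": comm}
                )
            t1 = by_role_time[(s.parent_role, "t1")]
            means_t1 = {
                SUBSCALES[i]: float(t1.data[:, i].mean()) for i in range(8)
            }
            means_tk = {
                SUBSCALES[i]: float(s.data[:, i].mean()) for i in range(8)
            }
            try:
                sizes = node_size_scale(means_tk, means_t1).sizes
            except ValueError:
                sizes = {sub: 1.0 for sub in SUBSCALES}
            export_network(net, outdir / f"network_{s.label}")
            net_summaries.append(
                {
                    "stratum": s.label,
                    "n": net.n,
                    "n_edges": len(net.edge_list()),
                    "n_sign_conflicts": len(net.sign_conflicts),
                    "n_communities": clusters.n_communities,
                    "modularity": clusters.modularity_by_level[clusters.chosen_level],
                    "node_sizes": {k: round(v, 6) for k, v in sizes.items()},
                }
            )
        pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.csv", index=False)
        report["networks"] = net_summaries
        logger.info("structure done in %.1fs", time.time() - t0)
    except Exception as e:
        raise StageFailure("structure", e) from e

    logger.info("pipeline done in %.1fs", time.time() - t_start)
    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (outdir / "report.md").write_text(render_report_md(report), encoding="utf-8")


def render_report_md(report: dict) -> str:
    """Human-readable rendering of the run report (same numbers as the JSON)."""
    lines = [f"# Cohort network analysis run (dyadnet {report['version']})", ""]
    lines.append(f"Status: **{report['status']}**")
    c = report.get("cohort")
    if c:
        lines += [
            "",
            "## Cohort",
            f"- enrolled dyads: {c['n_enrolled']}",
            f"- complete-case dyads: {c['n_complete']}",
            f"- dropped dyads: {c['n_dropped']}",
        ]
    cs = report.get("classical_stats", {})
    if "power_min_r" in cs:
        p = cs["power_min_r"]
        lines += [
            "",
            "## Power analysis",
            f"- minimal detectable correlation at n={p['n']}, alpha={p['alpha']}, "
            f"power={p['power']}: r = {p['r']:.3f}",
        ]
    if cs.get("anxiety_t1_vs_norm", {}).get("band"):
        a = cs["anxiety_t1_vs_norm"]
        lines += [
            "",
            "## Anxiety at first assessment vs control norm",
            f"- sample mean {a['sample_mean']:.2f} vs control "
            f"{a['control_mean']} +- {a['control_sd']}: **{a['band']}**",
        ]
    nets = report.get("networks") or []
    if nets:
        lines += ["", "## Networks", "",
                  "| stratum | n | edges | communities | modularity |",
                  "|---|---|---|---|---|"]
        for s in nets:
            lines.append(
                f"| {s['stratum']} | {s['n']} | {s['n_edges']} | "
                f"{s['n_communities']} | {s['modularity']:.3f} |"
            )
    lines.append("")
    return "\n".join(lines)
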