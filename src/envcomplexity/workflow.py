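"""End-to-end orchestration: config, staged runs, manifests, reports.

A run executes an ordered subset of stages — design → simulate → synth →
preprocess → epistasis → classify → cluster → report — writing each
stage's tables into the output directory and recording every artifact
(with a content hash) in ``manifest.json``.  Per-stage random seeds are
derived deterministically from the single root seed, so a rerun with the
same config reproduces every file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import ensemble as ens
from . import env_design, metrics, pipeline, synthetic
from .crm import CRMParams

__all__ = ["RunConfig", "run_workflow", "summary_report", "load_config"]

logger = logging.getLogger("envcomplexity")

STAGES = (
    "design",
    "simulate",
    "synth",
    "preprocess",
    "epistasis",
    "classify",
    "cluster",
    "report",
)

_DEPENDENCIES = {
    "simulate": ["design"],
    "synth": ["simulate"],
    "preprocess": ["synth"],
    "epistasis": ["design", "preprocess"],
    "classify": ["simulate"],
    "cluster": ["synth"],
    "report": [],
}


class SchemeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "hierarchical"  # or "full_subset"
    n_resources: int = 32
    total_carbon: float = 1.5
    rank_scores: list[float] | None = None
    all_bipartitions: bool = False


class CRMConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    g: float = 1.0
    w: float = 1e8
    m: float = 0.1
    l: float = 0.8
    k: float = 1e4
    dt: float = 0.01
    passage_interval: float = 48.0
    n_passages: int = 6
    dilution_factor: float = 1.0 / 30.0
    N0: float = 6e6
    R_total0: float = 1.5

    def to_params(self) -> CRMParams:
        return CRMParams(**self.model_dump())


class EnsembleSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    S: int = 13
    theta_mode: str = "uniform"
    theta_value: float = 0.5
    theta_values: list[float] | None = None
    theta_low: float = 0.15
    theta_high: float = 0.95
    n_replicates: int = 50
    byproduct_counts: list[int] = Field(default_factory=lambda: list(range(1, 11)))
    uptake_scale: float = 1e-2
    transition_probability: float = 0.25
    survival_threshold: float = 1e-3


class PreprocessSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    growth_threshold: float = 0.05
    alpha: float = 0.05
    mad_cutoff: float = 3.5
    survival_threshold: float = 1e-3


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    replicate_noise_sd: float = 0.01
    read_depth: int = 10_000
    n_replicates: int = 3
    blank_od: float = 0.04
    planted_EY: dict[str, float] = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Validated configuration for a workflow run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "envc_output"
    log_level: str = "INFO"
    scheme: SchemeConfig = Field(default_factory=SchemeConfig)
    crm: CRMConfig = Field(default_factory=CRMConfig)
    ensemble: EnsembleSection = Field(default_factory=EnsembleSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    synth: SynthSection = Field(default_factory=SynthSection)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _stage_seed(root_seed: int, stage: str) -> int:
    seq = np.random.SeedSequence(root_seed, spawn_key=(STAGES.index(stage),))
    return int(seq.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_scheme(cfg: SchemeConfig) -> env_design.CombinationTree:
    n = cfg.n_resources
    scores = cfg.rank_scores or list(range(1, n + 1))
    if len(scores) != n:
        raise ValueError("rank_scores length must equal n_resources")
    resources = [
        env_design.Resource(i, f"cs{i + 1}", float(scores[i])) for i in range(n)
    ]
    if cfg.kind == "hierarchical":
        return env_design.build_hierarchical_scheme(resources, cfg.total_carbon)
    if cfg.kind == "full_subset":
        return env_design.build_full_subset_scheme(
            resources, cfg.total_carbon, all_bipartitions=cfg.all_bipartitions
        )
    raise ValueError(f"unknown scheme kind {cfg.kind!r}")


def run_workflow(
    config: RunConfig, stages: Sequence[str] | None = None
) -> dict:
    """Execute the requested stages and return the artifact manifest."""
    stages = list(stages or STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        for dep in _DEPENDENCIES.get(s, []):
            if dep not in stages:
                raise ValueError(f"stage {s!r} requires stage {dep!r} to run first")
    stages.sort(key=STAGES.index)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    artifacts: dict[str, str] = {}
    ctx: dict = {}

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        artifacts[name] = _sha256(path)

    for stage in stages:
        logger.info("stage %s", stage)
        if stage == "design":
            tree = _build_scheme(config.scheme)
            ctx["tree"] = tree
            env_design.write_scheme(
                tree, outdir / "scheme.csv", outdir / "scheme_edges.json"
            )
            artifacts["scheme.csv"] = _sha256(outdir / "scheme.csv")
            artifacts["scheme_edges.json"] = _sha256(outdir / "scheme_edges.json")

        elif stage == "simulate":
            e = config.ensemble
            theta = ens.ThetaSpec(
                mode=e.theta_mode,
                value=e.theta_value,
                values=None if e.theta_values is None else np.array(e.theta_values),
                low=e.theta_low,
                high=e.theta_high,
            )
            cfg = ens.EnsembleConfig(
                S=e.S,
                scheme=ctx["tree"],
                theta=theta,
                n_replicates=e.n_replicates,
                byproduct_counts=e.byproduct_counts,
                uptake_scale=e.uptake_scale,
                transition_probability=e.transition_probability,
                survival_threshold=e.survival_threshold,
                seed=_stage_seed(config.seed, "simulate"),
            )
            result = ens.run_ensemble(cfg, config.crm.to_params())
            ctx["ensemble"] = result
            save_df(result.observations, "ensemble_observations.csv")
            save_df(result.rho, "ensemble_rho.csv")
            save_df(ens.scaling_summary(result), "scaling_summary.csv")

        elif stage == "synth":
            res = ctx["ensemble"]
            tree = ctx["tree"]
            # use replicate 0 / first byproduct count as the "true" experiment
            obs = res.observations
            sel = (obs["replicate"] == 0) & (
                obs["byproduct_count"] == obs["byproduct_count"].min()
            )
            truth = dict(
                zip(obs.loc[sel, "environment_id"], obs.loc[sel, "yield"])
            )
            # express simulated biomass yields on the OD scale for plates
            truth_od = {
                k: pipeline.cfu_od_convert(v, "cfu_to_od") for k, v in truth.items()
            }
            spec = synthetic.SyntheticSpec(
                n_replicates=config.synth.n_replicates,
                replicate_noise_sd=config.synth.replicate_noise_sd,
                planted_EY=config.synth.planted_EY,
                blank_od=config.synth.blank_od,
                read_depth=config.synth.read_depth,
                seed=_stage_seed(config.seed, "synth"),
            )
            plate, truths = synthetic.synth_community_plates(spec, truth_od)
            pipeline.write_plate_table(plate, outdir / "plates.csv")
            artifacts["plates.csv"] = _sha256(outdir / "plates.csv")
            mask = sel
            rows = np.flatnonzero(mask.to_numpy())
            endpoints = {
                obs.iloc[i]["environment_id"]: res.abundances[i] for i in rows
            }
            endpoints = {k: v for k, v in endpoints.items() if v.sum() > 0}
            abund = synthetic.synth_abundance_table(
                endpoints,
                read_depth=config.synth.read_depth,
                n_replicates=config.synth.n_replicates,
                rng=_stage_seed(config.seed, "synth") + 1,
            )
            pipeline.write_abundance_table(abund, outdir / "abundances.csv")
            artifacts["abundances.csv"] = _sha256(outdir / "abundances.csv")
            (outdir / "synth_manifest.json").write_text(
                json.dumps(
                    {
                        "seed": _stage_seed(config.seed, "synth"),
                        "truth_od": {k: float(v) for k, v in truths.items()},
                        "planted_EY": dict(config.synth.planted_EY),
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            artifacts["synth_manifest.json"] = _sha256(outdir / "synth_manifest.json")
            ctx["plate"] = plate
            ctx["abundance"] = abund

        elif stage == "preprocess":
            plate = ctx.get("plate") or pipeline.read_plate_table(outdir / "plates.csv")
            yields = pipeline.correct_and_call_growth(
                plate,
                growth_threshold=config.preprocess.growth_threshold,
                alpha=config.preprocess.alpha,
                mad_cutoff=config.preprocess.mad_cutoff,
            )
            ctx["yields"] = yields
            save_df(yields, "yields.csv")
            abund = ctx.get("abundance") or pipeline.read_abundance_table(
                outdir / "abundances.csv"
            )
            mean_comp = pipeline.average_replicates(abund)
            ctx["mean_comp"] = mean_comp
            save_df(mean_comp.reset_index(names="taxon"), "mean_compositions.csv")

        elif stage == "epistasis":
            tree = ctx["tree"]
            yields = ctx["yields"]
            mean_comp = ctx["mean_comp"]
            thr = config.preprocess.survival_threshold
            meas = {}
            for _, row in yields.iterrows():
                eid = row["environment_id"]
                ab = (
                    mean_comp[eid].to_dict() if eid in mean_comp.columns else None
                )
                meas[eid] = metrics.CommunityMeasurement(
                    environment_id=eid,
                    yield_=max(float(row["yield_mean"]), 0.0),
                    abundances=ab,
                    growth_flag=bool(row["growth_flag"]),
                    survival_threshold=thr,
                )
            ctx["measurements"] = meas
            frames = []
            for metric in ("E_Y", "E_S", "E_H"):
                recs = metrics.epistasis_over_tree(tree, meas, metric)
                frames.append(metrics.records_to_frame(recs))
            epi = pd.concat(frames, ignore_index=True)
            ctx["epistasis"] = epi
            save_df(epi, "epistasis.csv")

        elif stage == "classify":
            tree = ctx["tree"]
            res = ctx["ensemble"]
            surv = res.survivor_sets()
            obs = res.observations
            rows = []
            by_key = {}
            for i, (_, row) in enumerate(obs.iterrows()):
                by_key[(row["replicate"], row["byproduct_count"], row["environment_id"])] = i
            for comp, a, b in tree.edge_records():
                for rep in obs["replicate"].unique():
                    for mb in obs["byproduct_count"].unique():
                        key = lambda e: by_key.get((rep, mb, e))
                        ia, ib, ic = key(a), key(b), key(comp)
                        if None in (ia, ib, ic):
                            continue
                        out = metrics.classify_outcome(surv[ia], surv[ib], surv[ic])
                        rows.append(
                            {
                                "replicate": rep,
                                "byproduct_count": mb,
                                "composite_id": comp,
                                "type": out.label,
                            }
                        )
            outcomes = pd.DataFrame(rows)
            ctx["outcomes"] = outcomes
            save_df(outcomes, "outcome_types.csv")

        elif stage == "cluster":
            mean_comp = ctx.get("mean_comp")
            if mean_comp is None:
                abund = pipeline.read_abundance_table(outdir / "abundances.csv")
                mean_comp = pipeline.average_replicates(abund)
            try:
                cl = pipeline.cluster_environments(mean_comp)
            except ValueError as err:
                logger.warning("clustering skipped: %s", err)
            else:
                (outdir / "environments.nwk").write_text(cl.newick + "\n")
                artifacts["environments.nwk"] = _sha256(outdir / "environments.nwk")

        elif stage == "report":
            report = summary_report(ctx)
            (outdir / "report.txt").write_text(report)
            artifacts["report.txt"] = _sha256(outdir / "report.txt")

    manifest = {
        "seed": config.seed,
        "stages": stages,
        "config": config.model_dump(),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def summary_report(ctx: Mapping) -> str:
    """Human-readable summary of epistasis, outcome types, and scaling."""
    lines = ["envcomplexity run summary", "=" * 25, ""]
    epi = ctx.get("epistasis")
    if epi is None or epi.empty:
        lines.append("epistasis: no composites")
    else:
        for metric, grp in epi.groupby("metric"):
            vals = grp["E"].dropna()
            if len(vals) == 0:
                lines.append(f"{metric}: no measured composites")
                continue
            lines.append(
                f"{metric}: mean {vals.mean():+.4f}, sd {vals.std(ddof=1):.4f} "
                f"(n={len(vals)})"
            )
    outcomes = ctx.get("outcomes")
    if outcomes is not None and not outcomes.empty:
        counts = outcomes["type"].value_counts()
        total = counts.sum()
        prev = ", ".join(
            f"Type {t}: {100.0 * counts.get(t, 0) / total:.1f}%"
            for t in ("I", "II", "III", "IV")
        )
        lines.append(f"outcome types ({total} cases): {prev}")
    result = ctx.get("ensemble")
    if result is not None:
        lines.append("")
        lines.append("scaling (mean per complexity level):")
        summary = ens.scaling_summary(result)
        for _, row in summary.iterrows():
            lines.append(
                f"  complexity {int(row['complexity']):2d}: "
                f"yield {row['yield_mean']:.3e}, "
                f"S {row['richness_mean']:.2f}, H {row['shannon_mean']:.2f}"
            )
    return "\n".join(lines) + "\n"
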