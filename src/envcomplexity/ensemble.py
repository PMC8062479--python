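"""Statistical ensembles of random consumer-resource communities.

Every replicate draws a fresh uptake matrix ``C`` and byproduct matrix
``D``, simulates the community through serial passaging in every
environment of a combinatorial scheme, and records endpoint yield,
survivor set, species richness and Shannon entropy.  Two regimes are of
particular interest:

* *uniform theta* ("CRM-A"): every species can use each resource with the
  same probability, giving low niche overlap;
* *sampled / per-species theta* ("CRM-B"): utilization probabilities vary
  across species, mixing generalists and specialists, which raises niche
  overlap and flattens diversity scaling.

Niche overlap is summarized by ``rho = mu^2 / (mu^2 + sigma^2)`` of the
primary-resource uptake entries: 0 when species share no resources, 1 when
their utilization profiles coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .crm import (
    CRMParams,
    generate_byproduct_tensor,
    generate_uptake_matrix,
    simulate_passaged_batch,
)
from .env_design import CombinationTree
from .metrics import shannon_entropy, species_richness

__all__ = [
    "ThetaSpec",
    "EnsembleConfig",
    "EnsembleResult",
    "niche_overlap",
    "run_ensemble",
    "scaling_summary",
    "ensemble_epistasis",
]


def niche_overlap(C: np.ndarray, M_primary: int | None = None) -> float:
    """Community niche overlap ``rho = mu^2 / (mu^2 + sigma^2)``.

    ``mu`` and ``sigma^2`` are the mean and population variance over all
    primary-resource entries of the uptake matrix (byproduct columns are
    excluded when ``M_primary`` is given).  ``rho`` lies in [0, 1]; an
    all-zero matrix returns 0 by convention.  The metric is invariant to
    rescaling ``C`` by a positive constant.
    """
    if hasattr(C, "M_primary") and M_primary is None:
        M_primary = C.M_primary
    C = np.asarray(getattr(C, "C", C), dtype=float)
    entries = C[:, :M_primary].ravel() if M_primary is not None else C.ravel()
    if entries.size == 0:
        raise ValueError("empty uptake matrix")
    mu = entries.mean()
    if mu == 0.0:
        return 0.0
    var = entries.var()  # population variance
    return float(mu * mu / (mu * mu + var))


@dataclass
class ThetaSpec:
    """How per-species utilization probabilities are drawn.

    ``mode`` is one of:

    * ``"uniform"`` — a single ``value`` shared by all species (CRM-A style);
    * ``"per_species"`` — an explicit ``values`` vector (e.g. monoculture-
      derived fractions, CRM-B style);
    * ``"sampled_range"`` — each species' theta drawn uniformly on
      ``(low, high)`` fresh for every replicate (a generalist–specialist
      spread emulating CRM-B when no measured vector is available).
    """

    mode: str = "uniform"
    value: float = 0.5
    values: np.ndarray | None = None
    low: float = 0.15
    high: float = 0.95

    def draw(self, S: int, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "uniform":
            th = np.full(S, self.value)
        elif self.mode == "per_species":
            th = np.asarray(self.values, dtype=float)
            if th.shape != (S,):
                raise ValueError(f"theta vector must have length {S}")
        elif self.mode == "sampled_range":
            th = rng.uniform(self.low, self.high, size=S)
        else:
            raise ValueError(f"unknown theta mode {self.mode!r}")
        if np.any(th < 0) or np.any(th > 1):
            raise ValueError("theta values must lie in [0, 1]")
        return th


@dataclass
class EnsembleConfig:
    S: int = 13
    scheme: CombinationTree | None = None
    theta: ThetaSpec = field(default_factory=ThetaSpec)
    n_replicates: int = 50
    byproduct_counts: Sequence[int] = tuple(range(1, 11))
    uptake_scale: float = 1e-2
    transition_probability: float = 0.25
    survival_threshold: float = 1e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.S < 1:
            raise ValueError("S must be >= 1")


@dataclass
class EnsembleResult:
    """Tidy per-(replicate, byproduct count, environment) observations.

    ``observations`` columns: replicate, byproduct_count, environment_id,
    complexity, yield, richness, shannon.  ``abundances`` holds endpoint
    per-species abundances aligned row-for-row with ``observations``.
    ``rho`` has one niche-overlap value per (replicate, byproduct_count).
    """

    observations: pd.DataFrame
    abundances: np.ndarray
    rho: pd.DataFrame
    survival_threshold: float

    def survivor_sets(self) -> list[frozenset[int]]:
        totals = self.abundances.sum(axis=1, keepdims=True)
        rel = np.divide(
            self.abundances,
            totals,
            out=np.zeros_like(self.abundances),
            where=totals > 0,
        )
        return [
            frozenset(np.flatnonzero(row >= self.survival_threshold))
            for row in rel
        ]


def run_ensemble(config: EnsembleConfig, params: CRMParams | None = None) -> EnsembleResult:
    """Simulate the ensemble over every environment of the scheme.

    For each replicate and each byproduct count, a fresh theta vector,
    uptake matrix and conversion matrix are drawn, and the community is
    passaged in all environments at once.  Identical seeds give
    bit-identical results.
    """
    if config.scheme is None:
        raise ValueError("config.scheme is required")
    params = params or CRMParams()
    tree = config.scheme
    env_ids = sorted(tree.environments)
    envs = [tree.environments[e] for e in env_ids]
    Mp = max(max(int(r) for r in env.resources) for env in envs) + 1
    R0 = np.zeros((len(envs), Mp))
    for j, env in enumerate(envs):
        for rid, conc in env.concentrations.items():
            R0[j, int(rid)] = conc
    complexities = np.array([env.complexity for env in envs])

    root = np.random.SeedSequence(config.seed)
    rows = []
    abund = []
    rho_rows = []
    for rep, rep_seq in enumerate(root.spawn(config.n_replicates)):
        rng = np.random.default_rng(rep_seq)
        theta = config.theta.draw(config.S, rng)
        for Mb in config.byproduct_counts:
            uptake = generate_uptake_matrix(
                config.S, Mp, int(Mb), theta, config.uptake_scale, rng
            )
            byp = generate_byproduct_tensor(
                config.S, Mp, int(Mb), config.transition_probability, rng
            )
            rho_rows.append(
                {
                    "replicate": rep,
                    "byproduct_count": int(Mb),
                    "rho": niche_overlap(uptake.C, Mp),
                }
            )
            N_end, yields = simulate_passaged_batch(R0, uptake, byp, params)
            totals = N_end.sum(axis=1, keepdims=True)
            rel = np.divide(
                N_end, totals, out=np.zeros_like(N_end), where=totals > 0
            )
            for j, eid in enumerate(env_ids):
                rows.append(
                    {
                        "replicate": rep,
                        "byproduct_count": int(Mb),
                        "environment_id": eid,
                        "complexity": int(complexities[j]),
                        "yield": yields[j],
                        "richness": species_richness(
                            rel[j], config.survival_threshold
                        ),
                        "shannon": shannon_entropy(rel[j], normalize=True)
                        if totals[j, 0] > 0
                        else 0.0,
                    }
                )
            abund.append(N_end)
    observations = pd.DataFrame(rows)
    return EnsembleResult(
        observations=observations,
        abundances=np.concatenate(abund, axis=0),
        rho=pd.DataFrame(rho_rows),
        survival_threshold=config.survival_threshold,
    )


def ensemble_epistasis(
    result: EnsembleResult, tree: CombinationTree, metric: str = "E_Y"
) -> pd.DataFrame:
    """Environmental-epistasis values over the scheme, per simulation.

    For every (replicate, byproduct count) and every composite → (A, B)
    link of the scheme, computes the deviation of the composite's observed
    property from its constituent-based expectation: the mean of A and B
    for yield, the maximum of A and B for richness and Shannon entropy.
    Returns a tidy frame with one E value per (replicate, byproduct_count,
    composite).
    """
    col = {"E_Y": "yield", "E_S": "richness", "E_H": "shannon"}.get(metric)
    if col is None:
        raise ValueError("metric must be one of E_Y, E_S, E_H")
    piv = result.observations.pivot_table(
        index=["replicate", "byproduct_count"],
        columns="environment_id",
        values=col,
    )
    frames = []
    for comp, a, b in tree.edge_records():
        obs = piv[comp]
        expected = (
            (piv[a] + piv[b]) / 2.0
            if metric == "E_Y"
            else np.maximum(piv[a], piv[b])
        )
        df = (obs - expected).rename("E").reset_index()
        df["composite_id"] = comp
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["metric"] = metric
    return out[["replicate", "byproduct_count", "composite_id", "metric", "E"]]


def scaling_summary(result: EnsembleResult) -> pd.DataFrame:
    """Mean ± sd/sem of yield, richness and entropy per complexity level.

    Replicate-and-environment means are first formed within each byproduct
    count, then averaged across byproduct counts, so that every byproduct
    regime contributes equally.  Rows are ordered by ascending complexity.
    """
    obs = result.observations
    if obs.empty:
        raise ValueError("empty ensemble result")
    per_count = (
        obs.groupby(["byproduct_count", "complexity"])[["yield", "richness", "shannon"]]
        .agg(["mean", "std", "sem"])
    )
    out = per_count.groupby(level="complexity").mean()
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.sort_index().reset_index()
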