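"""Diversity measures and environmental-epistasis metrics.

"Environmental epistasis" quantifies how a community property on a
combined environment AB deviates from an expectation built from its
constituent environments A and B:

* yield:            E_Y = Y(AB) - (Y(A) + Y(B)) / 2
* species richness: E_S = S(AB) - max(S(A), S(B))
* Shannon entropy:  E_H = H(AB) - max(H(A), H(B))

The yield expectation is additive because every environment carries the
same total carbon; the diversity expectations are lower bounds built on
the naive assumption that a community on AB should be at least as diverse
as the more diverse of the two constituent communities.  Negative values
therefore flag losses of yield or diversity upon combining environments.

Survivor-set outcomes on composites are classified into four types:
Type I (a taxon appears on AB that grew on neither A nor B), Type II
(AB is exactly the union of A and B), Type III (AB equals the survivor
set of the less diverse constituent), Type IV (any other loss pattern).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .env_design import CombinationTree

__all__ = [
    "CommunityMeasurement",
    "EpistasisRecord",
    "shannon_entropy",
    "species_richness",
    "epistasis_yield",
    "epistasis_richness",
    "epistasis_shannon",
    "epistasis_over_tree",
    "records_to_frame",
    "classify_outcome",
    "distribution_stats",
]


def shannon_entropy(p: Sequence[float], normalize: bool = False) -> float:
    """Shannon entropy H = -sum_i p_i log2 p_i, in bits.

    ``p`` is a relative-abundance vector summing to 1 (tolerance 1e-9);
    zero entries are skipped.  ``normalize=True`` rescales ``p`` to sum to
    exactly 1 first (convenient for endpoint abundance vectors).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("relative abundances must be nonnegative")
    total = p.sum()
    if normalize:
        if total == 0:
            raise ValueError("cannot normalize an all-zero vector")
        p = p / total
    elif abs(total - 1.0) > 1e-9:
        raise ValueError(f"relative abundances must sum to 1, got {total}")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def species_richness(p: Sequence[float], threshold: float = 0.0) -> int:
    """Number of taxa with abundance strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    p = np.asarray(p, dtype=float)
    return int((p > threshold).sum())


def epistasis_yield(Y_AB: float, Y_A: float, Y_B: float) -> float:
    """E_Y = Y(AB) - (Y(A) + Y(B)) / 2.

    Zero when yields are additive (same total carbon in every environment
    implies the composite's yield should average the constituents').
    """
    for v in (Y_AB, Y_A, Y_B):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"yields must be finite and >= 0, got {v}")
    return Y_AB - (Y_A + Y_B) / 2.0


def epistasis_richness(S_AB: int, S_A: int, S_B: int) -> float:
    """E_S = S(AB) - max(S(A), S(B))."""
    if min(S_AB, S_A, S_B) < 0:
        raise ValueError("richness values must be >= 0")
    return float(S_AB - max(S_A, S_B))


def epistasis_shannon(H_AB: float, H_A: float, H_B: float) -> float:
    """E_H = H(AB) - max(H(A), H(B))."""
    if min(H_AB, H_A, H_B) < 0:
        raise ValueError("entropies must be >= 0")
    return H_AB - max(H_A, H_B)


@dataclass
class CommunityMeasurement:
    """Endpoint phenotype of one community-environment pairing.

    ``abundances`` are per-taxon relative abundances (may be empty when
    only yield was measured); ``growth_flag`` marks yields above the
    growth-call threshold — when False the community is treated as absent
    (survivor set empty, S = 0, H = 0).
    """

    environment_id: str
    yield_: float = 0.0
    abundances: Mapping[str, float] | None = None
    growth_flag: bool = True
    survival_threshold: float = 1e-3

    def survivors(self) -> frozenset[str]:
        if not self.growth_flag or not self.abundances:
            return frozenset()
        return frozenset(
            t for t, p in self.abundances.items() if p >= self.survival_threshold
        )

    def richness(self) -> int:
        return len(self.survivors())

    def entropy(self) -> float:
        if not self.growth_flag or not self.abundances:
            return 0.0
        p = np.array([v for v in self.abundances.values()])
        if p.sum() == 0:
            return 0.0
        return shannon_entropy(p, normalize=True)


@dataclass
class EpistasisRecord:
    composite_id: str
    a_id: str
    b_id: str
    metric: str  # "E_Y" | "E_S" | "E_H"
    observed: float
    expected: float

    @property
    def E(self) -> float:
        return self.observed - self.expected


_METRICS = ("E_Y", "E_S", "E_H")


def epistasis_over_tree(
    tree: CombinationTree,
    measurements: Mapping[str, CommunityMeasurement],
    metric: str = "E_Y",
    no_growth_yield: str = "zero",
) -> list[EpistasisRecord]:
    """One epistasis record per composite → (A, B) link of the scheme.

    No-growth environments contribute S = 0 and H = 0 to the diversity
    metrics; for E_Y their yield is treated as 0 (``no_growth_yield=
    "measured"`` keeps the measured value instead).  A composite whose
    constituents lack measurements is a structural error; a missing
    measurement for a linked environment produces a record with NaN
    observed/expected rather than being silently dropped.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if no_growth_yield not in ("zero", "measured"):
        raise ValueError("no_growth_yield must be 'zero' or 'measured'")

    offenders = sorted(
        {
            comp
            for comp, pairs in tree.edges.items()
            if comp in measurements
            and any(
                a not in measurements or b not in measurements for a, b in pairs
            )
        }
    )
    if offenders:
        raise ValueError(
            "composites measured without constituents: " + ", ".join(offenders)
        )

    def value(env_id: str) -> float:
        m = measurements[env_id]
        if metric == "E_Y":
            if not m.growth_flag and no_growth_yield == "zero":
                return 0.0
            return m.yield_
        if metric == "E_S":
            return float(m.richness())
        return m.entropy()

    records: list[EpistasisRecord] = []
    for comp, a, b in tree.edge_records():
        if comp not in measurements:
            # explicit gap, never a silent drop
            records.append(
                EpistasisRecord(comp, a, b, metric, float("nan"), float("nan"))
            )
            continue
        obs = value(comp)
        va, vb = value(a), value(b)
        expected = (va + vb) / 2.0 if metric == "E_Y" else max(va, vb)
        records.append(EpistasisRecord(comp, a, b, metric, obs, expected))
    return records


def records_to_frame(records: Iterable[EpistasisRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "composite_id": r.composite_id,
                "a_id": r.a_id,
                "b_id": r.b_id,
                "metric": r.metric,
                "observed": r.observed,
                "expected": r.expected,
                "E": r.E,
            }
            for r in records
        ]
    )


@dataclass
class OutcomeType:
    label: str  # "I" | "II" | "III" | "IV"
    surv_A: frozenset
    surv_B: frozenset
    surv_AB: frozenset


def classify_outcome(
    surv_A: Iterable, surv_B: Iterable, surv_AB: Iterable
) -> OutcomeType:
    """Classify a composite's survivor set against its constituents'.

    Precedence (mutually exclusive, exhaustive): Type I if AB contains any
    taxon absent from both A and B; else Type II if AB equals A ∪ B; else
    Type III if AB equals the survivor set of the less rich constituent
    (either qualifies on a richness tie); else Type IV.  All-empty sets
    classify as Type II (the union is vacuously reproduced).
    """
    A, B, AB = frozenset(surv_A), frozenset(surv_B), frozenset(surv_AB)
    if AB - (A | B):
        label = "I"
    elif AB == (A | B):
        label = "II"
    else:
        if len(A) == len(B):
            low = (A, B)
        elif len(A) < len(B):
            low = (A,)
        else:
            low = (B,)
        label = "III" if any(AB == s for s in low) else "IV"
    return OutcomeType(label, A, B, AB)


@dataclass
class DistributionStats:
    mean: float
    sd: float
    n: int
    p_vs_zero: float
    p_vs_baseline: float | None = None
    paired: bool | None = None
    alternative: str = "less"


def distribution_stats(
    E_values: Sequence[float],
    baseline: Sequence[float] | None = None,
    alternative: str = "less",
) -> DistributionStats:
    """Summary statistics of an epistasis distribution.

    Reports mean, sd (ddof=1), a one-sided one-sample t-test against zero,
    and — when a baseline distribution is supplied — a one-sided paired
    t-test against it (falling back to an independent-samples test, with
    ``paired=False`` recorded, when lengths differ).  ``alternative``
    follows scipy conventions ('less' tests for a negative shift).
    """
    x = np.asarray(E_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for distribution statistics")
    res0 = stats.ttest_1samp(x, 0.0, alternative=alternative)
    p_base: float | None = None
    paired: bool | None = None
    if baseline is not None:
        y = np.asarray(baseline, dtype=float)
        if y.size == x.size:
            paired = True
            if np.all(x == y):
                # identical distributions: zero mean difference, no evidence
                # in either direction for a one-sided test
                p_base = 0.5
            else:
                p_base = float(
                    stats.ttest_rel(x, y, alternative=alternative).pvalue
                )
        else:
            paired = False
            p_base = float(stats.ttest_ind(x, y, alternative=alternative).pvalue)
    return DistributionStats(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        n=int(x.size),
        p_vs_zero=float(res0.pvalue),
        p_vs_baseline=None if p_base is None else float(p_base),
        paired=paired,
        alternative=alternative,
    )
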