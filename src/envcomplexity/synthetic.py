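"""Synthetic experimental datasets with the statistical structure the
analysis pipeline assumes.

These generators stand in for the wet-lab stages: plate-reader OD tables
with replicate noise (and, optionally, planted epistasis offsets and
outlier replicates, so recovery can be verified end to end), monoculture
growth profiles, and 16S-style relative-abundance tables produced by
multinomial read sampling of community compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .env_design import CombinationTree
from .pipeline import AbundanceTable, PlateTable

__all__ = [
    "SyntheticSpec",
    "synth_monoculture_profile",
    "additive_truths",
    "synth_community_plates",
    "synth_abundance_table",
]


@dataclass
class SyntheticSpec:
    """Noise and sampling parameters for a synthetic dataset.

    ``replicate_noise_sd`` is plate-reader repeatability in OD units
    (default 0.01, typical for endpoint OD600 reads); ``planted_EY`` maps
    composite environment ids to yield-epistasis offsets added to the
    composite's true yield; ``planted_outliers`` maps environment ids to
    ``(replicate_index, shift_in_sds)`` for single-replicate outliers.
    """

    n_replicates: int = 3
    replicate_noise_sd: float = 0.01
    planted_EY: Mapping[str, float] = field(default_factory=dict)
    planted_outliers: Mapping[str, tuple[int, float]] = field(default_factory=dict)
    blank_od: float = 0.04
    read_depth: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicate_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def synth_monoculture_profile(
    S: int,
    M: int,
    theta: float | Sequence[float],
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Organisms x resources monoculture yield matrix.

    Organism ``i`` grows on each resource independently with probability
    ``theta_i`` (yield uniform on [0.1, 0.6] OD) and yields 0 elsewhere,
    so the empirical usable fraction per row recovers ``theta_i``.
    """
    th = np.broadcast_to(np.asarray(theta, dtype=float), (S,))
    if np.any(th < 0) or np.any(th > 1):
        raise ValueError("theta must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    mask = rng.random((S, M)) < th[:, None]
    yields = rng.uniform(0.1, 0.6, size=(S, M))
    return mask * yields


def additive_truths(
    tree: CombinationTree,
    leaf_yields: Mapping[str, float],
) -> dict[str, float]:
    """Propagate additive true yields up a combination tree.

    Composites receive the mean of their (canonical) constituents' yields,
    so every true yield-epistasis value is exactly zero — the natural
    ground truth on which offsets can then be planted.
    """
    truths = dict(leaf_yields)
    pending = dict(tree.edges)
    while pending:
        progressed = False
        for comp in sorted(pending):
            a, b = pending[comp][0]
            if a in truths and b in truths:
                truths[comp] = (truths[a] + truths[b]) / 2.0
                del pending[comp]
                progressed = True
        if not progressed:
            raise ValueError(f"cannot resolve truths for {sorted(pending)}")
    return truths


def synth_community_plates(
    spec: SyntheticSpec,
    base_measurements: Mapping[str, float],
    rng: np.random.Generator | int | None = None,
) -> tuple[PlateTable, dict[str, float]]:
    """Plate table of noisy replicate ODs around per-environment truths.

    Raw readings are blank + truth + Gaussian noise (truncated at the
    blank, i.e. corrected ODs never go negative); planted epistasis
    offsets shift the named composites' truths, and planted outliers shift
    one replicate by the requested number of noise sds.  Blank and
    negative-control wells are included.  Returns the table and the
    (offset-adjusted) truths actually used.
    """
    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    truths = dict(base_measurements)
    for comp, off in spec.planted_EY.items():
        if comp not in truths:
            raise KeyError(f"planted offset references unknown environment {comp!r}")
        truths[comp] = truths[comp] + off
    rows = []
    for eid in sorted(truths):
        noise = rng.normal(0.0, spec.replicate_noise_sd, size=spec.n_replicates)
        vals = truths[eid] + noise
        if eid in spec.planted_outliers:
            idx, shift = spec.planted_outliers[eid]
            vals[idx] += shift * spec.replicate_noise_sd
        vals = np.maximum(vals, 0.0)
        for r, v in enumerate(vals):
            rows.append(
                {
                    "environment_id": eid,
                    "replicate": r + 1,
                    "od_raw": spec.blank_od + v,
                }
            )
    controls = spec.blank_od + rng.normal(0.0, spec.replicate_noise_sd, size=3)
    plate = PlateTable(
        data=pd.DataFrame(rows),
        blank_od=spec.blank_od,
        negative_controls=controls,
    )
    return plate, truths


def synth_abundance_table(
    endpoints: Mapping[str, Sequence[float]],
    read_depth: int = 10_000,
    n_replicates: int = 3,
    taxa: Sequence[str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> AbundanceTable:
    """Multinomial read sampling of community compositions.

    ``endpoints`` maps environment id to a per-taxon (absolute or
    relative) abundance vector; each replicate draws ``read_depth`` reads
    from the normalized composition and reports relative read fractions.
    """
    if read_depth < 1:
        raise ValueError("read_depth must be >= 1")
    rng = np.random.default_rng(rng)
    env_ids = sorted(endpoints)
    first = np.asarray(endpoints[env_ids[0]], dtype=float)
    n_taxa = first.size
    if taxa is None:
        taxa = [f"sp{i + 1}" for i in range(n_taxa)]
    cols = {}
    meta = []
    for eid in env_ids:
        p = np.asarray(endpoints[eid], dtype=float)
        if np.any(p < 0):
            raise ValueError("endpoint abundances must be >= 0")
        total = p.sum()
        if total == 0:
            raise ValueError(f"environment {eid!r} has zero total abundance")
        p = p / total
        for r in range(n_replicates):
            counts = rng.multinomial(read_depth, p)
            sample = f"{eid}__r{r + 1}"
            cols[sample] = counts / read_depth
            meta.append(
                {"sample": sample, "environment_id": eid, "replicate": r + 1}
            )
    matrix = pd.DataFrame(cols, index=list(taxa))
    metadata = pd.DataFrame(meta).set_index("sample")
    return AbundanceTable(matrix=matrix, metadata=metadata)
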