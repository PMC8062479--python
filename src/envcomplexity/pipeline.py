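"""Preprocessing of experimental-style tables.

Two inputs are handled:

* plate-reader OD yield tables (long format: environment_id, replicate,
  od_raw), corrected against blank / negative-control wells, screened for
  outlying replicates with a median-absolute-deviation Z-score, and turned
  into per-environment yields with growth calls;
* taxon relative-abundance tables (wide format: taxa x samples), averaged
  across replicates and clustered (Spearman correlation between
  environments, then UPGMA agglomeration on Euclidean distances between
  correlation rows).

The modified MAD Z-score for replicate measurements ``x_i`` is

    M_i = 0.6745 (x_i - median(x)) / median(|x_i - median(x)|)

and a measurement with |M_i| > 3.5 is discarded as an outlier; when the
MAD is zero no replicate is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "PlateTable",
    "AbundanceTable",
    "ClusterResult",
    "mad_outlier_filter",
    "correct_and_call_growth",
    "average_replicates",
    "cluster_environments",
    "cfu_od_convert",
    "read_plate_table",
    "write_plate_table",
    "read_abundance_table",
    "write_abundance_table",
]

# reserved environment ids in plate files
BLANK_ID = "blank"
CONTROL_ID = "negative_control"
EVAP_ID = "evaporation_control"

# linear biomass conversion: OD 0.3 corresponds to 2.4e8 CFU/mL
CFU_PER_OD = 8e8


def mad_outlier_filter(
    x: Sequence[float], cutoff: float = 3.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Median-absolute-deviation outlier screen.

    Returns ``(kept_values, removed_indices, z_scores)``.  The modified
    Z-score is affine-equivariant, so shifting or positively rescaling the
    measurements removes the same indices.  A zero MAD (e.g. identical
    replicates) removes nothing.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        z = np.zeros_like(x)
    else:
        z = 0.6745 * (x - med) / mad
    removed = np.flatnonzero(np.abs(z) > cutoff)
    kept = np.delete(x, removed)
    return kept, removed, z


def cfu_od_convert(value: float, direction: str = "od_to_cfu") -> float:
    """Linear OD600 <-> CFU/mL conversion at 8e8 CFU/mL per OD unit."""
    if value < 0:
        raise ValueError("value must be >= 0")
    if direction == "od_to_cfu":
        return value * CFU_PER_OD
    if direction == "cfu_to_od":
        return value / CFU_PER_OD
    raise ValueError("direction must be 'od_to_cfu' or 'cfu_to_od'")


@dataclass
class PlateTable:
    """Raw plate-reader readings in long format.

    ``data`` columns: environment_id, replicate, od_raw.  Blank wells set
    the per-plate baseline; negative-control wells (inoculated, no carbon)
    provide the reference distribution for growth significance;
    evaporation controls, when present, are additionally subtracted.
    """

    data: pd.DataFrame
    blank_od: float = 0.0
    negative_controls: np.ndarray = field(default_factory=lambda: np.zeros(0))
    evap_control_od: float | None = None

    def __post_init__(self) -> None:
        required = {"environment_id", "replicate", "od_raw"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"plate table needs columns {sorted(required)}")
        if not np.all(np.isfinite(self.data["od_raw"])):
            raise ValueError("OD readings must be finite")
        self.negative_controls = np.asarray(self.negative_controls, dtype=float)

    def corrected(self) -> pd.DataFrame:
        """Blank- (and evaporation-) corrected readings."""
        out = self.data.copy()
        corr = out["od_raw"] - self.blank_od
        if self.evap_control_od is not None:
            corr = corr - (self.evap_control_od - self.blank_od)
        out["od_corrected"] = corr
        return out


def correct_and_call_growth(
    plate: PlateTable,
    growth_threshold: float = 0.05,
    alpha: float = 0.05,
    mad_cutoff: float = 3.5,
) -> pd.DataFrame:
    """Per-environment yields with outlier removal and growth calls.

    For each environment: blank-correct the replicate ODs, drop MAD
    outliers, then test growth above the negative controls with a
    one-tailed two-sample t-test at ``alpha``.  ``growth_flag`` is True
    only when the test is significant *and* the mean corrected OD reaches
    ``growth_threshold``.  Environments whose replicates were all removed
    are flagged unusable.
    """
    controls = plate.negative_controls - plate.blank_od
    corrected = plate.corrected()
    rows = []
    for eid, grp in corrected.groupby("environment_id", sort=True):
        vals = grp["od_corrected"].to_numpy()
        kept, removed, z = mad_outlier_filter(vals, mad_cutoff)
        usable = kept.size > 0
        mean = float(kept.mean()) if usable else float("nan")
        sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
        if usable and controls.size >= 2 and kept.size >= 2:
            p = float(
                stats.ttest_ind(kept, controls, alternative="greater").pvalue
            )
        elif usable and controls.size == 0:
            p = float("nan")
        else:
            p = 1.0
        significant = (p < alpha) if np.isfinite(p) else usable
        flag = bool(usable and significant and mean >= growth_threshold)
        rows.append(
            {
                "environment_id": eid,
                "yield_mean": mean,
                "yield_sd": sd,
                "n_replicates": int(kept.size),
                "n_removed": int(removed.size),
                "removed_z": ";".join(f"{z[i]:.3f}" for i in removed),
                "p_value": p,
                "growth_flag": flag,
                "usable": usable,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AbundanceTable:
    """Taxa x samples relative abundances with sample metadata.

    ``matrix`` is indexed by taxon with one column per sample; columns sum
    to 1 (tolerance 1e-6).  ``metadata`` is indexed by sample id with
    columns environment_id and replicate.  Reads that could not be
    assigned to a taxon are tracked per sample in ``unassigned_fraction``
    and excluded from the matrix (which is renormalized).
    """

    matrix: pd.DataFrame
    metadata: pd.DataFrame
    unassigned_fraction: pd.Series | None = None

    def __post_init__(self) -> None:
        if not {"environment_id", "replicate"}.issubset(self.metadata.columns):
            raise ValueError("metadata needs environment_id and replicate columns")
        if list(self.matrix.columns) != list(self.metadata.index):
            raise ValueError("matrix columns and metadata index must match")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = sums.index[np.abs(sums - 1.0) > 1e-6].tolist()
            raise ValueError(f"sample columns must sum to 1: {bad}")
        if np.any(self.matrix.to_numpy() < 0):
            raise ValueError("abundances must be nonnegative")
        self.matrix.index.name = "taxon"


def average_replicates(table: AbundanceTable) -> pd.DataFrame:
    """Mean composition per environment, renormalized to sum to 1."""
    env = table.metadata["environment_id"]
    means = {}
    for eid in sorted(env.unique()):
        cols = env.index[env == eid]
        mean = table.matrix[cols].mean(axis=1)
        total = mean.sum()
        means[eid] = mean / total if total > 0 else mean
    return pd.DataFrame(means)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    newick: str
    dropped: list[str] = field(default_factory=list)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def build(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        ha = h - (Z[int(a) - n][2] if a >= n else 0.0)
        hb = h - (Z[int(b) - n][2] if b >= n else 0.0)
        return f"({build(int(a))}:{ha / 2:.6g},{build(int(b))}:{hb / 2:.6g})"

    return build(2 * n - 2) + ";"


def cluster_environments(
    compositions: pd.DataFrame | AbundanceTable,
) -> ClusterResult:
    """UPGMA clustering of environments by community composition.

    Spearman correlations are computed between environment composition
    vectors; environments are then agglomerated by UPGMA (average linkage)
    on Euclidean distances between their correlation rows.  Environments
    with constant composition vectors (undefined correlations) are dropped
    with a warning column in the result.  Input column order does not
    affect merge heights; ids are sorted for a deterministic leaf order.
    """
    if isinstance(compositions, AbundanceTable):
        compositions = average_replicates(compositions)
    comp = compositions[sorted(compositions.columns)]
    if comp.shape[1] < 3:
        raise ValueError("need at least 3 environments to cluster")
    X = comp.to_numpy(dtype=float)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [comp.columns[j] for j in range(X.shape[1]) if j not in keep]
    labels = [str(comp.columns[j]) for j in keep]
    if len(keep) < 3:
        raise ValueError("fewer than 3 environments with non-constant composition")
    corr = stats.spearmanr(X[:, keep]).statistic
    corr = np.atleast_2d(corr)
    Z = hierarchy.linkage(pdist(corr, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage=Z,
        labels=labels,
        leaf_order=[labels[i] for i in order],
        newick=_linkage_to_newick(Z, labels),
        dropped=[str(d) for d in dropped],
    )


# ---------------------------------------------------------------------------
# file dialects (UTF-8 delimited text; comma or tab sniffed from the header)


def _sniff_sep(path: str | Path) -> str:
    header = Path(path).read_text().splitlines()[0]
    return "\t" if "\t" in header else ","


def write_plate_table(plate: PlateTable, path: str | Path, sep: str = ",") -> None:
    rows = plate.data[["environment_id", "replicate", "od_raw"]].copy()
    rows.columns = ["environment_id", "replicate", "value"]
    extra = [
        {"environment_id": BLANK_ID, "replicate": 1, "value": plate.blank_od}
    ]
    extra += [
        {"environment_id": CONTROL_ID, "replicate": i + 1, "value": v}
        for i, v in enumerate(plate.negative_controls)
    ]
    if plate.evap_control_od is not None:
        extra.append(
            {"environment_id": EVAP_ID, "replicate": 1, "value": plate.evap_control_od}
        )
    pd.concat([rows, pd.DataFrame(extra)], ignore_index=True).to_csv(
        path, sep=sep, index=False
    )


def read_plate_table(path: str | Path) -> PlateTable:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    special = df["environment_id"].isin([BLANK_ID, CONTROL_ID, EVAP_ID])
    data = df[~special].rename(columns={"value": "od_raw"}).reset_index(drop=True)
    blanks = df.loc[df["environment_id"] == BLANK_ID, "value"]
    controls = df.loc[df["environment_id"] == CONTROL_ID, "value"].to_numpy()
    evap = df.loc[df["environment_id"] == EVAP_ID, "value"]
    return PlateTable(
        data=data,
        blank_od=float(blanks.mean()) if len(blanks) else 0.0,
        negative_controls=controls,
        evap_control_od=float(evap.mean()) if len(evap) else None,
    )


def write_abundance_table(table: AbundanceTable, path: str | Path, sep: str = ",") -> None:
    out = table.matrix.copy()
    out.columns = [
        f"{table.metadata.loc[s, 'environment_id']}__r{table.metadata.loc[s, 'replicate']}"
        for s in table.matrix.columns
    ]
    if table.unassigned_fraction is not None:
        una = table.unassigned_fraction.copy()
        una.index = out.columns
        out = pd.concat([out * (1.0 - una), una.to_frame("Unassigned").T])
    out.index.name = "taxon"
    out.to_csv(path, sep=sep)


def read_abundance_table(path: str | Path) -> AbundanceTable:
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    una = None
    if "Unassigned" in df.index:
        una = df.loc["Unassigned"]
        df = df.drop(index="Unassigned")
        df = df / df.sum(axis=0)
    meta_rows = []
    for col in df.columns:
        env, _, rep = col.rpartition("__r")
        meta_rows.append({"sample": col, "environment_id": env, "replicate": int(rep)})
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return AbundanceTable(matrix=df, metadata=meta, unassigned_fraction=una)
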