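"""Combinatorial environment schemes with fixed total carbon.

Environments are sets of carbon sources at equal per-resource
concentrations, constructed so that every environment in a scheme carries
the same total carbon regardless of how many resources it contains.  Two
designs are provided:

* a *hierarchical* scheme on ``2**k`` resources (singletons, rank-extreme
  pairs, then successive merges of adjacent composites up to the full set),
  which yields ``2**(k+1) - 1`` environments; and
* a *full-subset* scheme enumerating every nonempty subset of a small
  resource panel (``2**n - 1`` environments).

Each composite environment is linked to constituent pairs ``(A, B)`` with
``resources(AB) = resources(A) | resources(B)`` and ``A ∩ B = ∅``; these
links are what downstream epistasis computations iterate over.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Resource",
    "Environment",
    "CombinationTree",
    "SchemeError",
    "equal_carbon_concentrations",
    "build_hierarchical_scheme",
    "build_full_subset_scheme",
    "write_scheme",
    "read_scheme",
]

_REL_TOL = 1e-9


class SchemeError(ValueError):
    """Raised when a scheme cannot be constructed from the given resources."""


@dataclass(frozen=True)
class Resource:
    """A carbon source.

    ``rank_score`` is the monoculture-yield ranking used to pair resources in
    the hierarchical design (lowest-yield paired with highest-yield, etc.).
    """

    id: int
    name: str
    rank_score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.rank_score == self.rank_score) or self.rank_score in (
            float("inf"),
            float("-inf"),
        ):
            raise ValueError(f"rank_score must be finite, got {self.rank_score!r}")
        if self.rank_score < 0:
            raise ValueError("rank_score must be >= 0")


@dataclass(frozen=True)
class Environment:
    """A medium: a set of resources with per-resource carbon concentrations."""

    id: str
    concentrations: Mapping[int, float]

    def __post_init__(self) -> None:
        if len(self.concentrations) == 0:
            raise ValueError(f"environment {self.id!r} has no resources")
        for rid, c in self.concentrations.items():
            if not c > 0:
                raise ValueError(
                    f"environment {self.id!r}: concentration for resource {rid} "
                    f"must be > 0, got {c}"
                )
        object.__setattr__(self, "concentrations", dict(self.concentrations))

    @property
    def resources(self) -> frozenset[int]:
        return frozenset(self.concentrations)

    @property
    def complexity(self) -> int:
        return len(self.concentrations)

    @property
    def total_carbon(self) -> float:
        return sum(self.concentrations.values())


def equal_carbon_concentrations(
    resource_ids: Iterable[int], total_carbon: float
) -> dict[int, float]:
    """Split ``total_carbon`` equally among the member resources.

    This is the equimolar-combination rule: every environment carries the same
    amount of carbon, so each of ``n`` members receives ``total_carbon / n``.
    """
    ids = list(resource_ids)
    if not ids:
        raise ValueError("empty resource set")
    if not total_carbon > 0:
        raise ValueError(f"total_carbon must be > 0, got {total_carbon}")
    per = total_carbon / len(ids)
    return {rid: per for rid in ids}


@dataclass
class CombinationTree:
    """Environments of a scheme plus composite → (A, B) constituent links.

    ``edges`` maps each composite environment id to a list of unordered
    bipartitions ``(a_id, b_id)``; hierarchical schemes have exactly one
    bipartition per composite, full-subset schemes may enumerate several.
    """

    environments: dict[str, Environment]
    edges: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    total_carbon: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = set(self.environments)
        for comp, pairs in self.edges.items():
            if comp not in ids:
                raise ValueError(f"edge references unknown composite {comp!r}")
            comp_res = self.environments[comp].resources
            for a, b in pairs:
                if a not in ids or b not in ids:
                    raise ValueError(f"edge {comp!r} references unknown constituent")
                ra = self.environments[a].resources
                rb = self.environments[b].resources
                if ra & rb:
                    raise ValueError(
                        f"constituents {a!r}, {b!r} of {comp!r} are not disjoint"
                    )
                if (ra | rb) != comp_res:
                    raise ValueError(
                        f"constituents {a!r}, {b!r} do not union to {comp!r}"
                    )
        for env in self.environments.values():
            if abs(env.total_carbon - self.total_carbon) > _REL_TOL * max(
                1.0, abs(self.total_carbon)
            ):
                raise ValueError(
                    f"environment {env.id!r} total carbon {env.total_carbon} "
                    f"!= scheme total {self.total_carbon}"
                )

    def __len__(self) -> int:
        return len(self.environments)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.edges.values())

    def complexity_levels(self) -> list[int]:
        return sorted({e.complexity for e in self.environments.values()})

    def environments_by_complexity(self, level: int) -> list[Environment]:
        return [
            e
            for _, e in sorted(self.environments.items())
            if e.complexity == level
        ]

    def edge_records(self) -> list[tuple[str, str, str]]:
        """Flat ``(composite, A, B)`` triples in deterministic order."""
        out = []
        for comp in sorted(self.edges):
            for a, b in self.edges[comp]:
                out.append((comp, a, b))
        return out


def _check_resources(resources: Sequence[Resource]) -> None:
    ids = [r.id for r in resources]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate resource ids")


def build_hierarchical_scheme(
    resources: Sequence[Resource], total_carbon: float = 1.5
) -> CombinationTree:
    """Hierarchical combination scheme on ``2**k`` resources.

    Level 1 contains every resource alone.  Level 2 pairs rank extremes:
    the lowest ``rank_score`` with the highest, the second-lowest with the
    second-highest, and so on (ties broken by resource id).  Each higher
    level merges adjacent environments of the level below in listing order,
    ending with the single full-panel environment.  On 32 resources this
    produces 32 + 16 + 8 + 4 + 2 + 1 = 63 environments.

    Environment ids are ``"<complexity>-<index>"`` (1-based within a level),
    so ``"4-1"`` contains the carbon sources of the first two 2-resource
    environments.
    """
    _check_resources(resources)
    n = len(resources)
    if n < 2 or (n & (n - 1)) != 0:
        raise SchemeError(f"need a power-of-two number of resources, got {n}")

    envs: dict[str, Environment] = {}
    edges: dict[str, list[tuple[str, str]]] = {}

    singles = [
        Environment(f"1-{i + 1}", equal_carbon_concentrations([r.id], total_carbon))
        for i, r in enumerate(resources)
    ]
    for e in singles:
        envs[e.id] = e
    single_id = {r.id: f"1-{i + 1}" for i, r in enumerate(resources)}

    # rank-extreme perfect matching: lowest with highest, etc.
    by_rank = sorted(resources, key=lambda r: (r.rank_score, r.id))
    level: list[Environment] = []
    for i in range(n // 2):
        lo, hi = by_rank[i], by_rank[n - 1 - i]
        env = Environment(
            f"2-{i + 1}",
            equal_carbon_concentrations([lo.id, hi.id], total_carbon),
        )
        envs[env.id] = env
        edges[env.id] = [(single_id[lo.id], single_id[hi.id])]
        level.append(env)

    size = 2
    while len(level) > 1:
        size *= 2
        nxt: list[Environment] = []
        for i in range(0, len(level), 2):
            a, b = level[i], level[i + 1]
            env = Environment(
                f"{size}-{i // 2 + 1}",
                equal_carbon_concentrations(
                    sorted(a.resources | b.resources), total_carbon
                ),
            )
            envs[env.id] = env
            edges[env.id] = [(a.id, b.id)]
            nxt.append(env)
        level = nxt

    return CombinationTree(envs, edges, total_carbon=total_carbon)


def build_full_subset_scheme(
    resources: Sequence[Resource],
    total_carbon: float = 1.5,
    all_bipartitions: bool = False,
) -> CombinationTree:
    """All-subsets scheme: every nonempty subset of the panel.

    On ``n`` resources this yields ``2**n - 1`` environments (for n=5:
    5 + 10 + 10 + 5 + 1 = 31).  Each subset of size >= 2 is linked to its
    canonical bipartition (subset minus its highest-ranked member, paired
    with that member); with ``all_bipartitions=True`` every unordered
    disjoint bipartition available in the scheme is enumerated.
    """
    _check_resources(resources)
    n = len(resources)
    if n < 1:
        raise SchemeError("need at least one resource")
    if n > 12:
        raise SchemeError(f"full-subset scheme limited to 12 resources, got {n}")

    by_id = {r.id: r for r in resources}
    order = sorted(by_id)
    envs: dict[str, Environment] = {}
    subset_id: dict[frozenset[int], str] = {}
    for size in range(1, n + 1):
        for i, combo in enumerate(itertools.combinations(order, size)):
            eid = f"{size}-{i + 1}"
            envs[eid] = Environment(
                eid, equal_carbon_concentrations(combo, total_carbon)
            )
            subset_id[frozenset(combo)] = eid

    edges: dict[str, list[tuple[str, str]]] = {}
    for subset, eid in subset_id.items():
        if len(subset) < 2:
            continue
        if all_bipartitions:
            members = sorted(subset)
            pairs = []
            # fix members[0] in side A to enumerate unordered bipartitions once
            for r in range(0, len(members)):
                for rest in itertools.combinations(members[1:], r):
                    a = frozenset((members[0],) + rest)
                    b = subset - a
                    if b:
                        pairs.append((subset_id[a], subset_id[b]))
            edges[eid] = pairs
        else:
            top = max(subset, key=lambda rid: (by_id[rid].rank_score, rid))
            rest = subset - {top}
            edges[eid] = [(subset_id[rest], subset_id[frozenset([top])])]

    return CombinationTree(envs, edges, total_carbon=total_carbon)


# ---------------------------------------------------------------------------
# serialization: delimited environment table + JSON edge list


def scheme_to_table(tree: CombinationTree) -> pd.DataFrame:
    rows = [
        {
            "environment_id": eid,
            "resource_id": rid,
            "concentration": conc,
        }
        for eid, env in sorted(tree.environments.items())
        for rid, conc in sorted(env.concentrations.items())
    ]
    return pd.DataFrame(rows, columns=["environment_id", "resource_id", "concentration"])


def write_scheme(tree: CombinationTree, table_path: str | Path, edges_path: str | Path) -> None:
    scheme_to_table(tree).to_csv(table_path, index=False)
    payload = {
        "total_carbon": tree.total_carbon,
        "edges": {comp: [list(p) for p in pairs] for comp, pairs in sorted(tree.edges.items())},
    }
    Path(edges_path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_scheme(table_path: str | Path, edges_path: str | Path) -> CombinationTree:
    df = pd.read_csv(table_path)
    payload = json.loads(Path(edges_path).read_text())
    envs = {
        str(eid): Environment(
            str(eid),
            dict(zip(g["resource_id"].astype(int), g["concentration"].astype(float))),
        )
        for eid, g in df.groupby("environment_id", sort=True)
    }
    edges = {
        comp: [tuple(p) for p in pairs] for comp, pairs in payload["edges"].items()
    }
    return CombinationTree(envs, edges, total_carbon=float(payload["total_carbon"]))
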