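"""MacArthur-style consumer resource model with cross-feeding and passaging.

Species abundances ``N_i`` and resource abundances ``R_a`` evolve as

    dN_i/dt = g_i N_i [ sum_a w_a (1 - l_a) C_ia R_a/(k_ia + R_a) - m_i ]
    dR_a/dt = - sum_i C_ia N_i R_a/(k_ia + R_a)
              + sum_{i,b} D_abi (w_b / w_a) l_b C_ib N_i R_b/(k_ib + R_b)

where ``C_ia`` is the stoichiometric uptake rate of resource ``a`` by
species ``i``, Monod kinetics saturate at half-velocity ``k``, a fraction
``l`` of each consumed flux leaks back into the medium as secreted
byproducts (routed by the per-species, mass-conserving stoichiometric
matrix ``D``), and ``m_i`` is the maintenance energy requirement.  Note the
consumption term enters ``dR_a/dt`` with a negative sign: resources are
depleted by uptake.

Cultures are serially passaged: batches of fixed duration, after which
species are diluted into fresh medium (primary resources restored,
byproducts discarded).  Integration is fixed-step explicit Euler with
clamp-to-zero, matching a 0.01 h reference timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .env_design import Environment

__all__ = [
    "CRMParams",
    "UptakeMatrix",
    "ByproductTensor",
    "CommunityState",
    "IntegrationError",
    "generate_uptake_matrix",
    "generate_byproduct_tensor",
    "crm_rhs",
    "integrate_batch",
    "simulate_passaged",
    "PassageResult",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class CRMParams:
    """Parameters of the consumer resource model.

    Defaults reproduce a serial-batch experiment: 6 passages of 48 h,
    1:30 dilution (10 µl into 290 µl of fresh medium), initial abundance
    6e6 CFU/mL per species and 1.5 g/mL total initial resource.  ``g`` and
    ``w`` (1 and 1e8) set the energy-to-biomass scale; ``k = 1e4`` puts
    uptake far from Monod saturation at these resource concentrations;
    ``l = 0.8`` is the leaked fraction of consumed flux.  Scalars broadcast
    over species/resources; arrays may be supplied per species (``g``,
    ``m``) or per resource (``w``, ``l``).
    """

    g: float | np.ndarray = 1.0
    w: float | np.ndarray = 1e8
    m: float | np.ndarray = 0.1
    l: float | np.ndarray = 0.8
    k: float = 1e4
    dt: float = 0.01
    passage_interval: float = 48.0
    n_passages: int = 6
    dilution_factor: float = 1.0 / 30.0
    N0: float = 6e6
    R_total0: float = 1.5

    def __post_init__(self) -> None:
        l = np.asarray(self.l, dtype=float)
        if np.any(l < 0) or np.any(l > 1):
            raise ValueError("leakage fraction l must lie in [0, 1]")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not (0 < self.dilution_factor <= 1):
            raise ValueError("dilution_factor must lie in (0, 1]")
        for name in ("k", "N0", "R_total0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if np.any(np.asarray(self.g, dtype=float) <= 0) or np.any(
            np.asarray(self.w, dtype=float) <= 0
        ):
            raise ValueError("g and w must be > 0")
        if np.any(np.asarray(self.m, dtype=float) < 0):
            raise ValueError("m must be >= 0")

    def with_(self, **kwargs) -> "CRMParams":
        return replace(self, **kwargs)


@dataclass
class UptakeMatrix:
    """Uptake rates ``C`` over primary-resource and byproduct columns.

    Columns ``0..M_primary-1`` are primary resources; the remaining
    ``M_byproduct`` columns are secreted metabolites, populated by the same
    Bernoulli(theta) x Uniform(0, uptake_scale] rule as the primaries.
    """

    C: np.ndarray
    M_primary: int
    M_byproduct: int
    theta: np.ndarray
    uptake_scale: float

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[1] != self.M_primary + self.M_byproduct:
            raise ValueError("C shape inconsistent with resource counts")
        if np.any(self.C < 0) or not np.all(np.isfinite(self.C)):
            raise ValueError("C entries must be finite and nonnegative")

    @property
    def S(self) -> int:
        return self.C.shape[0]

    @property
    def primary(self) -> np.ndarray:
        return self.C[:, : self.M_primary]


@dataclass
class ByproductTensor:
    """Per-species conversion ``D[i, a, b]``: primary ``b`` → byproduct ``a``.

    For each species and primary resource the column over byproducts sums
    to 1 (mass-conserving conversion) or 0 (no conversion drawn).
    Byproducts are terminal: they are never converted further.
    """

    D: np.ndarray  # (S, M_byproduct, M_primary)
    transition_probability: float = 0.25

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 3:
            raise ValueError("D must have shape (S, M_byproduct, M_primary)")
        if np.any(self.D < 0) or np.any(self.D > 1):
            raise ValueError("D entries must lie in [0, 1]")
        sums = self.D.sum(axis=1)
        ok = np.isclose(sums, 1.0) | np.isclose(sums, 0.0)
        if not np.all(ok):
            raise ValueError("each (species, primary) column of D must sum to 0 or 1")

    @property
    def S(self) -> int:
        return self.D.shape[0]

    @property
    def M_byproduct(self) -> int:
        return self.D.shape[1]

    @property
    def M_primary(self) -> int:
        return self.D.shape[2]


@dataclass
class CommunityState:
    """Species abundances ``N``, resource abundances ``R`` at time ``t`` (h)."""

    N: np.ndarray
    R: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if np.any(self.N < 0) or np.any(self.R < 0):
            raise ValueError("abundances must be nonnegative")

    def copy(self) -> "CommunityState":
        return CommunityState(self.N.copy(), self.R.copy(), self.t)


def generate_uptake_matrix(
    S: int,
    M_primary: int,
    M_byproduct: int,
    theta: float | Sequence[float],
    uptake_scale: float = 1e-2,
    rng: np.random.Generator | int | None = None,
) -> UptakeMatrix:
    """Draw a random uptake matrix.

    Entry ``C[i, a]`` is nonzero with probability ``theta_i`` (the fraction
    of resources usable by species ``i``; small theta makes a specialist),
    with nonzero magnitudes uniform on ``(0, uptake_scale]``.
    """
    if S < 1 or M_primary < 1:
        raise ValueError("S and M_primary must be >= 1")
    th = np.broadcast_to(np.asarray(theta, dtype=float), (S,)).copy()
    if np.any(th < 0) or np.any(th > 1):
        raise ValueError("theta must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    M = M_primary + M_byproduct
    mask = rng.random((S, M)) < th[:, None]
    # uniform on (0, scale]: flip the half-open interval of random()
    mags = (1.0 - rng.random((S, M))) * uptake_scale
    return UptakeMatrix(mask * mags, M_primary, M_byproduct, th, uptake_scale)


def generate_byproduct_tensor(
    S: int,
    M_primary: int,
    M_byproduct: int,
    transition_probability: float = 0.25,
    rng: np.random.Generator | int | None = None,
) -> ByproductTensor:
    """Draw the per-species conversion matrices ``D``.

    Each byproduct has ``transition_probability`` chance of being produced
    from each primary resource; selected entries share the column weight
    equally so every populated column sums to 1 (conservation of mass).
    """
    if not (0 <= transition_probability <= 1):
        raise ValueError("transition_probability must lie in [0, 1]")
    if M_byproduct < 0:
        raise ValueError("M_byproduct must be >= 0")
    rng = np.random.default_rng(rng)
    sel = rng.random((S, M_byproduct, M_primary)) < transition_probability
    counts = sel.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(counts > 0, sel / counts, 0.0)
    return ByproductTensor(D, transition_probability)


def _per_species(x, S: int) -> np.ndarray:
    return np.broadcast_to(np.asarray(x, dtype=float), (S,))


def _per_resource(x, M: int) -> np.ndarray:
    return np.broadcast_to(np.asarray(x, dtype=float), (M,))


def crm_rhs(
    state: CommunityState,
    uptake: UptakeMatrix,
    byproducts: ByproductTensor,
    params: CRMParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives ``(dN, dR)`` of the consumer resource model."""
    C = uptake.C
    S, M = C.shape
    Mp, Mb = uptake.M_primary, uptake.M_byproduct
    if state.N.shape != (S,) or state.R.shape != (M,):
        raise ValueError(
            f"state dims {state.N.shape}/{state.R.shape} do not match C {C.shape}"
        )
    if byproducts.D.shape != (S, Mb, Mp):
        raise ValueError("byproduct tensor dims do not match uptake matrix")

    g = _per_species(params.g, S)
    m = _per_species(params.m, S)
    w = _per_resource(params.w, M)
    l = _per_resource(params.l, M)

    f = state.R / (params.k + state.R)  # Monod factor, per resource
    uptake_flux = C * state.N[:, None] * f[None, :]  # (S, M) concentration/h
    energy = (C * (w * (1.0 - l))[None, :] * f[None, :]).sum(axis=1)
    dN = g * state.N * (energy - m)

    dR = -uptake_flux.sum(axis=0)
    # leaked flux from primary resources routed to byproduct pools
    leaked = uptake_flux[:, :Mp] * (w[:Mp] * l[:Mp])[None, :]  # (S, Mp) energy flux
    if Mb:
        inflow = np.einsum("iab,ib->a", byproducts.D, leaked) / w[Mp:]
        dR[Mp:] += inflow
    return dN, dR


def integrate_batch(
    state0: CommunityState,
    duration: float,
    uptake: UptakeMatrix,
    byproducts: ByproductTensor,
    params: CRMParams,
    record_every: int | None = None,
) -> list[CommunityState]:
    """Fixed-step Euler integration of one batch.

    Returns the trajectory including t=0 and t=duration; ``record_every``
    thins intermediate states (endpoints are always kept).  Negative
    components produced by a step are clamped to zero.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    n_steps = int(round(duration / params.dt))
    state = state0.copy()
    traj = [state.copy()]
    for step in range(n_steps):
        dN, dR = crm_rhs(state, uptake, byproducts, params)
        state.N = np.maximum(state.N + params.dt * dN, 0.0)
        state.R = np.maximum(state.R + params.dt * dR, 0.0)
        state.t = state0.t + (step + 1) * params.dt
        if not (np.all(np.isfinite(state.N)) and np.all(np.isfinite(state.R))):
            raise IntegrationError(f"non-finite state at step {step + 1}")
        if record_every and (step + 1) % record_every == 0:
            traj.append(state.copy())
    if not traj or traj[-1].t != state.t:
        traj.append(state.copy())
    return traj


def initial_resources(env: Environment, M_primary: int, M_byproduct: int) -> np.ndarray:
    """Fresh-medium resource vector for ``env`` (byproduct pools empty).

    Resource ids in ``env`` index the primary columns of ``C`` directly.
    """
    R0 = np.zeros(M_primary + M_byproduct)
    for rid, conc in env.concentrations.items():
        rid = int(rid)
        if not (0 <= rid < M_primary):
            raise ValueError(
                f"resource id {rid} outside primary columns [0, {M_primary})"
            )
        R0[rid] = conc
    return R0


@dataclass
class PassageResult:
    """Endpoint of a serial-passaging run plus per-passage endpoints.

    ``yield_`` is the growth yield of the final batch: endpoint biomass
    minus the biomass at the start of that batch, floored at zero.
    """

    endpoint: CommunityState
    passages: list[CommunityState] = field(default_factory=list)
    yield_: float = 0.0


def simulate_passaged(
    env: Environment,
    uptake: UptakeMatrix,
    byproducts: ByproductTensor,
    params: CRMParams,
) -> PassageResult:
    """Serial batch culture of a community in ``env``.

    Runs ``n_passages`` batches of ``passage_interval`` hours.  Between
    batches, species are diluted by ``dilution_factor`` and the medium is
    replaced: primary resources reset to the environment's concentrations,
    byproducts discarded.  All species start at ``N0``.
    """
    S = uptake.S
    R0 = initial_resources(env, uptake.M_primary, uptake.M_byproduct)
    state = CommunityState(np.full(S, params.N0), R0.copy(), 0.0)
    passages: list[CommunityState] = []
    peak = state.N.sum()
    start = peak
    for p in range(params.n_passages):
        if p > 0:
            state.N = state.N * params.dilution_factor
            state.R = R0.copy()
            start = state.N.sum()
            peak = start
        traj = integrate_batch(
            state, params.passage_interval, uptake, byproducts, params, record_every=1
        )
        peak = max(peak, max(s.N.sum() for s in traj))
        state = traj[-1]
        passages.append(state.copy())
    # growth yield: peak biomass reached in the final batch minus the
    # biomass the batch started from (maximum biomass at end of growth)
    return PassageResult(
        endpoint=state,
        passages=passages,
        yield_=max(peak - start, 0.0),
    )


# ---------------------------------------------------------------------------
# vectorized multi-environment engine (scalar-k fast path) for ensembles


def simulate_passaged_batch(
    R0: np.ndarray,
    uptake: UptakeMatrix,
    byproducts: ByproductTensor,
    params: CRMParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Serial passaging of one community across many environments at once.

    ``R0`` has shape ``(E, M_primary)``: one fresh-medium primary resource
    vector per environment.  Returns ``(N_end, yields)`` where ``N_end`` is
    ``(E, S)`` endpoint abundances and ``yields`` the growth yield per
    environment (peak biomass within the final batch minus the biomass the
    batch started from).  Requires a scalar Monod ``k`` (the default);
    results match :func:`simulate_passaged` environment by environment.
    """
    C = uptake.C
    S, M = C.shape
    Mp, Mb = uptake.M_primary, uptake.M_byproduct
    E = R0.shape[0]
    if R0.shape != (E, Mp):
        raise ValueError("R0 must have shape (E, M_primary)")
    if not np.isscalar(params.k):
        raise ValueError("batch engine requires scalar k")

    g = _per_species(params.g, S)
    m = _per_species(params.m, S)
    w = _per_resource(params.w, M)
    l = _per_resource(params.l, M)
    dt, k = params.dt, params.k

    EW = (C * (w * (1.0 - l))[None, :]).T  # (M, S): energy weights
    # P[(a), (i, b)]: leaked energy flux from (species i, primary b) into
    # byproduct a, divided by w_a to convert back to concentration
    if Mb:
        P = byproducts.D * (C[:, None, :Mp] * (w[:Mp] * l[:Mp])[None, None, :])
        P = P / w[Mp:][None, :, None]
        PmatT = P.transpose(0, 2, 1).reshape(S * Mp, Mb)  # (S*Mp, Mb)

    n_steps = int(round(params.passage_interval / dt))
    Rfull0 = np.zeros((E, M))
    Rfull0[:, :Mp] = R0

    N = np.full((E, S), params.N0)
    R = Rfull0.copy()
    start_biomass = N.sum(axis=1)
    peak_biomass = start_biomass.copy()
    for p in range(params.n_passages):
        if p > 0:
            N = N * params.dilution_factor
            R = Rfull0.copy()
            start_biomass = N.sum(axis=1)
            peak_biomass = start_biomass.copy()
        for _ in range(n_steps):
            f = R / (k + R)  # (E, M)
            energy = f @ EW  # (E, S)
            dN = g[None, :] * N * (energy - m[None, :])
            cons = (N @ C) * f  # (E, M)
            if Mb:
                G = (N[:, :, None] * f[:, None, :Mp]).reshape(E, S * Mp)
                inflow = G @ PmatT  # (E, Mb)
                dR = -cons
                dR[:, Mp:] += inflow
            else:
                dR = -cons
            N = np.maximum(N + dt * dN, 0.0)
            R = np.maximum(R + dt * dR, 0.0)
            np.maximum(peak_biomass, N.sum(axis=1), out=peak_biomass)
        if not (np.all(np.isfinite(N)) and np.all(np.isfinite(R))):
            raise IntegrationError(f"non-finite state in passage {p + 1}")
    # growth yield per environment: peak biomass reached in the final batch
    # minus the biomass that batch started from
    yields = np.maximum(peak_biomass - start_biomass, 0.0)
    return N, yields
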