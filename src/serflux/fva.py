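"""Flux balance analysis, flux variability analysis and serine-uptake scans.

FBA maximizes the biomass objective subject to steady state (S·v = 0) and
flux bounds.  FVA then asks, for each flux target, how low and how high that
flux can go while still supporting a stated fraction (default 0.99) of the
maximum feasible biomass growth.  The uptake scan repeats FVA along a grid of
serine uptake rates, re-optimizing biomass at every grid point so the
fraction-of-optimum floor always refers to the optimum *under the current
uptake constraint*.

All linear programs are solved with the HiGHS solver through
``scipy.optimize.linprog``.  Only envelope bounds (min/max flux) are
contractual; the flux vectors attaining them are one of possibly many
alternate optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError, set_exchange_bound

__all__ = [
    "FbaSolution",
    "FluxEnvelope",
    "LinearFluxTarget",
    "UptakeScanResult",
    "fba_maximize",
    "run_fva",
    "serine_reaction_panel",
    "serine_net_weights",
    "net_flux_envelope",
    "uptake_scan",
]

#: default "big" bound models use for practically unbounded fluxes; envelopes
#: that hit it are flagged unbounded but never reported as infinities.
BIG_BOUND = 1000.0

_LP_OPTIONS = {"presolve": True, "primal_feasibility_tolerance": 1e-9,
               "dual_feasibility_tolerance": 1e-9}


@dataclass
class FbaSolution:
    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class LinearFluxTarget:
    """A named linear combination of reaction fluxes, Σ weight_r · v_r."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"target {self.name!r} has no weights")

    @classmethod
    def single(cls, reaction_id: str, weight: float = 1.0) -> "LinearFluxTarget":
        return cls(name=reaction_id, weights={reaction_id: weight})


@dataclass
class FluxEnvelope:
    """Feasible flux range of one target at a fraction-of-optimum floor."""

    target: str
    min_flux: float
    max_flux: float
    fraction_of_optimum: float
    valid: bool = True
    unbounded: bool = False


@dataclass
class UptakeScanResult:
    exchange_id: str
    grid: np.ndarray
    envelopes: dict[str, list[FluxEnvelope]]
    max_biomass: np.ndarray
    fraction_of_optimum: float
    mode: str = "fixed"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (uptake rate, target)."""
        rows = []
        for name, envs in self.envelopes.items():
            for u, b, e in zip(self.grid, self.max_biomass, envs):
                rows.append(
                    {
                        "uptake_rate": u,
                        "target": name,
                        "min_flux": e.min_flux,
                        "max_flux": e.max_flux,
                        "max_biomass": b,
                        "status": "ok" if e.valid else "infeasible",
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------


def _lp_arrays(model: MetabolicModel):
    rids = [r.id for r in model.reactions]
    ridx = {rid: i for i, rid in enumerate(rids)}
    mids = [m.id for m in model.metabolites]
    midx = {mid: i for i, mid in enumerate(mids)}
    S = np.zeros((len(mids), len(rids)))
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            S[midx[mid], j] = coef
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, bounds, rids, ridx


def _solve(c, S, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options=_LP_OPTIONS,
    )
    return res


def fba_maximize(model: MetabolicModel) -> FbaSolution:
    """Maximize the objective (biomass) flux; never raises on infeasibility.

    Returns status ``optimal`` with one optimal flux vector, or
    ``infeasible`` / ``unbounded`` with empty fluxes.
    """
    S, bounds, rids, ridx = _lp_arrays(model)
    c = np.zeros(len(rids))
    c[ridx[model.objective_reaction]] = -1.0
    res = _solve(c, S, bounds)
    if res.status == 2:
        return FbaSolution(float("nan"), {}, "infeasible")
    if res.status == 3:
        return FbaSolution(float("nan"), {}, "unbounded")
    if not res.success:
        return FbaSolution(float("nan"), {}, "infeasible")
    fluxes = dict(zip(rids, res.x))
    return FbaSolution(-res.fun, fluxes, "optimal")


def run_fva(
    model: MetabolicModel,
    targets: Sequence[LinearFluxTarget | str],
    fraction: float = 0.99,
) -> list[FluxEnvelope]:
    """Flux variability analysis at a fraction-of-optimum floor.

    First maximizes biomass, then adds the constraint
    ``v_objective >= fraction * optimum`` and, for every target, minimizes and
    maximizes the target combination.  A per-target LP failure flags that
    envelope invalid and the run continues; an infeasible base model raises.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    targets = [
        LinearFluxTarget.single(t) if isinstance(t, str) else t for t in targets
    ]
    base = fba_maximize(model)
    if not base.optimal:
        raise ModelError(f"base model FBA is {base.status}; cannot run FVA")

    S, bounds, rids, ridx = _lp_arrays(model)
    n = len(rids)
    floor = np.zeros((1, n))
    floor[0, ridx[model.objective_reaction]] = -1.0
    b_floor = np.array([-fraction * base.objective_value])

    out: list[FluxEnvelope] = []
    for tgt in targets:
        missing = [rid for rid in tgt.weights if rid not in ridx]
        if missing:
            raise ModelError(f"target {tgt.name!r} references unknown reactions {missing}")
        w = np.zeros(n)
        for rid, coef in tgt.weights.items():
            w[ridx[rid]] = coef
        lo_res = _solve(w, S, bounds, floor, b_floor)
        hi_res = _solve(-w, S, bounds, floor, b_floor)
        if not (lo_res.success and hi_res.success):
            out.append(FluxEnvelope(tgt.name, float("nan"), float("nan"), fraction, valid=False))
            continue
        lo, hi = lo_res.fun, -hi_res.fun
        unb = abs(lo) >= BIG_BOUND - 1e-6 or abs(hi) >= BIG_BOUND - 1e-6
        out.append(FluxEnvelope(tgt.name, lo, hi, fraction, valid=True, unbounded=unb))
    return out


# ---------------------------------------------------------------------------
# Serine-flux targets
# ---------------------------------------------------------------------------


def serine_reaction_panel(
    model: MetabolicModel,
    serine_metabolites: Iterable[str],
    include_net_zero: bool = False,
) -> list[LinearFluxTarget]:
    """One target per reaction that produces or consumes serine.

    Each reaction touching any listed serine species becomes a
    single-reaction target weighted by the reaction's *net* serine
    coefficient over those species, so a positive target value always means
    serine production and a negative one consumption.  Pure transport between
    two listed compartments has net weight 0 and is excluded unless
    ``include_net_zero``.
    """
    serine_metabolites = set(serine_metabolites)
    for mid in serine_metabolites:
        model.metabolite(mid)  # raises for unknown ids
    panel: list[LinearFluxTarget] = []
    for r in model.reactions:
        net = sum(coef for mid, coef in r.stoichiometry.items() if mid in serine_metabolites)
        touches = any(mid in serine_metabolites for mid in r.stoichiometry)
        if not touches:
            continue
        if net == 0 and not include_net_zero:
            continue
        panel.append(LinearFluxTarget(name=r.id, weights={r.id: float(net)}))
    if not panel:
        warnings.warn("no reactions touch the listed serine metabolites", stacklevel=2)
    return panel


def serine_net_weights(
    model: MetabolicModel, reaction_ids: Iterable[str], serine_metabolites: Iterable[str]
) -> dict[str, float]:
    """Net serine coefficient per reaction, for building net-flux targets."""
    serine_metabolites = set(serine_metabolites)
    weights = {}
    for rid in reaction_ids:
        r = model.reaction(rid)
        weights[rid] = float(
            sum(c for mid, c in r.stoichiometry.items() if mid in serine_metabolites)
        )
    return weights


def net_flux_envelope(
    model: MetabolicModel,
    reaction_ids: Sequence[str],
    serine_metabolites: Iterable[str],
    fraction: float = 0.99,
    name: str = "net",
) -> FluxEnvelope:
    """Envelope of net serine production over a reaction set.

    The combination Σ (serine coefficient of r) · v_r is optimized *directly*
    as one linear objective — not assembled from per-reaction envelopes,
    which would ignore correlations between fluxes.
    """
    if not reaction_ids:
        raise ValueError("reaction set must be nonempty")
    weights = serine_net_weights(model, reaction_ids, serine_metabolites)
    target = LinearFluxTarget(name=name, weights=weights)
    return run_fva(model, [target], fraction=fraction)[0]


def uptake_scan(
    model: MetabolicModel,
    exchange_id: str,
    grid: Sequence[float],
    targets: Sequence[LinearFluxTarget | str],
    fraction: float = 0.99,
    mode: str = "fixed",
) -> UptakeScanResult:
    """FVA envelopes of the targets along a grid of uptake rates.

    At each grid value the exchange is constrained to that uptake
    (``mode="fixed"`` pins the flux; ``mode="max"`` only allows up to it),
    biomass is re-maximized, and FVA runs at ``fraction`` of that per-point
    optimum.  Infeasible grid points yield invalid envelopes and the scan
    continues.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0) and grid.size > 1:
        if np.any(grid < 0):
            raise ValueError("grid values must be nonnegative")
        raise ValueError("grid must be strictly increasing")
    targets = [
        LinearFluxTarget.single(t) if isinstance(t, str) else t for t in targets
    ]
    names = [t.name for t in targets]
    envelopes: dict[str, list[FluxEnvelope]] = {n: [] for n in names}
    max_biomass = np.full(grid.shape, float("nan"))
    for i, u in enumerate(grid):
        m_u = set_exchange_bound(model, exchange_id, float(u), mode=mode)
        sol = fba_maximize(m_u)
        if not sol.optimal:
            for n in names:
                envelopes[n].append(
                    FluxEnvelope(n, float("nan"), float("nan"), fraction, valid=False)
                )
            continue
        max_biomass[i] = sol.objective_value
        for env in run_fva(m_u, targets, fraction=fraction):
            envelopes[env.target].append(env)
    return UptakeScanResult(
        exchange_id=exchange_id,
        grid=grid,
        envelopes=envelopes,
        max_biomass=max_biomass,
        fraction_of_optimum=fraction,
        mode=mode,
    )
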