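"""Per-tree daily phenology and a surrogate carbon/water balance.

Budburst follows a thermal-time (degree-day) model: from the day of rest
onset, daily forcing ``max(T - T_base, 0)`` accumulates and budburst occurs
on the first day the sum reaches the tree's critical forcing requirement
F_critBB.  Accumulation includes the rest-onset day, and a tie at exact
equality counts as budburst.

The carbon/water balance is a deliberately simple daily surrogate for a
full process-based canopy model, delivering exactly the quantities the
demography consumes:

* before budburst, no assimilation; maintenance respiration
  ``r_m * B_tree^resp_exp * Q10^((T-15)/10)`` drains the reserve pool (the
  sublinear exponent stands in for the fact that only a sapwood-like
  fraction of a growing stem respires);
* at budburst, the canopy is built at a carbon cost of
  ``LAI_max * LMA * leaf C fraction`` plus a 50% growth-respiration
  overhead, drawn from reserves;
* during the leaf period (budburst to a fixed senescence day), daily
  assimilation is ``a_max * (1 - exp(-k_beer * LAI)) * f(T) * f(water)``
  with light absorption saturating in LAI, a linear temperature modifier
  capped at 1, and a drought modifier that declines linearly once relative
  soil water drops below 40% of the extractable reserve.  The daily drought
  shortfall ``1 - f(water)`` accumulates into the annual water stress index
  (WSI).  Positive net carbon is split by a fixed fraction between wood and
  reserves; deficits are paid from reserves.  Reserve storage is finite
  (``res_cap``): the excess is shed as litter, as is a slow structural
  turnover, so respiring biomass does not compound without bound;
* a single-bucket soil: water in by rain, out by evapotranspiration
  proportional to LAI and temperature, clipped to [0, SEW].

Late frosts after budburst initiation shrink the canopy multiplicatively:
each day with ``t_min`` below the frost threshold multiplies LAI by
``max(0, 1 - frost_k * (threshold - t_min))``.

Pools never go negative: respiration and leaf construction are paid only as
far as reserves allow, and the amounts actually paid are what enters the
annual carbon books, so the audit
``dB_tree + dB_res = GPP - respiration - leaf cost - litter`` holds to
round-off.
Two starvation indicators drive mortality downstream: ``CumCR``, the
reserve pool on the last day of the year, and ``bb_deficit``, the leaf
construction cost minus the reserves available the day before budburst.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate import DAYS_PER_YEAR

__all__ = [
    "PhenologyParams",
    "CarbonParams",
    "PhysioState",
    "AnnualSummary",
    "budburst_date",
    "budburst_dates",
    "frost_damage",
    "init_state",
    "run_year",
    "annual_summary",
    "leaf_construction_cost",
]


@dataclass(frozen=True)
class PhenologyParams:
    t_base: float = 0.0          # degC, base temperature for forcing
    rest_onset: int = 78         # day of year when forcing starts accumulating
    frost_threshold: float = 0.0  # degC, t_min below this damages leaves
    frost_k: float = 0.0         # fractional LAI loss per degC below threshold

    def __post_init__(self) -> None:
        if not 0.0 <= self.frost_k <= 1.0:
            raise ValueError("frost_k must lie in [0, 1]")


@dataclass(frozen=True)
class CarbonParams:
    """Surrogate carbon/water-balance settings (per m2 of crown-projected ground)."""

    a_max: float = 10.0            # gC m-2 d-1, assimilation ceiling
    k_beer: float = 0.5            # Beer-Lambert light extinction
    temp_opt: float = 20.0         # degC at which the temperature modifier saturates
    r_m: float = 0.0046            # d-1, maintenance respiration per unit respiring biomass
    resp_exp: float = 0.75         # respiring (sapwood-like) biomass ~ B_tree^resp_exp
    q10: float = 2.0
    lai_max: float = 5.0           # m2 m-2, canopy built at budburst
    lma: float = 93.0              # g dry mass per m2 leaf
    leaf_carbon_frac: float = 0.5  # gC per g dry mass
    growth_resp_overhead: float = 0.5  # extra construction cost fraction
    wood_fraction: float = 0.15    # share of positive net carbon allocated to wood
    turnover_rate: float = 0.02    # yr-1, structural turnover shed as litter
    senescence_doy: int = 285      # fixed leaf-fall day
    sew: float = 60.0              # mm, soil extractable water
    et_coeff: float = 0.03         # mm per unit LAI per degC of T above 0
    drought_threshold: float = 0.4  # relative soil water below which drought bites
    res_cap: float = 700.0         # gC m-2, reserve storage capacity; excess goes to wood
    init_reserves: float = 300.0   # gC m-2, reserve pool of a new recruit


def leaf_construction_cost(carbon: CarbonParams) -> float:
    """Carbon needed to flush the full canopy, incl. growth-respiration overhead."""
    return (
        carbon.lai_max
        * carbon.lma
        * carbon.leaf_carbon_frac
        * (1.0 + carbon.growth_resp_overhead)
    )


@dataclass
class PhysioState:
    """Carry-over pools of a cohort of trees (parallel arrays)."""

    b_tree: np.ndarray      # gC m-2, structural biomass
    b_res: np.ndarray       # gC m-2, carbon reserves
    soil_water: np.ndarray  # mm

    @property
    def n(self) -> int:
        return self.b_tree.size

    def subset(self, idx: np.ndarray) -> "PhysioState":
        return PhysioState(self.b_tree[idx].copy(), self.b_res[idx].copy(), self.soil_water[idx].copy())

    def write_back(self, idx: np.ndarray, sub: "PhysioState") -> None:
        self.b_tree[idx] = sub.b_tree
        self.b_res[idx] = sub.b_res
        self.soil_water[idx] = sub.soil_water


def init_state(
    n: int,
    carbon: CarbonParams | None = None,
    b_tree: np.ndarray | float = 1300.0,
    b_res: np.ndarray | float | None = None,
) -> PhysioState:
    c = carbon or CarbonParams()
    res = c.init_reserves if b_res is None else b_res
    return PhysioState(
        b_tree=np.broadcast_to(np.asarray(b_tree, float), (n,)).copy(),
        b_res=np.broadcast_to(np.asarray(res, float), (n,)).copy(),
        soil_water=np.full(n, c.sew),
    )


@dataclass
class AnnualSummary:
    """Per-tree annual outputs (parallel arrays; TBB is NaN when never reached)."""

    tbb: np.ndarray          # day of year
    lgs: np.ndarray          # days with leaves (senescence - TBB)
    wsi: np.ndarray          # summed daily drought shortfalls, dimensionless
    gpp: np.ndarray          # gC m-2 yr-1
    respiration: np.ndarray  # gC m-2 yr-1, actually paid
    wood: np.ndarray         # gC m-2 yr-1 allocated to wood
    litter: np.ndarray       # gC m-2 yr-1 shed (turnover + storage overflow)
    leaf_cost: np.ndarray    # gC m-2 paid for canopy construction
    cum_cr: np.ndarray       # gC m-2, reserves on day 365
    bb_deficit: np.ndarray   # gC m-2, leaf cost minus reserves before budburst
    b_tree_start: np.ndarray
    b_res_start: np.ndarray
    b_tree_end: np.ndarray
    b_res_end: np.ndarray


def budburst_dates(
    t_mean: np.ndarray, f_crit: np.ndarray, params: PhenologyParams | None = None
) -> np.ndarray:
    """Vectorised budburst day for each row of a ``(n, 365)`` temperature matrix.

    Returns a float array of days of year, NaN where the forcing requirement
    is never met.  A non-positive requirement degenerates to budburst on the
    rest-onset day.
    """
    p = params or PhenologyParams()
    tm = np.atleast_2d(np.asarray(t_mean, float))
    fc = np.broadcast_to(np.asarray(f_crit, float), (tm.shape[0],))
    forcing = np.maximum(tm - p.t_base, 0.0)
    forcing[:, : p.rest_onset - 1] = 0.0
    state = np.cumsum(forcing, axis=1)
    reached = state >= fc[:, None]
    any_ = reached.any(axis=1)
    first = np.argmax(reached, axis=1)
    tbb = np.where(any_, first + 1.0, np.nan)
    tbb = np.where(fc <= 0.0, float(p.rest_onset), tbb)
    return tbb


def budburst_date(
    daily_t_mean: np.ndarray, f_crit: float, params: PhenologyParams | None = None
) -> int | None:
    """Scalar budburst day for one year's mean-temperature series, or None."""
    tbb = budburst_dates(daily_t_mean[None, :], np.array([f_crit]), params)[0]
    return None if np.isnan(tbb) else int(tbb)


def frost_damage(
    lai: np.ndarray | float, t_min: np.ndarray | float, params: PhenologyParams
) -> np.ndarray | float:
    """LAI after one frost day: multiplicative loss per degree below threshold."""
    loss = params.frost_k * np.maximum(0.0, params.frost_threshold - np.asarray(t_min, float))
    return lai * np.clip(1.0 - loss, 0.0, 1.0)


def run_year(
    state: PhysioState,
    t_mean: np.ndarray,
    t_min: np.ndarray,
    precip: np.ndarray,
    f_crit: np.ndarray,
    phen: PhenologyParams | None = None,
    carbon: CarbonParams | None = None,
    record: bool = False,
) -> tuple[AnnualSummary, dict | None]:
    """Simulate one 365-day year for a cohort; mutates ``state`` in place.

    ``t_mean``/``t_min`` are ``(n, 365)`` (already lapse-adjusted per tree);
    ``precip`` may be ``(365,)`` shared or ``(n, 365)``.  With
    ``record=True`` a dict of daily traces is returned for auditing.
    """
    phen = phen or PhenologyParams()
    carbon = carbon or CarbonParams()
    n = state.n
    t_mean = np.atleast_2d(t_mean)
    t_min = np.atleast_2d(t_min)
    precip = np.broadcast_to(np.atleast_2d(precip), t_mean.shape)
    if t_mean.shape != (n, DAYS_PER_YEAR):
        raise ValueError("t_mean must have shape (n_trees, 365)")

    tbb = budburst_dates(t_mean, f_crit, phen)
    leaf_need = leaf_construction_cost(carbon)

    b_tree0 = state.b_tree.copy()
    b_res0 = state.b_res.copy()
    gpp = np.zeros(n)
    resp_tot = np.zeros(n)
    wood_tot = np.zeros(n)
    wsi = np.zeros(n)
    litter_tot = np.zeros(n)
    leaf_paid = np.zeros(n)
    bb_deficit = np.full(n, np.nan)
    lai = np.zeros(n)

    trace: dict[str, np.ndarray] | None = None
    if record:
        trace = {
            k: np.zeros((n, DAYS_PER_YEAR))
            for k in ("lai", "b_tree", "b_res", "soil_water", "assim", "resp", "wsi_inc")
        }
        trace["tbb"] = tbb

    # canopy is only built when budburst precedes senescence
    builds = (~np.isnan(tbb)) & (tbb < carbon.senescence_doy)

    for d in range(1, DAYS_PER_YEAR + 1):
        di = d - 1
        T = t_mean[:, di]
        Tm = t_min[:, di]

        at_bb = tbb == d
        if at_bb.any():
            bb_deficit[at_bb] = leaf_need - state.b_res[at_bb]
            build = at_bb & builds
            if build.any():
                paid = np.minimum(leaf_need, state.b_res[build])
                state.b_res[build] -= paid
                leaf_paid[build] += paid
                lai[build] = carbon.lai_max

        leafy = builds & (tbb <= d) & (d < carbon.senescence_doy)
        if phen.frost_k > 0.0:
            frosty = leafy & (Tm < phen.frost_threshold)
            if frosty.any():
                lai[frosty] = frost_damage(lai[frosty], Tm[frosty], phen)

        rel_water = state.soil_water / carbon.sew
        drought = np.where(
            rel_water >= carbon.drought_threshold,
            1.0,
            rel_water / carbon.drought_threshold,
        )
        assim = np.where(
            leafy,
            carbon.a_max
            * (1.0 - np.exp(-carbon.k_beer * lai))
            * np.clip(T / carbon.temp_opt, 0.0, 1.0)
            * drought,
            0.0,
        )
        wsi_inc = np.where(leafy, 1.0 - drought, 0.0)
        wsi += wsi_inc

        resp_demand = (
            carbon.r_m * state.b_tree**carbon.resp_exp * carbon.q10 ** ((T - 15.0) / 10.0)
        )
        net = assim - resp_demand
        pos = net > 0.0
        wood_inc = np.where(pos, carbon.wood_fraction * net, 0.0)
        res_inc = np.where(pos, net - wood_inc, net)
        new_res = state.b_res + res_inc
        shortfall = np.maximum(-new_res, 0.0)  # respiration demand reserves cannot pay
        overflow = np.maximum(new_res - carbon.res_cap, 0.0)  # storage is finite
        state.b_res = np.clip(new_res, 0.0, carbon.res_cap)
        turn = (carbon.turnover_rate / DAYS_PER_YEAR) * state.b_tree
        state.b_tree = state.b_tree + wood_inc - turn
        resp_paid = resp_demand - shortfall
        gpp += assim
        resp_tot += resp_paid
        wood_tot += wood_inc
        litter_tot += overflow + turn

        if d == carbon.senescence_doy:
            lai[:] = 0.0

        et = carbon.et_coeff * lai * np.maximum(T, 0.0)
        state.soil_water = np.clip(state.soil_water + precip[:, di] - et, 0.0, carbon.sew)

        if record:
            trace["lai"][:, di] = lai
            trace["b_tree"][:, di] = state.b_tree
            trace["b_res"][:, di] = state.b_res
            trace["soil_water"][:, di] = state.soil_water
            trace["assim"][:, di] = assim
            trace["resp"][:, di] = resp_paid
            trace["wsi_inc"][:, di] = wsi_inc

    lgs = np.where(builds, carbon.senescence_doy - tbb, 0.0)
    summary = AnnualSummary(
        tbb=tbb,
        lgs=lgs,
        wsi=wsi,
        gpp=gpp,
        respiration=resp_tot,
        wood=wood_tot,
        litter=litter_tot,
        leaf_cost=leaf_paid,
        cum_cr=state.b_res.copy(),
        bb_deficit=bb_deficit,
        b_tree_start=b_tree0,
        b_res_start=b_res0,
        b_tree_end=state.b_tree.copy(),
        b_res_end=state.b_res.copy(),
    )
    return summary, trace


def annual_summary(trace: dict, carbon: CarbonParams | None = None) -> dict[str, np.ndarray]:
    """Recompute annual aggregates from a recorded daily trace.

    Independent bookkeeping path over the same daily records, used to audit
    ``run_year``'s internal accumulation (GPP, respiration, WSI, CumCR, LGS).
    """
    carbon = carbon or CarbonParams()
    if "assim" not in trace:
        raise ValueError("incomplete trace: expected daily records of a full year")
    tbb = trace["tbb"]
    builds = (~np.isnan(tbb)) & (tbb < carbon.senescence_doy)
    return {
        "gpp": trace["assim"].sum(axis=1),
        "respiration": trace["resp"].sum(axis=1),
        "wsi": trace["wsi_inc"].sum(axis=1),
        "cum_cr": trace["b_res"][:, -1],
        "lgs": np.where(builds, carbon.senescence_doy - tbb, 0.0),
    }
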