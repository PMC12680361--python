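"""Exact stochastic simulation (Gillespie / SSA) of saccharification.

Direct-method SSA over the event catalogue maintained incrementally by
:class:`~lignosacc.substrate.SubstrateState`: waiting times are drawn
exponentially from the propensity sum, the event class is drawn in
proportion to its total propensity, and a uniform member of the class is
applied.  Lignin sequestration and end-product inhibition are
re-equilibrated deterministically before every draw, so propensities
always reflect the current soluble sugar pools.

A run terminates when the time horizon or the event budget is reached,
or when nothing digestible remains (propensity sum zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    CocktailConfig,
    EnzymePool,
    KineticParams,
    class_rates,
    effective_concentrations,
    lignin_sequestration,
    steric_window,
)
from .substrate import SubstrateConfig, SubstrateState, build_substrate

__all__ = ["Trajectory", "Event", "draw_event", "step", "run", "run_state", "replicate_mean"]


@dataclass(frozen=True)
class Event:
    """One realised SSA event."""

    kind: str  # EG_cut | XYL_cut | CBH_attach | CBH_step | BGL_split
    target: tuple | int | None
    propensity: float


@dataclass
class Trajectory:
    """Saccharification time-course sampled at fixed output times."""

    times: np.ndarray  # hours
    glucose: np.ndarray
    cellobiose: np.ndarray
    xylose: np.ndarray
    conversion: np.ndarray  # % of initial cellulose glucose equivalents
    events_applied: int = 0
    seed: int | None = None
    conversion_sd: np.ndarray | None = None  # populated by replicate_mean
    n_rep: int = 1

    def conversion_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.conversion))

    def final_conversion(self) -> float:
        return float(self.conversion[-1])


def _equilibrate(state: SubstrateState, pool: EnzymePool, params: KineticParams) -> EnzymePool:
    lignin_sequestration(pool, state.lignin_units, state.config.lignin_adhesion_rate)
    effective_concentrations(
        pool, state.pools["glucose"], state.pools["cellobiose"], params
    )
    return pool


def draw_event(
    state: SubstrateState,
    pool: EnzymePool,
    params: KineticParams,
    rng: np.random.Generator,
) -> tuple[int, float, np.ndarray] | None:
    """Draw the next event class and waiting time without applying it.

    Returns (class index, dt, class rates), or None when no event is
    possible.  The waiting time is exponential with the propensity sum as
    rate; the class is chosen in proportion to its total propensity.
    """
    _equilibrate(state, pool, params)
    rates = class_rates(state, pool, params)
    total = float(rates.sum())
    if total <= 0.0:
        return None
    dt = float(rng.exponential(1.0 / total))
    u = rng.random() * total
    cls = int(np.searchsorted(np.cumsum(rates), u, side="right"))
    return min(cls, len(rates) - 1), dt, rates


def step(
    state: SubstrateState,
    pool: EnzymePool,
    params: KineticParams,
    rng: np.random.Generator,
) -> tuple[Event, float] | None:
    """Draw and apply one SSA event; returns (event, dt) or None if no
    event is possible."""
    drawn = draw_event(state, pool, params, rng)
    if drawn is None:
        return None
    cls, dt, rates = drawn
    if cls == 0:
        key = state.eg_am.sample(rng)
        state.cleave(*key)
        ev = Event("EG_cut", key, rates[0])
    elif cls == 1:
        key = state.eg_cr.sample(rng)
        state.cleave(*key)
        ev = Event("EG_cut", key, rates[1])
    elif cls == 2:
        key = state.xyl_am.sample(rng)
        state.cleave(*key)
        ev = Event("XYL_cut", key, rates[2])
    elif cls == 3:
        key = state.xyl_cr.sample(rng)
        state.cleave(*key)
        ev = Event("XYL_cut", key, rates[3])
    elif cls == 4:
        key = state.cbh_ends.sample(rng)
        state.cbh_attach(*key)
        ev = Event("CBH_attach", key, rates[4])
    elif cls == 5:
        eid = state.step_am.sample(rng)
        state.cbh_step(eid)
        ev = Event("CBH_step", eid, rates[5])
    elif cls == 6:
        eid = state.step_cr.sample(rng)
        state.cbh_step(eid)
        ev = Event("CBH_step", eid, rates[6])
    else:
        state.bgl_split()
        ev = Event("BGL_split", None, rates[7])
    return ev, dt


def run_state(
    state: SubstrateState,
    cocktail: CocktailConfig,
    params: KineticParams,
    t_max: float = 48.0,
    max_events: int | None = None,
    sample_times: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    check_callback=None,
) -> Trajectory:
    """Simulate an already-built substrate to ``t_max`` hours.

    ``check_callback(state)``, if given, runs after every event (used by
    the bookkeeping-equivalence tests).
    """
    rng = np.random.default_rng(rng)
    if sample_times is None:
        sample_times = np.linspace(0.0, t_max, 97)
    sample_times = np.asarray(sample_times, dtype=float)
    pool = EnzymePool.from_cocktail(cocktail)

    t = 0.0
    ev_times = [0.0]
    glc = [state.pools["glucose"]]
    cbs = [state.pools["cellobiose"]]
    xyl = [state.pools["xylose"]]
    n_events = 0
    while True:
        out = step(state, pool, params, rng)
        if out is None:
            break
        _, dt = out
        if t + dt > t_max:
            # drawn event falls beyond the horizon: freeze the pools at
            # t_max (the overshoot event is never observed)
            t = t_max
            ev_times.append(t)
            glc.append(glc[-1])
            cbs.append(cbs[-1])
            xyl.append(xyl[-1])
            break
        t += dt
        n_events += 1
        ev_times.append(t)
        glc.append(state.pools["glucose"])
        cbs.append(state.pools["cellobiose"])
        xyl.append(state.pools["xylose"])
        if check_callback is not None:
            check_callback(state)
        if max_events is not None and n_events >= max_events:
            break

    ev_times = np.asarray(ev_times)
    glc_s = np.interp(sample_times, ev_times, np.asarray(glc, dtype=float))
    cbs_s = np.interp(sample_times, ev_times, np.asarray(cbs, dtype=float))
    xyl_s = np.interp(sample_times, ev_times, np.asarray(xyl, dtype=float))
    total = max(state.glucose_equivalents_total, 1)
    conv = 100.0 * (glc_s + 2.0 * cbs_s) / total
    return Trajectory(
        times=sample_times,
        glucose=glc_s,
        cellobiose=cbs_s,
        xylose=xyl_s,
        conversion=conv,
        events_applied=n_events,
    )


def run(
    config: SubstrateConfig,
    cocktail: CocktailConfig | None = None,
    params: KineticParams | None = None,
    t_max: float = 48.0,
    max_events: int | None = None,
    sample_times: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Build the substrate and simulate one stochastic trajectory."""
    cocktail = cocktail or CocktailConfig()
    params = params or KineticParams()
    rng = np.random.default_rng(rng)
    h = steric_window(params.r_enzyme, config.r_monomer)
    state = build_substrate(config, rng, steric_window=h)
    return run_state(
        state,
        cocktail,
        params,
        t_max=t_max,
        max_events=max_events,
        sample_times=sample_times,
        rng=rng,
    )


def replicate_mean(
    config: SubstrateConfig,
    cocktail: CocktailConfig | None = None,
    params: KineticParams | None = None,
    n_rep: int = 5,
    t_max: float = 48.0,
    sample_times: np.ndarray | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Per-time-point mean and standard deviation over ``n_rep``
    independent replicates; replicate streams derive from one master seed
    via ``SeedSequence.spawn``."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_rep)
    trajs = [
        run(
            config,
            cocktail,
            params,
            t_max=t_max,
            sample_times=sample_times,
            rng=np.random.default_rng(child),
        )
        for child in children
    ]
    conv = np.stack([tr.conversion for tr in trajs])
    glc = np.stack([tr.glucose for tr in trajs])
    cbs = np.stack([tr.cellobiose for tr in trajs])
    xyl = np.stack([tr.xylose for tr in trajs])
    return Trajectory(
        times=trajs[0].times,
        glucose=glc.mean(axis=0),
        cellobiose=cbs.mean(axis=0),
        xylose=xyl.mean(axis=0),
        conversion=conv.mean(axis=0),
        conversion_sd=conv.std(axis=0, ddof=0),
        events_applied=sum(tr.events_applied for tr in trajs),
        seed=seed,
        n_rep=n_rep,
    )
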