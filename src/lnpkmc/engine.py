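"""Event-driven kinetic Monte Carlo of pairwise LNP fusion.

Gillespie-type dynamics on the pair-rate table k_ij = Kcollide
exp(-Eb)/Vsystem: an event is drawn with probability k_ij / sum(k), time
advances by an exponential variate of mean 1/sum(k) (or deterministically
by the mean, if configured), the chosen pair merges conserving lipid and
RNA content, and only the rates involving the merged particle are
recomputed.  A time-stamped environment schedule (dialysis) changes salt
and ionization mid-run; events never straddle a change point.

The rate table is a dense symmetric matrix with per-row totals, giving
O(N) selection and O(N) update per event; full rebuilds (initialization
and environment changes) deduplicate work over identical particle types.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

from . import physchem
from .physchem import Environment, Formulation, InteractionParams
from .population import Population

__all__ = [
    "EnvironmentSchedule",
    "SimulationTrajectory",
    "SimulationState",
    "FrozenStateError",
    "compute_rates",
    "kmc_step",
    "merge_particles",
    "apply_environment",
    "simulate",
    "run_simulation",
]


class FrozenStateError(RuntimeError):
    """Total fusion rate is zero; no further events can occur."""


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Ordered (time_s, overrides) change points, e.g. dialysis at 1 h.

    ``overrides`` maps Environment field names (csalt, alpha_ionizable, ...)
    to their new values.
    """

    changes: tuple = ()

    def __post_init__(self):
        times = [t for t, _ in self.changes]
        if any(t < 0 for t in times):
            raise ValueError("schedule times must be >= 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")

    @staticmethod
    def dialysis(time_s: float = 3600.0, csalt: float = 0.15,
                 alpha_ionizable: float = None,
                 ph: float = 7.4, pka: float = 6.44) -> "EnvironmentSchedule":
        """Single-step dialysis: salt jump plus Henderson-Hasselbalch
        deprotonation of the ionizable lipid at the new pH."""
        if alpha_ionizable is None:
            alpha_ionizable = 1.0 / (1.0 + 10.0 ** (ph - pka))
        return EnvironmentSchedule(
            changes=((time_s, {"csalt": csalt,
                               "alpha_ionizable": alpha_ionizable}),)
        )


@dataclass
class SimulationTrajectory:
    """Recorded outcome of one kMC run."""

    snapshots: pd.DataFrame
    events: pd.DataFrame
    initial: Population
    final: Population
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)
    particles: Optional[pd.DataFrame] = None  # per-snapshot dumps, optional


class SimulationState:
    """Mutable engine state: population, clock, environment and rate table.

    Arrays are allocated at capacity ``n0`` and the first ``n`` entries are
    active; merges swap-remove so indices are dense.
    """

    def __init__(self, pop: Population, form: Formulation, env: Environment,
                 ip: InteractionParams, v_system: float,
                 rng: Optional[np.random.Generator] = None,
                 psi_model=None):
        if v_system <= 0:
            raise ValueError("v_system must be > 0")
        self.psi_model = psi_model
        self.pop = pop
        self.form = form
        self.env = env
        self.ip = ip
        self.v_system = float(v_system)
        self.rng = rng if rng is not None else np.random.default_rng()
        self.time = 0.0
        self.n = len(pop)
        self.event_count = 0
        self.next_id = int(pop.ids.max()) + 1
        cap = self.n
        self.units = np.zeros(cap, dtype=np.int64)
        self.rna = np.zeros(cap, dtype=np.int64)
        self.ids = np.zeros(cap, dtype=np.int64)
        self.psi = np.zeros(cap)
        self.units[:] = pop.units
        self.rna[:] = pop.rna
        self.ids[:] = pop.ids
        self.K = np.zeros((cap, cap))
        self.rowsum = np.zeros(cap)
        self._psi_cache = {}
        self.refresh_psi()
        compute_rates(self)

    # -- derived per-particle properties (active slice) ---------------------

    def _geometry(self, units, rna):
        """(radius, phi_peg, phi_ionizable, phi_rna) for unit/rna arrays."""
        form = self.form
        lip = units * self.pop.lipids_per_unit
        v_const = lip * form.mean_lipid_volume + rna * form.rna_volume
        radius = (3.0 * v_const / (4.0 * math.pi * (1.0 - form.fw))) ** (1 / 3)
        x = np.asarray(form.molar_fractions)
        vols = form.volumes
        phi_peg = lip * x[3] * vols[3] / v_const
        phi_ion = lip * x[0] * vols[0] / v_const
        phi_rna = rna * form.rna_volume / v_const
        return radius, phi_peg, phi_ion, phi_rna

    def _solve_psi_keyed(self, units, rna):
        """Charge-regulation psi per particle, memoized by (units, rna)."""
        units = np.atleast_1d(units)
        rna = np.atleast_1d(rna)
        out = np.empty(units.shape)
        tag = self.env.tag()
        for k, (u, m) in enumerate(zip(units, rna)):
            key = (int(u), int(m), tag)
            psi = self._psi_cache.get(key)
            if psi is None:
                r, _, phi_ion, phi_rna = self._geometry(
                    np.array([u]), np.array([m])
                )
                if self.psi_model is not None:
                    psi = float(self.psi_model(
                        float(r[0]), float(phi_rna[0]), self.env.csalt
                    ))
                else:
                    _, psi = physchem.solve_charge_regulation_scalar(
                        float(r[0]), float(phi_ion[0]), float(phi_rna[0]),
                        self.form, self.env,
                    )
                self._psi_cache[key] = psi
            out[k] = psi
        return out

    def refresh_psi(self):
        """Re-solve charge regulation for all active particles."""
        n = self.n
        self.psi[:n] = self._solve_psi_keyed(self.units[:n], self.rna[:n])

    @property
    def total_rate(self) -> float:
        return float(self.rowsum[: self.n].sum()) / 2.0

    def snapshot_population(self) -> Population:
        n = self.n
        pop = Population(
            units=self.units[:n].copy(),
            rna=self.rna[:n].copy(),
            lipids_per_unit=self.pop.lipids_per_unit,
            form=self.form,
            ids=self.ids[:n].copy(),
            psi=self.psi[:n].copy(),
            psi_env_tag=self.env.tag(),
        )
        return pop


def compute_rates(state: SimulationState) -> np.ndarray:
    """(Re)build the full symmetric rate table and per-row totals.

    Deduplicates over identical (units, rna) particle types: unique-type
    pair rates are computed once and scattered to the full table.
    """
    n = state.n
    units = state.units[:n]
    rna = state.rna[:n]
    if state.ip.kernel_mode == "constant":
        k = 8.0 * state.env.kbt / (3.0 * state.env.viscosity) * 1e27
        state.K[:n, :n] = k / state.v_system
        np.fill_diagonal(state.K[:n, :n], 0.0)
        state.rowsum[:n] = state.K[:n, :n].sum(axis=1)
        return state.K[:n, :n]
    keys = np.stack([units, rna], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    radius, phi_peg, _, _ = state._geometry(uniq[:, 0], uniq[:, 1])
    psi = state._solve_psi_keyed(uniq[:, 0], uniq[:, 1])
    nu = uniq.shape[0]
    ri = np.repeat(radius, nu).reshape(nu, nu)
    ku = physchem.pair_rate(
        ri, ri.T,
        np.repeat(phi_peg, nu).reshape(nu, nu),
        np.repeat(phi_peg, nu).reshape(nu, nu).T,
        np.repeat(psi, nu).reshape(nu, nu),
        np.repeat(psi, nu).reshape(nu, nu).T,
        state.form, state.env, state.ip, state.v_system,
    )
    state.K[:n, :n] = ku[np.ix_(inverse, inverse)]
    np.fill_diagonal(state.K[:n, :n], 0.0)
    state.rowsum[:n] = state.K[:n, :n].sum(axis=1)
    return state.K[:n, :n]


def _rates_vs_all(state: SimulationState, i: int) -> np.ndarray:
    """Fusion rates of particle i against all active particles (0 at i)."""
    n = state.n
    if state.ip.kernel_mode == "constant":
        k = 8.0 * state.env.kbt / (3.0 * state.env.viscosity) * 1e27
        out = np.full(n, k / state.v_system)
        out[i] = 0.0
        return out
    radius, phi_peg, _, _ = state._geometry(state.units[:n], state.rna[:n])
    out = physchem.pair_rate(
        np.full(n, radius[i]), radius,
        phi_peg[i], phi_peg,
        np.full(n, state.psi[i]), state.psi[:n],
        state.form, state.env, state.ip, state.v_system,
    )
    out[i] = 0.0
    return out


def merge_particles(pi: physchem.ParticleState, pj: physchem.ParticleState,
                    env: Environment, form: Formulation) -> physchem.ParticleState:
    """Merge two particles: counts add, volume is conserved, psi re-solved.

    For equal water fractions the merged bare radius is
    (Ri^3 + Rj^3)^(1/3).
    """
    merged = physchem.ParticleState.from_counts(
        pi.lipid_counts + pj.lipid_counts, pi.rna + pj.rna, form
    )
    physchem.solve_charge_regulation(merged, form, env)
    return merged


def _select_pair(state: SimulationState, u1: float, u2: float):
    n = state.n
    rs = state.rowsum[:n]
    csum = np.cumsum(rs)
    i = int(np.searchsorted(csum, u1 * csum[-1], side="right"))
    i = min(i, n - 1)
    row = state.K[i, :n]
    crow = np.cumsum(row)
    j = int(np.searchsorted(crow, u2 * crow[-1], side="right"))
    j = min(j, n - 1)
    return i, j


def kmc_step(state: SimulationState,
             rng: Optional[np.random.Generator] = None,
             time_increment: str = "exponential") -> tuple:
    """One fusion event: advance the clock, merge a pair, update rates.

    Returns (dt, id_i, id_j, id_new).  Raises :class:`FrozenStateError`
    when the total rate is zero.
    """
    if state.n < 2:
        raise FrozenStateError("fewer than two particles remain")
    rng = rng if rng is not None else state.rng
    total = state.total_rate
    if not total > 0.0:
        raise FrozenStateError("total fusion rate is zero")
    if time_increment == "exponential":
        dt = rng.exponential() / total
    elif time_increment == "mean":
        dt = 1.0 / total
    else:
        raise ValueError("time_increment must be 'exponential' or 'mean'")
    i, j = _select_pair(state, rng.random(), rng.random())
    id_i, id_j = int(state.ids[i]), int(state.ids[j])
    id_new, _ = _apply_merge(state, i, j)
    state.time += dt
    state.event_count += 1
    return dt, id_i, id_j, id_new


def _apply_merge(state: SimulationState, i: int, j: int) -> tuple:
    """Merge active particles i and j in place; returns (new id, slot)."""
    n = state.n
    K = state.K
    # remove old pair-rate contributions of i and j from every row total
    state.rowsum[:n] -= K[:n, i] + K[:n, j]
    # swap-remove slot j with the last active slot
    m = n - 1
    new_units = state.units[i] + state.units[j]
    new_rna = state.rna[i] + state.rna[j]
    if j != m:
        state.units[j] = state.units[m]
        state.rna[j] = state.rna[m]
        state.ids[j] = state.ids[m]
        state.psi[j] = state.psi[m]
        K[j, :n] = K[m, :n]
        K[:n, j] = K[:n, m]
        K[j, j] = 0.0
        state.rowsum[j] = state.rowsum[m]
        if i == m:
            i = j
    state.n = n = m
    # place the merged particle in slot i
    state.units[i] = new_units
    state.rna[i] = new_rna
    id_new = state.next_id
    state.ids[i] = id_new
    state.next_id += 1
    state.psi[i] = state._solve_psi_keyed(
        np.array([new_units]), np.array([new_rna])
    )[0]
    k_new = _rates_vs_all(state, i)
    state.rowsum[:n] += k_new
    state.rowsum[i] = k_new.sum()
    K[i, :n] = k_new
    K[:n, i] = k_new
    return id_new, i


def apply_environment(state: SimulationState, overrides: dict):
    """Apply an environment change: new Environment, fresh psi, full rebuild."""
    state.env = state.env.evolve(**overrides)
    state.refresh_psi()
    compute_rates(state)


def _summary_row(state: SimulationState, t: float) -> dict:
    n = state.n
    rna = state.rna[:n]
    radius, _, _, _ = state._geometry(state.units[:n], rna)
    loaded = rna[rna > 0]
    return {
        "time_s": t,
        "n_particles": n,
        "mean_radius_nm": float(radius.mean()),
        "theta_empty": float(np.mean(rna == 0)),
        "payload_var_total": float(np.var(rna)),
        "payload_var_loaded": float(np.var(loaded)) if loaded.size else float("nan"),
    }


def simulate(pop: Population, form: Formulation, env: Environment,
             ip: InteractionParams, v_system: float,
             schedule: EnvironmentSchedule = EnvironmentSchedule(),
             t_end: float = 64800.0,
             snapshot_times=None,
             seed=None,
             time_increment: str = "exponential",
             stop_count: Optional[int] = None,
             record_particles: bool = False,
             psi_model=None) -> SimulationTrajectory:
    """Run the fusion kMC from an existing population.

    ``snapshot_times`` defaults to 64 log-spaced points from 1 us to
    ``t_end``.  The run stops at ``t_end``, when fewer than 2 (or
    ``stop_count``) particles remain, or when the state freezes (zero
    total rate; remaining snapshots then repeat the frozen state).
    """
    rng = np.random.default_rng(seed)
    state = SimulationState(pop.copy(), form, env, ip, v_system, rng,
                            psi_model=psi_model)
    if snapshot_times is None:
        snapshot_times = np.geomspace(1e-6, max(t_end, 1e-6), 64)
    grid = np.asarray(sorted(float(t) for t in snapshot_times))
    grid = grid[(grid > 0) & (grid <= t_end)]

    rows = [_summary_row(state, 0.0)]
    dumps = []

    dumped_times = set()

    def dump(t):
        if record_particles and t not in dumped_times:
            dumped_times.add(t)
            n = state.n
            radius, phi_peg, _, _ = state._geometry(
                state.units[:n], state.rna[:n]
            )
            dumps.append(pd.DataFrame({
                "snapshot_time": t,
                "radius_nm": radius,
                "rna_count": state.rna[:n],
                "phi_peg": phi_peg,
                "psi0": state.psi[:n],
            }))

    dump(0.0)
    gi = 0  # next snapshot index

    def record_until(t, inclusive=True):
        nonlocal gi
        while gi < grid.size and (grid[gi] < t or (inclusive and grid[gi] <= t)):
            row = _summary_row(state, float(grid[gi]))
            rows.append(row)
            dump(float(grid[gi]))
            log.debug(
                "snapshot t=%.3es N=%d <R>=%.2fnm theta=%.3f",
                row["time_s"], row["n_particles"], row["mean_radius_nm"],
                row["theta_empty"],
            )
            gi += 1

    events = []
    pending = list(schedule.changes)
    floor = max(stop_count or 1, 1)
    frozen = False

    while state.time < t_end and state.n > floor and state.n >= 2:
        total = state.total_rate
        if total > 0.0:
            if time_increment == "exponential":
                dt = rng.exponential() / total
            elif time_increment == "mean":
                dt = 1.0 / total
            else:
                raise ValueError(
                    "time_increment must be 'exponential' or 'mean'"
                )
            t_next = state.time + dt
        else:
            t_next = math.inf
        t_change = pending[0][0] if pending else math.inf
        if t_change <= min(t_next, t_end) and t_change >= state.time:
            # events never straddle a change point: truncate and re-draw
            record_until(t_change)
            state.time = t_change
            apply_environment(state, pending.pop(0)[1])
            continue
        if t_next >= t_end:
            frozen = not np.isfinite(t_next)
            break
        record_until(t_next, inclusive=False)
        i, j = _select_pair(state, rng.random(), rng.random())
        id_i, id_j = int(state.ids[i]), int(state.ids[j])
        id_new, slot = _apply_merge(state, i, j)
        state.time = t_next
        state.event_count += 1
        events.append({
            "time_s": t_next,
            "id_i": id_i,
            "id_j": id_j,
            "id_new": id_new,
            "units_new": int(state.units[slot]),
        })

    if state.n <= floor and stop_count is not None:
        # ablation stop: freeze the record at the stop time
        record_until(state.time)
    else:
        # reached t_end (possibly frozen): fill the remaining grid
        record_until(t_end)
        state.time = t_end
    rows.append(_summary_row(state, state.time))
    dump(state.time)

    snapshots = pd.DataFrame(rows).drop_duplicates(
        subset="time_s").reset_index(drop=True)
    traj = SimulationTrajectory(
        snapshots=snapshots,
        events=pd.DataFrame(
            events,
            columns=["time_s", "id_i", "id_j", "id_new", "units_new"],
        ),
        initial=pop.copy(),
        final=state.snapshot_population(),
        seed=seed,
        meta={
            "t_end": t_end,
            "v_system_nm3": v_system,
            "kernel_mode": ip.kernel_mode,
            "n_events": state.event_count,
            "frozen": frozen,
        },
        particles=pd.concat(dumps, ignore_index=True) if dumps else None,
    )
    return traj


def run_simulation(config, seed=None) -> SimulationTrajectory:
    """Run one trajectory from a :class:`lnpkmc.config.RunConfig`.

    ``seed`` overrides the config seed.  Fully reproducible from
    (config, seed).
    """
    from .config import build_objects

    if seed is None:
        seed = config.seed
    form, env, ip, spec, schedule, kmc = build_objects(config)
    from .initializer import build_initial_population, derive_system_volume

    rng = np.random.default_rng(seed)
    pop = build_initial_population(spec, form, env, rng)
    v_system = derive_system_volume(spec, form)
    psi_model = None
    if kmc.get("use_surrogate"):
        from .ml_design import train_potential_surrogate

        psi_model = train_potential_surrogate(form=form, env=env, seed=0)
    traj = simulate(
        pop, form, env, ip, v_system,
        schedule=schedule,
        t_end=kmc["t_end"],
        snapshot_times=kmc["snapshot_times"],
        seed=rng,
        time_increment=kmc["time_increment"],
        stop_count=kmc["stop_count"],
        record_particles=kmc["record_particles"],
        psi_model=psi_model,
    )
    traj.seed = seed
    traj.meta["seed"] = seed
    return traj
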