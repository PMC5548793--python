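"""Stochastic trajectory simulation on the reduced chain.

Gillespie simulation draws exponential waiting times between substitutions
from the origin-fixation rates, producing single evolutionary trajectories
whose statistics (arrival times at macrostates, pathway identity, fraction of
deleterious fixations) complement the analytic steady-state and
hitting-time calculations.

Pathways to full specialization are classified by whether the trajectory
passes through the 'One TF Lost' macrostate before first reaching
'Specialize Both' (the slow pathway: binding must re-evolve from scratch) or
avoids it (the fast pathway via 'Partial' crosstalk states).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import ChainModel
from .thermo import ReducedGenotype

__all__ = [
    "Trajectory",
    "simulate_reduced",
    "simulate_ensemble",
    "classify_pathway",
    "trajectory_statistics",
]


@dataclass
class Trajectory:
    """One realisation of the substitution process.

    ``times[0] == 0`` is the start; ``times[i]`` (i >= 1) is the fixation
    time of the i-th substitution.  ``states``/``labels`` give the occupied
    reduced genotype and its macrostate on [times[i], times[i+1]); ``dF`` the
    per-substitution fitness change.  ``M`` tracks TF-TF divergence.
    """

    times: np.ndarray
    states: np.ndarray
    labels: np.ndarray
    dF: np.ndarray
    M: np.ndarray
    F: np.ndarray
    horizon: float
    reached_horizon: bool

    @property
    def n_substitutions(self) -> int:
        return len(self.times) - 1

    def first_hit(self, label: str) -> float | None:
        """Absolute time of first entry into macrostate ``label``; None if
        never reached (including occupation at t=0)."""
        hits = np.flatnonzero(self.labels == label)
        if len(hits) == 0:
            return None
        return float(self.times[hits[0]])

    def label_before(self, t: float) -> np.ndarray:
        """Macrostates visited strictly before time t."""
        return self.labels[self.times < t]


def simulate_reduced(
    chain: ChainModel,
    start: ReducedGenotype | int | None = None,
    horizon: float = 1e7,
    rng: np.random.Generator | int | None = None,
    stop_at: str | None = None,
    stop_after: int | None = None,
    max_events: int = 10_000_000,
) -> Trajectory:
    """Simulate one trajectory of the reduced-genotype substitution process.

    ``horizon`` is in generations; ``stop_at`` optionally ends the run on
    first entry into a macrostate, ``stop_after`` after a substitution
    count.  Event times are exact exponential draws; a fixed seed reproduces
    the trajectory event-for-event.
    """
    rng = np.random.default_rng(rng)
    if start is None:
        idx = int(np.argmax(chain.initial_distribution()))
    elif isinstance(start, ReducedGenotype):
        idx = chain.state_index(start)
    else:
        idx = int(start)

    Q = chain.Q
    indptr, indices, data = Q.indptr, Q.indices, Q.data
    labels = chain.labels
    F = chain.F
    Mvec = chain.space.M

    t = 0.0
    times = [0.0]
    states = [idx]
    dFs: list[float] = []
    reached_horizon = False
    for _ in range(max_events):
        if stop_at is not None and labels[idx] == stop_at:
            break
        if stop_after is not None and len(times) > stop_after:
            break
        lo, hi = indptr[idx], indptr[idx + 1]
        row_idx = indices[lo:hi]
        row_rate = data[lo:hi]
        off = row_idx != idx
        row_idx, row_rate = row_idx[off], row_rate[off]
        total = row_rate.sum()
        if total <= 0.0:
            reached_horizon = True
            t = horizon
            break
        dt = rng.exponential(1.0 / total)
        if t + dt > horizon:
            reached_horizon = True
            t = horizon
            break
        t += dt
        nxt = int(row_idx[rng.choice(len(row_rate), p=row_rate / total)])
        dFs.append(float(F[nxt] - F[idx]))
        idx = nxt
        times.append(t)
        states.append(idx)
    else:
        raise RuntimeError(f"exceeded {max_events} substitutions before horizon")

    states_arr = np.array(states, dtype=np.int64)
    return Trajectory(
        times=np.array(times),
        states=states_arr,
        labels=labels[states_arr],
        dF=np.array(dFs),
        M=Mvec[states_arr].astype(int),
        F=F[states_arr],
        horizon=horizon,
        reached_horizon=reached_horizon,
    )


def simulate_ensemble(
    chain: ChainModel,
    n_replicates: int = 400,
    horizon: float = 1e7,
    seed: int = 0,
    start: ReducedGenotype | int | None = None,
    stop_at: str | None = None,
) -> list[Trajectory]:
    """Independent replicates seeded from a root seed via a counter, so the
    ensemble is invariant to execution order."""
    return [
        simulate_reduced(chain, start=start, horizon=horizon,
                         rng=np.random.default_rng([seed, rep]),
                         stop_at=stop_at)
        for rep in range(n_replicates)
    ]


def classify_pathway(traj: Trajectory, target: str = "SpecializeBoth",
                     via: str = "OneTFLost") -> tuple[str, float | None]:
    """Classify a trajectory as ('fast'|'slow'|'unresolved', arrival time).

    'slow' iff the trajectory visits the ``via`` macrostate before first
    reaching ``target``; 'fast' otherwise; 'unresolved' when the horizon is
    reached before the target.
    """
    tau = traj.first_hit(target)
    if tau is None:
        return "unresolved", None
    visited = traj.label_before(tau)
    return ("slow" if (visited == via).any() else "fast"), tau


@dataclass
class TrajectoryStatistics:
    """Ensemble summary; times in generations (multiply by mu for 1/mu units)."""

    n_total: int
    n_fast: int
    n_slow: int
    n_unresolved: int
    tau_mean: float
    tau_se: float
    tau_fast_mean: float
    tau_fast_se: float
    tau_slow_mean: float
    tau_slow_se: float
    deleterious_fraction: float
    time_grid: np.ndarray = field(repr=False)
    mean_fitness: np.ndarray = field(repr=False)
    mean_M: np.ndarray = field(repr=False)

    @property
    def fraction_fast(self) -> float:
        n = self.n_fast + self.n_slow
        return self.n_fast / n if n else float("nan")

    @property
    def fraction_slow(self) -> float:
        n = self.n_fast + self.n_slow
        return self.n_slow / n if n else float("nan")


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    if len(x) == 0:
        return float("nan"), float("nan")
    se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
    return float(np.mean(x)), se


def _piecewise_at(traj: Trajectory, grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Piecewise-constant interpolation of a per-state quantity on a grid."""
    pos = np.searchsorted(traj.times, grid, side="right") - 1
    pos = np.clip(pos, 0, len(values) - 1)
    return values[pos]


def trajectory_statistics(
    trajs: list[Trajectory],
    target: str = "SpecializeBoth",
    via: str = "OneTFLost",
    time_grid: np.ndarray | None = None,
) -> TrajectoryStatistics:
    """Pathway fractions, conditional specialization times, deleterious-
    fixation fraction, and mean fitness / TF-TF match time courses.

    The deleterious fraction counts fixed substitutions with dF < 0 among
    all substitutions up to the arrival at ``target`` (whole trajectory for
    unresolved replicates).  Raises if every trajectory is unresolved.
    """
    if not trajs:
        raise ValueError("no trajectories given")
    kinds, taus = [], []
    for tr in trajs:
        kind, tau = classify_pathway(tr, target=target, via=via)
        kinds.append(kind)
        taus.append(tau)
    kinds = np.array(kinds)
    if not (kinds != "unresolved").any():
        raise ValueError("all trajectories unresolved; extend the horizon")

    tau_arr = np.array([t for t in taus if t is not None])
    tau_fast = np.array([t for t, k in zip(taus, kinds) if k == "fast"])
    tau_slow = np.array([t for t, k in zip(taus, kinds) if k == "slow"])

    n_del = 0
    n_sub = 0
    for tr, tau in zip(trajs, taus):
        upto = len(tr.dF) if tau is None else int(np.searchsorted(tr.times, tau))
        d = tr.dF[:upto]
        n_del += int((d < 0).sum())
        n_sub += len(d)

    if time_grid is None:
        t_max = max(tr.horizon for tr in trajs)
        time_grid = np.logspace(0, np.log10(max(t_max, 10.0)), 40)
    meanF = np.mean([_piecewise_at(tr, time_grid, tr.F) for tr in trajs], axis=0)
    meanM = np.mean([_piecewise_at(tr, time_grid, tr.M.astype(float)) for tr in trajs],
                    axis=0)

    m, se = _mean_se(tau_arr)
    mf, sef = _mean_se(tau_fast)
    ms, ses = _mean_se(tau_slow)
    return TrajectoryStatistics(
        n_total=len(trajs),
        n_fast=int((kinds == "fast").sum()),
        n_slow=int((kinds == "slow").sum()),
        n_unresolved=int((kinds == "unresolved").sum()),
        tau_mean=m, tau_se=se,
        tau_fast_mean=mf, tau_fast_se=sef,
        tau_slow_mean=ms, tau_slow_se=ses,
        deleterious_fraction=n_del / n_sub if n_sub else float("nan"),
        time_grid=time_grid, mean_fitness=meanF, mean_M=meanM,
    )
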