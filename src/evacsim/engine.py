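"""Coupled simulation engine and stochastic ensembles.

One run wires the pieces together per physical time step ``dt``:
every communication interval the directed influence graph is rebuilt
among not-yet-evacuated agents, attitudes are updated, and decisions
re-evaluated (so agents can start *and* stop evacuating); then the
movement model advances evacuating agents, and agents reaching a
destination leave the simulation (removed from both communication and
forces).

Ensembles rerun the simulation under resampled stochastic inputs:
``mode="attitudes"`` redraws the initial attitude vector per run;
``mode="leaders"`` fixes one attitude vector (canonically that of the
median-completion run of a baseline ensemble) and redraws only the
leading-evacuee assignment, with an exact leader count in every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from evacsim.attitudes import (
    CommunicationGraph,
    CommunicationParams,
    build_communication_graph,
    decide,
    update_attitudes,
)
from evacsim.movement import MovementParams, check_completion, step_movement
from evacsim.navigation import NavigationField, navigation_field_for
from evacsim.urban import UrbanModel, assign_leaders, place_agents, sample_initial_attitudes

IDLE, EVACUATING, EVACUATED = 0, 1, 2

_PAIR_REFRESH_STEPS = 10  # with the added slack radius, caching stays conservative


@dataclass
class SimulationConfig:
    """Full configuration of one simulation run.

    ``restrict_to_inundation`` defaults to the grid-style convention
    (agents only in buildings of the coastal inundation band) when the
    urban model is grid-style, mirroring how low-lying plain cities
    concentrate their at-risk population near the coast.
    """

    urban: UrbanModel
    n_agents: int = 500
    comm: CommunicationParams = field(default_factory=CommunicationParams)
    move: MovementParams = field(default_factory=MovementParams)
    leader_fraction: float = 0.0
    horizon: float = 900.0
    record_interval: float = 5.0
    seed: int = 0
    restrict_to_inundation: bool | None = None
    arrival_radius: float = 2.0
    evacuated_broadcast: bool = False
    stop_when_static: bool = True
    initial_positions: np.ndarray | None = None
    initial_attitudes: np.ndarray | None = None
    leader_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if not 0.0 <= self.leader_fraction <= 1.0:
            raise ValueError("leader_fraction must be in [0, 1]")
        if self.record_interval < self.comm.comm_interval:
            raise ValueError("record_interval must be >= comm_interval")

    @property
    def n_leaders(self) -> int:
        if self.leader_indices is not None:
            return len(self.leader_indices)
        return int(round(self.leader_fraction * self.n_agents))

    def resolve_restriction(self) -> bool:
        if self.restrict_to_inundation is not None:
            return self.restrict_to_inundation
        return self.urban.style == "grid"


@dataclass
class SimulationResult:
    """Snapshots and final outcome of one run."""

    times: np.ndarray  # (S,) snapshot times, s
    attitudes: np.ndarray  # (S, n) float32
    positions: np.ndarray  # (S, n, 2) float32
    states: np.ndarray  # (S, n) int8: 0 idle, 1 evacuating, 2 evacuated
    graphs: list[CommunicationGraph]  # snapshot communication graphs
    initial_attitudes: np.ndarray
    initial_positions: np.ndarray
    leader_indices: np.ndarray
    arrival_times: np.ndarray  # (n,) s, NaN if never arrived
    final_states: np.ndarray  # (n,) int8
    horizon: float
    seed: int

    @property
    def n_agents(self) -> int:
        return len(self.final_states)

    def completion_timeseries(self) -> np.ndarray:
        return (self.states == EVACUATED).mean(axis=1)


def completion_ratio(result: SimulationResult) -> float:
    """Fraction of agents that reached a destination within the horizon."""
    return float((result.final_states == EVACUATED).mean())


def relative_difference(ratio_a: float, ratio_b: float) -> float:
    """Relative difference (a - b) / b in percent; b must be nonzero."""
    if ratio_b == 0:
        raise ValueError("relative difference undefined for a zero reference ratio")
    return (ratio_a - ratio_b) / ratio_b * 100.0


def paired_relative_difference(ratios_a: np.ndarray, ratios_b: np.ndarray) -> float:
    """Mean over seed-paired runs of the per-pair relative difference (percent)."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired ensembles must have equal length")
    if np.any(b == 0):
        raise ValueError("relative difference undefined for zero reference ratios")
    return float(np.mean((a - b) / b) * 100.0)


def unpaired_relative_difference(ratios_a: np.ndarray, ratios_b: np.ndarray) -> float:
    """Relative difference of the ensemble means (percent)."""
    return relative_difference(float(np.mean(ratios_a)), float(np.mean(ratios_b)))


def _spawn_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def run_simulation(
    config: SimulationConfig,
    nav: NavigationField | None = None,
) -> SimulationResult:
    """Execute one coupled attitude/movement run. Reproducible given the seed."""
    urban = config.urban
    n = config.n_agents
    move = config.move
    comm = config.comm
    seeds = _spawn_seeds(config.seed, 3)

    if nav is None:
        nav = navigation_field_for(urban)

    pos = (
        np.array(config.initial_positions, dtype=float)
        if config.initial_positions is not None
        else place_agents(urban, n, config.resolve_restriction(), seed=seeds[0])
    )
    A = (
        np.array(config.initial_attitudes, dtype=float)
        if config.initial_attitudes is not None
        else sample_initial_attitudes(n, seed=seeds[1])
    )
    leaders = (
        np.asarray(config.leader_indices, dtype=np.intp)
        if config.leader_indices is not None
        else assign_leaders(n, config.n_leaders, seed=seeds[2])
    )
    if len(pos) != n or len(A) != n:
        raise ValueError("initial positions/attitudes must match n_agents")
    leader_mask = np.zeros(n, dtype=bool)
    leader_mask[leaders] = True
    A = A.copy()
    A[leader_mask] = comm.leader_attitude
    A0 = A.copy()
    pos0 = pos.copy()

    start_cost = nav.cost_at(pos)
    if not np.all(np.isfinite(start_cost)):
        warnings.warn(
            f"{int((~np.isfinite(start_cost)).sum())} agents start on cells unreachable "
            "from any destination and can never complete evacuation",
            stacklevel=2,
        )

    dt = move.dt
    n_steps = int(round(config.horizon / dt))
    comm_every = max(1, int(round(comm.comm_interval / dt)))
    rec_every = max(1, int(round(config.record_interval / dt)))
    n_snap = n_steps // rec_every + 1

    vel = np.zeros((n, 2))
    state = np.zeros(n, dtype=np.int8)
    arrival = np.full(n, np.nan)

    times = np.arange(n_snap) * config.record_interval
    snap_A = np.empty((n_snap, n), dtype=np.float32)
    snap_pos = np.empty((n_snap, n, 2), dtype=np.float32)
    snap_state = np.empty((n_snap, n), dtype=np.int8)
    graphs: list[CommunicationGraph] = []

    last_graph = CommunicationGraph(0, np.empty(0, np.intp), np.empty(0, np.intp))
    pairs_cache: np.ndarray | None = None
    snap_i = 0
    static = False
    t_s = 0

    for step in range(n_steps + 1):
        active = state != EVACUATED
        if step % comm_every == 0 and active.any():
            if config.evacuated_broadcast:
                # arrived agents keep broadcasting from the safe area
                ids = np.arange(n)
            else:
                ids = np.flatnonzero(active)
            graph = build_communication_graph(
                pos[ids], A[ids], comm, t_s=t_s, node_ids=ids
            )
            frozen = leader_mask[ids] | (state[ids] == EVACUATED)
            newA = A.copy()
            newA[ids] = update_attitudes(A[ids], graph, comm.mu, frozen)
            dA_max = float(np.max(np.abs(newA - A))) if len(ids) else 0.0
            A = newA
            t_s += 1
            flags = decide(A, comm.threshold)
            stop = active & ~flags & (state == EVACUATING)
            state[active & flags & (state == IDLE)] = EVACUATING
            state[stop] = IDLE
            vel[stop] = 0.0  # dissuaded agents halt and become standing obstacles
            last_graph = graph
            if (
                config.stop_when_static
                and not (state == EVACUATING).any()
                and dA_max < 1e-12
            ):
                static = True

        if step % rec_every == 0:
            snap_A[snap_i] = A
            snap_pos[snap_i] = pos
            snap_state[snap_i] = state
            graphs.append(last_graph)
            snap_i += 1

        if static or not active.any() or step == n_steps:
            if static or not active.any():
                break
            continue

        moving = state == EVACUATING
        if moving.any():
            act = np.flatnonzero(active)
            if pairs_cache is None or step % _PAIR_REFRESH_STEPS == 0:
                slack = move.v0 * move.overshoot_cap * dt * _PAIR_REFRESH_STEPS
                pairs_cache = cKDTree(pos[act]).query_pairs(
                    move.neighbour_range + slack, output_type="ndarray"
                )
            new_p, new_v = step_movement(
                pos[act],
                vel[act],
                moving[act],
                nav,
                move,
                landuse=urban.landuse,
                pairs=pairs_cache,
            )
            pos[act] = new_p
            vel[act] = new_v
            arrived_local = check_completion(
                pos[act], urban.destinations, config.arrival_radius
            ) & moving[act]
            if arrived_local.any():
                gl = act[arrived_local]
                state[gl] = EVACUATED
                arrival[gl] = (step + 1) * dt
                vel[gl] = 0.0
                pairs_cache = None  # node set changed; rebuild next step

    # pad remaining snapshots with the frozen end state
    while snap_i < n_snap:
        snap_A[snap_i] = A
        snap_pos[snap_i] = pos
        snap_state[snap_i] = state
        graphs.append(last_graph)
        snap_i += 1

    return SimulationResult(
        times=times,
        attitudes=snap_A,
        positions=snap_pos,
        states=snap_state,
        graphs=graphs,
        initial_attitudes=A0,
        initial_positions=pos0,
        leader_indices=leaders,
        arrival_times=arrival,
        final_states=state.copy(),
        horizon=config.horizon,
        seed=config.seed,
    )


@dataclass
class EnsembleResult:
    """Per-run metrics and a recomputable box-plot summary."""

    mode: str
    completions: np.ndarray  # (R,)
    metrics: pd.DataFrame  # one row per run
    run_seeds: list[int]
    initial_attitudes: np.ndarray  # (R, n) float32
    summary: dict
    results: list[SimulationResult] | None = None

    def median_case(self) -> tuple[int, np.ndarray]:
        """Run index with the median completion (lower median for even R)
        and its initial attitude vector — what leader-mode ensembles fix."""
        order = np.argsort(self.completions, kind="stable")
        idx = int(order[(len(order) - 1) // 2])
        return idx, np.asarray(self.initial_attitudes[idx], dtype=float)


def summarise(values: np.ndarray) -> dict:
    """Box-plot statistics: median, quartiles (linear interpolation),
    whiskers at the most extreme data within 1.5 x IQR, and fliers."""
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    whisk_lo = float(inside.min()) if len(inside) else float(v.min())
    whisk_hi = float(inside.max()) if len(inside) else float(v.max())
    fliers = v[(v < whisk_lo) | (v > whisk_hi)]
    return {
        "n": int(len(v)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": whisk_lo,
        "whisker_high": whisk_hi,
        "mean": float(v.mean()),
        "fliers": [float(x) for x in fliers],
    }


def run_ensemble(
    config: SimulationConfig,
    n_runs: int,
    mode: str = "attitudes",
    attitudes: np.ndarray | None = None,
    keep_results: bool = False,
    metric_fns: dict | None = None,
    nav: NavigationField | None = None,
) -> EnsembleResult:
    """Stochastic ensemble of simulation runs.

    ``mode="attitudes"``: initial positions are placed once (from the
    master seed) and each run redraws the initial attitude vector (and
    the leader assignment, if any).  ``mode="leaders"``: the supplied
    ``attitudes`` vector is fixed for every run and only the leader
    assignment is redrawn, with an exact leader count per run.
    Run seeds derive from the master seed, so the whole ensemble is
    reproducible.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if mode not in ("attitudes", "leaders"):
        raise ValueError("mode must be 'attitudes' or 'leaders'")
    if mode == "leaders" and attitudes is None:
        raise ValueError("leader mode fixes the attitude vector: pass attitudes=")

    base_seeds = _spawn_seeds(config.seed, 1)
    positions = (
        config.initial_positions
        if config.initial_positions is not None
        else place_agents(
            config.urban, config.n_agents, config.resolve_restriction(), seed=base_seeds[0]
        )
    )
    if nav is None:
        nav = navigation_field_for(config.urban)

    run_seeds = _spawn_seeds(config.seed + 1, n_runs)
    completions = np.empty(n_runs)
    init_A = np.empty((n_runs, config.n_agents), dtype=np.float32)
    rows = []
    results = [] if keep_results else None
    for r, rs in enumerate(run_seeds):
        cfg = replace(
            config,
            seed=rs,
            initial_positions=positions,
            initial_attitudes=attitudes if mode == "leaders" else None,
        )
        res = run_simulation(cfg, nav=nav)
        completions[r] = completion_ratio(res)
        init_A[r] = res.initial_attitudes
        row = {
            "run": r,
            "seed": rs,
            "completion": completions[r],
            "n_leaders": len(res.leader_indices),
        }
        if metric_fns:
            for name, fn in metric_fns.items():
                row[name] = fn(res)
        rows.append(row)
        if keep_results:
            results.append(res)

    return EnsembleResult(
        mode=mode,
        completions=completions,
        metrics=pd.DataFrame(rows),
        run_seeds=run_seeds,
        initial_attitudes=init_A,
        summary=summarise(completions),
        results=results,
    )
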