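"""Communication-network and behavioural metrics.

Clusters are the strongly connected components of the snapshot
communication graph: within a cluster every agent can reach every
other through chains of accepted influence, which is what lets a group
maintain a shared attitude against outside pressure.  The metrics here
quantify the mechanism by which urban structure shapes evacuation:
who evacuates (by initial attitude), in what group sizes, where the
positive and negative clusters sit over time, and how many initially
willing agents end up dissuaded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from evacsim.attitudes import CommunicationGraph
from evacsim.engine import EVACUATED, EVACUATING, SimulationResult


@dataclass
class Cluster:
    """A strongly connected component of one communication snapshot."""

    members: np.ndarray  # global agent ids
    size: int
    centre: np.ndarray | None = None  # mean member position, m
    mean_attitude: float | None = None
    timestamp: float | None = None


def extract_clusters(
    graph: CommunicationGraph,
    positions: np.ndarray | None = None,
    attitudes: np.ndarray | None = None,
    timestamp: float | None = None,
) -> list[Cluster]:
    """Partition the graph's agents into strongly connected components.

    ``positions``/``attitudes`` are indexed by global agent id and, if
    given, fill in cluster centres and mean attitudes.
    """
    n = graph.n
    ids = np.arange(n) if graph.node_ids is None else np.asarray(graph.node_ids)
    if n == 0:
        return []
    adj = coo_matrix(
        (np.ones(len(graph.src)), (graph.src, graph.dst)), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=True, connection="strong")
    clusters = []
    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(labels.max() + 2))
    for lb in range(labels.max() + 1):
        local = order[bounds[lb] : bounds[lb + 1]]
        members = ids[local]
        c = Cluster(members=members, size=len(members), timestamp=timestamp)
        if positions is not None:
            c.centre = np.asarray(positions)[members].mean(axis=0)
        if attitudes is not None:
            c.mean_attitude = float(np.asarray(attitudes)[members].mean())
        clusters.append(c)
    return clusters


def group_size_timeseries(
    result: SimulationResult, size_threshold: int = 10
) -> pd.DataFrame:
    """Large- vs small-group membership of evacuating agents over time.

    At each snapshot the communication graph is restricted to the
    currently evacuating agents (the moving crowd communicating within
    itself); evacuating agents in induced clusters of
    ``size_threshold`` or more members (inclusive) count as
    large-group, the rest as small-group.
    """
    if size_threshold < 2:
        raise ValueError("size_threshold must be >= 2")
    rows = []
    for s, t in enumerate(result.times):
        evac = result.states[s] == EVACUATING
        large = small = 0
        if evac.any():
            sub = _induced_subgraph(result.graphs[s], evac)
            for c in extract_clusters(sub):
                if c.size >= size_threshold:
                    large += c.size
                else:
                    small += c.size
        rows.append({"time": float(t), "large": large, "small": small})
    return pd.DataFrame(rows)


def _induced_subgraph(graph: CommunicationGraph, keep_global: np.ndarray) -> CommunicationGraph:
    """Restrict a snapshot graph to the globally-flagged agents."""
    ids = np.arange(graph.n) if graph.node_ids is None else np.asarray(graph.node_ids)
    keep_local = keep_global[ids]
    new_ids = ids[keep_local]
    remap = -np.ones(graph.n, dtype=np.intp)
    remap[np.flatnonzero(keep_local)] = np.arange(len(new_ids))
    if len(graph.src):
        ok = keep_local[graph.src] & keep_local[graph.dst]
        src = remap[graph.src[ok]]
        dst = remap[graph.dst[ok]]
    else:
        src = dst = np.empty(0, np.intp)
    return CommunicationGraph(
        n=len(new_ids), src=src, dst=dst, t_s=graph.t_s, node_ids=new_ids
    )


def cluster_trajectories(
    result: SimulationResult,
    sign: str,
    min_size: int = 2,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Centres and sizes of positive- or negative-attitude clusters.

    A cluster is *positive* when its mean member attitude is at least
    the decision threshold, *negative* when it is below zero.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    rows = []
    for s, t in enumerate(result.times):
        clusters = extract_clusters(
            result.graphs[s],
            positions=result.positions[s],
            attitudes=result.attitudes[s],
            timestamp=float(t),
        )
        for c in clusters:
            if c.size < min_size:
                continue
            if sign == "positive" and c.mean_attitude >= threshold:
                pass
            elif sign == "negative" and c.mean_attitude < 0.0:
                pass
            else:
                continue
            rows.append(
                {
                    "time": float(t),
                    "x": float(c.centre[0]),
                    "y": float(c.centre[1]),
                    "size": c.size,
                    "mean_attitude": c.mean_attitude,
                }
            )
    return pd.DataFrame(rows, columns=["time", "x", "y", "size", "mean_attitude"])


def max_negative_cluster_size(result: SimulationResult, min_size: int = 2) -> int:
    """Largest negative-attitude cluster observed over the whole run."""
    traj = cluster_trajectories(result, "negative", min_size=min_size)
    return int(traj["size"].max()) if len(traj) else 0


def evacuated_attitude_histogram(
    result: SimulationResult,
    bin_width: float = 0.1,
    band: tuple[float, float] = (0.2, 0.8),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of evacuated agents' *initial* attitudes.

    Returns ``(counts, bin_edges, band_fraction)`` where the band
    fraction is the share of evacuated agents whose initial attitude
    fell in ``band`` (inclusive) — the moderately-positive range whose
    fate distinguishes the two urban structures.
    """
    nbins = 2.0 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin_width must divide the attitude range [-1, 1] evenly")
    edges = np.linspace(-1.0, 1.0, int(round(nbins)) + 1)
    evac = result.final_states == EVACUATED
    a0 = result.initial_attitudes[evac]
    counts, _ = np.histogram(a0, bins=edges)
    frac = float(((a0 >= band[0]) & (a0 <= band[1])).mean()) if len(a0) else 0.0
    return counts, edges, frac


def behaviour_change_ratio(result: SimulationResult, high_threshold: float = 0.5) -> float:
    """Among agents with initial attitude >= threshold, the fraction
    dissuaded (not evacuated by the horizon)."""
    high = result.initial_attitudes >= high_threshold
    if not high.any():
        raise ValueError("no agent with an initial attitude above the threshold")
    return float((result.final_states[high] != EVACUATED).mean())


def normalise_time(result: SimulationResult) -> np.ndarray:
    """Snapshot times rescaled by the last arrival time to [0, 1]-ish.

    Different cities have different evacuation distances; rescaling by
    the last arrival makes group-composition timeseries comparable.
    """
    if not np.isfinite(result.arrival_times).any():
        raise ValueError("no agent evacuated: normalised time undefined")
    t_last = float(np.nanmax(result.arrival_times))
    return np.asarray(result.times, dtype=float) / t_last


def large_group_share(
    result: SimulationResult,
    size_threshold: int = 10,
    phase: tuple[float, float] | None = (0.5, 0.95),
) -> float:
    """Large-group share of evacuating agents in the established-flow phase.

    Mean per-snapshot share of evacuating agents that belong to
    induced clusters of ``size_threshold`` or more, over snapshots
    between the ``phase`` quantiles of the arrival-time distribution
    (default: from the median arrival to the 95th percentile).  By
    then the departure transient — everyone who will ever move setting
    off from wherever they happen to live — has washed out, and the
    group composition reflects how the street structure organises the
    flows.  ``phase=None`` aggregates total membership over the whole
    run instead.  Returns 0 when nobody evacuates.
    """
    ts = group_size_timeseries(result, size_threshold)
    if phase is None:
        tot = float(ts["large"].sum() + ts["small"].sum())
        return float(ts["large"].sum() / tot) if tot else 0.0
    finite = result.arrival_times[np.isfinite(result.arrival_times)]
    if len(finite) == 0:
        return 0.0
    t0, t1 = np.quantile(finite, phase)
    tot = (ts["large"] + ts["small"]).to_numpy().astype(float)
    share = np.divide(ts["large"].to_numpy(), tot, out=np.zeros_like(tot), where=tot > 0)
    m = (ts["time"].to_numpy() >= t0) & (ts["time"].to_numpy() <= t1) & (tot > 0)
    return float(share[m].mean()) if m.any() else 0.0
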