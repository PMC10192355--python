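"""Bounded-confidence attitude dynamics over a radius-limited influence graph.

Each agent carries a scalar attitude ``A_i`` in [-1, 1] expressing its
degree of intention to evacuate.  At every communication step the agent
averages the attitudes of accepted in-neighbours:

    A_i(t+1) = A_i(t) + mu * sum_j I(A_i, A_j) (A_j - A_i) / sum_j I(A_i, A_j)

where the sum runs over agents j within the communication radius and
the indicator ``I`` accepts j if and only if ``|A_i - A_j| < eps(A_i)``
(strict inequality).  The bounded confidence ``eps`` is attitude
dependent: agents already committed to evacuating (high A) are
narrow-minded and hard to dissuade, while hesitant agents are open to
influence.  Leading evacuees hold a constant positive attitude (0.7
by default) immune to any communication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree


def default_bounded_confidence(A: np.ndarray, base: float = 0.2, slope: float = 1.0) -> np.ndarray:
    """eps(A) = base + slope * (1 - A) / 2.

    Linearly interpolates from ``base`` at A = 1 (committed, closed)
    to ``base + slope`` at A = -1 (refusing, but open to persuasion).
    The asymmetry is what lets a cohesive evacuating group hold its
    attitude while still recruiting hesitant bystanders, and lets a
    converged negative crowd drag down moderately positive agents.
    """
    return base + slope * (1.0 - np.asarray(A)) / 2.0


@dataclass
class CommunicationParams:
    """Parameters of the communication model.

    mu : update gain in (0, 1]
    radius : communication radius in metres (15 m: talking distance
        plus seeing nearby people act)
    epsilon_fn : attitude-dependent bounded-confidence function
    comm_interval : physical seconds between communication steps
    threshold : attitude at which an agent starts (A >= thr) or stops
        (A < thr) evacuating
    leader_attitude : the constant attitude of leading evacuees
    """

    mu: float = 0.5
    radius: float = 15.0
    epsilon_fn: Callable[[np.ndarray], np.ndarray] = field(default=default_bounded_confidence)
    comm_interval: float = 1.0
    threshold: float = 0.5
    leader_attitude: float = 0.7

    def __post_init__(self) -> None:
        # mu = 0 freezes attitudes entirely: a useful analytic limit
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not -1.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (-1, 1)")


@dataclass
class CommunicationGraph:
    """Directed influence graph at one communication step.

    An edge ``src -> dst`` means *src influences dst* and exists iff
    the two agents are within the communication radius, differ, and
    ``|A_dst - A_src| < eps(A_dst)``.  Nodes are 0..n-1 local indices;
    ``node_ids`` maps them to global agent ids when the graph was
    built on a subset.
    """

    n: int
    src: np.ndarray  # (m,) int, influencers
    dst: np.ndarray  # (m,) int, influenced
    t_s: int = 0
    node_ids: np.ndarray | None = None

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        ids = np.arange(self.n) if self.node_ids is None else self.node_ids
        g.add_nodes_from(ids.tolist())
        g.add_edges_from(zip(ids[self.src].tolist(), ids[self.dst].tolist()))
        return g


def indicator(A_i, A_j, eps_i):
    """Eq.-style acceptance indicator: 1 iff |A_i - A_j| < eps_i (strict)."""
    return (np.abs(np.asarray(A_i) - np.asarray(A_j)) < np.asarray(eps_i)).astype(int)


def build_communication_graph(
    positions: np.ndarray,
    A: np.ndarray,
    params: CommunicationParams,
    t_s: int = 0,
    node_ids: np.ndarray | None = None,
) -> CommunicationGraph:
    """Directed influence graph from positions and attitudes.

    Asymmetric edges arise whenever ``eps(A_i) != eps(A_j)``: a
    hesitant agent may listen to a committed one that ignores it back.
    """
    positions = np.asarray(positions, dtype=float)
    A = np.asarray(A, dtype=float)
    if len(positions) != len(A):
        raise ValueError("positions and attitudes must have the same length")
    n = len(A)
    if n < 2:
        return CommunicationGraph(
            n=n, src=np.empty(0, np.intp), dst=np.empty(0, np.intp), t_s=t_s, node_ids=node_ids
        )
    pairs = cKDTree(positions).query_pairs(params.radius, output_type="ndarray")
    if len(pairs) == 0:
        return CommunicationGraph(
            n=n, src=np.empty(0, np.intp), dst=np.empty(0, np.intp), t_s=t_s, node_ids=node_ids
        )
    eps = np.asarray(params.epsilon_fn(A), dtype=float)
    a, b = pairs[:, 0], pairs[:, 1]
    diff = np.abs(A[a] - A[b])
    fwd = diff < eps[b]  # a influences b
    rev = diff < eps[a]  # b influences a
    src = np.concatenate([a[fwd], b[rev]])
    dst = np.concatenate([b[fwd], a[rev]])
    return CommunicationGraph(n=n, src=src, dst=dst, t_s=t_s, node_ids=node_ids)


def update_attitudes(
    A: np.ndarray,
    graph: CommunicationGraph,
    mu: float,
    leader_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One synchronous bounded-confidence update.

    Agents with no accepted in-neighbour keep their attitude (empty-sum
    convention); leaders are reset to their fixed attitude; the result
    is clamped to [-1, 1] (a no-op for mu <= 1, kept as a guard).
    """
    A = np.asarray(A, dtype=float)
    out = A.copy()
    if len(graph.src):
        acc = np.zeros(len(A))
        cnt = np.zeros(len(A))
        np.add.at(acc, graph.dst, A[graph.src] - A[graph.dst])
        np.add.at(cnt, graph.dst, 1.0)
        has = cnt > 0
        out[has] += mu * acc[has] / cnt[has]
    if leader_mask is not None:
        out[leader_mask] = A[leader_mask]
    return np.clip(out, -1.0, 1.0)


def decide(A: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Evacuation decision: True iff A >= threshold (inclusive).

    Re-evaluated at every communication step, so an evacuating agent
    whose attitude drops below the threshold stops evacuating.
    """
    return np.asarray(A) >= threshold
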