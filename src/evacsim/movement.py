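"""Social-force pedestrian movement with anticipatory collision avoidance.

Acceleration of an evacuating agent is relaxation toward the desired
velocity given by the navigation field, plus pairwise interaction
forces:

    dv_i/dt = (v0 e0_i - v_i) / tau_alpha + sum_j F_ij

The interaction force is anticipatory: from the linear extrapolation of
relative motion it projects the time to collision ``tau_c`` (the first
instant at which the two discs of radius ``agent_radius`` would touch)
and applies a repulsion of magnitude ``k / tau_c**2 * exp(-tau_c /
tau0)`` directed along the predicted closest-approach separation.
Agents that will not collide exert no force on each other.

Non-evacuating agents have zero desired velocity and decelerate by the
same relaxation term; they exert interaction forces on evacuees
(standing people are obstacles) but are not displaced by them.
Building and water cells block entry; an agent still inside its start
building may move freely until it exits.  Blocked displacement is
resolved by cancelling the offending axis component (sliding along
walls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from evacsim.navigation import NavigationField
from evacsim.urban import BUILDING, WATER

_TAU_FLOOR = 1e-2  # s; guards the 1/tau^2 magnitude for already-touching discs


@dataclass
class MovementParams:
    """Movement-model constants.

    v0 : preferred walking speed, m/s (1.33: typical free walking)
    tau_alpha : velocity relaxation time, s
    dt : explicit-Euler integration step, s (0.1 s keeps per-step
        displacement below one 1-m cell, so walls cannot be tunnelled)
    force_k : interaction strength
    force_tau0 : time-to-collision decay scale, s
    tau_cutoff : collisions further than this in the future are ignored, s
    agent_radius : body disc radius, m
    overshoot_cap : hard cap on speed as a multiple of v0
    neighbour_range : candidate-pair search radius for forces, m
        (at 6 m the anticipated-collision force is already far below
        the relaxation-term scale, so farther pairs are skipped)
    """

    v0: float = 1.33
    tau_alpha: float = 0.5
    dt: float = 0.1
    force_k: float = 1.5
    force_tau0: float = 3.0
    tau_cutoff: float = 10.0
    agent_radius: float = 0.3
    overshoot_cap: float = 1.3
    neighbour_range: float = 6.0

    def __post_init__(self) -> None:
        for name in ("v0", "tau_alpha", "dt", "force_k", "force_tau0", "agent_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt > self.tau_alpha:
            raise ValueError("dt must be small against tau_alpha")


def _time_to_collision(d: np.ndarray, v_rel: np.ndarray, radius_sum: float) -> np.ndarray:
    """First time at which |d + v_rel t| = radius_sum, else inf.

    ``d`` is the separation (pos_j - pos_i), ``v_rel`` the relative
    velocity (vel_j - vel_i); both (m, 2).  Already-overlapping pairs
    get tau = 0 (treated as imminent).
    """
    a = np.einsum("ij,ij->i", v_rel, v_rel)
    b = 2.0 * np.einsum("ij,ij->i", d, v_rel)
    c = np.einsum("ij,ij->i", d, d) - radius_sum**2
    tau = np.full(len(d), np.inf)
    tau[c <= 0] = 0.0  # already touching/overlapping
    disc = b * b - 4.0 * a * c
    ok = (c > 0) & (a > 0) & (disc >= 0) & (b < 0)  # approaching with a real root
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t1 = (-b - sq) / np.where(a > 0, 2.0 * a, 1.0)
    good = ok & (t1 >= 0)
    tau[good] = t1[good]
    return tau


def interaction_force(
    pos_i: np.ndarray,
    vel_i: np.ndarray,
    pos_j: np.ndarray,
    vel_j: np.ndarray,
    params: MovementParams,
) -> np.ndarray:
    """Anticipatory force exerted on agent i by agent j (single pair).

    Newton's third law holds: swapping i and j flips the sign.
    """
    d = (np.asarray(pos_j) - np.asarray(pos_i)).reshape(1, 2)
    v_rel = (np.asarray(vel_j) - np.asarray(vel_i)).reshape(1, 2)
    tau = _time_to_collision(d, v_rel, 2.0 * params.agent_radius)[0]
    if not np.isfinite(tau) or tau > params.tau_cutoff:
        return np.zeros(2)
    sep = -(d[0] + v_rel[0] * tau)  # i's position relative to j at closest approach
    norm = np.hypot(*sep)
    if norm == 0.0:
        return np.zeros(2)
    tau_eff = max(tau, _TAU_FLOOR)
    mag = params.force_k / tau_eff**2 * np.exp(-tau_eff / params.force_tau0)
    return mag * sep / norm


def _pairwise_forces(
    positions: np.ndarray,
    velocities: np.ndarray,
    params: MovementParams,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Summed interaction force on every agent (n, 2), vectorised."""
    n = len(positions)
    F = np.zeros((n, 2))
    if n < 2:
        return F
    if pairs is None:
        pairs = cKDTree(positions).query_pairs(params.neighbour_range, output_type="ndarray")
    if len(pairs) == 0:
        return F
    i, j = pairs[:, 0], pairs[:, 1]
    d = positions[j] - positions[i]
    v_rel = velocities[j] - velocities[i]
    tau = _time_to_collision(d, v_rel, 2.0 * params.agent_radius)
    hit = np.isfinite(tau) & (tau <= params.tau_cutoff)
    if not hit.any():
        return F
    i, j, d, v_rel, tau = i[hit], j[hit], d[hit], v_rel[hit], tau[hit]
    sep = -(d + v_rel * tau[:, None])
    norm = np.linalg.norm(sep, axis=1)
    nz = norm > 0
    i, j, sep, norm, tau = i[nz], j[nz], sep[nz], norm[nz], tau[nz]
    tau_eff = np.maximum(tau, _TAU_FLOOR)
    mag = params.force_k / tau_eff**2 * np.exp(-tau_eff / params.force_tau0)
    f = mag[:, None] * sep / norm[:, None]
    np.add.at(F, i, f)
    np.add.at(F, j, -f)
    return F


def _blocked(landuse: np.ndarray, resolution: float, pts: np.ndarray) -> np.ndarray:
    """True where a point is outside the domain or on a building/water cell."""
    ny, nx = landuse.shape
    ex, ey = nx * resolution, ny * resolution
    out = (pts[:, 0] < 0) | (pts[:, 0] >= ex) | (pts[:, 1] < 0) | (pts[:, 1] >= ey)
    res = out.copy()
    ok = ~out
    if ok.any():
        col = (pts[ok, 0] / resolution).astype(np.intp)
        row = (pts[ok, 1] / resolution).astype(np.intp)
        cat = landuse[row, col]
        res[ok] = (cat == BUILDING) | (cat == WATER)
    return res


def step_movement(
    positions: np.ndarray,
    velocities: np.ndarray,
    evacuating: np.ndarray,
    nav: NavigationField,
    params: MovementParams,
    landuse: np.ndarray | None = None,
    pairs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One explicit-Euler step of the movement model for all agents.

    ``evacuating`` selects agents with a non-zero desired velocity; the
    rest relax to rest and stay put.  ``pairs`` may supply a cached
    candidate-pair list (neighbour lists change slowly against dt).
    Returns the new ``(positions, velocities)``.
    """
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    evacuating = np.asarray(evacuating, dtype=bool)
    n = len(positions)
    e0 = np.zeros((n, 2))
    if evacuating.any():
        e0[evacuating] = nav.directions_at(positions[evacuating])

    F = _pairwise_forces(positions, velocities, params, pairs=pairs)
    F[~evacuating] = 0.0  # standing agents are obstacles, not billiard balls

    desired = params.v0 * e0
    acc = (desired - velocities) / params.tau_alpha + F
    vel = velocities + params.dt * acc

    speed = np.linalg.norm(vel, axis=1)
    cap = params.v0 * params.overshoot_cap
    fast = speed > cap
    if fast.any():
        vel[fast] *= (cap / speed[fast])[:, None]

    move = np.zeros((n, 2))
    move[evacuating] = vel[evacuating] * params.dt
    new_pos = positions + move

    if landuse is not None and evacuating.any():
        res = nav.resolution
        inside_building = _blocked(landuse, res, positions)  # still exiting: free to move
        bad = evacuating & ~inside_building & _blocked(landuse, res, new_pos)
        if bad.any():
            # slide: try the x component alone, then the y component alone
            idx = np.flatnonzero(bad)
            try_x = positions[idx].copy()
            try_x[:, 0] = new_pos[idx, 0]
            ok_x = ~_blocked(landuse, res, try_x)
            new_pos[idx] = np.where(ok_x[:, None], try_x, positions[idx])
            vel[idx[ok_x], 1] = 0.0
            rest = idx[~ok_x]
            if len(rest):
                try_y = positions[rest].copy()
                try_y[:, 1] = positions[rest, 1] + vel[rest, 1] * params.dt
                ok_y = ~_blocked(landuse, res, try_y)
                new_pos[rest] = np.where(ok_y[:, None], try_y, positions[rest])
                vel[rest[ok_y], 0] = 0.0
                vel[rest[~ok_y]] = 0.0

    return new_pos, vel


def check_completion(
    positions: np.ndarray,
    destinations: np.ndarray,
    arrival_radius: float = 2.0,
) -> np.ndarray:
    """True for agents within ``arrival_radius`` (inclusive) of any destination."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    dests = np.atleast_2d(np.asarray(destinations, dtype=float))
    d2 = ((positions[:, None, :] - dests[None, :, :]) ** 2).sum(axis=2)
    return (d2.min(axis=1) <= arrival_radius**2)
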