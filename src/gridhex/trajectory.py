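"""Trajectory generators: star-like, piecewise-linear, and random walks.

All trajectories move at constant speed ``v`` and are discretized into M
time steps of length ``dt``; step ``m`` starts at ``positions[m]`` and moves
a distance ``v*dt`` along direction ``directions[m]``.  Star-like walks
consist of radial segments that restart ("teleport") at a common origin;
piecewise-linear walks chain the same segments end to end in random order;
random walks update the heading with Gaussian increments of variance
``sigma_theta**2 * dt`` (a Wiener process in direction space, so
``sigma_theta`` is a tortuosity in rad/s^1/2).

Bounded arenas (square or circle, centered at the origin) are supported for
random walks by rejection sampling of heading increments, with a temporary
tortuosity escalation to avoid getting stuck at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Environment",
    "Trajectory",
    "containment_deficit",
    "load_trajectory",
    "piecewise_linear_walk",
    "random_walk",
    "save_trajectory",
    "star_walk",
]

TWO_PI = 2.0 * np.pi


@dataclass
class Environment:
    """Arena geometry: infinite plane, square of half-length L, or circle of
    radius R, both centered at the origin."""

    kind: str = "infinite"  # "infinite" | "square" | "circle"
    half_length: float = 0.0  # L (cm), square
    radius: float = 0.0  # R (cm), circle

    def __post_init__(self) -> None:
        if self.kind not in ("infinite", "square", "circle"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if self.kind == "square" and not self.half_length > 0:
            raise ValueError("square environment requires half_length > 0")
        if self.kind == "circle" and not self.radius > 0:
            raise ValueError("circle environment requires radius > 0")

    @property
    def finite(self) -> bool:
        return self.kind != "infinite"

    def contains(self, point) -> bool:
        return not np.any(containment_deficit(point, self)) if self.finite else True


def containment_deficit(point, env: Environment) -> tuple[float, float, float]:
    """(dx, dy, dr): how far ``point`` lies outside ``env`` along each test.

    For squares ``dx = max(|x| - L, 0)`` and ``dy = max(|y| - L, 0)``; for
    circles ``dr = max(||r|| - R, 0)``.  All three are zero iff the point is
    inside.  Rejects infinite environments (the test is vacuous there).
    """
    if not env.finite:
        raise ValueError("containment_deficit requires a finite environment")
    x, y = float(point[0]), float(point[1])
    if env.kind == "square":
        return (
            max(abs(x) - env.half_length, 0.0),
            max(abs(y) - env.half_length, 0.0),
            0.0,
        )
    return (0.0, 0.0, max(np.hypot(x, y) - env.radius, 0.0))


@dataclass
class Trajectory:
    """A discretized constant-speed path.

    Attributes
    ----------
    dt : time step (s).
    speed : movement speed v (cm/s).
    positions : (M, 2) start position of each step (cm).
    directions : (M,) movement direction of each step (rad, in [0, 2*pi)).
    segment_id : (M,) integer label of the contiguous linear piece.
    teleport : (M,) True where the step position jumped discontinuously.
    """

    dt: float
    speed: float
    positions: np.ndarray
    directions: np.ndarray
    segment_id: np.ndarray = None
    teleport: np.ndarray = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.directions = np.mod(np.asarray(self.directions, dtype=float), TWO_PI)
        m = len(self.directions)
        if self.positions.shape != (m, 2):
            raise ValueError("positions must have shape (M, 2)")
        if self.segment_id is None:
            self.segment_id = np.zeros(m, dtype=np.int64)
        if self.teleport is None:
            self.teleport = np.zeros(m, dtype=bool)
        self.segment_id = np.asarray(self.segment_id, dtype=np.int64)
        self.teleport = np.asarray(self.teleport, dtype=bool)

    @property
    def n_steps(self) -> int:
        return len(self.directions)

    @property
    def step_length(self) -> float:
        return self.speed * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    @property
    def step_vectors(self) -> np.ndarray:
        """(M, 2) displacement of each step, v*dt*(cos, sin)."""
        return self.step_length * np.stack(
            [np.cos(self.directions), np.sin(self.directions)], axis=1
        )

    @property
    def midpoints(self) -> np.ndarray:
        """(M, 2) midpoint of each step; used by midpoint-rule averaging."""
        return self.positions + 0.5 * self.step_vectors

    @property
    def endpoints(self) -> np.ndarray:
        """(M, 2) end position of each step."""
        return self.positions + self.step_vectors

    def segment_slices(self) -> list[slice]:
        """Slices of contiguous steps sharing a segment_id."""
        breaks = np.flatnonzero(np.diff(self.segment_id) != 0) + 1
        edges = np.concatenate([[0], breaks, [self.n_steps]])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _validate_common(dt: float, v: float) -> None:
    for name, val in (("dt", dt), ("v", v)):
        if not (np.isfinite(val) and val > 0):
            raise ValueError(f"{name} must be finite and positive, got {val}")


def random_walk(
    T: float,
    dt: float = 0.01,
    v: float = 10.0,
    sigma_theta: float = 0.5,
    seed: int | np.random.Generator | None = None,
    env: Environment | None = None,
    theta0: float | None = None,
    start: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Correlated random walk with heading diffusion ``sigma_theta``.

    The heading is updated per step by a Gaussian increment with variance
    ``sigma_theta**2 * dt``.  In finite arenas, increments leading out of
    bounds are resampled; after every 50 consecutive rejections the working
    tortuosity is multiplied by 1.1, and it resets to ``sigma_theta`` on the
    first accepted step.  The walk starts at the arena center with a heading
    drawn uniformly from [0, 2*pi) unless ``theta0`` is given.
    """
    _validate_common(dt, v)
    if not (np.isfinite(T) and T > 0):
        raise ValueError("T must be finite and positive")
    if not (np.isfinite(sigma_theta) and sigma_theta >= 0):
        raise ValueError("sigma_theta must be finite and >= 0")
    env = env or Environment()
    if env.kind == "square" and v * dt >= 2 * env.half_length:
        raise ValueError("arena smaller than one step")
    if env.kind == "circle" and v * dt >= 2 * env.radius:
        raise ValueError("arena smaller than one step")

    m = int(np.floor(T / dt))
    if abs(m * dt - T) > 1e-9 * dt:
        logger.info("random_walk: T not divisible by dt, truncating to %d steps", m)
    rng = np.random.default_rng(seed)
    th0 = rng.uniform(0.0, TWO_PI) if theta0 is None else float(theta0)

    if not env.finite:
        theta = th0 + sigma_theta * np.cumsum(
            np.concatenate([[0.0], rng.normal(0.0, np.sqrt(dt), m - 1)])
        )
        steps = v * dt * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        positions = np.asarray(start, dtype=float) + np.concatenate(
            [np.zeros((1, 2)), np.cumsum(steps[:-1], axis=0)]
        )
        # heading changes every step: each step is its own linear piece
        return Trajectory(
            dt=dt,
            speed=v,
            positions=positions,
            directions=theta,
            segment_id=np.arange(m),
        )

    theta = np.empty(m)
    positions = np.empty((m, 2))
    pos = np.asarray(start, dtype=float)
    th = th0
    sd = np.sqrt(dt)
    work_sigma = sigma_theta
    rejections = 0
    for i in range(m):
        theta[i] = th
        positions[i] = pos
        if i == m - 1:
            break
        # step i displaces along theta_i; candidate headings for the next
        # step are resampled until the resulting position stays inside
        pos = pos + v * dt * np.array([np.cos(th), np.sin(th)])
        while True:
            cand = th + work_sigma * rng.normal(0.0, sd)
            nxt = pos + v * dt * np.array([np.cos(cand), np.sin(cand)])
            if env.contains(nxt):
                th = cand
                work_sigma = sigma_theta
                rejections = 0
                break
            rejections += 1
            if rejections % 50 == 0:
                work_sigma *= 1.1
    return Trajectory(
        dt=dt,
        speed=v,
        positions=positions,
        directions=theta,
        segment_id=np.arange(m),
    )


def _segment_layout(n_angles: int, r_max: float, v: float, dt: float) -> int:
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    if not r_max > 0:
        raise ValueError("r_max must be > 0")
    step = v * dt
    n_steps = int(np.floor(r_max / step + 1e-9))
    if abs(n_steps * step - r_max) > 1e-9 * r_max:
        logger.info(
            "segment length %.6g not a multiple of v*dt=%.6g; dropping partial step",
            r_max,
            step,
        )
    if n_steps < 1:
        raise ValueError("r_max shorter than one step")
    return n_steps


def star_walk(
    n_angles: int = 360,
    r_max: float = 300.0,
    v: float = 10.0,
    dt: float = 0.01,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Star-like walk: ``n_angles`` radial segments of length ``r_max`` from a
    common origin at equally spaced directions ``2*pi*i/n_angles`` (sampled
    consecutively), teleporting back to the origin between segments."""
    _validate_common(dt, v)
    n_steps = _segment_layout(n_angles, r_max, v, dt)
    angles = TWO_PI * np.arange(n_angles) / n_angles
    r = np.arange(n_steps) * v * dt
    origin = np.asarray(origin, dtype=float)

    directions = np.repeat(angles, n_steps)
    cossin = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (n_angles, 2)
    positions = origin + (r[None, :, None] * cossin[:, None, :]).reshape(-1, 2)
    segment_id = np.repeat(np.arange(n_angles), n_steps)
    teleport = np.zeros(n_angles * n_steps, dtype=bool)
    teleport[n_steps::n_steps] = True
    return Trajectory(
        dt=dt,
        speed=v,
        positions=positions,
        directions=directions,
        segment_id=segment_id,
        teleport=teleport,
    )


def piecewise_linear_walk(
    n_angles: int = 360,
    r_max: float = 300.0,
    v: float = 10.0,
    dt: float = 0.01,
    seed: int | np.random.Generator | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Piecewise-linear walk: the star-like segments placed end to end as one
    continuous path, with the ``n_angles`` directions visited exactly once in
    uniformly random order."""
    _validate_common(dt, v)
    n_steps = _segment_layout(n_angles, r_max, v, dt)
    rng = np.random.default_rng(seed)
    angles = TWO_PI * rng.permutation(n_angles) / n_angles
    seg_len = n_steps * v * dt
    seg_vec = seg_len * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    seg_starts = np.asarray(origin, dtype=float) + np.concatenate(
        [np.zeros((1, 2)), np.cumsum(seg_vec[:-1], axis=0)]
    )
    r = np.arange(n_steps) * v * dt
    cossin = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    positions = (seg_starts[:, None, :] + r[None, :, None] * cossin[:, None, :]).reshape(
        -1, 2
    )
    return Trajectory(
        dt=dt,
        speed=v,
        positions=positions,
        directions=np.repeat(angles, n_steps),
        segment_id=np.repeat(np.arange(n_angles), n_steps),
    )


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as tab-separated text (t, x, y, theta, segment_id,
    teleport), with units recorded in header comments."""
    df = pd.DataFrame(
        {
            "t": traj.times,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "theta": traj.directions,
            "segment_id": traj.segment_id,
            "teleport": traj.teleport.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# dt={traj.dt} s, v={traj.speed} cm/s; t in s, x/y in cm, theta in rad\n")
        df.to_csv(fh, sep="\t", index=False)


def load_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`save_trajectory` (or any tabular
    file with columns t, x, y, theta and optional segment_id/teleport)."""
    with open(path) as fh:
        header = fh.readline()
        dt = v = None
        if header.startswith("#"):
            for tok in header.replace(",", " ").split():
                if tok.startswith("dt="):
                    dt = float(tok[3:])
                elif tok.startswith("v="):
                    v = float(tok[2:])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    t = df["t"].to_numpy()
    if dt is None:
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    pos = df[["x", "y"]].to_numpy()
    if v is None:
        d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        v = float(np.median(d) / dt) if len(d) else 1.0
    return Trajectory(
        dt=dt,
        speed=v,
        positions=pos,
        directions=df["theta"].to_numpy(),
        segment_id=df["segment_id"].to_numpy() if "segment_id" in df else None,
        teleport=df["teleport"].to_numpy().astype(bool) if "teleport" in df else None,
    )
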