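"""Grid-cell firing-rate model and phase-offset geometry.

A grid cell fires on the vertices of a triangular lattice.  Its rate map is
modeled as a product of three cosine gratings whose wavevectors are rotated
by 60 degrees from each other,

    G(x, y) = (Amax / 8) * prod_k (1 + cos[k_k . (r - b)]),   k = 0, 1, 2,

with wavevector magnitude ``a = 4*pi / (sqrt(3)*s)`` for grid spacing ``s``
and directions ``(sin(pi*k/3 + gamma), cos(pi*k/3 + gamma))`` for grid
orientation ``gamma``.  The Cartesian phase offset ``b`` places one firing
field at ``b``; the rate there is exactly ``Amax`` and the spatial mean over
one lattice cell is ``5*Amax/32``.

Phase offsets live on the unit rhombus (the fundamental domain of the
lattice).  They are stored in *square* coordinates ``(xhat, yhat)`` in
[0, 1)^2 and mapped to rhombus (Cartesian, units of the spacing) coordinates
with :func:`rhombus_map`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GridParams",
    "GridPopulation",
    "grid_rate",
    "min_phase_distance",
    "rhombus_map",
    "rhombus_unmap",
    "sample_phases",
    "wavevectors",
]

#: rhombus lattice translates used for toroidal phase distances (3 x 3 copies)
_RHOMBUS_TRANSLATES = np.array(
    [
        (i * 1.0 + j * 0.5, j * np.sqrt(3.0) / 2.0)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
    ]
)


def wavevectors(spacing: float, orientation: float = 0.0) -> np.ndarray:
    """The three grating wavevectors, shape (3, 2), units cm^-1.

    Magnitude ``4*pi/(sqrt(3)*spacing)`` makes the distance between adjacent
    firing-field centers exactly ``spacing``.
    """
    a = 4.0 * np.pi / (np.sqrt(3.0) * spacing)
    k = np.arange(3)
    return a * np.stack(
        [np.sin(np.pi / 3.0 * k + orientation), np.cos(np.pi / 3.0 * k + orientation)],
        axis=1,
    )


def rhombus_map(square_coords: np.ndarray) -> np.ndarray:
    """Map unit-square phase coordinates to unit-rhombus coordinates.

    ``(xhat, yhat) -> (xhat + yhat/2, sqrt(3)/2 * yhat)``.  The map is a
    shear, so the uniform distribution on the square maps to the uniform
    distribution on the rhombus.  Inputs outside [0, 1) are wrapped.
    """
    sq = np.asarray(square_coords, dtype=float)
    if np.any((sq < 0.0) | (sq >= 1.0)):
        logger.info("rhombus_map: wrapping out-of-range square coordinates modulo 1")
        sq = np.mod(sq, 1.0)
    xh, yh = sq[..., 0], sq[..., 1]
    return np.stack([xh + yh / 2.0, np.sqrt(3.0) / 2.0 * yh], axis=-1)


def rhombus_unmap(rhombus_coords: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rhombus_map` (rhombus -> square coordinates)."""
    rc = np.asarray(rhombus_coords, dtype=float)
    yh = rc[..., 1] * 2.0 / np.sqrt(3.0)
    xh = rc[..., 0] - yh / 2.0
    return np.stack([xh, yh], axis=-1)


@dataclass
class GridParams:
    """Parameters of a single grid cell.

    Attributes
    ----------
    amax : peak firing rate (spk/s).
    spacing : grid spacing s (cm), distance between adjacent field centers.
    orientation : grid orientation gamma (rad).
    phase : (xhat, yhat) phase offset in unit-square coordinates, each in
        [0, 1).  The Cartesian offset is ``spacing * rhombus_map(phase)``.
    """

    amax: float = 8.0
    spacing: float = 30.0
    orientation: float = 0.0
    phase: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.amax > 0 and self.spacing > 0):
            raise ValueError("amax and spacing must be positive")

    @property
    def cartesian_offset(self) -> np.ndarray:
        """Cartesian offset b = s * rhombus_map(phase), shape (2,), cm."""
        return self.spacing * rhombus_map(np.asarray(self.phase))


@dataclass
class GridPopulation:
    """A population of N grid cells sharing spacing and orientation.

    Only the phase offsets differ between cells; head-direction tuning and
    adaptation parameters are attached at evaluation time (see
    :mod:`gridhex.hypotheses`).
    """

    phases: np.ndarray  # (N, 2) square coordinates in [0, 1)
    amax: float = 8.0
    spacing: float = 30.0
    orientation: float = 0.0

    def __post_init__(self) -> None:
        self.phases = np.atleast_2d(np.asarray(self.phases, dtype=float))
        if self.phases.shape[1] != 2:
            raise ValueError("phases must have shape (N, 2)")
        if not (self.amax > 0 and self.spacing > 0):
            raise ValueError("amax and spacing must be positive")

    @property
    def n_cells(self) -> int:
        return self.phases.shape[0]

    @property
    def cartesian_offsets(self) -> np.ndarray:
        """Per-cell Cartesian offsets b_i, shape (N, 2), cm."""
        return self.spacing * rhombus_map(self.phases)

    def phase_constants(self) -> np.ndarray:
        """Per-cell grating phase constants e_k = k_k . b_i, shape (3, N)."""
        return wavevectors(self.spacing, self.orientation) @ self.cartesian_offsets.T

    def cell(self, i: int) -> GridParams:
        return GridParams(
            amax=self.amax,
            spacing=self.spacing,
            orientation=self.orientation,
            phase=tuple(self.phases[i]),
        )


def grid_rate(x, y, cell: GridParams | GridPopulation):
    """Firing rate (spk/s) of one cell -- or of each cell of a population --
    at Cartesian position(s) (x, y) in cm.

    For a :class:`GridParams` the output matches the broadcast shape of
    ``x``/``y``; for a :class:`GridPopulation` an axis of length N is
    prepended.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("coordinates must be finite")
    if isinstance(cell, GridPopulation):
        kk = wavevectors(cell.spacing, cell.orientation)  # (3, 2)
        e = cell.phase_constants()  # (3, N)
        phase = kk[:, 0, None] * x.ravel()[None, :] + kk[:, 1, None] * y.ravel()[None, :]
        g = cell.amax / 8.0 * np.prod(
            1.0 + np.cos(phase[:, None, :] - e[:, :, None]), axis=0
        )
        return g.reshape((cell.n_cells,) + x.shape)
    kk = wavevectors(cell.spacing, cell.orientation)
    b = cell.cartesian_offset
    g = cell.amax / 8.0
    for k in range(3):
        g = g * (1.0 + np.cos(kk[k, 0] * (x - b[0]) + kk[k, 1] * (y - b[1])))
    return g


def sample_phases(
    n: int,
    mode: str = "uniform",
    mu_s: tuple[float, float] = (0.0, 0.0),
    kappa_s: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw N phase offsets in square coordinates, shape (N, 2).

    ``mode="uniform"`` draws uniformly on the unit rhombus (uniform square
    coordinates).  ``mode="clustered"`` draws each axis independently from a
    von Mises distribution centered at ``2*pi*mu_s`` with concentration
    ``kappa_s``, rescaled to [0, 1); ``kappa_s = 0`` reduces to uniform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        return rng.uniform(0.0, 1.0, size=(n, 2))
    if mode == "clustered":
        if kappa_s < 0:
            raise ValueError("kappa_s must be >= 0")
        out = np.empty((n, 2))
        for axis in range(2):
            ang = rng.vonmises(2.0 * np.pi * mu_s[axis], kappa_s, size=n)
            out[:, axis] = np.mod(ang / (2.0 * np.pi), 1.0)
        return out
    raise ValueError(f"unknown mode {mode!r}; use 'uniform' or 'clustered'")


def min_phase_distance(p, q) -> np.ndarray:
    """Toroidal Euclidean distance between phases on the unit rhombus.

    ``p`` and ``q`` are square-coordinate phases (last axis length 2); the
    distance is minimized over the 3 x 3 rhombus translates of ``q`` so that
    phases near opposite edges of the fundamental domain are recognized as
    close.  Symmetric, and zero iff the phases coincide modulo the lattice.
    """
    pr = rhombus_map(np.asarray(p, dtype=float))
    qr = rhombus_map(np.asarray(q, dtype=float))
    diff = pr[..., None, :] - (qr[..., None, :] + _RHOMBUS_TRANSLATES)  # (..., 9, 2)
    return np.sqrt(np.sum(diff**2, axis=-1)).min(axis=-1)
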