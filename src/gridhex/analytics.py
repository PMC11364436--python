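"""Closed-form line integrals of grid activity and path-hexasymmetry theory.

Averaging the triple-cosine grid rate along a straight ray at angle ``psi``
from radius ``r0`` to ``r1`` has an exact antiderivative.  Expanding the
product gives a constant part, three single-grating terms, three pairwise
products and one triple product; each oscillatory term integrates to
``sin(d*r - e)/d`` where ``d`` is the projection of the (summed) wavevector
onto the ray and ``e`` the corresponding phase constant.  Whenever a
projected frequency ``d`` vanishes the term degenerates to a linear ramp
``r*cos(e)``; all of these limit branches are implemented and are exercised
on every star-like walk (the projections vanish at directions perpendicular
to a grating).  Notably ``d0 - d1 + d2 = 0`` identically, which is what
makes the spatial mean of the rate ``5*Amax/32`` rather than ``Amax/8``.

The second half of the module gives the expectation of the squared path
hexasymmetry of a correlated random walk.  Heading differences after
``m`` steps are wrapped-normal with variance ``m*sigma_theta**2*dt``, so
``E(cos 6(theta_m1 - theta_m2)) = exp(-alpha*|m1 - m2|)`` with
``alpha = 18*sigma_theta**2*dt``, and the double sum over step pairs has a
geometric-series closed form.
"""

from __future__ import annotations

import numpy as np

from .gridpop import GridParams, GridPopulation, wavevectors

__all__ = [
    "equivalent_step_factor",
    "expected_sq_path_hex",
    "mean_rate_on_general_segment",
    "mean_rate_on_segment",
    "path_hex_bound",
    "segment_mean_matrix",
]

#: relative tolerance (vs the wavevector magnitude) for degenerate branches
DEGENERATE_RTOL = 1e-12


def segment_mean_matrix(
    directions: np.ndarray,
    pop: GridPopulation,
    r0: float = 0.0,
    r1: float = 300.0,
    phase_shift: np.ndarray | None = None,
) -> np.ndarray:
    """Mean rate of each cell along rays from radius ``r0`` to ``r1``.

    Parameters
    ----------
    directions : (n_dir,) ray angles psi (rad); rays start on the line
        through the origin.
    pop : the population whose cells are averaged.
    phase_shift : optional (3, n_dir) additive shift of the grating phase
        constants, used to move a segment's start point into the cell
        offsets (see :func:`mean_rate_on_general_segment`).

    Returns
    -------
    (n_dir, N) array of exact segment-averaged rates (spk/s).
    """
    directions = np.atleast_1d(np.asarray(directions, dtype=float))
    if not r1 > r0:
        raise ValueError("requires r1 > r0")
    kk = wavevectors(pop.spacing, pop.orientation)  # (3, 2)
    a = float(np.linalg.norm(kk[0]))
    cospsi, sinpsi = np.cos(directions), np.sin(directions)
    d = kk[:, 0, None] * cospsi[None, :] + kk[:, 1, None] * sinpsi[None, :]  # (3, n_dir)
    e = pop.phase_constants()  # (3, N)
    if phase_shift is not None:
        e = e[:, None, :] - np.asarray(phase_shift)[:, :, None]  # (3, n_dir, N)

    dr = r1 - r0
    tol = DEGENERATE_RTOL * a

    def accumulate(total, dsum, esum, coef):
        # dsum (n_dir,), esum (N,) or (n_dir, N) -> adds (n_dir, N)
        degenerate = np.abs(dsum) < tol
        dsafe = np.where(degenerate, 1.0, dsum)[:, None]
        if esum.ndim == 1:
            esum = esum[None, :]
        general = (np.sin(r1 * dsafe - esum) - np.sin(r0 * dsafe - esum)) / dsafe
        limit = np.cos(esum) * dr
        total += coef * np.where(degenerate[:, None], limit, general)
        return total

    n_cells = e.shape[-1]
    total = np.full((len(directions), n_cells), dr)
    for k in range(3):  # single gratings
        total = accumulate(total, d[k], e[k], 1.0)
    for k, l in ((0, 1), (0, 2), (1, 2)):  # pairwise products
        for sgn in (1.0, -1.0):
            total = accumulate(total, d[k] + sgn * d[l], e[k] + sgn * e[l], 0.5)
    for s1 in (1.0, -1.0):  # triple product
        for s2 in (1.0, -1.0):
            total = accumulate(
                total, d[0] + s1 * d[1] + s2 * d[2], e[0] + s1 * e[1] + s2 * e[2], 0.25
            )
    return pop.amax / 8.0 * total / dr


def mean_rate_on_segment(r0: float, r1: float, psi: float, cell: GridParams) -> float:
    """Exact average rate of ``cell`` along the ray at angle ``psi`` between
    radii ``r0`` and ``r1`` (requires ``r1 > r0``)."""
    pop = GridPopulation(
        phases=np.asarray([cell.phase]),
        amax=cell.amax,
        spacing=cell.spacing,
        orientation=cell.orientation,
    )
    return float(segment_mean_matrix(np.asarray([psi]), pop, r0, r1)[0, 0])


def mean_rate_on_general_segment(p_start, p_end, cell: GridParams) -> float:
    """Exact average rate along the straight segment from ``p_start`` to
    ``p_end`` (Cartesian, cm).

    The segment is shifted to start at the origin by absorbing ``p_start``
    into the cell's phase constants, then the radial formula applies with
    ``r0 = 0`` and ``r1 = |p_end - p_start|``.
    """
    p_start = np.asarray(p_start, dtype=float)
    p_end = np.asarray(p_end, dtype=float)
    delta = p_end - p_start
    length = float(np.hypot(*delta))
    if length <= 0:
        raise ValueError("segment must have positive length")
    psi = float(np.arctan2(delta[1], delta[0]))
    pop = GridPopulation(
        phases=np.asarray([cell.phase]),
        amax=cell.amax,
        spacing=cell.spacing,
        orientation=cell.orientation,
    )
    kk = wavevectors(cell.spacing, cell.orientation)
    shift = (kk @ p_start)[:, None]  # (3, 1)
    return float(
        segment_mean_matrix(np.asarray([psi]), pop, 0.0, length, phase_shift=shift)[0, 0]
    )


def expected_sq_path_hex(
    M: int, sigma_theta: float, dt: float, method: str = "auto"
) -> float:
    """E(|T6|^2) for a random walk of M steps: the expected squared magnitude
    of the sixth circular harmonic of the heading distribution.

    ``method='sum'`` evaluates the O(M^2) double sum directly and serves as
    the oracle for the closed form (``method='closed'``); ``'auto'`` switches
    to the closed form above M = 10^4.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    alpha = 18.0 * sigma_theta**2 * dt
    if method == "auto":
        method = "sum" if M <= 10_000 else "closed"
    if method == "sum":
        m = np.arange(M)
        lag = np.abs(m[:, None] - m[None, :])
        off = np.exp(-alpha * lag[lag > 0].astype(float))
        return float((M + off.sum()) / M**2)
    if method == "closed":
        if alpha == 0.0:
            return 1.0
        q = np.exp(-alpha)
        k = M - 1
        # sum_{m1 != m2} q^|m1-m2| = 2*sum_{m=1}^{M-1} (M-m)*q^m, in closed form
        sum_q = q * (1.0 - q**k) / (1.0 - q)
        sum_mq = q * (1.0 - (k + 1) * q**k + k * q ** (k + 1)) / (1.0 - q) ** 2
        return float((M + 2.0 * (M * sum_q - sum_mq)) / M**2)
    raise ValueError(f"unknown method {method!r}")


def path_hex_bound(
    M: int, sigma_theta: float, dt: float, regime: str = "exact"
) -> float:
    """Upper bound on E(|T6|) of a random walk.

    regime='exact'       sqrt(E(|T6|^2)) (always valid, Jensen).
    regime='large_alpha' 1/sqrt(M): headings decorrelate within one step.
    regime='geometric'   sqrt((1/M)*(1 + 2/(e^alpha - 1))): M*alpha >> 1.
    regime='small_alpha' (1/sqrt(M))/(3*sigma_theta*sqrt(dt)): additionally
                         alpha << 1.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    alpha = 18.0 * sigma_theta**2 * dt
    if regime == "exact":
        return float(np.sqrt(expected_sq_path_hex(M, sigma_theta, dt)))
    if regime == "large_alpha":
        return float(1.0 / np.sqrt(M))
    if regime == "geometric":
        return float(np.sqrt((1.0 + 2.0 / np.expm1(alpha)) / M))
    if regime == "small_alpha":
        return float(1.0 / (np.sqrt(M) * 3.0 * sigma_theta * np.sqrt(dt)))
    raise ValueError(f"unknown regime {regime!r}")


def equivalent_step_factor(
    sigma_a: float, dt_a: float, sigma_b: float, dt_b: float
) -> float:
    """Step-count multiplier matching the expected path hexasymmetry of two
    random walks: walk B needs ``Delta_M * M_A`` steps, with
    ``Delta_M = (sigma_a^2 * dt_a) / (sigma_b^2 * dt_b)``."""
    if min(sigma_a, sigma_b) <= 0 or min(dt_a, dt_b) <= 0:
        raise ValueError("parameters must be positive")
    return float((sigma_a**2 * dt_a) / (sigma_b**2 * dt_b))
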