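"""Hexasymmetry statistics and legacy direction-modulation metrics.

The central statistic is the magnitude of the sixth circular Fourier
harmonic of direction-resolved population activity,

    H = | (1/M) * sum_m  Abar_m * exp(-6j * theta_m) |      (spk/s),

where ``Abar_m`` is the segment-averaged summed activity while moving along
direction ``theta_m``.  A pure hexadirectional sinusoid
``Abar = c*(1 + cos 6(theta - phi))`` gives ``H = c/2`` -- half its
amplitude -- and a direction-independent profile gives ``H = 0``.  The same
harmonic of the bare direction distribution, ``|T6|``, is the *path*
hexasymmetry: the part of H that the trajectory alone would contribute,
``|T6| * A0``, is the natural reference against which H is tested
(Mann-Whitney U across realizations).

Three metrics used by earlier fMRI studies are included for comparison: a
two-stage GLM (orientation on the first half, amplitude on the second), the
same with a +/-1 aligned/misaligned binning regressor, and a circular-linear
regression with circular-shift surrogate z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DirectionalProfile",
    "HexResult",
    "LegacyFit",
    "TestResult",
    "apparent_orientation",
    "circular_linear_hexasymmetry",
    "glm_binning_hexasymmetry",
    "glm_hexasymmetry",
    "hex_result",
    "hypothesis_test",
    "neural_hexasymmetry",
    "path_contribution",
    "path_hexasymmetry",
]


@dataclass
class DirectionalProfile:
    """Per-step (or per-segment) mean activity paired with direction."""

    directions: np.ndarray  # (M,) rad
    mean_activity: np.ndarray  # (M,) spk/s

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.mean_activity = np.asarray(self.mean_activity, dtype=float)
        if self.directions.shape != self.mean_activity.shape:
            raise ValueError("directions and mean_activity must have equal length")
        if self.directions.size < 1:
            raise ValueError("profile must contain at least one step")

    @property
    def n_steps(self) -> int:
        return self.directions.size

    def sixth_harmonic(self) -> complex:
        """Complex sixth Fourier coefficient (1/M) * sum A * exp(-6j*theta)."""
        return complex(
            np.mean(self.mean_activity * np.exp(-6j * self.directions))
        )


@dataclass
class HexResult:
    """Summary of one realization: neural hexasymmetry H, mean activity A0,
    path hexasymmetry |T6|, and apparent orientation (deg in [0, 60))."""

    H: float
    A0: float
    T6: float
    orientation: float

    @property
    def contribution(self) -> float:
        """Path contribution |T6| * A0 (spk/s)."""
        return self.T6 * self.A0


@dataclass
class LegacyFit:
    """Output of the legacy two-stage metrics."""

    beta1: float
    beta2: float
    phi: float  # estimated hexadirectional orientation (rad)
    beta: float  # second-half amplitude
    H: float  # hexasymmetry estimate beta/2 (may be negative)
    z: float | None = None  # surrogate z-score (circular-linear metric)


@dataclass
class TestResult:
    U: float
    p: float
    n1: int
    n2: int


def neural_hexasymmetry(profile: DirectionalProfile) -> float:
    """H = |sixth harmonic| of the direction-resolved activity (spk/s)."""
    return abs(profile.sixth_harmonic())


def path_hexasymmetry(directions) -> float:
    """|T6| of a set of movement directions, in [0, 1]."""
    directions = np.asarray(directions, dtype=float)
    if directions.size < 1:
        raise ValueError("need at least one direction")
    return float(np.abs(np.mean(np.exp(-6j * directions))))


def mean_activity(profile: DirectionalProfile) -> float:
    """Time-averaged population activity A0 (spk/s)."""
    return float(np.mean(profile.mean_activity))


def apparent_orientation(profile: DirectionalProfile) -> float:
    """Movement direction (deg, mod 60) of maximal hexadirectional fit.

    Defined as ``-arg(A6)/6`` mapped to [0, 60); undefined (raises) when the
    sixth harmonic vanishes.
    """
    a6 = profile.sixth_harmonic()
    scale = max(float(np.mean(np.abs(profile.mean_activity))), 1.0)
    if abs(a6) <= 1e-12 * scale:
        raise ValueError("apparent orientation undefined for vanishing H")
    return float(np.rad2deg(-np.angle(a6) / 6.0) % 60.0)


def path_contribution(profile: DirectionalProfile) -> float:
    """|T6| * A0: the part of H attributable to the trajectory (spk/s)."""
    return path_hexasymmetry(profile.directions) * mean_activity(profile)


def hex_result(profile: DirectionalProfile) -> HexResult:
    """Bundle H, A0, |T6| and apparent orientation for one realization."""
    h = neural_hexasymmetry(profile)
    try:
        orientation = apparent_orientation(profile)
    except ValueError:
        orientation = np.nan
    return HexResult(
        H=h,
        A0=mean_activity(profile),
        T6=path_hexasymmetry(profile.directions),
        orientation=orientation,
    )


def hypothesis_test(
    h_samples, contribution_samples, alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test of neural hexasymmetries against path
    contributions across realizations."""
    h_samples = np.asarray(h_samples, dtype=float)
    contribution_samples = np.asarray(contribution_samples, dtype=float)
    if min(h_samples.size, contribution_samples.size) < 2:
        raise ValueError("need at least two samples per group")
    if np.array_equal(h_samples, contribution_samples):
        return TestResult(
            U=h_samples.size * contribution_samples.size / 2.0,
            p=1.0,
            n1=h_samples.size,
            n2=contribution_samples.size,
        )
    res = stats.mannwhitneyu(
        contribution_samples, h_samples, alternative=alternative
    )
    return TestResult(
        U=float(res.statistic),
        p=float(res.pvalue),
        n1=h_samples.size,
        n2=contribution_samples.size,
    )


def _halves(profile: DirectionalProfile) -> tuple[slice, slice]:
    m = profile.n_steps
    if m < 2:
        raise ValueError("need at least two steps to split")
    return slice(0, m // 2), slice(m // 2, m)


def _fit_orientation(theta: np.ndarray, activity: np.ndarray) -> tuple[float, float, float]:
    """First-stage quadrature regression (with intercept); returns
    (beta1, beta2, phi)."""
    design = np.column_stack(
        [np.ones_like(theta), np.cos(6.0 * theta), np.sin(6.0 * theta)]
    )
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design: too few distinct directions")
    coef, *_ = np.linalg.lstsq(design, activity, rcond=None)
    beta1, beta2 = float(coef[1]), float(coef[2])
    return beta1, beta2, float(np.arctan2(beta2, beta1) / 6.0)


def glm_hexasymmetry(profile: DirectionalProfile) -> LegacyFit:
    """Two-stage GLM metric: orientation from quadrature regressors on the
    first half, amplitude from ``cos[6(theta - phi)]`` on the second half;
    H = beta/2 and may be negative when the halves disagree."""
    first, second = _halves(profile)
    th, act = profile.directions, profile.mean_activity
    beta1, beta2, phi = _fit_orientation(th[first], act[first])
    design = np.column_stack(
        [np.ones(second.stop - second.start), np.cos(6.0 * (th[second] - phi))]
    )
    coef, *_ = np.linalg.lstsq(design, act[second], rcond=None)
    beta = float(coef[1])
    return LegacyFit(beta1=beta1, beta2=beta2, phi=phi, beta=beta, H=beta / 2.0)


def glm_binning_hexasymmetry(profile: DirectionalProfile) -> LegacyFit:
    """GLM metric with a binary aligned/misaligned regressor: +1 within 15
    degrees (mod 60) of the estimated orientation, -1 otherwise."""
    first, second = _halves(profile)
    th, act = profile.directions, profile.mean_activity
    beta1, beta2, phi = _fit_orientation(th[first], act[first])
    offset = np.rad2deg(th[second] - phi) % 60.0
    aligned = np.where((offset < 15.0) | (offset > 45.0), 1.0, -1.0)
    design = np.column_stack([np.ones_like(aligned), aligned])
    coef, *_ = np.linalg.lstsq(design, act[second], rcond=None)
    beta = float(coef[1])
    return LegacyFit(beta1=beta1, beta2=beta2, phi=phi, beta=beta, H=beta / 2.0)


def circular_linear_hexasymmetry(
    profile: DirectionalProfile,
    n_surrogates: int = 300,
    seed: int | np.random.Generator | None = None,
    segment_steps: int | None = None,
) -> LegacyFit:
    """Circular-linear metric: H = sqrt(beta1^2 + beta2^2)/2 from quadrature
    regressors on the full profile, z-scored against circular-shift
    surrogates.

    Surrogate shifts preserve the multisets of directions and activities:
    uniform random shifts for random walks, integer multiples of
    ``segment_steps`` for star-like / piecewise-linear walks.
    """
    if n_surrogates < 20:
        warnings.warn("fewer than 20 surrogates gives unstable z-scores")
    rng = np.random.default_rng(seed)
    th, act = profile.directions, profile.mean_activity

    def amplitude(theta: np.ndarray) -> tuple[float, float, float]:
        b1, b2, _ = _fit_orientation(theta, act)
        return b1, b2, float(np.hypot(b1, b2) / 2.0)

    beta1, beta2, h = amplitude(th)
    m = profile.n_steps
    if segment_steps:
        n_seg = m // segment_steps
        shifts = rng.integers(1, n_seg, size=n_surrogates) * segment_steps
    else:
        shifts = rng.integers(1, m, size=n_surrogates)
    sur = np.array([amplitude(np.roll(th, int(s)))[2] for s in shifts])
    sd = sur.std(ddof=1)
    z = float((h - sur.mean()) / sd) if sd > 0 else 0.0
    return LegacyFit(
        beta1=beta1,
        beta2=beta2,
        phi=float(np.arctan2(beta2, beta1) / 6.0),
        beta=2.0 * h,
        H=h,
        z=z,
    )
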