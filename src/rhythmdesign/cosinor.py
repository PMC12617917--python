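"""Cosinor model core: designs, design matrices, least-squares fits, simulators.

The cosinor (harmonic regression) model describes a rhythmic signal

    Y(t) = M + A cos(2 pi f t - phi) + eps(t),    eps ~ N(0, sigma^2)

with MESOR ``M`` (Midline Estimating Statistic of Rhythm), amplitude ``A``,
acrophase ``phi`` (radians) and frequency ``f`` in cycles per study interval.
Time is normalised to the unit study interval, so a 24 h study probing a 2 h
period corresponds to ``f = 12``.  Rewriting the cosine through the angle-sum
identity gives a model that is linear in the unknowns,

    Y(t) = b0 + b1 cos(2 pi f t) + b2 sin(2 pi f t) + eps(t),

with ``b1 = A cos(phi)``, ``b2 = A sin(phi)``, which is fitted by ordinary
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SingularDesignError",
    "Design",
    "CosinorParams",
    "LinearCoefficients",
    "FitResult",
    "WaveformKind",
    "OptimizationResult",
    "design_matrix",
    "fit_fixed_period",
    "fit_free_period",
    "simulate_signal",
    "equispaced_design",
    "nyquist_rate",
    "CONDITION_THRESHOLD",
]

#: Condition-number threshold above which a normal-equation matrix is treated
#: as numerically singular (designs probing a frequency they cannot resolve).
CONDITION_THRESHOLD = 1e12


class SingularDesignError(ValueError):
    """The design cannot resolve the requested frequency (X'X singular)."""


@dataclass(frozen=True)
class Design:
    """Ordered measurement times on the unit study interval [0, 1).

    Parameters
    ----------
    times : sequence of float
        Measurement times; sorted on construction.  Raw measurement times
        must be distinct (at most one measurement per linear time); exact
        duplicates are only accepted when ``allow_duplicates`` is set, which
        optimisers use for degenerate intermediate candidates.
    """

    times: np.ndarray
    allow_duplicates: bool = field(default=False, compare=False)

    def __init__(self, times: Sequence[float], allow_duplicates: bool = False):
        t = np.sort(np.asarray(times, dtype=float).ravel())
        if t.size == 0:
            raise ValueError("a design needs at least one measurement time")
        if np.any(t < 0.0) or np.any(t >= 1.0):
            raise ValueError("measurement times must lie in [0, 1)")
        if not allow_duplicates and t.size > 1 and np.any(np.diff(t) <= 0.0):
            raise ValueError(
                "duplicate measurement times; pass allow_duplicates=True "
                "if coincident times are intentional"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "allow_duplicates", allow_duplicates)

    @property
    def n(self) -> int:
        return int(self.times.size)

    def rotated(self, shift: float) -> "Design":
        """Shift all times by ``shift`` modulo the unit interval."""
        return Design(np.mod(self.times + shift, 1.0),
                      allow_duplicates=self.allow_duplicates)

    def reversed(self) -> "Design":
        """Time-reverse the design, t -> 1 - t (mod 1)."""
        return Design(np.mod(1.0 - self.times, 1.0),
                      allow_duplicates=self.allow_duplicates)


def equispaced_design(n: int) -> Design:
    """The n-point equispaced design {0, 1/n, ..., (n-1)/n}."""
    if n < 1:
        raise ValueError("n must be positive")
    return Design(np.arange(n) / n)


def nyquist_rate(n: int) -> float:
    """Nyquist rate N/2 (cycles per study interval) of an N-point equispaced design."""
    return n / 2.0


@dataclass(frozen=True)
class CosinorParams:
    """Signal model parameters: MESOR, amplitude, acrophase, frequency, noise SD."""

    mesor: float
    amplitude: float
    acrophase: float
    frequency: float
    sigma: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.sigma < 0:
            # sigma = 0 is allowed for noise-free simulation; power
            # computations require a strictly positive noise SD.
            raise ValueError("sigma must be non-negative")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def beta(self) -> np.ndarray:
        """Linear coefficients (b0, b1, b2) = (M, A cos phi, A sin phi)."""
        return np.array([
            self.mesor,
            self.amplitude * np.cos(self.acrophase),
            self.amplitude * np.sin(self.acrophase),
        ])

    def mean_curve(self, times: np.ndarray) -> np.ndarray:
        """Noise-free cosinor mean at the given times."""
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * self.frequency * np.asarray(times) - self.acrophase
        )


@dataclass(frozen=True)
class LinearCoefficients:
    beta0: float
    beta1: float
    beta2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.beta1, self.beta2))

    @property
    def acrophase(self) -> float:
        """Acrophase in (-pi, pi] from the two-argument arctangent."""
        return float(np.arctan2(self.beta2, self.beta1))


@dataclass(frozen=True)
class FitResult:
    coefficients: LinearCoefficients
    amplitude_hat: float
    acrophase_hat: float
    frequency_used: float
    rss: float
    tss: float


VALID_WAVEFORMS = ("cosinor", "amplitude_modulated", "rhythmic_noise", "square", "burst")


@dataclass(frozen=True)
class WaveformKind:
    """Waveform family for the signal simulator.

    ``square`` / ``burst`` are 0/A pulse trains with the given duty cycle
    (defaults 0.5 and 0.25).  ``amplitude_modulated`` multiplies the cosine
    amplitude by a slow envelope ``1 + depth * cos(2 pi rate t)``; the
    envelope's functional form is a modelling choice exposed through
    ``envelope_rate`` / ``envelope_depth`` rather than fixed.
    ``rhythmic_noise`` keeps the cosinor mean but modulates the noise SD by
    ``1 + A cos(2 pi f t - phi)``.
    """

    tag: str = "cosinor"
    duty_cycle: float | None = None
    envelope_rate: float = 1.0
    envelope_depth: float = 0.5

    def __post_init__(self):
        if self.tag not in VALID_WAVEFORMS:
            raise ValueError(f"unknown waveform tag {self.tag!r}; "
                             f"expected one of {VALID_WAVEFORMS}")
        duty = self.duty_cycle
        if duty is None:
            duty = 0.25 if self.tag == "burst" else 0.5
        if not 0.0 < duty < 1.0:
            raise ValueError("duty_cycle must lie in (0, 1)")
        object.__setattr__(self, "duty_cycle", duty)


@dataclass(frozen=True)
class OptimizationResult:
    """A design plus method metadata shared by every optimiser in the package."""

    design: Design
    objective: float
    method: str
    trace: np.ndarray | None = None
    seed: int | None = None
    certificate: dict | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Design matrices and least squares
# ---------------------------------------------------------------------------

def design_matrix(design: Design | np.ndarray, frequency: float) -> np.ndarray:
    """Cosinor design matrix X = [1, cos(2 pi f t), sin(2 pi f t)], shape (N, 3)."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    t = design.times if isinstance(design, Design) else np.asarray(design, float)
    w = 2 * np.pi * frequency * t
    return np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])


def _normal_solve(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve the normal equations, raising SingularDesignError when X'X is
    numerically singular (condition number above CONDITION_THRESHOLD)."""
    XtX = X.T @ X
    if np.linalg.cond(XtX) > CONDITION_THRESHOLD:
        raise SingularDesignError(
            "design matrix is numerically singular at this frequency "
            "(too few distinct phases)"
        )
    return np.linalg.solve(XtX, X.T @ y)


def fit_fixed_period(y: Sequence[float], design: Design, frequency: float) -> FitResult:
    """Least-squares cosinor fit at a fixed frequency.

    Returns coefficient estimates together with the derived amplitude
    ``sqrt(b1^2 + b2^2)`` and acrophase ``atan2(b2, b1)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != design.n:
        raise ValueError("response length does not match design size")
    X = design_matrix(design, frequency)
    beta = _normal_solve(X, y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    centred = y - y.mean()
    tss = float(centred @ centred)
    coeff = LinearCoefficients(*beta)
    return FitResult(
        coefficients=coeff,
        amplitude_hat=coeff.amplitude,
        acrophase_hat=coeff.acrophase,
        frequency_used=float(frequency),
        rss=rss,
        tss=tss,
    )


def fit_free_period(
    y: Sequence[float],
    design: Design,
    f_min: float,
    f_max: float,
    n_freq: int,
) -> FitResult:
    """Free-period cosinor fit: grid search for the RSS-minimising frequency.

    The frequency window [f_min, f_max] is discretised on a uniform grid of
    ``n_freq`` points; frequencies where the design is singular are skipped.
    """
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if n_freq < 2:
        raise ValueError("n_freq must be at least 2")
    best: FitResult | None = None
    for f in np.linspace(f_min, f_max, n_freq):
        try:
            fit = fit_fixed_period(y, design, f)
        except SingularDesignError:
            continue
        if best is None or fit.rss < best.rss:
            best = fit
    if best is None:
        raise SingularDesignError(
            "design is singular at every frequency on the grid"
        )
    return best


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------

def simulate_signal(
    params: CosinorParams,
    design: Design,
    waveform: WaveformKind | str = "cosinor",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one dataset at the design's times.

    The ``cosinor`` waveform is the homoscedastic Gaussian model; the other
    tags emulate rhythm shapes that violate cosinor assumptions (pulse trains,
    amplitude-modulated cosines, rhythmically heteroscedastic noise) and are
    used to probe robustness of detection benchmarks.
    """
    if isinstance(waveform, str):
        waveform = WaveformKind(tag=waveform)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = design.times
    z = rng.standard_normal(design.n)
    phase = 2 * np.pi * params.frequency * t - params.acrophase

    if waveform.tag == "cosinor":
        return params.mean_curve(t) + params.sigma * z
    if waveform.tag == "amplitude_modulated":
        envelope = 1.0 + waveform.envelope_depth * np.cos(
            2 * np.pi * waveform.envelope_rate * t
        )
        return params.mesor + params.amplitude * envelope * np.cos(phase) + params.sigma * z
    if waveform.tag == "rhythmic_noise":
        noise = params.sigma * z * (1.0 + params.amplitude * np.cos(phase))
        return params.mean_curve(t) + noise
    if waveform.tag in ("square", "burst"):
        frac = np.mod(params.frequency * t - params.acrophase / (2 * np.pi), 1.0)
        pulse = np.where(frac < waveform.duty_cycle, params.amplitude, 0.0)
        return params.mesor + pulse + params.sigma * z
    raise ValueError(f"unknown waveform tag {waveform.tag!r}")  # pragma: no cover
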