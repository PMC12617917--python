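"""Exact power of the fixed-period cosinor F-test and worst-case criteria.

Detection is the F-test of ``b1 = b2 = 0`` against ``b1 != 0 or b2 != 0``.
At arbitrary measurement times the test statistic follows a noncentral
F(2, N-3) distribution with noncentrality

    lambda = beta' H' (H (X'X)^{-1} H')^{-1} H beta / sigma^2,

where ``H`` selects the two rhythmic coefficients, so the power is the
survival function of that distribution at the central-F critical value.

The matrix ``Binv = (H (X'X)^{-1} H')^{-1}`` admits the closed form
``Xt'Xt - (1/N) b b'`` where ``Xt`` is the trigonometric block of the design
matrix and ``b`` its column sums (a Schur complement in X'X); its smallest
eigenvalue ``xi_min`` governs the worst case over acrophase:

    lambda_worst = (A^2 / sigma^2) * xi_min(Binv),

and maximising ``xi_min`` (E-optimality) maximises worst-case power.  For a
set of candidate frequencies F the design criterion is

    J(t) = min_{f in F} xi_min(Binv(t; f)),

bounded above by N/2, a bound attained by equispaced (and more generally
equiphase) designs at every resolvable frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist, ncf

from .cosinor import (
    CosinorParams,
    Design,
    SingularDesignError,
    design_matrix,
)

__all__ = [
    "PowerSpec",
    "ObjectiveReport",
    "HYPOTHESIS_MATRIX",
    "b_inverse",
    "worstcase_eigenvalue",
    "noncentrality",
    "power_fixed",
    "power_from_lambda",
    "multifreq_objective",
    "worstcase_power_over_acrophase",
    "monte_carlo_power",
]

#: The 2x3 hypothesis matrix selecting the rhythmic coefficients (b1, b2).
HYPOTHESIS_MATRIX = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class PowerSpec:
    """Test specification: type-I error rate, signal amplitude, noise SD."""

    alpha: float = 0.05
    amplitude: float = 1.0
    sigma: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def snr2(self) -> float:
        """Squared amplitude-to-noise ratio A^2 / sigma^2."""
        return (self.amplitude / self.sigma) ** 2


@dataclass(frozen=True)
class ObjectiveReport:
    """Per-frequency minimum eigenvalues and their worst-case summaries."""

    per_frequency_xi_min: dict
    j_value: float
    worst_case_lambda: float
    worst_case_power: float | None
    spec: PowerSpec | None = field(default=None, compare=False)


def _trig_sums(times: np.ndarray, frequency: float):
    w = 2 * np.pi * frequency * times
    c = np.cos(w)
    s = np.sin(w)
    return c, s


def b_inverse(design: Design | np.ndarray, frequency: float) -> np.ndarray:
    """Closed-form inverse of B = H (X'X)^{-1} H' as a 2x2 PSD matrix.

    Computed as ``Xt'Xt - (1/N) b b'`` (trig block minus rank-one mean
    correction), which stays well defined, with a zero eigenvalue, when the
    design is singular at the frequency.
    """
    t = design.times if isinstance(design, Design) else np.asarray(design, float)
    n = t.size
    c, s = _trig_sums(t, frequency)
    sc, ss = c.sum(), s.sum()
    return np.array([
        [c @ c - sc * sc / n, c @ s - sc * ss / n],
        [c @ s - sc * ss / n, s @ s - ss * ss / n],
    ])


def _xi_min_2x2(m: np.ndarray) -> float:
    """Smallest eigenvalue of a symmetric 2x2 matrix, closed form."""
    a, b, d = m[0, 0], m[0, 1], m[1, 1]
    return float((a + d) / 2.0 - np.hypot((a - d) / 2.0, b))


def worstcase_eigenvalue(design: Design | np.ndarray, frequency: float) -> float:
    """xi_min(Binv): smallest eigenvalue of the acrophase-information matrix.

    Lies in [0, N/2]; equals 0 at frequencies the design cannot resolve
    (e.g. an equispaced design at its Nyquist rate) and N/2 at frequencies
    where the design is equiphase.
    """
    xi = _xi_min_2x2(b_inverse(design, frequency))
    # clip tiny negative round-off; the matrix is PSD analytically
    return max(xi, 0.0)


def noncentrality(design: Design, params: CosinorParams) -> float:
    """Noncentrality parameter lambda of the detection F-test.

    Requires N > 3 and a design non-singular at the signal frequency.
    """
    if design.n <= 3:
        raise ValueError("power analysis requires more than 3 measurements")
    if params.sigma <= 0:
        raise ValueError("noncentrality requires sigma > 0")
    # raises SingularDesignError via the condition check
    X = design_matrix(design, params.frequency)
    if np.linalg.cond(X.T @ X) > 1e12:
        raise SingularDesignError(
            "design is singular at the signal frequency; lambda undefined"
        )
    v = params.beta[1:]  # H beta = (A cos phi, A sin phi)
    lam = v @ b_inverse(design, params.frequency) @ v / params.sigma**2
    return float(max(lam, 0.0))


def _noncentral_f_sf(crit: float, dfd: int, lam):
    """Survival of the noncentral F(2, dfd) at ``crit``.

    scipy's ncf degenerates incorrectly at zero noncentrality, where the
    distribution reduces to the central F, so that case is dispatched to
    the central survival function.
    """
    lam = np.asarray(lam, float)
    out = np.where(lam > 0, ncf.sf(crit, 2, dfd, np.where(lam > 0, lam, 1.0)),
                   f_dist.sf(crit, 2, dfd))
    return out


def power_from_lambda(lam: float, n: int, alpha: float) -> float:
    """Power of the F(2, N-3) test at noncentrality ``lam``.

    Defined for any lam >= 0; equals alpha at lam = 0.
    """
    if n <= 3:
        raise ValueError("power analysis requires more than 3 measurements")
    crit = f_dist.ppf(1.0 - alpha, 2, n - 3)
    return float(_noncentral_f_sf(crit, n - 3, lam))


def power_fixed(design: Design, params: CosinorParams, spec: PowerSpec) -> float:
    """Closed-form power of the fixed-period cosinor F-test.

    The amplitude/noise entering the noncentrality are taken from ``params``;
    ``spec`` supplies the type-I error rate.
    """
    lam = noncentrality(design, params)
    return power_from_lambda(lam, design.n, spec.alpha)


def multifreq_objective(
    design: Design,
    frequencies,
    spec: PowerSpec | None = None,
) -> ObjectiveReport:
    """Worst-case-over-frequency design criterion J(t) = min_f xi_min(Binv).

    When a :class:`PowerSpec` is given the report also carries the worst-case
    noncentrality ``(A/sigma)^2 * J`` and the corresponding power; without a
    spec the conversion uses A = sigma (the unit signal-to-noise convention),
    and the power field is left unset.
    """
    freqs = [float(f) for f in np.atleast_1d(np.asarray(frequencies, float))]
    if not freqs:
        raise ValueError("frequency list must be non-empty")
    per = {f: worstcase_eigenvalue(design, f) for f in freqs}
    j = min(per.values())
    snr2 = spec.snr2 if spec is not None else 1.0
    lam = snr2 * j
    power = power_from_lambda(lam, design.n, spec.alpha) if spec is not None else None
    return ObjectiveReport(
        per_frequency_xi_min=per,
        j_value=float(j),
        worst_case_lambda=float(lam),
        worst_case_power=power,
        spec=spec,
    )


def worstcase_power_over_acrophase(
    design: Design,
    frequency: float,
    spec: PowerSpec,
    n_phase: int = 256,
):
    """Scan power over a uniform acrophase grid.

    Returns ``(min_power, max_power, delta)`` with ``delta`` the
    peak-to-trough variability in percentage points of power.  The grid
    minimum converges to the exact worst case, which equals the power at
    noncentrality ``(A/sigma)^2 * xi_min(Binv)``.
    """
    if n_phase < 8:
        raise ValueError("n_phase must be at least 8")
    if design.n <= 3:
        raise ValueError("power analysis requires more than 3 measurements")
    X = design_matrix(design, frequency)
    if np.linalg.cond(X.T @ X) > 1e12:
        raise SingularDesignError("design is singular at this frequency")
    M = b_inverse(design, frequency)
    phis = np.linspace(0.0, 2 * np.pi, n_phase, endpoint=False)
    v = np.stack([np.cos(phis), np.sin(phis)])  # (2, n_phase)
    lam = spec.snr2 * np.einsum("ij,ik,kj->j", v, M, v)
    crit = f_dist.ppf(1.0 - spec.alpha, 2, design.n - 3)
    powers = _noncentral_f_sf(crit, design.n - 3, np.maximum(lam, 0.0))
    pmin, pmax = float(powers.min()), float(powers.max())
    return pmin, pmax, (pmax - pmin) * 100.0


def monte_carlo_power(
    design: Design,
    params: CosinorParams,
    spec: PowerSpec,
    n_sim: int = 20_000,
    seed: int | np.random.Generator = 0,
):
    """Monte-Carlo power estimate (fraction of simulated F-tests rejecting).

    Serves as the simulation oracle for the closed-form power.  Returns
    ``(estimate, standard_error)`` with a binomial standard error.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    if design.n <= 3:
        raise ValueError("power analysis requires more than 3 measurements")
    if params.sigma <= 0:
        raise ValueError("Monte-Carlo power requires sigma > 0")
    X = design_matrix(design, params.frequency)
    if np.linalg.cond(X.T @ X) > 1e12:
        raise SingularDesignError("design is singular at the signal frequency")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = design.n
    mean = params.mean_curve(design.times)
    Y = mean[:, None] + params.sigma * rng.standard_normal((n, n_sim))
    Q, _ = np.linalg.qr(X)
    fitted_ss = np.einsum("ij,ij->j", Q.T @ Y, Q.T @ Y)
    total_ss = np.einsum("ij,ij->j", Y, Y)
    rss = total_ss - fitted_ss
    col_mean = Y.mean(axis=0)
    tss = total_ss - n * col_mean**2
    fstat = (tss - rss) / 2.0 / (rss / (n - 3))
    crit = f_dist.ppf(1.0 - spec.alpha, 2, n - 3)
    estimate = float(np.mean(fstat > crit))
    se = float(np.sqrt(max(estimate * (1 - estimate), 1e-12) / n_sim))
    return estimate, se
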