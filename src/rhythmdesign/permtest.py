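"""Free-period amplitude statistics, permutation p-values, and AUC scoring.

Under continuous period uncertainty the test statistic is built from the
free-period amplitude profile: per grid frequency f in [f_min, f_max] the
least-squares amplitude estimate A_f = ||H beta_f||.  Two summaries are
used: T2, the trapezoidal integral of A_f^2 over the window (mean squared
amplitude up to normalisation), and Tinf, the profile maximum (the analogue
of a periodogram peak).  Both are invariant to permutations of an
exchangeable null sample, so a permutation test applies: the p-value is the
fraction of permutations whose statistic is at least the observed one,
Monte-Carlo estimated with add-one smoothing (never below 1/(n_perm+1)).

Grid frequencies where the design is singular (an equispaced design at its
Nyquist rate) are excluded from the profile, mirroring the usual restriction
to frequencies below ~0.99 of the Nyquist rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cosinor import CONDITION_THRESHOLD, Design, SingularDesignError, design_matrix

__all__ = [
    "FrequencyWindow",
    "PermTestResult",
    "amplitude_profile",
    "stat_T2",
    "stat_Tinf",
    "permutation_pvalue",
    "exact_permutation_pvalue",
    "permutation_power",
    "auc_score",
]


@dataclass(frozen=True)
class FrequencyWindow:
    """Uniform frequency grid on [f_min, f_max] for free-period statistics."""

    f_min: float
    f_max: float
    n_grid: int = 48

    def __post_init__(self):
        if not 0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")
        if self.n_grid < 2:
            raise ValueError("n_grid must be at least 2")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.f_min, self.f_max, self.n_grid)

    def retained(self, design: Design) -> tuple[np.ndarray, np.ndarray]:
        """(retained frequencies, excluded frequencies) for this design.

        A grid frequency is excluded when the design matrix there is
        numerically singular.
        """
        keep, drop = [], []
        for f in self.grid:
            X = design_matrix(design, f)
            if np.linalg.cond(X.T @ X) > CONDITION_THRESHOLD:
                drop.append(f)
            else:
                keep.append(f)
        return np.asarray(keep), np.asarray(drop)


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p_value: float
    n_perm: int
    statistic_kind: str


def _profile_operators(design: Design, window: FrequencyWindow):
    """Per-frequency 2xN operators mapping a response to (b1_hat, b2_hat)."""
    freqs, _ = window.retained(design)
    if freqs.size == 0:
        raise SingularDesignError(
            "design is singular at every frequency in the window"
        )
    ops = np.empty((freqs.size, 2, design.n))
    for i, f in enumerate(freqs):
        X = design_matrix(design, f)
        ops[i] = np.linalg.pinv(X)[1:, :]
    return freqs, ops


def _profiles(ops: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Amplitude profiles for response columns: (n_freq, n_col)."""
    coef = np.einsum("fkn,nc->fkc", ops, Y)
    return np.sqrt(coef[:, 0, :] ** 2 + coef[:, 1, :] ** 2)


def amplitude_profile(y, design: Design, window: FrequencyWindow):
    """Per-frequency amplitude estimates over the retained grid.

    Returns ``(frequencies, amplitudes)``.
    """
    y = np.asarray(y, float).ravel()
    if y.size != design.n:
        raise ValueError("response length does not match design size")
    freqs, ops = _profile_operators(design, window)
    return freqs, _profiles(ops, y[:, None])[:, 0]


def _statistic(freqs: np.ndarray, amps: np.ndarray, kind: str) -> np.ndarray:
    """T2 or Tinf for amplitude profile columns (n_freq, n_col)."""
    if kind == "T2":
        return np.trapezoid(amps**2, freqs, axis=0)
    if kind == "Tinf":
        return amps.max(axis=0)
    raise ValueError("statistic_kind must be 'T2' or 'Tinf'")


def stat_T2(y, design: Design, window: FrequencyWindow) -> float:
    """Integrated squared amplitude over the window (trapezoidal rule)."""
    freqs, amps = amplitude_profile(y, design, window)
    return float(_statistic(freqs, amps[:, None], "T2")[0])


def stat_Tinf(y, design: Design, window: FrequencyWindow) -> float:
    """Maximum amplitude estimate over the window."""
    freqs, amps = amplitude_profile(y, design, window)
    return float(_statistic(freqs, amps[:, None], "Tinf")[0])


def permutation_pvalue(
    y,
    design: Design,
    window: FrequencyWindow,
    statistic_kind: str = "Tinf",
    n_perm: int = 200,
    seed: int | np.random.Generator = 0,
) -> PermTestResult:
    """Monte-Carlo permutation p-value with add-one smoothing.

    p = (1 + #{T(pi y) >= T(y)}) / (n_perm + 1) over uniformly random
    permutations of the response against the fixed measurement times.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    y = np.asarray(y, float).ravel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs, ops = _profile_operators(design, window)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
    Y = np.column_stack([y, perms])
    stats = _statistic(freqs, _profiles(ops, Y), statistic_kind)
    observed = stats[0]
    p = (1.0 + np.sum(stats[1:] >= observed)) / (n_perm + 1.0)
    return PermTestResult(
        statistic=float(observed),
        p_value=float(p),
        n_perm=n_perm,
        statistic_kind=statistic_kind,
    )


def exact_permutation_pvalue(
    y,
    design: Design,
    window: FrequencyWindow,
    statistic_kind: str = "Tinf",
) -> float:
    """Exact average over all n! permutations with a strict inequality.

    The textbook definition of the permutation p-value; only tractable for
    n <= 7 and used as the enumeration oracle for the Monte-Carlo estimator.
    """
    y = np.asarray(y, float).ravel()
    if y.size > 7:
        raise ValueError("exact enumeration limited to n <= 7")
    freqs, ops = _profile_operators(design, window)
    perms = np.array(list(itertools.permutations(y))).T  # (n, n!)
    stats = _statistic(freqs, _profiles(ops, perms), statistic_kind)
    observed = _statistic(freqs, _profiles(ops, y[:, None]), statistic_kind)[0]
    return float(np.mean(stats > observed))


def permutation_power(
    design: Design,
    frequencies,
    acrophases,
    amplitude: float,
    sigma: float,
    alpha: float = 0.05,
    n_samp: int = 100,
    n_perm: int = 100,
    statistic_kind: str = "Tinf",
    seed: int = 0,
    window: FrequencyWindow | None = None,
) -> pd.DataFrame:
    """Permutation-test power on a frequency x acrophase grid.

    Independent cosinor signals are simulated at every (frequency,
    acrophase) cell; each dataset's permutation p-value is compared to
    ``alpha``.  Returns a table with per-cell power and the minimum over
    acrophase per frequency (the worst-case power curve of a free-period
    benchmark).
    """
    freqs_sig = np.atleast_1d(np.asarray(frequencies, float))
    phis = np.atleast_1d(np.asarray(acrophases, float))
    if window is None:
        window = FrequencyWindow(freqs_sig.min(), freqs_sig.max(),
                                 n_grid=2 * freqs_sig.size)
    rng = np.random.default_rng(seed)
    grid_freqs, ops = _profile_operators(design, window)
    t = design.times
    n = design.n
    rows = []
    for f in freqs_sig:
        for phi in phis:
            mean = amplitude * np.cos(2 * np.pi * f * t - phi)
            Y0 = mean[:, None] + sigma * rng.standard_normal((n, n_samp))
            rejections = 0
            for s in range(n_samp):
                y = Y0[:, s]
                perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
                Y = np.column_stack([y, y[perm_idx].T])
                stats = _statistic(grid_freqs, _profiles(ops, Y), statistic_kind)
                p = (1.0 + np.sum(stats[1:] >= stats[0])) / (n_perm + 1.0)
                rejections += p <= alpha
            rows.append({"frequency": float(f), "acrophase": float(phi),
                         "power": rejections / n_samp})
    table = pd.DataFrame(rows)
    worst = table.groupby("frequency")["power"].min().rename("min_power")
    return table.merge(worst, on="frequency")


def auc_score(scores_positive, scores_negative) -> float:
    """Probability that a positive score outranks a negative one (ties half).

    The rank-sum (Mann-Whitney) estimator of the area under the ROC curve.
    """
    pos = np.asarray(scores_positive, float).ravel()
    neg = np.asarray(scores_negative, float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be non-empty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
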