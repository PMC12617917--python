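"""Continuous-time stochastic optimisers and timing-jitter robustness.

For continuous period uncertainty the worst-case fixed-period criterion
J(t) = min_f xi_min(Binv(t; f)) over a frequency window is maximised with a
classic DE/rand/1/bin differential evolution: candidates are built
coordinate-wise from three distinct other members of the current population
and accepted only on strict improvement, so the per-member objective is
monotone.  A constrained stochastic search with anchored times (t_1 = 0,
t_{N/2+1} = 1/2) and a minimum spacing between consecutive measurements is
provided for objectives defined on ordered designs.  Jitter analysis
perturbs a design's times with Gaussian noise (wrapped modulo the study
interval) and tracks the distribution of worst-case power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cosinor import Design, OptimizationResult
from .power import PowerSpec, multifreq_objective

__all__ = [
    "DEConfig",
    "differential_evolution",
    "constrained_search",
    "jitter_design",
    "jitter_robustness_curve",
    "OptimizationResult",
]


@dataclass(frozen=True)
class DEConfig:
    """Differential evolution hyper-parameters.

    Defaults mirror a small-step, low-crossover configuration
    (CR = 0.05, weight = 0.05, population 1000) that explores timing space
    conservatively; reduce ``pop_size``/``n_iter`` for desk-scale runs.
    """

    pop_size: int = 1000
    weight: float = 0.05
    crossover: float = 0.05
    n_iter: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 4:
            raise ValueError("pop_size must be at least 4")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        if not 0.0 < self.crossover < 1.0:
            raise ValueError("crossover must lie in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")


def _as_design(times: np.ndarray) -> Design:
    return Design(np.mod(times, 1.0), allow_duplicates=True)


def differential_evolution(
    objective: Callable[[Design], float],
    n: int,
    config: DEConfig,
    constraint: Callable[[np.ndarray], np.ndarray] | None = None,
) -> OptimizationResult:
    """Maximise ``objective`` over N-point designs with DE/rand/1/bin.

    The population is initialised uniformly on [0, 1)^N.  Per member and
    generation a candidate is assembled coordinate-wise: with probability CR
    the coordinate mutates to ``x_a + weight * (x_b - x_c)`` using three
    distinct other members, otherwise it is copied; the candidate replaces
    the member only when strictly better.  ``constraint`` may remap raw
    candidate coordinates (e.g. to a feasible region) before evaluation.
    """
    rng = np.random.default_rng(config.seed)
    npop = config.pop_size
    pop = rng.random((npop, n))
    if constraint is not None:
        pop = np.apply_along_axis(constraint, 1, pop)

    def score(x: np.ndarray) -> float:
        return float(objective(_as_design(x)))

    fitness = np.array([score(x) for x in pop])
    trace = [float(fitness.max())]
    members = np.arange(npop)
    for _ in range(config.n_iter):
        for i in range(npop):
            others = np.delete(members, i)
            a, b, c = rng.choice(others, size=3, replace=False)
            u = rng.random(n)
            y = np.where(
                u < config.crossover,
                pop[a] + config.weight * (pop[b] - pop[c]),
                pop[i],
            )
            y = np.mod(y, 1.0)
            if constraint is not None:
                y = constraint(y)
            fy = score(y)
            if fy > fitness[i]:
                pop[i] = y
                fitness[i] = fy
        trace.append(float(fitness.max()))
    best = int(np.argmax(fitness))
    design = _as_design(pop[best])
    return OptimizationResult(
        design=design,
        objective=float(fitness[best]),
        method="differential_evolution",
        trace=np.asarray(trace),
        seed=config.seed,
    )


def _repair_anchored(
    times: np.ndarray,
    anchors: dict[int, float],
    epsilon_gap: float,
) -> np.ndarray:
    """Project raw coordinates onto the ordered, anchored, gap-feasible set.

    Times are sorted, anchor positions (0-based indices) are pinned exactly,
    and points between consecutive anchors are spread inside the open anchor
    interval respecting the minimum gap (linear rescaling of ranks when the
    raw spacing is infeasible).
    """
    n = times.size
    t = np.sort(np.mod(times, 1.0))
    if 0 not in anchors:
        anchors = {0: 0.0, **anchors}
    idx = sorted(anchors)
    if [anchors[i] for i in idx] != sorted(anchors[i] for i in idx):
        raise ValueError("anchor values must increase with anchor index")
    bounds = idx + [n]
    out = np.empty(n)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        left = anchors[lo]
        # right boundary: next anchor, or the first anchor one cycle on
        right = anchors[hi] if hi < n else anchors[idx[0]] + 1.0
        out[lo] = left
        k = hi - lo - 1  # interior points of this segment
        if k == 0:
            if right - left < epsilon_gap:
                raise ValueError("anchors closer than the minimum gap")
            continue
        if right - left <= epsilon_gap * (hi - lo):
            raise ValueError("anchors leave no room for the minimum gap")
        interior = np.sort(t[lo + 1: hi])
        # forward pass: each point at least one gap above its predecessor
        prev = left
        for j in range(k):
            interior[j] = max(interior[j], prev + epsilon_gap)
            prev = interior[j]
        # backward pass: each point at least one gap below its successor;
        # feasibility guarantees the result respects the forward bounds too
        nxt = right
        for j in range(k - 1, -1, -1):
            interior[j] = min(interior[j], nxt - epsilon_gap)
            nxt = interior[j]
        out[lo + 1: hi] = interior
    return out


def constrained_search(
    objective: Callable[[Design], float],
    n: int,
    epsilon_gap: float,
    anchors: dict[int, float] | None = None,
    budget: int = 2000,
    seed: int = 0,
    step_init: float = 0.1,
) -> OptimizationResult:
    """Stochastic search over ordered designs with anchored times.

    Default anchors pin the first measurement at 0 and the (N/2+1)-th at
    1/2, keeping candidates spread over the study; consecutive times stay at
    least ``epsilon_gap`` apart.  The objective is pluggable — the
    worst-case fixed-period criterion is the validated default heuristic for
    continuous period uncertainty.  Search is a seeded Gaussian-move hill
    climb with geometrically decaying step size and repair to exact
    feasibility.
    """
    if anchors is None:
        anchors = {0: 0.0, n // 2: 0.5}
    if epsilon_gap <= 0 or epsilon_gap * (n - 1) >= 1.0:
        raise ValueError("need 0 < epsilon_gap and epsilon_gap*(n-1) < 1")
    for i, v in anchors.items():
        if not 0 <= i < n or not 0.0 <= v < 1.0:
            raise ValueError("anchor indices/values out of range")
    rng = np.random.default_rng(seed)

    current = _repair_anchored(np.linspace(0, 1, n, endpoint=False), anchors,
                               epsilon_gap)
    free = np.array([i for i in range(n) if i not in anchors])
    best_val = float(objective(Design(current, allow_duplicates=True)))
    trace = [best_val]
    step = step_init
    for it in range(budget):
        proposal = current.copy()
        proposal[free] += step * rng.standard_normal(free.size)
        try:
            proposal = _repair_anchored(proposal, anchors, epsilon_gap)
        except ValueError:
            continue
        val = float(objective(Design(proposal, allow_duplicates=True)))
        if val > best_val:
            best_val, current = val, proposal
        trace.append(best_val)
        step = max(step * 0.999, 1e-3)
    design = Design(current, allow_duplicates=True)
    return OptimizationResult(
        design=design,
        objective=best_val,
        method="constrained_search",
        trace=np.asarray(trace),
        seed=seed,
        extras={"epsilon_gap": epsilon_gap, "anchors": dict(anchors)},
    )


def jitter_design(
    design: Design,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> Design:
    """Perturb each time with Gaussian noise (SD as a fraction of the study
    interval), wrapping modulo the unit interval and re-sorting."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return design
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.mod(design.times + noise_sd * rng.standard_normal(design.n), 1.0)
    return Design(times, allow_duplicates=True)


def jitter_robustness_curve(
    design: Design,
    frequencies: Sequence[float],
    spec: PowerSpec,
    noise_grid: Sequence[float],
    n_rep: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Distribution of worst-case power under increasing timing jitter.

    For each noise level, ``n_rep`` jittered replicates are scored by the
    worst-case power over the frequency set (via the eigenvalue route, so
    degenerate replicates score at the alpha floor rather than erroring).
    Returns a table of (noise_sd, median, q25, q75).
    """
    if n_rep < 10:
        raise ValueError("n_rep must be at least 10")
    rng = np.random.default_rng(seed)
    rows = []
    for noise in noise_grid:
        if noise == 0:
            report = multifreq_objective(design, frequencies, spec=spec)
            powers = np.full(n_rep, report.worst_case_power)
        else:
            powers = np.empty(n_rep)
            for r in range(n_rep):
                jd = jitter_design(design, noise, rng)
                rep = multifreq_objective(jd, frequencies, spec=spec)
                powers[r] = rep.worst_case_power
        rows.append({
            "noise_sd": float(noise),
            "median": float(np.median(powers)),
            "q25": float(np.quantile(powers, 0.25)),
            "q75": float(np.quantile(powers, 0.75)),
        })
    return pd.DataFrame(rows)
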