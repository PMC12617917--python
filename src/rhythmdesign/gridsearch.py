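"""Discrete design space: necklace enumeration, brute-force and equiphase designs.

When measurements are confined to a uniform partition {k/Nt} with at most one
measurement per slot, a design is a binary occupancy mask with N ones.  Cyclic
rotations of a mask give identical worst-case power (the criterion depends on
times only through phases), so the unconstrained search space is the set of
fixed-density binary necklaces, counted by

    C(N, Nt) = (1/Nt) * sum_{j | gcd(N, Nt)} phi(j) * binom(Nt/j, N/j)

with phi Euler's totient.  Constrained searches (e.g. a rest window that
breaks rotational symmetry) fall back to plain combinations of allowed slots,
scored in vectorised batches via per-slot trigonometric tables.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .cosinor import Design, OptimizationResult, equispaced_design
from .power import multifreq_objective, worstcase_eigenvalue

__all__ = [
    "Partition",
    "GridDesign",
    "ConstraintMask",
    "count_necklaces",
    "enumerate_necklaces",
    "brute_force_optimal",
    "naive_constrained_design",
    "equiphase_construct",
    "is_equiphase",
    "SEARCH_CAP",
]

#: Default cap on the number of candidate masks an exhaustive search will score.
SEARCH_CAP = 20_000_000


@dataclass(frozen=True)
class Partition:
    """Uniform partition of the unit interval into n_t slots at {k/n_t}."""

    n_t: int

    def __post_init__(self):
        if self.n_t < 2:
            raise ValueError("partition needs at least 2 slots")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_t) / self.n_t


@dataclass(frozen=True)
class GridDesign:
    """Binary occupancy mask over a partition; the discrete design encoding."""

    mask: tuple

    def __init__(self, mask: Sequence[int]):
        m = tuple(int(v) for v in mask)
        if any(v not in (0, 1) for v in m):
            raise ValueError("mask entries must be 0 or 1")
        object.__setattr__(self, "mask", m)

    @property
    def n_t(self) -> int:
        return len(self.mask)

    @property
    def n(self) -> int:
        return sum(self.mask)

    @property
    def slots(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.mask))

    def to_design(self) -> Design:
        return Design(self.slots / self.n_t)

    @classmethod
    def from_slots(cls, slots: Iterable[int], n_t: int) -> "GridDesign":
        mask = [0] * n_t
        for s in slots:
            if mask[s]:
                raise ValueError("at most one measurement per slot")
            mask[s] = 1
        return cls(mask)


@dataclass(frozen=True)
class ConstraintMask:
    """Per-slot collection permission (1 = measurement allowed)."""

    allowed: tuple

    def __init__(self, allowed: Sequence[int]):
        a = tuple(int(bool(v)) for v in allowed)
        object.__setattr__(self, "allowed", a)

    @property
    def n_t(self) -> int:
        return len(self.allowed)

    @property
    def allowed_slots(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.allowed))

    @classmethod
    def rest_window(cls, n_t: int, start_slot: int, length_slots: int) -> "ConstraintMask":
        """Disallow the half-open slot range [start, start + length) mod n_t."""
        allowed = [1] * n_t
        for k in range(length_slots):
            allowed[(start_slot + k) % n_t] = 0
        return cls(allowed)


# ---------------------------------------------------------------------------
# Necklace counting and enumeration
# ---------------------------------------------------------------------------

def _totient(m: int) -> int:
    result, p, k = m, 2, m
    while p * p <= k:
        if k % p == 0:
            while k % p == 0:
                k //= p
            result -= result // p
        p += 1
    if k > 1:
        result -= result // k
    return result


def count_necklaces(n: int, n_t: int) -> int:
    """Number of fixed-density binary necklaces with n ones among n_t beads."""
    if not 1 <= n <= n_t:
        raise ValueError("need 1 <= n <= n_t")
    g = math.gcd(n, n_t)
    total = 0
    for j in range(1, g + 1):
        if g % j == 0:
            total += _totient(j) * math.comb(n_t // j, n // j)
    assert total % n_t == 0
    return total // n_t


def enumerate_necklaces(n: int, n_t: int) -> Iterator[GridDesign]:
    """Yield one canonical representative per rotation class.

    Uses the classic prenecklace recursion (FKM scheme) restricted to fixed
    density; each emitted mask is the lexicographically smallest rotation of
    its class.
    """
    if not 1 <= n <= n_t:
        raise ValueError("need 1 <= n <= n_t")
    a = [0] * (n_t + 1)

    def gen(t: int, p: int, ones: int):
        if ones > n or ones + (n_t - t + 1) < n:
            return
        if t > n_t:
            if n_t % p == 0 and ones == n:
                yield GridDesign(a[1:])
            return
        a[t] = a[t - p]
        yield from gen(t + 1, p, ones + a[t])
        if a[t - p] == 0:
            a[t] = 1
            yield from gen(t + 1, t, ones + 1)

    yield from gen(1, 1, 0)


# ---------------------------------------------------------------------------
# Vectorised exhaustive search
# ---------------------------------------------------------------------------

def _slot_tables(n_t: int, frequencies) -> list[np.ndarray]:
    """Per-frequency (n_t, 5) tables of cos^2, sin^2, cos*sin, cos, sin."""
    t = np.arange(n_t) / n_t
    tables = []
    for f in frequencies:
        w = 2 * np.pi * float(f) * t
        c, s = np.cos(w), np.sin(w)
        tables.append(np.stack([c * c, s * s, c * s, c, s], axis=1))
    return tables


def _batch_j(idx: np.ndarray, n: int, tables: list[np.ndarray]) -> np.ndarray:
    """J(t) = min_f xi_min for a batch of slot-index rows, shape (m, n)."""
    j = None
    for V in tables:
        F = V[idx].sum(axis=1)  # (m, 5)
        a = F[:, 0] - F[:, 3] ** 2 / n
        d = F[:, 1] - F[:, 4] ** 2 / n
        b = F[:, 2] - F[:, 3] * F[:, 4] / n
        xi = (a + d) / 2.0 - np.hypot((a - d) / 2.0, b)
        j = xi if j is None else np.minimum(j, xi)
    return np.maximum(j, 0.0)


def _chunked_index_arrays(combos: Iterator[tuple], width: int, chunk: int):
    while True:
        flat = np.fromiter(
            itertools.chain.from_iterable(itertools.islice(combos, chunk)),
            dtype=np.int64,
        )
        if flat.size == 0:
            return
        yield flat.reshape(-1, width)


def brute_force_optimal(
    n: int,
    partition: Partition,
    frequencies,
    constraint: ConstraintMask | None = None,
    cap: int = SEARCH_CAP,
    chunk: int = 500_000,
) -> OptimizationResult:
    """Exhaustive search for the mask maximising min_f xi_min(Binv).

    Without a constraint the search runs over necklace representatives
    (rotational symmetry); with a constraint it runs over all n-subsets of
    the allowed slots.  Ties are broken by the lexicographically smallest
    mask.  The result carries an exhaustiveness certificate.
    """
    n_t = partition.n_t
    freqs = [float(f) for f in np.atleast_1d(np.asarray(frequencies, float))]
    if n < 1 or n > n_t:
        raise ValueError("need 1 <= n <= n_t")

    if constraint is None:
        n_candidates = count_necklaces(n, n_t)
        combos = (tuple(g.slots) for g in enumerate_necklaces(n, n_t))
    else:
        if constraint.n_t != n_t:
            raise ValueError("constraint length does not match partition")
        allowed = constraint.allowed_slots
        if allowed.size < n:
            raise ValueError(
                f"infeasible constraint: only {allowed.size} allowed slots for n={n}"
            )
        n_candidates = math.comb(allowed.size, n)
        combos = (
            tuple(allowed[list(c)])
            for c in itertools.combinations(range(allowed.size), n)
        )
    if n_candidates > cap:
        raise ValueError(
            f"search space of {n_candidates} candidates exceeds the cap of {cap}"
        )

    tables = _slot_tables(n_t, freqs)
    best_j = -np.inf
    best_slots: tuple | None = None
    best_mask: tuple | None = None
    for idx in _chunked_index_arrays(combos, n, chunk):
        jvals = _batch_j(idx, n, tables)
        jmax = float(jvals.max())
        if jmax < best_j:
            continue
        for row in idx[jvals == jmax]:
            slots = tuple(int(v) for v in row)
            slot_set = set(slots)
            mask = tuple(1 if k in slot_set else 0 for k in range(n_t))
            if jmax > best_j or best_mask is None or mask < best_mask:
                best_j, best_slots, best_mask = jmax, slots, mask

    grid = GridDesign.from_slots(best_slots, n_t)
    design = grid.to_design()
    report = multifreq_objective(design, freqs)
    return OptimizationResult(
        design=design,
        objective=report.j_value,
        method="brute_force",
        certificate={"exhaustive": True, "n_candidates": n_candidates,
                     "rotational_symmetry": constraint is None},
        extras={"grid_design": grid, "report": report},
    )


# ---------------------------------------------------------------------------
# Naive constrained designs
# ---------------------------------------------------------------------------

def _allowed_arc(constraint: ConstraintMask) -> tuple[int, int]:
    """(first allowed slot after the window, arc length in slots).

    Requires the allowed slots to form a single circular arc (one rest
    window); the arc runs from the slot after the window end back to the
    window start.
    """
    allowed = np.asarray(constraint.allowed)
    n_t = allowed.size
    if allowed.all():
        return 0, n_t
    if not allowed.any():
        raise ValueError("constraint allows no slots")
    # starts of disallowed runs (circularly)
    blocked = 1 - allowed
    starts = [k for k in range(n_t) if blocked[k] and not blocked[(k - 1) % n_t]]
    if len(starts) != 1:
        raise ValueError("naive design requires a single contiguous rest window")
    w0 = starts[0]
    length = int(blocked.sum())
    return (w0 + length) % n_t, n_t - length


def naive_constrained_design(
    n: int,
    partition: Partition,
    constraint: ConstraintMask,
    snap: bool = False,
) -> Design:
    """Measurements at equal intervals spanning the allowed arc.

    The n times run from the window's end boundary to its start boundary one
    cycle on, endpoints inclusive (spacing span/(n-1)).  With ``snap=True``
    the times are rounded to the nearest partition slot (with a warning when
    rounding actually moves a point), which may be required when downstream
    tooling insists on gridded designs.
    """
    if n < 1:
        raise ValueError("n must be positive")
    n_t = partition.n_t
    arc_start, arc_len = _allowed_arc(constraint)
    if arc_len == n_t:
        return equispaced_design(n)
    if n == 1:
        times = np.array([arc_start / n_t])
    else:
        span = arc_len / n_t
        times = arc_start / n_t + span * np.arange(n) / (n - 1)
    times = np.mod(times, 1.0)
    if snap:
        slots = np.mod(np.rint(times * n_t).astype(int), n_t)
        if np.max(np.abs(np.sort(slots / n_t) - np.sort(times))) > 1e-9:
            warnings.warn(
                "naive design times are off-grid; snapped to nearest slots",
                stacklevel=2,
            )
        if len(set(slots.tolist())) < n:
            raise ValueError("snapping collapses measurement times; grid too coarse")
        times = np.sort(slots) / n_t
    return Design(np.sort(times))


# ---------------------------------------------------------------------------
# Equiphase constructions
# ---------------------------------------------------------------------------

def _match_phase(value: float, pool: list[float], tol: float) -> int | None:
    for i, p in enumerate(pool):
        d = abs(p - value)
        if min(d, 1.0 - d) <= tol:
            return i
    return None


def _partition_uniform(phases: list[float], tol: float) -> bool:
    """Can the phase multiset be split into rotated uniform sets of size >= 3?"""
    if not phases:
        return True
    theta = phases[0]
    rest_count = len(phases)
    for m in range(rest_count, 2, -1):
        pool = phases[1:]
        taken = []
        ok = True
        for k in range(1, m):
            i = _match_phase((theta + k / m) % 1.0, pool, tol)
            if i is None:
                ok = False
                break
            taken.append(pool.pop(i))
        if ok and _partition_uniform(pool, tol):
            return True
    return False


def is_equiphase(design: Design, frequency: int, tol: float = 1e-8) -> bool:
    """True when the phases f*t (mod 1) split into rotated equispaced sets.

    Each set must contain at least 3 distinct phases (the resolvability
    requirement); coincident phases are grouped by multiplicity.  A design
    equiphase at f attains the theoretical maximum xi_min = N/2 there.
    """
    if frequency < 1 or int(frequency) != frequency:
        raise ValueError("is_equiphase expects a positive integer frequency")
    phases = sorted(float(np.mod(frequency * t, 1.0)) for t in design.times)
    return _partition_uniform(phases, tol)


def _ordered_factorizations(n: int, parts: int) -> Iterator[tuple[int, ...]]:
    """Ordered factorizations of n into exactly `parts` factors, each >= 3."""
    if parts == 1:
        if n >= 3:
            yield (n,)
        return
    q = 3
    while q * 3 ** (parts - 1) <= n:
        if n % q == 0:
            for rest in _ordered_factorizations(n // q, parts - 1):
                yield (q,) + rest
        q += 1


def _set_partitions(items: list) -> Iterator[list[list]]:
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
        yield [[head]] + part


def equiphase_construct(n: int, frequencies) -> Design:
    """Construct a design equiphase at every listed integer frequency.

    The construction is a product of levels: level j contributes an
    equispaced ladder of q_j offsets with step 1/(q_j * b_j), where b_j is
    the slowest frequency handled at that level.  A frequency f is handled
    at level j when b_j divides f and the ladder spreads f's phases over at
    least 3 distinct values (q_j / gcd(q_j, f / b_j) >= 3); contributions
    from faster levels shift a phase class by a constant and are absorbed.
    Every feasible split of the frequency set into levels and of n into
    level sizes is tried; failure raises with the obstruction.
    """
    freqs = sorted({int(f) for f in np.atleast_1d(frequencies)})
    if not freqs or freqs[0] < 1:
        raise ValueError("frequencies must be positive integers")
    if any(abs(float(f) - int(f)) > 0 for f in np.atleast_1d(frequencies)):
        raise ValueError("equiphase construction requires integer frequencies")
    if len(freqs) > 6:
        raise ValueError("too many frequencies for constructive search")

    for groups in _set_partitions(freqs):
        groups = sorted(groups, key=min)
        bases = [min(g) for g in groups]
        for sizes in _ordered_factorizations(n, len(groups)):
            ok = True
            for group, base, q in zip(groups, bases, sizes):
                for f in group:
                    if f % base != 0 or q // math.gcd(q, f // base) < 3:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            steps = [1.0 / (q * b) for q, b in zip(sizes, bases)]
            grids = np.meshgrid(*[np.arange(q) for q in sizes], indexing="ij")
            times = np.zeros(n)
            for g, step in zip(grids, steps):
                times = times + g.ravel() * step
            times = np.mod(times, 1.0)
            times.sort()
            if np.unique(np.round(times, 12)).size < n:
                continue
            return Design(times)
    raise ValueError(
        f"no equiphase construction found for n={n}, frequencies={freqs}: "
        "n admits no factorization into level sizes >= 3 spreading every "
        "frequency over >= 3 phases"
    )


def check_equiphase_design(design: Design, frequencies) -> dict:
    """Convenience check: per-frequency xi_min and equiphase flags."""
    freqs = [int(f) for f in np.atleast_1d(frequencies)]
    return {
        f: {
            "xi_min": worstcase_eigenvalue(design, f),
            "equiphase": is_equiphase(design, f),
        }
        for f in freqs
    }
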