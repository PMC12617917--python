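"""Mixed-integer conic program for discrete period uncertainty.

Choosing N of the Nt partition slots so as to maximise the worst-case
criterion min_f xi_min(Binv) is equivalent (via a Schur-complement lift of
the rank-one mean correction) to the mixed-integer semidefinite program

    max eta   s.t.  X(f)' diag(mu) X(f) - eta I  >= 0   for every f,
                    mu binary, sum(mu) = N, eta in [0, N/2],

linear in the occupancy vector mu.  No open MISDP solver is at hand, so the
PSD constraints are enforced by outer approximation: a mixed-integer LINEAR
relaxation (solved with HiGHS through scipy.optimize.milp) carries the
scalar cuts  v' [X' diag(mu) X] v >= eta  for an accumulating set of unit
vectors v; at each incumbent the most negative eigenvector of each
frequency's lifted matrix supplies the next cut.  The relaxation value is
non-increasing, every incumbent is certificate-checked, and termination with
no violated cut proves optimality of the incumbent up to the tolerance.
"""

from __future__ import annotations

import contextlib
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp


@contextlib.contextmanager
def _quiet_fd1():
    """Silence HiGHS' C-level stdout/stderr chatter during MILP solves."""
    try:
        saved = [os.dup(fd) for fd in (1, 2)]
        devnull = os.open(os.devnull, os.O_WRONLY)
        os.dup2(devnull, 1)
        os.dup2(devnull, 2)
        os.close(devnull)
    except OSError:  # pragma: no cover - exotic environments
        yield
        return
    try:
        yield
    finally:
        try:  # flush libc buffers into the null sink before restoring
            import ctypes

            ctypes.CDLL(None).fflush(None)
        except Exception:  # pragma: no cover
            pass
        for fd, s in zip((1, 2), saved):
            os.dup2(s, fd)
            os.close(s)

from .cosinor import design_matrix
from .gridsearch import GridDesign, Partition

__all__ = ["MicpInstance", "MicpResult", "build_instance", "solve_micp",
           "verify_certificate"]


@dataclass(frozen=True)
class MicpInstance:
    """Precomputed data for one conic design problem."""

    n: int
    partition: Partition
    frequencies: tuple
    design_matrices: tuple = field(repr=False)  # one (n_t, 3) array per frequency

    @property
    def eta_bounds(self) -> tuple[float, float]:
        return (0.0, self.n / 2.0)


def build_instance(n: int, partition: Partition, frequencies) -> MicpInstance:
    """Assemble per-slot design matrices so the LMI is linear in the mask.

    The lifted matrix at mask mu is ``X' diag(mu) X = sum_k mu_k x_k x_k'``
    with x_k the k-th row of the full-partition design matrix.
    """
    n_t = partition.n_t
    if not 1 <= n <= n_t:
        raise ValueError("need 1 <= n <= n_t (trivially infeasible budget)")
    freqs = tuple(float(f) for f in np.atleast_1d(np.asarray(frequencies, float)))
    if not freqs:
        raise ValueError("frequency list must be non-empty")
    mats = tuple(design_matrix(partition.times, f) for f in freqs)
    return MicpInstance(n=n, partition=partition, frequencies=freqs,
                        design_matrices=mats)


def lifted_matrix(instance: MicpInstance, mask: np.ndarray, freq_index: int) -> np.ndarray:
    """X' diag(mu) X for one frequency; symmetric by construction."""
    X = instance.design_matrices[freq_index]
    return (X * np.asarray(mask, float)[:, None]).T @ X


@dataclass(frozen=True)
class MicpResult:
    mask: GridDesign
    eta: float
    status: str  # optimal | feasible | infeasible | iteration_limit
    n_cuts: int
    gap: float
    n_iterations: int = 0


def _incumbent_eta(instance: MicpInstance, mask: np.ndarray):
    """Certified objective of a mask: min over frequencies of xi_min, plus
    the worst (frequency, eigenvector) pair for cut generation."""
    worst = np.inf
    worst_pair = None
    for i in range(len(instance.frequencies)):
        M = lifted_matrix(instance, mask, i)
        vals, vecs = np.linalg.eigh(M)
        if vals[0] < worst:
            worst = float(vals[0])
            worst_pair = (i, vecs[:, 0])
    return worst, worst_pair


def verify_certificate(
    mask: GridDesign | np.ndarray,
    eta: float,
    instance: MicpInstance,
    tol: float = 1e-6,
) -> bool:
    """True iff every frequency's lifted matrix minus eta*I is PSD within tol."""
    m = np.asarray(mask.mask if isinstance(mask, GridDesign) else mask, float)
    if int(round(m.sum())) != instance.n:
        raise ValueError("mask cardinality does not match the instance budget")
    for i in range(len(instance.frequencies)):
        M = lifted_matrix(instance, m, i)
        if np.linalg.eigvalsh(M)[0] < eta - tol:
            return False
    return True


def solve_micp(
    instance: MicpInstance,
    max_iter: int = 200,
    tol: float = 1e-6,
    milp_time_limit: float | None = None,
) -> MicpResult:
    """Outer-approximation solve of the mixed-integer conic program.

    Alternates MILP relaxations with eigenvector cut separation until the
    incumbent's smallest eigenvalue certifies the relaxation value (status
    ``optimal``), the iteration budget runs out (``iteration_limit``), or a
    time-limited MILP returns without proof (``feasible``).
    """
    d = instance.partition.n_t
    n_freq = len(instance.frequencies)

    # variables: mu_0..mu_{d-1}, eta
    c = np.zeros(d + 1)
    c[-1] = -1.0
    integrality = np.concatenate([np.ones(d), [0.0]])
    eta_lo, eta_hi = instance.eta_bounds
    bounds = Bounds(lb=np.concatenate([np.zeros(d), [eta_lo]]),
                    ub=np.concatenate([np.ones(d), [eta_hi]]))
    card_row = np.concatenate([np.ones(d), [0.0]])

    cut_rows: list[np.ndarray] = []
    cut_dirs: list[list[np.ndarray]] = [[] for _ in range(n_freq)]

    def add_cut(freq_index: int, v: np.ndarray) -> bool:
        v = v / np.linalg.norm(v)
        for u in cut_dirs[freq_index]:
            if abs(u @ v) > 1.0 - 1e-8:
                return False
        X = instance.design_matrices[freq_index]
        coeffs = (X @ v) ** 2
        cut_rows.append(np.concatenate([coeffs, [-1.0]]))
        cut_dirs[freq_index].append(v)
        return True

    for i in range(n_freq):
        for j in range(3):
            add_cut(i, np.eye(3)[j])

    options = {}
    if milp_time_limit is not None:
        options["time_limit"] = float(milp_time_limit)

    best_mask = None
    best_eta = -np.inf
    relax_eta = eta_hi
    status = "iteration_limit"
    iteration = 0
    for iteration in range(1, max_iter + 1):
        A = np.vstack([card_row] + cut_rows)
        lb = np.concatenate([[instance.n], np.zeros(len(cut_rows))])
        ub = np.concatenate([[instance.n], np.full(len(cut_rows), np.inf)])
        with _quiet_fd1():
            res = milp(c=c, constraints=LinearConstraint(A, lb, ub),
                       integrality=integrality, bounds=bounds, options=options)
        if res.status == 2:  # infeasible
            status = "infeasible"
            break
        if res.x is None:
            raise RuntimeError(f"MILP backend failed: {res.message}")
        mask = np.rint(res.x[:d])
        relax_eta = min(relax_eta, float(res.x[-1]))
        inc_eta, (wi, wv) = _incumbent_eta(instance, mask)
        if inc_eta > best_eta:
            best_eta, best_mask = inc_eta, mask
        if inc_eta >= relax_eta - tol:
            status = "optimal"
            break
        if not add_cut(wi, wv):
            # separation stalled on numerics; incumbent stays certified
            status = "feasible"
            break
        if res.status == 1:  # hit the MILP time limit
            status = "feasible"
    if status == "infeasible" or best_mask is None:
        raise ValueError("conic program infeasible for this budget")
    grid = GridDesign(best_mask.astype(int))
    return MicpResult(
        mask=grid,
        eta=float(best_eta),
        status=status,
        n_cuts=len(cut_rows),
        gap=float(max(relax_eta - best_eta, 0.0)),
        n_iterations=iteration,
    )
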