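# Methods

## Model and conventions

The package works with the single-component cosinor model
`Y(t) = M + A cos(2πft − φ) + ε(t)`, `ε ~ N(0, σ²)` i.i.d.
(homoscedastic), fitted by ordinary least squares in its linear form
`β₀ + β₁cos(2πft) + β₂sin(2πft)`. Conventions used throughout:

* **Time** is normalised to the unit study interval; **frequency** is in
  cycles per interval (a 24 h study probing a 2 h period has f = 12). This
  makes the Nyquist rate of an N-point equispaced design the unitless
  N/2. The CLI and JSON design format convert physical units via a
  `study_length` field.
* **Acrophase** φ follows the `cos(2πft − φ)` convention and estimates are
  reported in (−π, π] from `atan2(β̂₂, β̂₁)`.
* **Singularity**: a design is treated as unable to resolve a frequency
  when cond(XᵀX) > 1e12 (e.g. an equispaced design at an integer multiple
  of its Nyquist rate). Fitting and power evaluation raise a
  `SingularDesignError` there; the eigenvalue criterion instead returns 0,
  so optimisers can score degenerate candidates continuously.
* **Randomness**: every stochastic routine takes an explicit seed (or a
  shared `numpy` Generator) and is bit-reproducible given it.

## Exact power and the worst-case criterion

Under the alternative, the cosinor F-statistic (2 and N−3 degrees of
freedom, N > 3 required) is noncentral-F with noncentrality
`λ = βᵀHᵀ(H(XᵀX)⁻¹Hᵀ)⁻¹Hβ/σ²`; power is the survival function at the
central-F critical value. `B⁻¹ = (H(XᵀX)⁻¹Hᵀ)⁻¹` is evaluated in closed
form as the trig-block Gram matrix minus its rank-one mean correction
(`X̃ᵀX̃ − bbᵀ/N`, a Schur complement), which is PSD for every design and
avoids explicit inversion. Because `(A cos φ, A sin φ)` sweeps a circle,
the worst case over acrophase is `λ = (A²/σ²)·ξ_min(B⁻¹)` with `ξ_min`
computed by the closed-form 2×2 eigenvalue formula. Two consequences are
used as test oracles: amplitude and noise enter only through A/σ, and
`ξ_min ≤ N/2` for every design, with equality exactly for designs whose
first and second trigonometric moment sums vanish at f (equispaced designs
at integer f < N/2, and equiphase designs below).

Worst-case powers reported by the package use the eigenvalue route
(exact); the uniform acrophase scan exists for peak-to-trough curves and
the variability delta, which is reported in percentage points of power.
scipy's noncentral-F survival function misbehaves at exactly zero
noncentrality, so λ = 0 is dispatched to the central F (power = α).

A vectorised Monte-Carlo power estimator (QR-based F-statistics on
simulated datasets, binomial standard errors) serves as the independent
simulation oracle for the closed form; the defaults α = 0.05 and σ = 1 are
the conventional choices for such benchmarks.

## Discrete designs, necklaces, and exhaustive search

On a uniform partition of Nt slots with at most one measurement per slot,
designs are binary masks. The criterion is invariant to cyclic rotation,
so unconstrained searches enumerate one representative per fixed-density
binary necklace class (counted by the totient-divisor formula; generated
with the classic prenecklace recursion with density pruning, emitting
lexicographically smallest rotations). Reflection (bracelet) symmetry is
deliberately not exploited — it would roughly halve the space but
complicates canonical forms; rotation alone already divides the space by
~Nt. Constrained searches (a rest window breaks rotational symmetry) scan
plain combinations of allowed slots. Scoring is vectorised: per-slot
tables of (cos², sin², cos·sin, cos, sin) let batches of masks be scored
with a handful of array operations; the 10.5-million-candidate rest-window
search completes in well under a minute on one CPU. The candidate cap
defaults to 2×10⁷; ties are broken by the lexicographically smallest mask.

The **naive** rest-window design places N measurements at equal intervals
spanning the closed allowed arc endpoints-inclusive (spacing = arc span /
(N−1)), starting at the window's end boundary; these times are generally
off-grid and are kept continuous (optional snapping to the nearest slot is
available and warns when it moves a point). This endpoint-inclusive
convention is what the package's own rest-window study quantifies: the
8 h-window naive design's power varies by ≈22.9 pp over acrophase while
the brute-force optimum varies by ≈0.4 pp.

## Equiphase constructions for several periods

A design is *equiphase* at integer frequency f when its phases f·t mod 1
split into rotated uniform sets of at least 3 distinct values (coincident
phases grouped by multiplicity). Each such set has vanishing first and
second harmonic sums, so equiphase designs attain `ξ_min = N/2` exactly.
`equiphase_construct` builds designs equiphase at every frequency in a set
by a product of "levels": level j contributes an offset ladder
`k/(q_j·b_j)`, k < q_j, where b_j is the slowest frequency handled at that
level; a frequency f is handled there when b_j | f and the ladder spreads
its phases over `q_j/gcd(q_j, f/b_j) ≥ 3` distinct values. Contributions
from faster levels shift each phase class by a constant and are harmless.
The constructor searches all splits of the frequency set into levels and
all factorizations of N into level sizes ≥ 3, and reports the obstruction
when none exists — e.g. N = 12 with frequencies {1, 12} succeeds
(3 × 4 levels, J = 6) while N = 16 with {1, 12, 336} is infeasible
(16 admits no three-level factorization; the minimal feasible size is 36).

## Mixed-integer conic program

For discrete period uncertainty the grid problem is lifted to
`max η s.t. Xᵀdiag(μ)X − ηI ⪰ 0` per frequency, `Σμ = N`,
`η ∈ [0, N/2]` — linear in μ. Since no open mixed-integer SDP solver is
available in the scientific Python stack, the PSD constraints are enforced
by outer approximation: a MILP (HiGHS via `scipy.optimize.milp`) carries
scalar cuts `vᵀ[Xᵀdiag(μ)X]v ≥ η` for an accumulated set of unit vectors
(seeded with the coordinate basis per frequency); at each incumbent the
most negative eigenvector supplies the next cut, and termination with no
violated cut certifies optimality within the tolerance (default 1e−6 on
eigenvalues; cuts deduplicated by cosine similarity). The relaxation value
is monotonically non-increasing and every returned incumbent passes the
explicit PSD certificate check. Time-limited solves return the certified
incumbent with status `feasible`.

One property worth knowing: `ξ_min(Xᵀdiag(μ)X) ≤ ξ_min(B⁻¹)` for every
mask, with equality when the trig column sums vanish — in particular at
every bound-attaining (equiphase) optimum, where both equal N/2. On small
instances where the N/2 bound is unattainable the two criteria can have
different maximisers; the solver optimises the lifted quantity exactly as
stated, and the exhaustive-search cross-checks in the test suite compare
against the same quantity.

## Stochastic optimisation

`differential_evolution` is classic DE/rand/1/bin: population initialised
uniformly on [0,1)^N; per member a candidate is built coordinate-wise
(with probability CR, `x_a + ε(x_b − x_c)` from three distinct other
members, wrapped mod 1; otherwise copied) and accepted only on strict
improvement, making per-member objectives and the best-of-generation trace
monotone. Defaults CR = 0.05, ε = 0.05, population 1000 favour small,
conservative moves; the package's desk-scale studies use reduced budgets
(population tens, ~100 generations), which already resolve the Nyquist
blindspot of equispaced designs — the qualitative target of this
optimiser — though not necessarily the globally optimal J.

`constrained_search` maximises a pluggable objective over ordered designs
with anchored times (defaults t₁ = 0, t_{N/2+1} = 1/2) and a minimum
consecutive gap ε, via a seeded Gaussian-move hill climb with a decaying
step and a repair projection (sort, pin anchors, forward/backward gap
passes), so returned designs satisfy the constraints exactly. The default
objective is the worst-case fixed-period criterion — the heuristic that
correlates strongly with free-period permutation power and is far cheaper
to evaluate.

Jitter analysis perturbs each time with Gaussian noise (SD as a fraction
of the study interval), wrapping modulo the interval — phases, not clipped
clock times — and summarises worst-case power over replicate ensembles by
median and interquartile range. At extreme noise any design's times become
effectively i.i.d. uniform, so equispaced and irregular designs converge
in distribution; the tests check this as IQR overlap.

## Free-period permutation testing

The free-period model fits every frequency on a window grid and keeps the
RSS minimiser. Detection statistics are built from the amplitude profile
`Â_f = ||Hβ̂_f||`: T₂ integrates `Â_f²` over the window (trapezoidal rule
— the definition is an integral with no rule prescribed) and T∞ takes the
maximum. Grid frequencies where the design is singular are excluded
per-design (condition-number rule), which generalises the usual "below
0.99 × Nyquist" restriction for equispaced designs. The permutation
p-value is Monte-Carlo with `≥` and add-one smoothing,
`p = (1 + #{T(πy) ≥ T(y)})/(n_perm + 1)`, guaranteeing valid p-values with
floor 1/(n_perm+1); an exact all-permutations estimator with strict `>`
(the textbook definition) is provided for n ≤ 7 as an enumeration oracle.
Permutation power maps rejection rates over a frequency × acrophase grid
and reports the per-frequency minimum over acrophase; AUC benchmarking
uses the rank-sum estimator with ties counted half.

## Synthetic data

The simulator generates the study conditions the package's analyses
assume: homoscedastic Gaussian cosinor signals, plus four deliberate
violations for robustness benchmarks — amplitude-modulated cosines (the
envelope's form and rate are exposed as parameters, defaulting to a slow
cosine of depth 0.5, since only "modulation" is specified by the use
case), rhythmically heteroscedastic noise (noise SD scaled by
`1 + A cos(2πft − φ)`), and square/burst pulse trains (duty cycles 0.5 and
0.25). Passing tests on these synthetic families shows correct
implementation of the stated models; it does not certify behaviour on real
data with autocorrelated or non-Gaussian noise, missing samples, or
multi-harmonic waveforms, none of which are modelled.

## Problem sizes and numerical notes

The bundled studies and tests run at desk scale by choice: the exhaustive
rest-window search at Nt = 48/N = 8, conic instances up to a few dozen
slots and three frequencies, DE with reduced budgets, permutation
calibration at 500 null replicates × 200 permutations. Headline large-N
sweeps (e.g. harmonic windows at N ≥ 48 with hour-long optimiser budgets)
use the same code paths but are not part of the test suite. Floating-point
tie-breaking in exhaustive searches compares exact equality of batch
maxima; rotation invariance means rest-window optima are reported up to a
rotation fixed by the window position. Known limitations: no replicate
measurements per time point, no heteroscedastic or autocorrelated noise in
the fitted model, and power exactly at singular frequencies is defined
only through the eigenvalue route (0, hence power = α), not by a limiting
argument.
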