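# rhythmdesign

Optimal measurement timing for biological-rhythm detection experiments.

Studies of circadian and other biological rhythms usually sample at equally
spaced times. That is provably the best choice when the oscillator's period
is known — but when the period is uncertain, or practical constraints (such
as a participant's sleep window) forbid equispaced collection, naive
schedules can lose a large and acrophase-dependent fraction of their
statistical power. `rhythmdesign` gives experimentalists and
biostatisticians the tools to quantify that loss exactly and to design
schedules that avoid it.

## The model and criterion

Rhythm detection uses the cosinor model

```
Y(t) = M + A·cos(2πft − φ) + ε(t),   ε ~ N(0, σ²),
```

fitted by least squares after the linearisation
`Y(t) = β₀ + β₁cos(2πft) + β₂sin(2πft) + ε(t)`, and tested with the F-test
of `β₁ = β₂ = 0`. For **any** set of measurement times **t** (normalised to
the unit study interval; frequency f in cycles per interval) the power of
this test is available in closed form: the F-statistic follows a noncentral
F(2, N−3) distribution with noncentrality

```
λ = βᵀHᵀ(H(XᵀX)⁻¹Hᵀ)⁻¹Hβ / σ²,
```

where `X = [1, cos(2πf t), sin(2πf t)]` and `H` selects (β₁, β₂). The
worst case over the unknown acrophase φ is governed by the smallest
eigenvalue `ξ_min` of `B⁻¹ = (H(XᵀX)⁻¹Hᵀ)⁻¹`, via
`λ_worst = (A²/σ²)·ξ_min`, so E-optimal design reduces to maximising

```
J(t) = min_{f ∈ ℱ} ξ_min(B(t; f)⁻¹)  ≤  N/2,
```

with the bound attained by equispaced — and, for several periods at once,
*equiphase* — designs. Four optimisers maximise J: an exhaustive
necklace-aware grid search, a mixed-integer conic program solved by
eigenvector cutting planes, differential evolution, and an anchored
constrained stochastic search. A free-period permutation test (T₂ and T∞
amplitude statistics) benchmarks designs under continuous period
uncertainty.

## Worked example: an 8 h rest window

An 8-sample circadian study (24 h cycle, half-hour grid) must avoid waking
participants during an 8 h rest window. Compare the naive schedule (equal
spacing across the allowed 16 h) against the exhaustively optimal one:

```python
import numpy as np
import rhythmdesign as rd

part   = rd.Partition(48)                            # half-hour grid
window = rd.ConstraintMask.rest_window(48, 0, 16)    # 8 h rest window
spec   = rd.PowerSpec(alpha=0.05, amplitude=2.5, sigma=1.0)

naive = rd.naive_constrained_design(8, part, window)
lo, hi, delta = rd.worstcase_power_over_acrophase(naive, 1.0, spec, 512)
print(f"naive   min power {lo:.4f}  max power {hi:.4f}  delta {delta:.2f} pp")

opt = rd.brute_force_optimal(8, part, [1.0], window)   # scans all C(32,8) masks
lo, hi, delta = rd.worstcase_power_over_acrophase(opt.design, 1.0, spec, 512)
print(f"optimal min power {lo:.4f}  max power {hi:.4f}  delta {delta:.2f} pp")
print(f"optimal xi_min {opt.objective:.4f}  (equispaced bound N/2 = 4)")
print("optimal times (h):", np.round(opt.design.times * 24, 2))
```

prints

```
naive   min power 0.7175  max power 0.9468  delta 22.93 pp
optimal min power 0.8708  max power 0.8750  delta 0.41 pp
optimal xi_min 3.6377  (equispaced bound N/2 = 4)
optimal times (h): [ 8.   8.5 14.5 15.  16.5 17.  23.  23.5]
```

The naive schedule's power swings by ~23 percentage points depending on
where the rhythm peaks; the optimised schedule detects rhythms of any
acrophase with nearly constant (and higher worst-case) power, giving up
only ~9% of the unconstrained noncentrality (ξ_min 3.64 vs 4).

A command-line interface mirrors the library:

```sh
rhythmdesign optimize brute --n 8 --grid 48 --freqs 1 \
    --rest-window 00:00-08:00 --out design.json
rhythmdesign power eval --design design.json --freq 1 --amp 2.5
rhythmdesign optimize de --n 48 --fmax 24 --seed 1 --out de.csv
rhythmdesign scenario run --tag bifrequency --seed 0 --out-dir results/
```

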