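# Methods

## Model

The package simulates hyperplasia of airway smooth muscle (ASM) as a
two-compartment cell population coupled to a scalar inflammatory status.
Cells are proliferative (`p`) or non-proliferative (`c`), measured as
fractions of the airway wall's carrying capacity `V` (so the total
`s = p + c` saturates at 1):

```
dp/dt = λ_p p (1 − s) − λ_pc p + λ_cp(μ) c
dc/dt = λ_pc p − λ_cp(μ) c − λ_a c
```

The logistic crowding term uses the *total* population `s`, since the
capacity constrains all ASM cells regardless of state.  The inflammatory
status `μ(t)` lumps together every downstream trigger of ASM mass increase
(inflammatory mediators, growth factors, bronchoconstriction-derived
signals).  Exacerbations add an instantaneous impulse `a` to `μ`; between
events `μ` decays exponentially at the clearance rate `λ_d`.  The
recruitment rate `λ_cp(μ)` is a three-level step function with thresholds
`μ₁ < μ₂`:

| regime   | condition      | λ_cp/λ_p (default) | behaviour |
|----------|----------------|--------------------|-----------|
| healthy  | μ < μ₁         | 0.016              | near-stationary, very slow decline |
| moderate | μ₁ ≤ μ < μ₂    | 0.8                | slow growth (weeks–months) |
| severe   | μ ≥ μ₂         | 40                 | fast growth (days–weeks) |

Thresholds are inclusive upward (`μ = μ₂` is severe).  The default rate
ratios are `λ_pc/λ_p = 50`, `λ_a/λ_p = 4×10⁻⁴`, `μ₂/μ₁ = 2.5`, with
`λ_p = 1/3 day⁻¹`; the healthy level is chosen so that state-switching
almost balances apoptosis (`λ_cp/λ_pc ≈ λ_a/λ_p`), which produces the
characteristic very slow decay of ASM mass in a sustained non-inflamed
environment (≈1% over 300 days from the standard initial state) and, with
it, effective hysteresis: mass gained during a severe excursion is not
lost when `μ` returns to baseline, because apoptosis acts on a timescale
of years while severe-regime growth acts on days.

All quantities are handled dimensionally (rates per day) with `μ` in units
of `μ₁` (`μ₁ = 1` internally).  Only the ratios `a/μ₁`, `ω/λ_p` and
`IR = λ_d/λ_p` affect the dynamics, so configuration is ratio-first and a
dimensional `rates` block is converted on input.  The slow remodelling
timescale `T = 100 days` and `ε = 1/(λ_p T)` are carried as documentation
attributes only and never enter any computation.

## Hybrid integration scheme

Because `μ` is piecewise closed-form (`μ(t) = μ₀ e^{−λ_d t}` between
impulses), every regime switching time is a root of an exponential and is
computed analytically: `t = ln(μ₀/μ_th)/λ_d`.  A simulation is therefore a
sequence of segments with constant `λ_cp`, delimited by event times and
threshold crossings.  On each segment the two-variable cell subsystem is
integrated with an adaptive Dormand–Prince RK45 pair (rtol 1e-8,
atol 1e-10), compiled with numba for throughput; without numba the package
falls back to `scipy.integrate.solve_ivp`.  The two code paths and an
independent fixed-step RK4 integrator are cross-checked in the test suite
(agreement to ≤1e-5 over 30-day segments; whole-trajectory agreement to
≤1e-3 relative against a dense RK4 integration of a smooth-switching
variant of the model).  The system is only mildly stiff within a segment
(the fastest rate is `λ_pc + λ_cp ≈ 30/day`), so an explicit adaptive pair
is adequate.

Numerical conventions:

* outputs are sampled on a uniform grid (default 0.1 day) *plus* every
  segment boundary, so time-in-regime accounting is exact (regime
  durations sum to the horizon to ≈1e-12 day);
* a crossing at exactly the segment start (μ₀ on a threshold) is not a
  crossing; the regime of a segment is classified at its midpoint, which
  is unambiguous because `μ` is monotone between events;
* integrator output is validated against `p, c ≥ −10·rtol` and
  `s ≤ 1 + 10·rtol`, then clipped to `[0, 1]`;
* `λ_d = 0` is valid (no clearance: `μ` accumulates without decay);
* populations `(0, 0)` are an exact fixed point and short-circuit the
  integrator.

A smoothed variant of `λ_cp(μ)` (logistic interpolation of the step levels
in log-rate space, width `δ·μ₁`, default off) exists solely so that an
independent dense integrator of a smooth ODE can serve as an oracle for
the hybrid scheme; it is not a production path.

## Stimulus model

Events are instantaneous additive impulses (Dirac-δ forcing) of a fixed
magnitude `a` — "average magnitude" is read as a constant per-event
magnitude; randomising magnitudes is an extension hook deliberately left
out.  Periodic schedules place events at `t_k = k/ω` with the first event
at `t = 0` by default (a flag moves it to `1/ω`, since the phase is a free
choice); Poisson schedules draw exponential inter-arrival gaps from a
dedicated seeded generator, so a schedule is a pure function of its seed.
Under sustained periodic forcing the pre-event `μ` plateau is the
geometric series `a e^{−λ_d Δt}/(1 − e^{−λ_d Δt})` and the long-run mean
of `μ` is `a ω/λ_d`; both closed forms are verified against simulation in
the tests.

## Outcome metrics

The headline outcome is the fold-increase `s(horizon)/s(0)` at the default
horizon of 300 days from the standard healthy initial state
`(p, c) = (0.01, 0.1)`, `μ(0) = 0`.  Classes: healthy (< 2-fold), moderate
(2–8-fold), severe (≥ 8-fold), boundaries inclusive upward.  Because
`s ≤ 1` and `s(0) = 0.11`, the fold-increase saturates at ≈9.09, so severe
outcomes cluster just above the 8-fold boundary.

The inflammation-severity index is implemented as
`IS = (ω/λ_d) ln(a/μ₂)` for `a > μ₂`, else 0.  Rationale: at fast
resolution events are independent and each spends `ln(a/μ₂)/λ_d` above the
severe threshold, so `horizon · ω · ln(a/μ₂)/λ_d` is the expected total
severe time — the quantity that controls long-term growth in that regime —
and constant `IS` traces the predicted growth isolines
`IR ∼ (ω/λ_p) ln(a/μ₂)`.  The exact normalisation of such an index is a
design choice; this one is dimensionless and is validated in the tests by
its proportionality to the measured severe-residence time (within 10%).

## Ensembles and sweeps

Monte Carlo ensembles draw per-run schedule seeds from
`numpy.random.SeedSequence(master_seed)`, making results independent of
execution order and bit-exactly reproducible; a failed member aborts the
ensemble with its seed attached.  The outcome histogram defaults to 30
bins spanning `[1, 1/s(0)]` (extended if samples fall outside).  Mode
counting uses a Gaussian KDE (Silverman-type bandwidth, configurable)
evaluated on a grid padded by three bandwidths, with local maxima of
prominence ≥ 5% of the peak density counted as modes; the bandwidth policy
is a pragmatic choice for detecting the healthy/severe bimodality of
slow-resolution ensembles, not a formal multimodality test (dip-type tests
are out of scope).

Parameter sweeps cover the planes `(a/μ₁, IR)` and `(ω/λ_p, IR)`,
log-spaced by default over the reference ranges (`a/μ₁` and `IR` 0.1–10,
`ω/λ_p` 0.1–1; 25×25 cells by default).  Deterministic sweeps use periodic
schedules; stochastic sweeps run a Poisson ensemble per cell with seeds
derived from `(master_seed, row, column)`.  Isolines (default levels 2 and
8) are extracted with marching squares (`skimage.measure.find_contours`)
on the grid indices, i.e. linearly on log-transformed axes, and mapped
back to parameter coordinates.  The fast-resolution branch (`IR > 1`,
`a > μ₂`) of a computed isoline is regressed as `IR = k·ln(a/μ₂) + b` with
the proportionality constant fitted, not assumed.

## Synthetic conditions and what the tests show

There is no external data: the stimulus generator *is* the experimental
condition.  Defaults reproduce the reference survey — healthy initial
state, 300-day horizon, event frequencies of roughly monthly to weekly
(`ω/λ_p` 0.1–1), magnitudes `a/μ₁` 0.1–10, `N = 1000` ensemble members for
outcome distributions.  Scenario checks in the test suite use the survey's
parameter triples, e.g. `(a/μ₁, ω/λ_p, IR)` = (2, 0.25, 7) healthy,
(5, 0.25, 5) moderate, (8, 0.25, 2) severe, (1.5, 0.25, 0.22)
slow-resolution accumulation, and (0.5, 0.25, 0.08) for the
bimodal-ensemble regime.  Test sweeps use coarser grids (≈10×12) than the
default 25×25 purely to keep the suite brisk; the contoured fields are
smooth and the conclusions insensitive to this resolution.

What passing tests do **not** show about real airways: the model is
qualitative.  It omits cell hypertrophy, spatially heterogeneous and
anisotropic growth, mechanochemical coupling between ASM mass, wall
stiffness and bronchoconstriction, and any molecular identity for `μ` —
so fold-increases should be read as remodelling classes, not predicted
biopsy measurements, and no translation to lumen narrowing or FEV₁ is
attempted.

## Known limitations and open choices

* The frequency-doubling comparison (monthly → semi-monthly at
  `a/μ₁ = 5`, `IR = 5`) yields a mass ratio of ≈1.76 here, consistent with
  the expected "about two-fold" but on its lower side: the monthly
  scenario lands at a fold of ≈2.09, essentially on the healthy/moderate
  boundary, so its classification is boundary-sensitive.
* Event magnitudes are constant; inhomogeneous (e.g. seasonal) Poisson
  forcing is not implemented.
* The KDE mode count can be bandwidth-sensitive for weakly separated
  modes; the default is validated only for well-separated synthetic
  mixtures and the slow-resolution ensemble geometry.
* Treatment-path optimisation over the outcome landscape (navigating the
  `(IR, a)` plane around the high-uncertainty zone) is a documented
  extension, not implemented.
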