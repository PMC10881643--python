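# Methods

## Model

`sflt1kin` describes constitutive secretion of sFLT1 from endothelial
cells with two pools — intracellular `S_i` and extracellular `S_x`, both
in molecules per cell (media content is cell-normalized so the kinetic
core stays geometry-free) — and four first-order processes:

```
dS_i/dt = k_prod · u(t − τ) − (k_out_Si + k_deg_Si) · S_i
dS_x/dt = k_out_Si · S_i − k_deg_Sx · S_x
```

Assumptions:

* **Linearity.** All transport and degradation steps are first order; no
  saturation of the secretory machinery or the lysosome. This is adequate
  for unstimulated cells near their constitutive operating point and makes
  the model exactly solvable.
* **Delay on the production input.** Newly synthesized protein becomes
  part of the secretable/degradable pool only after a fixed transit delay
  τ, representing ER→Golgi maturation. Placing the discrete delay on the
  exogenous input (rather than on `S_i` inside the loss terms) matches the
  ordering production → maturation → secretion/degradation, and keeps the
  system an ordinary linear ODE driven by a time-shifted gate, which is
  what makes the exact engine possible. The `Protocol` abstraction leaves
  room for alternative delay placements should a future variant need one.
* **Well-mixed media, homogeneous cells.** One extracellular pool; no
  re-uptake (cell-surface binding and internalization of secreted sFLT1
  are not modelled).
* **History.** Protocols starting from an unperturbed culture take
  `S_i(0)` at the constitutive steady state with the production gate held
  at 1 for t < 0; synthesis-onset (and labeling) protocols start from
  zero with a zero history. The extracellular pool always starts at zero
  — every protocol begins at a media change.

Derived quantities: `S_i* = k_prod/(k_out_Si + k_deg_Si)`, steady-state
secretion flux `k_out_Si · S_i*`, and the fraction secreted
`φ = k_out_Si/(k_out_Si + k_deg_Si)` — the probability that an
intracellular molecule is secreted rather than degraded.

## Parameters

| name | meaning | units | reference default |
|---|---|---|---|
| `k_prod` | production rate entering the pathway | molecules·cell⁻¹·h⁻¹ | 60,000 |
| `tau` | synthesis-to-availability delay | h | 0.5 |
| `k_out_Si` | secretion rate constant | h⁻¹ | 0.3 |
| `k_deg_Si` | intracellular degradation rate constant | h⁻¹ | 0.3 |
| `k_deg_Sx` | extracellular degradation rate constant | h⁻¹ | 10⁻³ |

The reference set (`DEFAULT_PARAMS`) encodes the measured phenotypes of
endothelial sFLT1 secretion rather than any single published table: a
steady-state secretion flux of 30,000 molecules/cell/hr, an even split
between secretion and intracellular degradation (φ = 0.5), conditioned
media that is essentially stable over 72 h (half-life ≈ 690 h), and an
ER→Golgi transit time of about half an hour. It is the default for
examples and for the synthetic-data generator; fits always estimate all
five parameters from data.

## Simulation engines

The input gate is piecewise constant, so between events (media changes,
inhibition onsets, delayed gate switches) the system is a linear
constant-coefficient ODE. The **exact engine** propagates the closed-form
solution segment by segment. The two-exponential terms are evaluated
through the φ-functions `φk(z) = (e^z − Σ_{j<k} z^j/j!)/z^k` using
`expm1` and short Taylor series near z = 0, and the resonant case
`k_deg_Sx = k_out_Si + k_deg_Si` goes through stable divided differences,
so there is no catastrophic cancellation anywhere in parameter space.
Cumulative audit channels (produced, secreted, degraded in each pool,
removed at media changes) are computed by independent analytic integrals
— not from the balance identity — so the mass-balance invariant

```
produced + initial = S_i + S_x + degraded_i + degraded_x + removed
```

is a genuine consistency check; it holds to < 10⁻¹² relative in practice.

The **numeric engine** integrates the same segments with
`scipy.integrate.solve_ivp` (LSODA, rtol 10⁻¹⁰, atol 10⁻⁹), carrying the
pool integrals as extra states. The two engines agree to ~10⁻⁷ relative
over 0–48 h across random parameter sets spanning rates 10⁻³–10 h⁻¹,
providing a dual-route validation of both.

Media changes reset `S_x` to zero and credit the discarded amount to a
`cum_removed` channel so balance holds across events. Samples exactly at
an event time report the post-event state.

## Protocols and observables

* **Accumulation**: steady-state cells, fresh media at t = 0, constitutive
  production; the observable is media content (molecules/cell or, through
  a `Geometry` block — cell count, media volume, molecular weight — in
  ng/mL), optionally normalized to a reference time point as densitometry
  series are.
* **Pulse-chase**: a labeled cohort produced only during the pulse window;
  by linearity it evolves independently of the unlabeled pool, so fold
  changes are invariant to `k_prod`. Two normalization conventions are
  supported: `per_compartment` (intracellular to its chase-start value,
  extracellular to its own maximum) and `shared_initial` (both to the
  intracellular chase-start value). The shared convention preserves the
  intra/extra amplitude ratio and with it the secreted fraction φ; the
  per-compartment convention reduces both curves to shape only, leaving φ
  structurally unidentifiable. The fit benchmark therefore declares
  `shared_initial`; the choice is per-dataset metadata, not global.
* **Cell-free decay**: `S_x(t) = S_x0 · e^(−k_deg_Sx t)`, no cells.
* **Inhibitor treatment**: control and treated arms both start from the
  unperturbed steady state with a media change at t = 0; the treated arm
  runs with one parameter scaled by (1 − f) from t = 0 as a step (no
  pharmacokinetic ramp — inhibitors are modelled as constant fractional
  reductions over the window). Read-out is the treated/control media and
  lysate ratio at 18 h, the standard inhibitor media window.

**Inhibition inversion** evaluates f → R_x on the monotone dose curve and
inverts an observed ratio by bisection (|ΔR_x| < 10⁻⁸, deterministic).
Bisection is chosen over derivative-based root finding because the map is
monotone and cheap; robustness beats speed. Inversion is defined
per-parameter against the media ratio only; `k_out_Si` is the intended
target, other monotone-decreasing targets are supported but secondary,
and non-monotone targets (e.g. `k_deg_Sx`, whose inhibition raises the
ratio) are rejected with an error.

## Fitting

Weighted least squares: residuals are scaled by per-point σ when the
dataset provides it, otherwise by the dataset's mean observed value
(relative error); by default each dataset's summed squared residuals are
divided by its point count so every dataset carries equal total weight —
the sparse absolute-concentration series that anchors the `k_prod` scale
is not swamped by denser fold-change series.

Optimization is bounded Nelder–Mead over log₁₀-transformed rates and
`k_prod` (linear τ), from a seeded Latin-hypercube of starting points
(default 20), with a simplex-restart polish of the best optimum. A
derivative-free simplex is used because the objective is cheap and has
non-smooth corners from max-normalization. Default box bounds:
rates 10⁻⁴–10² h⁻¹, `k_prod` 1–10⁷ molecules/cell/h, τ 0–8 h. Results are
bitwise reproducible for a given seed.

After convergence a cheap structural probe perturbs each parameter ±5%;
parameters whose perturbation leaves the cost unchanged are flagged
non-identifiable (this catches `k_prod` under fold-change-only data,
where normalization cancels the scale exactly).

**Profile likelihood**: one parameter fixed on a grid spanning its bounds
(log-spaced for rates), the other four re-optimized, walking outward from
the optimum with warm starts plus a restart from the global optimum at
each grid point. The 95% interval is where the profile stays within 3.84
(χ²₁, 0.95) of the optimal cost, with linear interpolation at the
crossings. An interval that reaches both bounds with the profile still
under threshold marks the parameter as flat/non-identifiable; profile
likelihood is used instead of bootstrap for determinism and low cost.

## Synthetic data

The generator mimics how secretion time courses are actually produced:
simulate the protocol, convert units through the experiment geometry,
multiply every raw observation by an independent lognormal factor with
mean 1 and coefficient of variation `noise_cv`, then normalize **within
each replicate** against that replicate's own (noisy) reference — noise
before normalization, which yields the realistic structure where every
replicate is exactly 1 at the reference point and errors are correlated
through the shared reference. Lognormal noise is positivity-preserving;
the default CV of 0.2 reflects typical immunoblot replicate scatter.
When `noise_cv > 0`, a per-point σ column (CV × noise-free value) is
attached, which makes the least-squares cost approximately χ²-scaled; the
σ ignores the reference-point correlation, a deliberate simplification.

The fit benchmark (`generate_fit_benchmark`) draws true parameters
log-uniformly from documented ranges (rates 0.1–1 h⁻¹ for turnover,
0.01–0.1 h⁻¹ for media decay, τ 0.25–1.5 h, `k_prod` 10³–10⁵) and emits
one pulse-chase fold-change dataset (2 h pulse, 8 chase points over 8 h,
both compartments, shared-initial normalization) and one media
concentration dataset (6 points over 24 h, 10⁶ cells in 2 mL, 100 kDa),
n = 3 replicates at CV 20% by default.

What the generator does **not** emulate: band saturation, loading-control
error, detection thresholds, day effects shared across time points, or
cell-number drift over long collections. Passing recovery tests therefore
show that the estimation machinery is correct and well-conditioned under
the declared noise model — not that real densitometry data carry enough
information in every regime; in particular `k_deg_Sx` near the stable-media
limit is weakly informed at realistic noise, and fits of real data should
always be read together with their profile intervals.

## Problem sizes and numerical choices

The validation and acceptance computations run at these scales, chosen as
the package's standard benchmark sizes: 100 random parameter sets for
engine cross-validation (rates 10⁻³–10 h⁻¹, τ 0–4 h, 25-point 0–48 h
grids); one noise-free recovery fit at 20 starts (tolerance: every
parameter within 1%); 25 noisy recovery studies (CV 20%, n = 3) at 6
starts each, scored by the median relative error of `k_out_Si` and
`k_deg_Si` (< 30%); profile-interval coverage of `k_out_Si` over 10
studies at CV 15%, n = 6 (≥ 80% nominal-95% coverage); inversion round
trips at f = 0.1…0.9 (|Δf| < 10⁻⁶); 101-point inhibition sweeps.

Degenerate inputs: zero turnover has no steady state (error when one is
requested); a labeling delay exceeding the pulse makes the chase-start
reference zero (error suggesting a different normalization); zero-length
segments return their initial condition; ties between event times are
merged to a single breakpoint at 10⁻¹² h resolution.

## Known limitations

* Single homogeneous secretory pathway: no distinct Golgi/vesicle
  compartments, no lysosomal sub-model; inhibitors act as fractional rate
  reductions only.
* No re-uptake or surface binding of secreted sFLT1, and no VEGF binding
  kinetics.
* Joint inversion of multiple inhibited parameters from a single ratio is
  deliberately unsupported (underdetermined).
* Profile intervals rely on the asymptotic χ² threshold; at n = 3
  replicates they are approximate, which the coverage benchmark quantifies.
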