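# Methods

## Model and inversion

The illness-death model (IDM) for an irreversible condition has states
condition-free, with condition, dead, and intensities incidence `i(t, a)`,
mortality without condition `m0(t, a)` and with condition
`m1 = R·m0`, where `R(t, a) ≥ 1` is the mortality rate ratio (MRR).
Remission is assumed zero — appropriate for need for long-term care, which
is administratively near-irreversible. On the Lexis plane the prevalence
`p(t, a)` then obeys

    (∂/∂a + ∂/∂t) p = (1 − p)(i − m·p(R−1)/(p(R−1)+1)),

where `m = p·m1 + (1−p)·m0` is the *general* mortality of the whole
population, the quantity official statistics actually publish. The package
works with `m` directly; the split into `m0 = m/(1 + p(R−1))`, `m1 = R·m0`
(`split_mortality`) is used by the simulator and tested against the mixture
identity.

The estimator evaluates the inversion

    i = D/(1 − p) + m·p(R−1)/(p(R−1)+1),    D = (∂/∂a + ∂/∂t) p,

pointwise and reports both terms separately; their sum is the estimate by
construction, which makes the decomposition a free diagnostic. The excess
term is non-negative and bounded by `m` for `R ≥ 1`, and vanishes at
`R = 1`, where the inversion degenerates to the mortality-free
`i = D/(1−p)`.

## Surfaces and differencing

Prevalence and mortality are rectangular (year × age) grids; queries use
bilinear interpolation (exact at nodes, monotone between nodes), with
clamped constant extrapolation allowed up to a configurable margin (default
1 year) beyond the hull — needed because the lifeline stencil steps to
`(t ± h, a ± h)` and may leave a biennial reporting grid by one year. Ages
are treated as exact points; converting published age bands to midpoints is
a data-preparation step, deliberately outside the package.

`D` is a central difference along the lifeline,
`[p(t+h, a+h) − p(t−h, a−h)]/(2h)`, second-order on smooth surfaces. The
default step is half the year spacing of the prevalence grid (`h = 1` for
biennial data) so the stencil stays on interpolable territory. At the first
and last grid years a one-sided difference with the same `h` is
substituted and flagged on the estimate (`one_sided_forward` /
`one_sided_backward`); the flag matters because the trend summary uses
exactly those endpoint years.

**Endpoint attenuation.** On a biennial grid the one-sided stencil at 2011
effectively measures the secant over [2011, 2013], i.e. the derivative near
2012, and symmetrically near 2020 at the 2021 end. For an incidence growing
at a constant rate this shifts the effective APC window inward by roughly
`h` at each end and attenuates the recovered APC (about 3.6 %/yr recovered
at age 55 for a generating +5 %/yr on the benchmark). This is a property of
endpoint differencing on coarse registry grids, not of the inversion; the
recovery harness therefore simulates one year beyond the analysis window so
that the endpoint estimates use the same central stencil as the interior,
and recovers generating APCs of 0–18 %/yr to within 0.05 pp.

Negative estimated incidence is reported with a flag, never clipped: it is
the tell-tale of inputs incompatible with the assumed scenario (e.g. an MRR
far above the truth). An optional centred moving-average smoother over age
(`smooth_ages`) exists as an explicit pre-processing hook and is off
everywhere by default, since smoothing changes estimates and must be a
logged choice.

## MRR scenarios

`R(t, a) = max(1, exp(L(a)) · (1 + apc/100)^(t − t_ref))` with `L` the
linear interpolant of `(50, log r50)` and `(95, log r95)`; ages outside
[50, 95] clamp to the nearest anchor before the time factor, and the floor
is applied last so `R ≥ 1` holds globally, also after long negative trends.
The time trend is the discrete power form evaluated at decimal `t` (it
coincides with per-year compounding at integer years). The trend anchor
`t_ref` defaults to 2011, the start of the biennial study window, and is
configurable. The built-in `standard8` set crosses the two literature
anchor profiles (3.2→1.2 log-affine; constant 3.2; constant 1.2) with
annual MRR changes of 0, −2.5, −5 and −10 %/yr; a declining MRR halves
every `log(0.5)/log(1 + apc/100)` years (6.58 years at −10 %/yr).

## APC of incidence

`APC = 100·((i_end/i_start)^(1/(end−start)) − 1)` with the exponent
generalised from the fixed decade so other windows work; only the two
endpoint years enter (no joinpoint or log-linear regression), matching how
such trend tables are published. Internal values keep full precision; the
report layout rounds to one decimal place at output only. A scenario that
differs from the (unknown) truth is a feature of the sweep, not an error —
each row records the scenario that produced it.

## Forward simulator and benchmark

The transport equation reduces to `dp/du = (1−p)(i − excess)` along
lifelines `a − t = const`, so the simulator integrates characteristics
exactly rather than discretising the PDE on a grid: classical RK4 with a
per-node uniform substep ≤ 0.25 years, all grid nodes advanced in lockstep
as vectorised array operations. Entry prevalence at the minimum-age edge
defaults to 0.005 (real populations have small positive prevalence at age
50). When no explicit initial-time condition is given, lifelines are
continued backwards to the minimum-age edge ("spin-up"), making the first
cross-section itself consistent with the rate model. The state is checked
against [0, 1] (tolerance 1e−9) and an instability error suggests a smaller
substep; with the shipped rates RK4 at 0.25 years matches the closed form
`p = 1 − exp(−i0·u)` (constant `i0`, `R = 1`) to ~1e−12, comfortably inside
the 1e−8 working tolerance.

The benchmark generator emulates the registry setting: biennial years
2011–2021, single-year ages 50–99, two sexes. Generating rates are
parametric — incidence `i50·exp(λ_i(a−50))·(1+APC_i/100)^(t−2011)` with
`i50 = 0.002` (male) / `0.0025` (female), `λ_i ≈ 0.09`, default trend
+5 %/yr; Gompertz general mortality `κ·exp(λ(a−50))` with
`κ = 0.0030/0.0016`, `λ = 0.100/0.106` (male/female) and a −1 %/yr time
trend; base-case MRR. These values put prevalence at ~1–2 % in the
mid-50s rising to ~30–50 % around age 90, female above male, the magnitudes
seen in German care statistics. Observation noise (multiplicative
log-normal on prevalence) is available but defaults to zero, because the
emulated source is a full-population register, not a sample; the seed is an
explicit argument and only matters when noise is on.

What the synthetic data do **not** emulate: age banding of published
tables, the 2017 redefinition of care eligibility (a level shift in the
real series), COVID-era mortality, and sampling noise. Passing recovery
tests therefore demonstrate correctness of the numerics and the inversion
— not robustness to those real-data artefacts.

## Problem sizes and tolerances

The recovery harness simulates a 0.25-year grid over years 2010–2022 and
ages 50–99 (~9,700 nodes, ≤ 196 RK4 substeps each, vectorised; well under a
second) and inverts with `h = 0.5` at ages 55–95. Working tolerances, fixed
in advance of the checks: oracle-closure relative incidence error < 1 % at
interior points; error ratio ≥ 2 when `h` halves (≥ first-order behaviour;
the measured ratio ~2.1–2.4 reflects the second-order stencil against the
interpolation-error floor of the underlying grid); APC recovery within
0.3 pp of generating trends 0/5/10/18 %/yr. The biennial benchmark closes
the loop at interior points to < 1 % as well.

## Known limitations

* The APC uses endpoint years only; short-window endpoint noise propagates
  with a factor ≈ 10/window-length into the APC.
* One-sided endpoint differencing on coarse grids biases the APC toward
  zero (see endpoint attenuation above); real biennial data inherit this.
* The inversion is pointwise and unregularised; with noisy prevalence the
  derivative term amplifies noise, and the optional smoother or a wider `h`
  are the only mitigations offered.
* No uncertainty quantification: the intended inputs are full-population
  registry counts, and scenario spread — not sampling error — is the
  dominant uncertainty the design addresses.
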