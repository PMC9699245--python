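# Methods

## Aggregation kinetics

The fibrillar fraction is modelled by the two-parameter autocatalytic
rate law `f(t) = ρ{exp[(1+ρ)kt] − 1}/(1 + ρ·exp[(1+ρ)kt]}` with boundary
condition f(0) = 0 and plateau f(∞) = 1. The form assumes a closed
system (no monomer inflow), a single dominant nucleation–elongation
pathway, and that ThT fluorescence is proportional to fibril mass. No
secondary-nucleation or seeding terms are included, and no inner-filter
correction is applied.

A raw trace is fitted as `signal(t) = F_bg + A·f(t; k, ρ)` with all four
parameters free. We deliberately do not min–max normalise the signal to
[0, 1] before fitting: with noisy endpoints that normalisation biases k
and ρ, whereas the joint fit treats baseline and amplitude as nuisance
parameters with honest uncertainties. The fitted curve is evaluated in
the overflow-free form `ρ(1 − e⁻ˣ)/(ρ + e⁻ˣ)` with x = (1+ρ)kt, so the
plateau is returned exactly once e⁻ˣ underflows (x ≳ 745) instead of
overflowing `exp`.

Starting values: F_bg = min(signal), A = max − min, the inflection is
placed at the steepest finite-difference slope, k = 4·(max slope)/A
(since df/dx = (1+ρ)/4 ≈ 1/4 at the inflection for small ρ), and ρ from
one fixed-point pass of ρ = exp(−(1+ρ)k·t_infl) started at ρ₀ = 0.01.
Bounds: k ∈ (0, 10] s⁻¹, ρ ∈ (0, 10]. A fit is "converged" only when
the optimiser reports success and neither k nor ρ is pinned at a bound.
Flat or net-decreasing traces return `converged=False` with a
diagnostic rather than raising, because a screening pipeline must keep
going past dead wells.

Characteristic times come from the tangent at the inflection of the
fitted fraction curve. In reduced time x = (1+ρ)kt:
x_infl = ln(1/ρ), f(x_infl) = (1−ρ)/2, df/dx = (1+ρ)/4,
x₀ = x_infl − 2(1−ρ)/(1+ρ) (lag), x₁ = x_infl + 2 (end),
x(f=½) = ln((1+2ρ)/ρ). These closed forms are verified in the test
suite against an independent numerical tangent construction (symbolic
differentiation, sign-change bracketing, Brent root-finding) to 10⁻⁶
relative over ρ ∈ [10⁻⁴, 0.5] × k ∈ [10⁻⁴, 10⁻²] s⁻¹. The construction
requires ρ < 1; at ρ ≥ 1 the inflection falls at non-positive time and a
domain error is raised. Two half-aggregation times are reported: the
tangent midpoint (t₀+t₁)/2, which is what kinetic tables in this assay
tradition tabulate, and the exact f = 0.5 solution; they differ only in
the third significant figure for small ρ and coincide as ρ → 0.

"Plateau" means the fitted plateau (fraction 1), not the largest
observed datum; this makes the end time robust to endpoint noise.

### Identifiability of ρ

ρ is set by the curvature of the lag phase only, and is the
weakest-identified parameter. For the default study conditions
(k ≈ 3.5 × 10⁻³ s⁻¹, ρ ≈ 5 × 10⁻³, 60-s sampling, Gaussian noise with
σ = 2% of amplitude) the Cramér–Rao bound gives a relative standard
deviation of ~14% on ρ (and ~2.5% on k); the observed median recovery
errors (~12% and ~2%) sit at that bound, so they reflect the information
content of such a trace, not the optimiser. Per-parameter standard
errors are reported from the fit covariance and should be quoted
alongside ρ and k_n. Averaging replicate traces before fitting, denser
sampling through the lag phase, or lower-noise acquisition are the ways
to tighten ρ; the pipeline itself cannot.

## Enzyme inhibition

Initial rates are OLS slopes of absorbance over the first 120 s
(assumed linear; no substrate-depletion correction), converted to µM/s
with ε = 13 600 M⁻¹ cm⁻¹ for the TNB chromophore at 412 nm and a 1-cm
path; both are overridable where a different plate geometry applies.

`K_M`/`V_max` come from an unweighted OLS fit on double-reciprocal
(Lineweaver–Burk) axes, matching how such plots are conventionally
analysed; the noise amplification inherent to reciprocal axes is
accepted for parity with that practice, and a direct nonlinear
Michaelis–Menten fit is provided as a cross-check. A nonpositive 1/V_max
intercept is reported as an indeterminate fit, never as a negative
constant.

Mechanism classification uses the ratios r_K = K_M,inh/K_M,free and
r_V = V_max,inh/V_max,free with a relative tolerance (default 0.35)
separating "unchanged" from "shifted": noncompetitive when K_M is
unchanged and V_max is down; competitive when V_max is unchanged and
K_M is up; uncompetitive when both fall proportionally; mixed
otherwise. The 0.35 default is chosen so that a K_M drift of
0.15 → 0.20 (ratio 1.33) — the kind of shift practitioners describe as
"little impact" — still reads as unchanged, while a genuine competitive
K_M shift (≥ ×1.4) does not. The call is a pure function of
(r_K, r_V, tolerance), so substrate ordering and rate rescaling cannot
change it.

IC50 is a Hill fit `Inh = max·[I]ʰ/(IC50ʰ + [I]ʰ)` with the maximum
bounded at 100%. When the data never cross 50% inhibition the IC50 is
reported indeterminate rather than extrapolated; if the nonlinear fit
fails with a valid bracket, a log-linear interpolation between the
bracketing points is returned and flagged `interpolated`. For a
noncompetitive inhibitor the rate law implies IC50 = K_i at any
substrate concentration, which the suite uses as a closed-form check.

Units follow assay convention: substrate in mM on reciprocal axes,
rates in µM/s. Conversions are explicit arguments, never implicit.

## Binding by fluorescence quenching

Stern–Volmer: OLS of F₀/F against [Q] over all titration points (the
[Q] = 0 point anchors the intercept near 1); K_q = K_sv/τ₀ is reported
only when the unquenched lifetime is supplied. The double-log isotherm
log₁₀[(F₀−F)/F] = log₁₀K_a + n·log₁₀[Q] is fitted with [Q] converted to
molar first, so K_a is in M⁻¹. Points with F ≥ F₀ have no defined log
and are excluded and counted; fewer than three usable points is an
error that reports the exclusion count. Sequential-addition dilution of
the protein is not corrected for by default. The double-log analysis
assumes static (ground-state complex) quenching with identical
independent sites; no static-vs-dynamic discrimination or FRET distance
analysis is attempted.

## Radical scavenging

RSC(%) = 100·(A_ctrl − A)/A_ctrl at 517 nm, reported unclipped — values
slightly below 0 or above 100 are measurement noise and are preserved
because clipping would bias replicate averages. "Total quench" is the
smallest measured concentration with RSC ≥ 99% (threshold overridable);
99% rather than 100% because complete bleaching reads just under or
over 100 within noise. No solvent-blank subtraction by default and no
Trolox-equivalent conversion.

## Synthetic data

All generators draw from `numpy.random.default_rng(seed)`; identical
(config, seed) reproduces identical bytes through the CSV writer, and
every generator returns its ground truth alongside the data.

- **ThT traces** — deterministic autocatalytic curve plus iid Gaussian
  noise, σ = noise_fraction × amplitude (default 2%, consistent with
  the <5% replicate SD typical of these assays). The control truth is
  k_n = 1.83 × 10⁻⁵ s⁻¹ and k_e = 175.73 M⁻¹s⁻¹ at 20 µM monomer;
  condition multipliers emulate flavonoid co-incubation (k_n ×3.2;
  k_n ×4.5 with k_e ×0.46) and enzyme-induced aggregation (k_n ×0.44,
  k_e ×1.76). Sampling every 60 s over 0–21 600 s covers the slowest
  end time (~4 000 s) with a long plateau. Not emulated: stochastic
  nucleation (no Gillespie dynamics), heteroscedastic or correlated
  noise, evaporation/photobleaching drift — so passing recovery tests
  demonstrates estimator correctness under the stated noise model, not
  robustness to every instrumental artefact.
- **Ellman progress curves** — exact standard rate laws
  (noncompetitive `v = V_max·S/((K_M+S)(1+I/K_i))`, competitive
  `v = V_max·S/(K_M(1+I/K_i)+S)`, uncompetitive
  `v = V_max·S/(K_M+S(1+I/K_i))`) with multiplicative rate noise
  (default 2–3%); defaults V_max = 3.94 µM/s, K_M = 0.15 (substrate-axis
  units), K_i = 40 µM, four substrate levels matching a 1–4 µL
  substrate-addition design. Curves are exactly linear within the
  window, so the initial-rate linearity assumption holds by
  construction.
- **Quench titrations** — inverse of the double-log isotherm with
  multiplicative intensity noise; the default quencher grid follows a
  sequential-addition design (0.5–10 µL of a 10 µM stock into ~140 µL).
- **DPPH series** — Hill-shaped bleaching
  `A = A_ctrl(1 − cʰ/(EC50ʰ + cʰ))` with EC50 = 1.5 µM and h = 7. The
  steep default reproduces the near-stoichiometric transition a strong
  scavenger shows on a 1, 2, 3, 4 µM grid (negligible bleach at 1 µM,
  ~99% at 3 µM); a gentler h would smear the total-quench concentration
  across the grid, which is not what such data look like.

## Benchmark problem sizes

The recovery benchmarks run 50 single-replicate ThT traces (361 points
each) and 100 triplicate Ellman datasets (4 substrate levels × 2
inhibitor levels used); the oracle-equivalence grid is 10 × 10 in
(k, ρ). These sizes give stable medians/rates while keeping the full
suite interactive.

## Known limitations

- ρ (hence k_n) carries ~10–15% intrinsic uncertainty at realistic
  noise (see identifiability above); compare conditions via fold
  changes of replicate means, not single-trace values.
- Double-reciprocal fitting amplifies low-substrate noise; the
  nonlinear cross-check should be consulted when the two disagree.
- The IC50 Hill model assumes monotone dose response; bell-shaped
  curves are not handled.
- CSV I/O accepts one dialect only (comma separator, point decimal,
  UTF-8, header required); decimal-comma exports must be converted
  upstream, and the reader's row-numbered schema errors are designed to
  make that failure obvious.
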