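# fibrilkin

Analysis toolkit for in-vitro anti-amyloid drug-discovery assays:
thioflavin-T (ThT) aggregation kinetics of amyloid-β peptide,
acetylcholinesterase (AChE) inhibition by Ellman's assay, ligand–protein
binding by intrinsic-fluorescence quenching, and DPPH radical-scavenging
capacity. It is aimed at wet-lab groups characterising small-molecule
aggregation inhibitors (e.g. flavonoids such as apigenin and quercetin)
who need the plate-reader-to-parameter-table step to be scripted,
testable and reproducible.

## Models

**Aggregation kinetics.** A ThT fluorescence time course is fitted to the
two-parameter autocatalytic model of fibril formation,

    f(t) = ρ·{exp[(1+ρ)kt] − 1} / (1 + ρ·exp[(1+ρ)kt]),

where `f` is the fibrillar fraction, `k` (s⁻¹) the overall rate constant
and `ρ = k_n/k` the dimensionless nucleation-to-overall ratio. The raw
signal is modelled as `F_bg + A·f(t)` with baseline and amplitude fitted
jointly. Given the monomer concentration `a`, the nucleation and
elongation rate constants follow as `k_n = ρk` and `k_e = k/a`. The
tangent at the inflection of the fitted curve yields the lag time `t_0`
(intercept with f = 0), the end time `t_1` (intercept with the plateau)
and two half-aggregation times: the midpoint `(t_0+t_1)/2` and the exact
`f = 0.5` solution. In reduced time `x = (1+ρ)kt` these have closed
forms (`x_infl = ln 1/ρ`, `x_0 = x_infl − 2(1−ρ)/(1+ρ)`, `x_1 = x_infl + 2`).

**Enzyme inhibition.** Ellman progress curves (412 nm) are reduced to
initial rates by OLS over the early window and converted to µM/s via
Beer–Lambert (ε = 13 600 M⁻¹cm⁻¹ by default). Rates give dose–response
inhibition and a Hill-equation IC50, and — across substrate levels — a
Lineweaver–Burk `K_M`/`V_max` fit. Comparing inhibited and free fits
classifies the mechanism (competitive / noncompetitive / uncompetitive /
mixed).

**Binding.** Quenching titrations are analysed with the Stern–Volmer
equation `F₀/F = 1 + K_sv[Q]` and the double-logarithmic isotherm
`log[(F₀−F)/F] = log K_a + n·log[Q]`, giving the association constant
`K_a` (M⁻¹) and binding-site number `n`.

**Radical scavenging.** DPPH absorbance at 517 nm gives
`RSC(%) = 100·(A_ctrl − A)/A_ctrl` and the minimal concentration
achieving total quench.

A seeded synthetic-data module (`fibrilkin.simulate`) generates all four
assay types with known ground truth, so the entire pipeline is testable
without instrument data.

## Worked example

```python
import fibrilkin as fk
from fibrilkin.simulate import gen_tht, ScenarioConfig

traces, truth = gen_tht(config=ScenarioConfig(seed=1, n_replicates=1))
for tr in traces:
    fit = fk.fit_trace(tr)
    d = fk.derived_times(fit)
    print(f"{tr.condition:10s} k_n={fit.k_n*1e5:5.2f}e-5 s^-1  "
          f"k_e={fit.k_e:6.1f} M^-1 s^-1  t0={d.t0_lag:6.1f} s  "
          f"t1/2={d.t_half_mid:6.1f} s  t1={d.t1_end:6.1f} s")
```

prints

```
control    k_n= 1.60e-5 s^-1  k_e= 180.4 M^-1 s^-1  t0= 948.3 s  t1/2=1497.9 s  t1=2047.4 s
apigenin   k_n= 5.69e-5 s^-1  k_e= 177.7 M^-1 s^-1  t0= 608.4 s  t1/2=1153.5 s  t1=1698.6 s
quercetin  k_n= 8.61e-5 s^-1  k_e=  78.7 M^-1 s^-1  t0= 670.5 s  t1/2=1812.4 s  t1=2954.4 s
ache       k_n= 0.64e-5 s^-1  k_e= 322.1 M^-1 s^-1  t0= 763.5 s  t1/2=1073.3 s  t1=1383.2 s
```

One noisy replicate per condition (2% amplitude noise, 60-s sampling):
the flavonoid-like conditions recover their injected nucleation-rate
increases (×3.2 and ×4.5 over the control k_n of 1.83 × 10⁻⁵ s⁻¹, within
fit noise), quercetin halves the elongation rate, and the enzyme-like
condition shows the opposite pattern (nucleation down, elongation up,
shorter half-time). The same analyses are available from the shell:

```sh
fibrilkin simulate tht --seed 1 --out sim/
fibrilkin fit-tht --input sim/tht.csv --monomer-conc 20e-6 \
    --control-condition control --out results/
fibrilkin fit-ellman --input ellman.csv --out results/
fibrilkin quench --input quench.csv --tau0 1e-8 --out results/
fibrilkin dpph --input dpph.csv --out results/
```

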