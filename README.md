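# pbsneutron

Out-of-field neutron dosimetry for pencil beam scanning (PBS) proton
therapy.

In proton therapy, the dose delivered away from the treated volume is
dominated by secondary neutrons, which today's treatment planning systems
ignore. Estimating these stray doses matters most for children, pregnant
patients, and patients with implanted devices. `pbsneutron` packages the
computational building blocks used to characterize the neutron field in a
PBS treatment room and to extrapolate it to other treatment plans:

* **Neutron fluence spectra** — lethargy-binned energy grids
  (ln E<sub>i</sub>/E<sub>i−1</sub> constant, default 0.26), per-lethargy
  views, band fractions for the characteristic thermal / epithermal /
  evaporation / high-energy structure, and a deterministic parametric
  generator of treatment-room spectra from the proton energy layers of a
  plan.
* **Monitor response convolution** — true ambient dose equivalent
  H\*(10) = Σᵢ Φᵢ h\*(Eᵢ) from tabulated fluence-to-H\*(10) conversion
  coefficients, the H\*(10)-weighted expected response
  R̄ = Σ Φ h\* R / Σ Φ h\* of an area neutron monitor, and the reading it
  would display. Real monitors under-respond badly above ~20 MeV (moderated
  counters) or over-respond (some TEPCs); the convolution quantifies that.
* **TEPC microdosimetry** — the variance method
  (ȳ_D = m·V_rel·D̄/ℓ̄, H\* = D̄(a + b·ȳ_D) with a = 0.88,
  b = 0.09 µm/keV, and a photon/neutron split from
  ȳ_D = ȳ_{D,γ}d_γ + ȳ_{D,n}d_n with 1.4 and 96 keV/µm endpoints) and the
  single-event method
  (H\* = N_low ∫₀.₅¹⁰ Q(y)d(y)dy + N_high ∫₁₀¹⁰²⁴ Q(y)d(y)dy with
  N_low = 1.1, N_high = 0.8), plus a seeded event-stream simulator with
  analytically known ground truth.
* **Scaling laws** — a per-position multiplicative model of H\*(10) per Gy
  target dose versus plan parameters: exactly linear in field-size area,
  linear in (effective) range, quadratic in modulation width, with the
  range shifter treated as adding its water-equivalent thickness (3.1 cm)
  to the range and the air gap deliberately ignored. Fitted in log space
  per position, with an organ-dose estimator that chains field-size,
  range, modulation, and inverse-square distance corrections.
* **Uncertainty budget** — positioning (uniform-distribution σ from a dose
  mesh), counting statistics (1/√N), calibration, energy-response, and
  target-dose components combined in quadrature at k = 1.
* **Synthetic campaigns** — factorial plan grids with ground-truth doses
  from a known scaling model plus lognormal measurement noise (15–30 % per
  position), standing in for Monte Carlo runs and measurement campaigns.

## Worked example

Simulate a campaign, fit the scaling model, and predict the dose for a
brain-treatment-like plan (33 cm² field, 18 cm range, 5 cm modulation) in
the beam direction, extrapolated to 10 cm from the isocenter:

```sh
$ pbsneutron simulate-campaign --seed 42 --out sim
wrote 420 rows to sim/campaign.csv
$ pbsneutron fit-scaling --campaign sim/campaign.csv --out model.yaml
position A: n=70 rmse(log)=0.2098
position B: n=70 rmse(log)=0.1294
...
$ pbsneutron predict-dose --model model.yaml --field-size 33 --range 18 \
    --modulation 5 --position B --distance 0.1
H*(10) at B: 25.3508 uSv/Gy
baseline A0 (B, reference plan): 64.6748 uSv/Gy
factor field_size: 0.3300
factor range: 1.3018
factor modulation: 0.9124
factor inverse_square: 1.0000
H*(10) at 0.1 m (inverse square from 1 m): 2535.08 uSv/Gy
```

Reading the factors: relative to the fitted reference plan (100 cm² field,
15 cm range, 10 cm modulation, measured at 1 m in the beam direction), the
smaller field divides the dose by ~3 (33/100), the longer range raises it
by ~30 %, the narrower modulation lowers it by ~9 %, and moving from 1 m to
10 cm multiplies it by 100 via the inverse square law.

Spectrum synthesis and monitor convolution:

```sh
$ pbsneutron spectrum --layers layers.csv --out spectrum.csv
source energies: 103-212 MeV
total fluence: 6.5 n/cm2/Gy
fraction thermal: 0.1540
...
$ pbsneutron convolve-response --spectrum spectrum.csv --monitor lb6411
H*(10): 0.00161617 uSv/Gy
expected response (lb6411): 0.5071
predicted reading: 0.00081955 uSv/Gy
```

The bundled conversion-coefficient and monitor-response tables are
synthetic fixtures shaped after published curves (see the `_synthetic`
file names); replace them with tables of record for real analyses. An
expected response of ~0.5 shows the familiar failure mode of a moderated
counter in a high-energy-rich field: half the true H\*(10) goes unseen.

## Layout

```
src/pbsneutron/
  spectra.py             energy grids, spectra, parametric generator
  response.py            h*(E) conversion, monitor response convolution
  tepc.py                variance + single-event microdosimetry
  scaling.py             scaling-law model, fitting, organ-dose estimate
  uncertainty.py         k = 1 uncertainty budget
  synthetic_campaign.py  plan grids, ground truth, noise
  _io.py, cli.py         CSV/YAML formats and the pbsneutron CLI
  data/                  synthetic conversion/response fixtures
docs/methods.md          model assumptions, defaults, limitations
```
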