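# Methods

This note records the models implemented in `pbsneutron`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Spectra

Neutron fields in PBS proton therapy rooms are conventionally tallied on
constant-lethargy energy grids. `EnergyGrid` bins are half-open
[E<sub>i</sub>, E<sub>i+1</sub>) with E<sub>i+1</sub>/E<sub>i</sub> =
exp(w); the default grid runs from 10⁻⁹ MeV to at least 240 MeV (the
transport cutoff comfortably above the 212 MeV maximum clinical proton
energy) with w = 0.26. Fluence is stored as the per-bin integral, not a
density, so band sums are exact; the per-lethargy view divides by the bin
lethargy width and is exactly invertible.

The parametric generator superposes four components, each normalized to
unit fluence on the grid and weighted by its amplitude:

* thermal Maxwellian, fluence density ∝ E·exp(−E/kT) with
  kT = 2.585 × 10⁻⁸ MeV (room temperature);
* epithermal 1/E tail, supported on 0.5 eV–10 keV by default;
* evaporation Maxwellian with kT = 1 MeV (typical nuclear evaporation
  temperature);
* high-energy (cascade) Gaussian centred at 0.6 × E<sub>max</sub> with
  σ = 0.15 × E<sub>max</sub>, truncated to (0, E<sub>max</sub> + 3σ].

The component forms and the default band boundaries (thermal < 0.5 eV,
epithermal to 10 keV, evaporation to 20 MeV, high-energy above) are package
conventions: treatment-room spectra show these three peaks, but no standard
numeric boundaries exist, so all of them are configurable. The generator is
deterministic, homogeneous of degree 1 in the amplitudes, and moves the
cascade peak up in energy with the maximum proton energy, as real spectra
do when the range (and hence beam energy) grows.

## Conversion and monitor response

True H\*(10) is Σᵢ Φᵢ h\*(Eᵢ) with Eᵢ the geometric-mean bin energy
(consistent with logarithmic binning) and h\*(E) interpolated log-log
between tabulated points — both quantities vary over decades of energy.
The expected monitor response is the H\*(10)-weighted mean of R(E), which
makes it scale-free in the spectrum, and the predicted reading is defined
as true H\*(10) × expected response, so the factorization identity holds
by construction and is enforced by test.

Response tables are interpolated log-log as well, except when a table
contains zeros (monitors with a hard high-energy cutoff), where the
response is interpolated linearly against log E — log-log is undefined at
zero. Inside a monitor's declared valid range but beyond its tabulated
energies, R extends as a constant at the edge value; evaluating non-zero
fluence outside the valid range raises instead of silently returning zero,
because a fabricated cutoff would bias the convolution invisibly.

The shipped conversion table and the six monitor response files are
synthetic fixtures: they follow the shape of the published ambient dose
equivalent curve and of the qualitative response behaviour of each
instrument family (moderated sphere, extended-range designs, TEPCs), and
the conversion table is explicitly extended from 201 to 240 MeV by smooth
continuation. They carry `_synthetic` in their file names and provenance
comments in their headers; none is a metrological claim.

## TEPC algorithms

**Variance method.** Mean absorbed dose per charge-integration interval is
D̄ = (q̄/e)(W/e)/(M·m_det) with W/e = 28 eV per ion pair by default. The
relative variance of the per-interval doses uses the unbiased (n−1)
estimator for small-sample correctness. The dose-mean lineal energy is
computed as ȳ_D = m_det · V_rel · D̄ / ℓ̄. This rendering deserves a
prominent note: the four quantities admit only one dimensionally consistent
arrangement (energy per unit length), and that is the one implemented —
mass × relative variance × dose gives energy, divided by the mean chord
length (1.88 µm default). No beam-intensity-variance term is subtracted
from V_rel (plain variance method); in fields with strongly fluctuating
delivery this overestimates ȳ_D.

Dose equivalent is H\* = D̄(a + b·ȳ_D) with a = 0.88 and b = 0.09 µm/keV,
constants appropriate for high-energy neutron fields. The photon/neutron
split inverts ȳ_D = ȳ_{D,γ}d_γ + ȳ_{D,n}d_n with endpoints 1.4 and
96 keV/µm; since measurement noise can push the estimator past an
endpoint, out-of-range values are clamped to [0, 1] with a warning rather
than rejected. For scanned irradiations the single-spot ȳ_D is looked up
by maximum proton energy; a non-exact energy match falls back to the
nearest entry with a warning.

**Single-event method.** H\* = N_low Σ Q(yᵢ)dᵢ (0.5 ≤ y < 10 keV/µm) +
N_high Σ Q(yᵢ)dᵢ (10 ≤ y ≤ 1024 keV/µm) with N_low = 1.1 (compensating
the 0.5 keV/µm electronic threshold) and N_high = 0.8 (compensating the
proton-edge y-scale calibration), yᵢ the geometric-mean bin lineal energy.
d(y) is stored as absolute dose per bin (Gy) so the sums yield Sv
directly; a normalized view exists for plotting. Q(y) is the standard
piecewise quality factor with lineal energy substituted for LET
(1 below 10; 0.32y − 2.2 to 100; 300/√y above), continuous at 10 with a
small documented step at 100 (29.8 vs 30.0); the exact function inside
instrument firmware is not public, so Q is user-overridable via
`HawkConfig.quality_function`.

**Event-stream simulator.** Events arrive as a compound Poisson process
(default 50 events per 0.1 s interval); lineal energies are drawn from a
two-component lognormal mixture whose components are specified by their
dose-mean y (1.4 and 96 keV/µm defaults) and geometric standard deviation
(1.8 photon-like, 1.6 neutron-like). The photon *dose* fraction is mapped
analytically to an event-type probability, and the returned ground truth
(D̄, ȳ_D = E[y²]/E[y]) is exact for the generating mixture, which makes
the recovery tests self-contained: for compound Poisson sampling the
variance-method estimator is consistent for exactly this quantity.

## Scaling model

Per position p:

H(plan) = A₀ₚ · (FS/100 cm²) · (1 + c_R,ₚ(R_eff − 15 cm)) ·
(1 + c_M1,ₚ·M + c_M2,ₚ·M²)/(1 + 10·c_M1,ₚ + 100·c_M2,ₚ)

with R_eff = R + 3.1 cm when the range shifter is in (`effective_range`
mode, the first-approximation rule that the shifter acts like extra range)
or R with a flat ×2 factor (`flat_factor` mode, the campaign-average
alternative). The reference plan (100 cm², 15 cm, 10 cm, no shifter) is
the central configuration around which single-parameter sweeps are
typically reported, which makes A₀ directly interpretable. The air gap is
accepted and deliberately ignored — no significant air-gap effect was
observed at room positions — with a one-time log message so users know
the omission is intentional.

Multiplicative separability across field size, range and modulation is the
package's modelling choice, not a physical law: the axes have
interdependencies (the range effect depends on position and modulation,
for instance), which is why coefficients are per-position and why the fit
reports the log-space residual spread — cross-position extrapolation
should not be trusted beyond a factor of a few. The fit minimizes
least-squares residuals in log space because doses span four decades and
relative error is the meaningful metric; rows are sorted by irradiation id
so the result is permutation-invariant; coefficient standard errors come
from the Gauss-Newton covariance (JᵀJ)⁻¹·s². The design must contain at
least two distinct field sizes and ranges and three distinct modulation
widths (the quadratic term needs three support points); missing variation
raises an error naming the axis. The fitted law is exactly linear in
field-size area by construction, so the 9 → 900 cm² prediction ratio is
100 independent of the fitted coefficients — the fit determines the other
axes.

The organ-dose estimator chains, in order: field-size ratio, range-law
ratio between the two effective ranges, modulation-law ratio, and the
inverse square of the distance ratio, returning each factor separately so
the 100 → 33 cm² step is visible as a division by 3.03. Inverse-square
extrapolation from a room position toward a phantom surface is a rough
model — the treated volume is not a point source at short distances — and
is provided as such.

## Uncertainty budget

Positioning: the dose is volume-averaged (mean over lattice points within
the detector radius) at the nominal position and at ±shift (default 5 cm,
the placement precision) along each axis; the component is
(max − min)/(√12 · nominal), the k = 1 standard deviation of a uniform
distribution spanning the observed dose range. The nominal average is
included in the min/max pool. Counting statistics is 1/√counts.
Energy response enters as |1 − R̄| with over/under metadata when the
reading is *not* corrected for the response; when the correction is
applied (the predicted-reading path), its residual uncertainty should be
entered instead — folding |1 − R̄| into quadrature on top of a correction
would double-count. Components are combined in quadrature, the standard
treatment for independent k = 1 components; whether the original campaigns
combined linearly or in quadrature is not documented, so quadrature is an
assumption of this package.

## Synthetic campaigns

The generator emulates the *structure* of a verification campaign: a
factorial grid over field size (9–625 cm²), range (8–25 cm), modulation
(3–25 cm, dropping combinations with modulation > range) and range-shifter
state; six positions; ground truth from a known scaling model; optional
per-position monitor-response bias (off by default so fitting tests are
not confounded); and multiplicative lognormal noise with per-position σ
between 0.15 and 0.30, matching typical combined measurement
uncertainties. The default grid yields 70 irradiations × 6 positions =
420 rows, sized so the full fit-and-recover cycle runs in well under a
second.

The default truth model's baselines (A₀ = 66, 30, 20, 10, 3, 1 µSv/Gy at
B, A, C, F, E, D) and slopes were chosen once so that generated campaigns
reproduce the qualitative room behaviour: doses falling with distance and
backward angle (B > F > E ≥ D), a range factor of roughly 3 from 10 to
25 cm, a ~40 % modulation effect from 3 to 20 cm, and a range-shifter
ratio below 2.5 everywhere except position D (which sits in line of sight
of the shifter and exceeds it). They are fixtures for testing the
machinery, not measurements of any facility. The positions for A and C
ship as synthetic placeholders (1.8 m/45°, 2.0 m/30°) because their true
geometry was never published.

What passing tests therefore show: the estimators recover the parameters
of data generated by their own model class under realistic noise, and the
algebraic identities hold. What they do not show: that the multiplicative
law is an accurate description of any particular treatment room, that the
synthetic spectra match measured ones quantitatively, or that the bundled
response fixtures describe real instruments.

## Numerical conventions and degenerate inputs

* Representative bin energies are geometric means of the edges throughout.
* CSV floats are written with 17 significant digits (shortest-round-trip
  territory), so writer/reader pairs are value-identical.
* An all-zero spectrum: H\*(10) = 0; band fractions are NaN with a warning
  (keeps batch pipelines alive); the expected monitor response is an error
  (undefined weighted mean).
* A constant charge series gives V_rel = 0 and hence ȳ_D = 0; an all-zero
  series is an error.
* Fits clip the range/modulation terms at 10⁻⁹ inside the log to keep the
  optimizer defined away from the solution; predictions that end up
  non-positive raise a model-validity error rather than returning a
  negative dose.
* Problem sizes in tests: variance-method recovery uses 10⁵ intervals
  (~0.5 s); the bias-shrinkage check averages 15 seeds at 10³ vs 10⁴
  intervals; campaign fits use the 420-row default design.

## Known limitations

No radiation transport: spectra are parametric shapes, not physics. No
in-phantom doses (room positions only). No correlated-uncertainty
propagation. The scaling law is descriptive within the campaign domain;
outside it (field sizes beyond 625 cm², ranges outside 8–25 cm) the
package warns and extrapolates linearly, which is unvalidated. The
0.84-type range-correction factors quoted in the literature for specific
plan pairs depend on fitted coefficients never published; this package
computes range corrections from its own fitted model instead of
hard-coding literature values.
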