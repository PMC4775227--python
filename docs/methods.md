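# Methods

## Scope and data model

The pipeline starts from centroided isotope-cluster peak lists — one
(m/z, intensity) list per peptide, charge state and condition — supplied as
plain CSV/TSV. Everything upstream (vendor file conversion, chromatography,
MS/MS peptide identification, peak picking) is out of scope. A cluster must
have at least 4 peaks, strictly increasing m/z, and consecutive spacings
within ±20 % of the median spacing; violations are rejected with the
offending cluster or row named.

## Envelope deconvolution

Each series (one peptide/charge over temperatures or times) is fitted
jointly with a two-Gaussian mixture at the observed discrete peak positions
only — no continuous resampling, since the data are discrete isotopologue
peaks. The centroids μ̄₁ < μ̄₂ and the single width σ are shared across the
series; the component areas are per-spectrum and bounded non-negative.
Sharing one σ for both components encodes the assumption that both
subpopulations carry the same envelope width, and keeps the per-spectrum
problem linear in the areas.

Numerical choices:

- **Ordering constraint.** μ̄₂ is parameterized as μ̄₁ + gap with gap > 0, so
  "high-exchanging" always refers to the heavier centroid regardless of the
  series orientation.
- **Initialization.** μ̄₁ and μ̄₂ from the centroids of the lowest- and
  highest-condition spectra (or the unexchanged / fully deuterated controls
  when present — controls inform initialization only and are excluded from
  the fit); σ from the RMS width of the lowest-condition spectrum; areas
  from the total intensity split by a coarse 11-point fraction grid.
- **Convergence.** Trust-region least squares, relative cost tolerance
  1e-10, iteration cap 500 per start, up to 3 jittered restarts before a
  fit is flagged non-convergent. Standard errors come from the SVD
  pseudo-inverse of the Jacobian scaled by the residual variance.
- **Identifiability.** If one component's area share stays below 2 % across
  the whole series, its centroid is flagged unidentifiable rather than
  reported as a trustworthy number.

Per-peak attribution divides each observed intensity in proportion to the
two fitted component densities at that peak's m/z. This is the unique rule
that conserves the observed intensity exactly per peak and reduces to the
components themselves in the noise-free limit. Peaks beyond both tails
(both densities below ~1e-300) are split 50/50 with a warning; such peaks
carry negligible intensity by construction. Uptake values use the
intensity-weighted centroid with the two-point back-exchange correction
(unexchanged and fully deuterated anchors), the only correction compatible
with the stated controls; replicate aggregation happens at the fraction
level only (mean ± SEM across experiments), and uptake differences
propagate SEM in quadrature.

## Transition, kinetics, Arrhenius

The thermal transition equation is evaluated through a logistic `expit`, so
it is stable for steepness arguments far beyond ±700. Temperatures are
Kelvin internally and Celsius at every interface (R = 8.314462618 J/mol/K).
ΔH is labelled *apparent* throughout: the transition is irreversible under
the assay conditions, so the fitted steepness is not an equilibrium
unfolding enthalpy and is used only to locate the midpoint. Falling
transitions are fitted with f_max < f₀ rather than by pre-flipping the
data, preserving the raw orientation in reports. Initialization puts T_m at
the sampled condition closest to the half-range crossing and |ΔH| at
3e5 J/mol; per-point standard errors, when supplied, enter as inverse
weights. A midpoint more than 10 K outside the sampled range raises an
extrapolation flag. Kinetic fits leave both plateaus free (the data decide
the orientation); a rate collapsing to the positivity floor is flagged
non-convergent rather than returned silently. The Arrhenius step is plain
OLS of ln k on 1/T with E_a = −slope·R exactly.

## Binding

The exact two-species bound fraction is computed in the cancellation-free
form 2P/(P+D+K+√((P+D+K)²−4PD)), which agrees with a bisection solution of
the mass-action system to 1e-10 over six decades and reduces continuously
to the hyperbolic limit at D → 0. The global anisotropy fit shares K_D,
r_min and r_max across all pre-incubation conditions (the default; the
alternative of per-condition bounds was considered and rejected as
over-parameterized for four-condition panels) and estimates one active
fraction per condition, bounded to [0,1]; estimates pinned at a bound are
flagged. The active concentration is a_c × theoretical trimer, with
theoretical trimer = monomer concentration / 3, held constant along a
dilution series because formed trimers do not dissociate on dilution in
this system — an explicit model assumption, stated in reports. Trimer–DNA
stoichiometry is 1:1 on the three-element probe; multi-site binding cannot
be distinguished at this resolution.

## Monomer–dimer setpoint model

"Fraction of dimer" means the fraction of monomer *units* in dimers,
f_D = 2[D]/c, which gives the clean closed form f_D = ½ at c = K_D,dim; the
molecule-count alternative [D]/([M]+[D]) is available via
`fraction_convention="molecules"` (it gives ⅓ at c = K_D,dim). Under either
convention the predicted midpoints for 10–130 nM agree with the expected
47–53 °C window only to within about 1 °C; no attempt is made to force
agreement. The mass-action solution uses
[M] = K(√(1+8c/K)−1)/4, which satisfies [M]+2[D] = c to machine precision.
Fits of (c, T_m) data carry two flags: a low-concentration caveat when no
point lies below K/3 (the monomer plateau is then an extrapolation and the
estimates are rough), and a K_D-identifiability flag that fires when no
sampled concentration falls inside the transition region (dimer fraction
between 0.1 and 0.9). (c, T_m) points from different assays are fitted
unweighted.

## Synthetic data

The generators mirror the fitted models exactly, so round-trip tests
separate optimizer behaviour from model error:

- **Envelopes.** Peaks on a grid with 1.00336 Da spacing per unit charge (a
  symmetric compromise between the ¹³C and ²H isotopologue spacings; the
  choice only affects synthesis because generator and fitter share whatever
  spacing the data carry). Intensities are the mixture density times the
  grid step and a total area (default 1e6 arbitrary units), plus additive
  Gaussian noise scaled to the maximum clean intensity and truncated at
  zero; the default noise level is 2 % of the peak maximum. Natural
  isotopic fine structure is not modelled — the low-exchanging Gaussian
  subsumes it, as the fitted model assumes. The default thermal law uses
  T_m = 36.15 °C with steepness 3.5e5 J/mol, making the 10–90 % transition
  span roughly 10 °C over a seven-temperature 20–42 °C design; kinetic
  series use the standard 10–1000 s time points.
- **Titrations.** Twofold dilution series (12 steps) from four
  pre-incubation conditions against a 10 nM probe, K_D = 1.1 nM, anisotropy
  noise 2 % of the dynamic range.
- **Setpoint data.** Five concentrations from 50 to 5000 nM around a
  (330 nM, 53 °C, 33 °C) model with 0.3 °C midpoint noise.

All randomness flows from explicit integer seeds — never global state — and
a fixed seed reproduces the data bit for bit. What passing recovery tests
show is that the estimators are unbiased and precise *under the generating
model*; they do not certify behaviour under model violations real spectra
can show (asymmetric envelopes, overlapping peptides, heteroscedastic
detector noise, drifting back-exchange), which is the main limitation to
keep in mind when transferring tolerances to real data.

## Precision of the transition midpoint

A single seven-point series with 2 % fraction noise and all four transition
parameters free carries a Cramér–Rao bound of about 0.25 °C on T_m, so
sub-0.2 °C precision requires pooling. The recovery study therefore pools
three replicate series per fit — matching the practice of fitting the
pooled points of three independent experiments — which brings the standard
error to about 0.14 °C and the 95 % recovery error within ±0.3 °C.

## Problem sizes

The simulation studies use 20 seeds per scenario with the designs above
(7 spectra × 12 peaks per deconvolution; 21 pooled points per transition
fit; 7 time points per kinetic fit; 48 titration points per binding fit;
5 concentrations per setpoint fit). These sizes match the study designs the
generators emulate; the whole suite and the acceptance script each complete
in a few seconds.
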