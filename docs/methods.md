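# Methods

This note documents the models implemented in `mechamap`, the assumptions
behind the synthetic-data generator, the numerical choices, and what the
test suite does and does not establish about real instrument data.

## 1. Force-curve model

### Forward physics

A rigid sphere of radius R indenting an isotropic elastic half-space
follows the Hertz law F(δ) = (4/3)·E/(1−ν²)·√R·δ^{3/2}. During a ramp the
piezo travel z couples to the cantilever deflection F/k, so the measured
force at travel s = z − z₀ past contact solves the fixed-point equation
F = A·(s − F/k)^{3/2}; the simulator solves it per sample by Newton
iteration (`physics.force_at_travel`). The approach terminates at the
first sample at or above the force trigger; if the trigger is unreachable
within the maximum ramp the curve is returned with a `truncated` flag.
The retract segment mirrors the approach with a single negative
Gaussian-shaped adhesion well near contact; it exists so retract code
paths are exercised but is never fitted — only the approach segment
carries the elasticity information used here.

Key acquisition defaults (all configurable, SI units internally):
bead diameter 10.2 µm; spring constant 0.2 N/m (instrument range
0.15–0.24 N/m); force trigger 2 nN; ramp rate 2 µm/s; ramp length up to
50 µm; 10 × 10 grid over 50 × 50 µm; section thickness 20 µm. The fit
window is capped at 10% of the section thickness (2 µm of indentation) so
the rigid-substrate contribution stays negligible without an explicit
bottom-effect correction. The Poisson ratio is ν = 0.5 (incompressible
soft tissue); it is not measurable from these data and enters only
through the factor 1/(1−ν²).

Generator choices the protocol does not pin down: additive i.i.d.
Gaussian force noise with σ = 20 pN (a plausible thermal noise floor for
a ~0.2 N/m lever in liquid); z sampling of 5 nm per point (≈ 2000 samples
on a typical ramp); 6 µm of pre-contact travel on clean curves so the
2 µm flatness criterion has headroom. Viscoelastic and poroelastic
response, piezo drift and tip contamination are deliberately not
modelled: the elastic Hertz picture is the model being inverted.

### Inverse chain

Per curve: (1) a straight-line baseline is fitted in two passes — first
on the earliest 30% of the approach, then, once a contact point is
located, refitted on the actual pre-contact window — and subtracted;
(2) the contact point is seeded at the first force excursion that stays
above 5 × the noise sd for 10 consecutive samples, then back-extrapolated
with the F^{2/3} linearization (F^{2/3} is linear in z near contact),
which matters for very soft samples where the threshold crossing can sit
0.5 µm past true contact; (3) indentation pairs δ = (z − z₀) − F/k are
formed for post-contact samples; (4) E, a contact-point shift, and a
residual force offset are refined jointly by trust-region least squares
over δ ∈ (0, 2 µm], seeded by the same F^{2/3} linearization. The
per-curve noise sd is estimated robustly as the scaled median absolute
successive difference of the early approach, so noiseless synthetic data
(floored at 0.1 pN) and very noisy curves are both handled.

On noiseless synthetic curves the chain recovers E to better than 1e-4
relative across 0.05–50 kPa; at the default 20 pN noise the median
relative error at 1 kPa is about 1%, and the refined contact point lands
within ~1 sample spacing of truth at the median.

### Quality control

Three exclusion criteria, each with an explicit operationalization:

1. **Permanent contact** — no pre-contact window exists. Because the
   absolute force zero of an AFM channel is arbitrary, this is detected
   from shape on the raw approach: the slope over the first 0.5 µm is
   already a sizeable fraction (> 0.1) of the end slope and its rise
   clearly exceeds the noise (> 3 sd).
2. **Ill-defined contact point** — a window exists but the flat stretch
   before contact is shorter than 2 µm, or its local slope exceeds
   2 × noise sd per µm (with a small-sample allowance). Evaluated only
   when criterion 1 is false, so each failure mode maps to one flag.
3. **Too noisy** — the pre-contact force sd reaches c × trigger with
   c = 0.25, a concrete reading of "noise comparable with the trigger
   force"; c is configurable.

The generator can inject artifacts violating exactly one criterion each
(`permanent_contact`, `short_baseline`, `high_noise`); at default
settings the high-noise sd is 0.75 nN — 1.5 × the decision boundary — so
flagging is deterministic rather than a coin flip on the sample sd.
Curves with fewer than 5 usable pairs yield a non-converged fit and are
tallied separately from the three criteria.

## 2. Map coverage

Valid (QC-passing, converged) pixels of a map sit at pixel-centred
coordinates ((index + 0.5) × pitch, pitch = side/grid = 5 µm by default;
an endpoint-inclusive 50/9 µm spacing is available by flag). The coverage
index is the mean over valid pixels of the Euclidean distance to the
nearest other valid pixel, in µm — exactly the pitch for a full grid,
pitch·√2 ≈ 7.07 µm for a half-coverage checkerboard, and large for sparse
maps. Maps are retained when the index is ≤ 8 µm (the threshold keeps the
"adequate coverage" semantics: higher index = poorer coverage). With
fewer than two valid pixels the index is undefined and the map is
dropped. A weighted one-way ANOVA (weights = valid-pixel counts,
variance assumed ∝ 1/weight) checks that coverage does not differ
systematically across tissue types; it is hand-written because no
installed Python package exposes a single-call weighted ANOVA, and is
cross-checked against a statsmodels WLS fit in the tests.

## 3. Gamma mixed models by penalized quasi-likelihood

Observations are per-pixel moduli E (kPa) with map-in-patient nesting.
The model family is fixed: gamma conditional distribution, log link,

    log μ = Xβ + Σ_c Z_c b_c,   b_c ~ N(0, σ_c² I),

with random-intercept factors drawn from {patient, map, map×tissue}.

PQL iterates a working-response linearization: y* = η + (y − μ)/μ. A
structural convenience of the gamma/log pair is that the IRLS working
weights (dμ/dη)²/V(μ) = μ²/μ² are identically one, so each PQL step is an
*unweighted* Gaussian linear mixed model on y*. That inner LMM is solved
by profiled REML over the variance ratios λ_c = σ_c²/σ_e²: the
cross-products X'X, X'Z, Z'Z are formed once per dataset, and each REML
evaluation is a single Cholesky factorization of the (q × q)
mixed-model-equation block, optimized by Nelder–Mead over log λ (bounds
e^{−15}–e^{10}; a component at the lower bound is effectively zero — the
boundary case). Convergence: relative change in β below 1e-6, at most
100 PQL iterations. The gamma dispersion is reported as the Pearson
moment estimator Σ((y−μ)/μ)²/(n−p); fixed-effect covariance is
σ_e²(X'V₀⁻¹X)⁻¹ from the converged working model. Random terms with
fewer than two levels are dropped with a warning, which also makes the
estimator collapse exactly to the ordinary gamma GLM (verified against
statsmodels to 1e-6). Estimates are equivariant to rescaling E (kPa vs
Pa): only the intercept shifts, by log of the scale factor.

**Wald tests.** For a term with contrast rows C,
F = (Cβ)'(C V C')⁻¹(Cβ)/q. Denominator degrees of freedom follow the
containment rule: a fixed term constant within patients is tested against
n_patients − 1 − p_patient; one constant within maps but varying across
them against n_maps − n_patients − p_map; an observation-level term
against n_obs − n_maps − p_obs (p_ℓ = number of fixed-effect columns
estimated at that level, intercept at the coarsest). Duplicate random
partitions (e.g. map×tissue when every map carries one tissue) are
collapsed for the df bookkeeping. Under the null generator at the default
design the Wald F type-I error at α = 0.05 measures ≈ 0.05 (the
acceptance suite checks membership in [0.03, 0.08] over 500 runs).

**Analyses.**

- *Variability* (per tissue): the "Map" row fits map as fixed effect with
  a patient random intercept; the "Patient" row fits patient as fixed
  with a map random intercept. The source protocol describes the
  intra-patient model both ways (patient-fixed narrative vs map-fixed
  table legend); both presets are provided (`legend`, the default, and
  `narrative`) rather than resolving the ambiguity silently.
- *Tissue contrasts*: tissue fixed; patient, map and map×tissue random;
  treatment coding against a configurable reference. Pooling helpers
  merge distal+proximal normal epithelium into "normal" and, optionally,
  tumor epithelium + stroma into a merged compartment for the mixed-zone
  comparison.
- *Clinical associations*: tumor-derived observations only (tumor
  epithelium, stroma, mixed), one covariate at a time with patient and
  map random intercepts — mirroring per-variable map counts — with
  reference levels female / left colon / stage I+II / MSI and wild-type
  for mutations. Covariates constant across the analysed patients are
  skipped with a notice. No multiple-testing correction is applied
  across covariates.
- *Descriptives*: count and percentage per categorical level, mean ± sd /
  median / range for age.

## 4. The synthetic cohort as study conditions

The generator is the model the fitter must invert, with the hierarchy on
the log-Pa scale: baseline log(80 Pa) for normal mucosa (mean < 0.1 kPa);
tissue effects +0.192 (tumor epithelium), +2.18 (stroma), +1.75 (mixed);
clinical effects applied to tumor-derived tissue only (late stage +0.90,
right-vs-left location −0.564, RAS +0.498, perinervous +0.625, and so
on), matching the tumor-restricted clinical analysis. Random structure:
patient sd 0.5 and map sd 0.25 on the log scale (magnitudes consistent
with the patient-specific stiffness profiles and map-to-map scatter the
analyses are designed to absorb), map×tissue and per-probe offsets zero
by default, gamma shape 2 (coefficient of variation ≈ 0.71, strongly
right-skewed with mass near zero, as per-pixel tissue moduli are).
Covariate marginals default to an 18-patient colon-adenocarcinoma
profile (11/18 female, 10/18 right colon, stages 1/10/3/4, 9/18 MSI,
12/18 mutated with KRAS:NRAS:BRAF hits 7:1:4); `demo_cohort()` realizes
those counts deterministically. Default observation design: 20 patients
× 4 maps × 56 points per map — the retained-points median of a realistic
acquisition — with map tissues cycling through normal / tumor epithelium
/ stroma / mixed. Pixels are spatially independent by default; an
optional Gaussian-copula correlated field exists for robustness
experiments only.

What passing tests therefore show: the chain inverts its own generating
model accurately and its inference is calibrated under that model. What
they do not show: robustness to viscoelastic response, substrate
bleed-through beyond the 10% rule, spatially correlated heterogeneity,
probe-to-probe offsets, or non-gamma stiffness marginals — real-data
properties the generator intentionally does not emulate.

## 5. Problem sizes and reproducibility

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give identical outputs.
The acceptance script runs 200 null cohorts for the type-I measurement
and 100 recovery cohorts per effect family (the test suite uses 500 and
200 respectively), each at the default 20 × 4 × 56 design — sizes at
which one cohort fits in well under a second and the Monte-Carlo
standard error of a 5% rejection rate is about 1.5 percentage points.
Recovered effect means under isolated-effect generators land within a few
percent of the generator truths (e.g. stroma 2.179 vs 2.18, stage 0.87
vs 0.90 at seed 1).

## 6. Known limitations

- PQL is approximate likelihood; its fixed-effect estimates carry small
  bias for strongly non-Gaussian conditional distributions, and variance
  components at the boundary are reported as (near-)zero rather than
  tested.
- The containment-df rule is one defensible choice among several
  (Satterthwaite and Kenward–Roger are not implemented).
- The contact-point detector assumes an approach that ends at or near
  the trigger; exotic curve shapes (snap-in, double contact) are not
  classified beyond the three criteria.
- Vendor binary force formats are not read; the TSV dialect is the
  ingestion contract.
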