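# Methods

`paleocmr` estimates how two genus-level traits — body size (log10
biovolume, mm³) and geographical range (log10 maximum great-circle
distance, km) — relate to extinction probability across geologic stages,
and whether that selectivity differs between background intervals and
mass-extinction stages. This note records the model, the data
treatment, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## The model

Fossil genera are treated as individuals in a capture–mark–recapture
design whose "occasions" are geologic stages. Three parameter families
describe each genus *i* at occasion *t*:

- **φ (survival)** — probability of persisting across the stage
  boundary *t → t+1*; its complement *q = 1 − φ* is the per-stage
  extinction probability;
- **γ (seniority)** — probability that a genus extant at *t* was
  already extant at *t − 1*; the time-reversed mirror of survival, which
  is what lets origination be estimated without conditioning on first
  appearance (the Pradel seniority construction);
- **p (detection)** — probability that an extant genus is sampled in a
  stage; the model's handle on fossil-record incompleteness.

Each family gets a logit-linear predictor over occasion fixed effects
("time"), the class-standardized size score, the class-×-stage
standardized range score, their product, and 0/1 regime flags: a
mass-extinction flag interacting with the φ covariates and a recovery
flag (the stage immediately after a flagged one) interacting with the γ
covariates. In a formula such as `~time + BS + GR × ME`, the crossing
expands R-style into main effect plus interaction; the ME main effect
is absorbed by the occasion fixed effects and is never a separate
column. Survival-scale coefficients are reported negated, i.e. as the
change in ln(q/(1−q)) per +1 SD of the trait, so "narrow range → higher
extinction risk" appears as a negative range coefficient.

### Likelihood

For a history with first detection *f* and last detection *l*, the core
probability is

    Q(h) = ξ_f · p_f · Π_{t=f}^{l−1} [φ_t · p_{t+1}^{ω} (1−p_{t+1})^{1−ω}] · χ_l

with the backward tail ξ_1 = 1, ξ_t = (1−γ_t) + γ_t(1−p_{t−1})ξ_{t−1}
(never detected before *f*, entry weighted by seniority) and the forward
tail χ_T = 1, χ_t = (1−φ_t) + φ_t(1−p_{t+1})χ_{t+1} (never detected
after *l*). `pradel_loglik` returns log Q and is verified, for every
nonzero history with T ≤ 6, against an independent oracle that
enumerates all latent (origination, extinction) occasion pairs
explicitly (agreement to 1e−12).

Q alone conditions on presence at *f*, a different event for every
history; as an objective it degenerates (it is monotone decreasing in
every γ, so "maximizing" it drives all seniority estimates to zero).
The fitted objective is therefore the proper conditional likelihood

    L(h) = N_f · Q(h) / D,

where N_t is the relative expected abundance implied by the seniority
parameterization (N_1 = 1, N_t = N_{t−1} φ_{t−1} / γ_t), B_a the
expected entries at occasion *a* (B_1 = N_1, B_a = N_a(1−γ_a)), v_a the
probability that an entrant at *a* is never detected (v_T = 1 − p_T,
v_a = (1−p_a)[(1−φ_a) + φ_a v_{a+1}]), and D = Σ_a B_a(1 − v_a). The
per-history L(h) sum to exactly 1 over all observable histories (a
property test asserts this), seniority becomes estimable, and the
≥1-detection ascertainment of any fossil dataset is accounted for —
without the 1/D term, trait coefficients acquire a selection bias that
does not shrink with sample size whenever detection is incomplete.
Both logQ and logL are exposed; everything downstream fits logL.

The likelihood is exactly time-symmetric: refitting time-reversed
histories reproduces the same maximized likelihood with the φ and γ
sequences exchanged (read backwards). This is used as a standing
diagnostic (`time_reversal_check`); terminal parameters (φ_{T−1} with
p_T, γ_2 with p_1) are compared only as the interior sequence because
they are identifiable only as products.

### Fitting and uncertainty

Coefficients are estimated by L-BFGS-B with an exact analytic gradient
(reverse-mode accumulation through the ξ/χ/v recursions and the
abundance terms, checked against central finite differences). Linear
predictors are clamped to ±15 before the inverse logit so boundary
cells cannot produce log 0. The default is 3 starts (the origin plus
two seeded N(0, 0.5) perturbations) with relative tolerance 1e−8;
replicated experiments use a single start plus warm starts (a simpler
model's occasion intercepts, or the previous replicate's MLE), which
changes only where the optimizer begins. A failed line search on a
single-start fit earns up to two automatic fresh starts.

Standard errors come from a finite-difference Hessian of the analytic
gradient at the MLE (one-sided differences by default, k+1 gradient
evaluations; the central scheme is available where extra accuracy is
worth twice the cost — the two agree to ~1e-4 relative on the
coefficients reported here). Full time-dependent CMR models always
have a rank-deficient information matrix (the terminal confounds
above), so the covariance is the SVD generalized inverse — the standard
handling in this model family — with per-coefficient validity: a
coefficient whose variance estimate is not positive reports SE = NaN,
and a model enters coefficient averaging only if every trait/interaction
quantity it contributes has a finite SE. The AICc parameter count is
the number of retained design columns (columns identically zero over
the data, e.g. an ME interaction in a window without a flagged stage,
are pruned); no estimability adjustment is applied, which keeps the
count deterministic.

## Data treatment

Occurrences (Paleobiology Database download dialect) are resolved to a
single stage when the early and late interval name the same stage in
the stage table (a blank late interval counts as the early one);
subgenera are elevated to genus rank (either a subgenus column or the
"Genus (Subgenus)" pattern); occurrences without a stage assignment
inside the analysis window, genera without a body-size trait, and
classes with fewer than `min_genera` (default 500) qualifying genera
are removed, with per-rule tallies logged. The packaged stage table has
86 stages from the base of the Ordovician (485.4 Ma) to the early
Pleistocene, with the Big Five mass extinctions flagged at Hirnantian,
Frasnian, Changhsingian, Rhaetian and Maastrichtian and the five
successor stages flagged as recovery; Cambrian occurrences fall outside
the window by construction. The flag set is a configuration list, so
alternate definitions (e.g. Famennian for the Late Devonian, or
dropping the Maastrichtian) are presets, not code changes. The window
ends at the Gelasian: the exact early-Pleistocene truncation is a
convention, constrained only by the 81 background / 5 mass-extinction
arithmetic.

Geographical range per genus × stage is the maximum pairwise
great-circle distance (haversine, spherical Earth R = 6371.0 km)
between its occurrence points in that stage, computed on
palaeocoordinates with modern coordinates as fallback (configurable).
Points are deduplicated after rounding to 4 decimal places. Stages
within a genus's observed span holding ≤ 1 distinct point get a nominal
1 km (log10 = 0) before transformation — the published treatment rule.
Size scores are standardized within class; range scores within class ×
stage (denominator n − 1; a zero-variance cell gets z = 0 with a
warning).

**Covariate values outside the observed span.** The likelihood's
origination and ascertainment terms evaluate survival odds at occasions
before a genus's first and after its last record, where the range
covariate is unobservable. Extending the 1 km rule there — plausible at
first sight — paints every pre-appearance interval as
survived-at-minimum-range and demonstrably flips the sign of the fitted
range coefficient on synthetic data; those occasions therefore carry
the neutral class × stage mean (z = 0) instead. The within-span 1 km
rule is kept exactly as published.

Capture histories are encoded per class over the class's observed stage
window (or the full table, configurable): detection 1 iff ≥ 1
stage-resolved occurrence, with the size score and the per-occasion
range series alongside. For the φ interval *t → t+1* the range value
and the ME flag are taken from stage *t* (start-of-interval timing;
end-of-interval available by option). Stage durations are deliberately
ignored — every stage counts as one occasion — matching the method's
standard equal-interval assumption.

## Model set, selection, averaging

The canonical candidate set crosses 11 φ structures (time; time+BS;
time+GR; time+BS+GR; time+BS×GR; time+BS×ME; time+GR×ME; time+BS×ME+GR;
time+BS+GR×ME; time+BS×ME+GR×ME; time+BS×GR×ME) with the mirror-image
11 γ structures (Rec for ME) and one detection structure (time+BS):
121 models per class, 605 over five classes. An intercept-only γ
("~1"), which some published selection tables show, is available as an
optional extension but kept out of the canonical count. Models are
ranked by AICc with effective sample size = number of capture histories
(genus count; total detections or histories × occasions are selectable
alternatives, as the field's conventions differ), and Akaike weights
follow. Models at or above a weight threshold (default 0.01)
contribute to model averaging with weights renormalized over that
subset; a model lacking a term contributes 0 for it (full-model zero
substitution); the unconditional SE is Burnham–Anderson
√[Σ wᵢ(seᵢ² + (θᵢ − θ̄)²)], with the mass-extinction coefficient's
per-model SE taken from the covariance of (main + interaction). The
background coefficient is the averaged main effect; the mass-extinction
coefficient the averaged main + interaction. A model is classified
two-regime if its φ structure contains any ME term.

## The synthetic generator

The generator emulates a stage-binned fossil record with the exact
statistical structure the analysis assumes: static size z ~ N(0,1); a
latent AR(1) range trait with unit marginal variance, lag-1 correlation
`rho_range` (default 0.6) and size coupling `kappa_size_range` (0.3);
survival logits `alpha_phi + β_size·z + β_range·z_range(t)` with
additive ME shifts at flagged stages (baseline survival ≈ 0.75);
detection logits `alpha_p + delta_size_p·z` (baseline ≈ 0.62, size bias
0.5 — a size-biased record); detected genus-stages emit
1 + Poisson(occ_rate − 1) occurrence points along a great circle whose
end-to-end arc equals 10^(3 + 0.5·z_range) km, so the recovered
distance is exact (to coordinate rounding ≪ 1%) and, being affine in
the latent trait on the log scale, standardizes back to the latent
z-scores within multi-occurrence cells.

Origination has two modes. The default draws entry occasions from a
fixed schedule (uniform over the first two-thirds of the window, to
avoid edge pile-ups). The `seniority` mode instead draws entry from the
distribution implied by logit-linear seniority
(`alpha_gamma + β·covariates`, Rec shifts available) — the exact
generative mirror of the fitted model. The distinction matters: under a
fixed schedule the true per-genus seniority is a *nonlinear* function
of covariate history, every logit-linear γ structure is misspecified,
and the misfit leaks into the survival coefficients through the shared
abundance terms. Calibration experiments therefore use seniority mode;
qualitative fixtures may use either.

What the generator does **not** emulate: real taxonomic noise and
synonymy, collection-level spatial structure, palaeogeography (points
sit on a great circle), stage-duration variation, and any correlation
between preservation and geography. Passing tests demonstrate that the
estimator recovers the truth *of this generative model*; they cannot
certify the biological conclusions from real data.

## Validation experiments and their problem sizes

- **Interval calibration** (`coverage_experiment`): 100 replicates of
  2000 genera × 30 stages (3 ME stages), survival-scale truth 0.5 per
  SD for both traits, regime shifts 0, seniority-mode entry with γ
  covariates 0.3; the generating model (with the zero-truth ME
  interactions included) is fitted to each replicate. Checks: Wald 95%
  interval coverage of both trait coefficients within [0.90, 0.99], and
  interaction estimates centred on zero within 2 Monte-Carlo SE.
- **Regime recovery** (`regime_experiment`): 50 replicates of the
  `regime_demo` fixture — survival-scale β_range +0.8 in the
  background, ME shift −0.8 (selectivity erased at flagged stages),
  β_size +0.2, homogeneous origination — fitted with a reduced 8-model
  set (4 single-regime + 4 two-regime φ structures) and averaged.
  Checks: a two-regime model ranks first *and* the averaged ME range
  coefficient sits nearer zero than the background one in ≥ 90% of
  seeds. Replicates use the generator's covariates; a single-seed
  companion test runs the same fixture through the full occurrence
  pipeline and asserts the regime classification and the background
  sign, because the within-span 1 km rule acts as covariate measurement
  error that attenuates magnitudes (background −0.8 recovers around
  −0.2 to −0.4 end-to-end) while preserving direction.
- Smaller experiments (null-model regime support, the time-reversal
  diagnostic, the saturated closed form with detection pinned at 1) run
  at 500–3000 genera and 8–15 stages. `scripts/acceptance.py` re-runs
  the calibration and regime experiments at 40 and 20 replicates
  respectively; the analysis drivers use 10–20.

## Known limitations

- With incomplete detection the 1 km rule makes the time-varying range
  covariate error-laden wherever a genus goes unsampled; this
  attenuates range selectivity and, in regime contrasts, can inflate
  the apparent mass-extinction coefficient. Any analysis using this
  covariate construction — not just this implementation — inherits the
  effect; it is the main reason the end-to-end pipeline demonstrations
  assert signs and regime classification rather than magnitudes.
- Seniority structures that are logit-linear in *current* covariates
  cannot represent the seniority process implied by an arbitrary entry
  schedule; survival-coefficient bias from that misfit is second-order
  when origination is near-homogeneous but grows with covariate effects
  on entry.
- Terminal-occasion parameters are estimable only as products; their
  SEs are reported as missing rather than regularized away.
- Stage durations are treated as equal, per the method's standard
  assumption; coefficients are per stage transition, not per Myr.
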