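# Methods

## Data model and classification rules

A cohort row holds Gd-enhancing volume (cm³, scans 1 and 2), TBRmax
(dimensionless, scans 1 and 2), overall survival and progression-free
survival (months). Any imaging value may be missing; survival is
always present. The built-in reference cohort has 25 patients, of
whom 23 are PET-evaluable and 21 MRI-evaluable.

Boundary conventions of the four rules:

* **PET** uses a strict inequality (responder ⇔ TBRmax₂ < 0.8·TBRmax₁).
  No reference patient sits exactly on the boundary, so the choice is
  unobservable there; strict `<` matches the stated "decrease of at
  least 20 %" read as a strict sub-80 % ratio.
* **MRI** uses a non-strict inequality (responder ⇔ Gd₂ ≤ Gd₁):
  "no change or a decrease" is a response, and a patient with a stable
  0.0 → 0.0 cm³ volume is classified as a responder, which forces `≤`.
* **OS** is strict (responder ⇔ OS > 10 months); **PFS** is inclusive
  (responder ⇔ PFS ≥ 6 months, "6 months or more"). No reference
  patient lies on either boundary, so both conventions reproduce every
  recorded status either way.

## Chance nodes and effectiveness

All probabilities are estimated available-case per modality: the PET
arm uses the 23 PET-evaluable patients, the MRI arm the 21
MRI-evaluable ones, *including* the denominator of the identification
rate (true non-responders with that modality available). This
modality-specific denominator is what makes the two arms each
internally consistent; pooling denominators across modalities would
mix patients one arm never observed.

Node-based effectiveness is evaluated in exact rational arithmetic
(`fractions.Fraction`) when the nodes come from counts, so the
node-algebra route and the direct-counting route
(`effectiveness_by_count`) agree bit for bit — an identity the test
suite checks on thousands of random cohorts. The identification rate
is non-decreasing in both conditional truth probabilities p and q;
when p = 1 it equals 1 regardless of the call rate, which is why the
OS tree's increment is invariant to N1 and N4 sweeps.

The per-diagnosis effectiveness is overall diagnostic accuracy
R·p + (1−R)·q. The per-diagnosis ICER for the PFS tree computed this
way is ≈ 3,427 EUR; this is the value the package reports (see
Limitations).

## Cost model

Per-patient follow-up cost covers two PET scans. Three printed
(annual scan volume, cost) anchors — (5,063, 813.20), (5,626, 780.50),
(6,189, 735.74) EUR — are mutually inconsistent with any two-parameter
smooth form (a straight line or a + b/n), so the default
volume-dependent model is piecewise-linear interpolation through the
anchors with linear extrapolation outside them: exact at every printed
value, monotone non-increasing. Deterministic base-case analyses use
the fixed 780.50 EUR cost. An explicit two-cost-center model
`scans_per_patient · (F/n + r)` (annual budget envelope F, per-scan
fee r, defaults calibrated to the base anchor) is available for users
with a known tariff structure.

## One-way deterministic sensitivity analysis

Each parameter is set to the low and high end of its interval with all
others at base case. Node intervals: half-width 0.15 for the call
probabilities N1/N2 and 0.075 for N3–N6, truncated at 1 (tree 1's N3
interval is one-sided, [0.925, 1.0]); these widths derive from
confidence intervals of a comparable PET assessment study, not from
the cohort itself. The scan-volume interval is 5,063–6,189 (±1.96 SD
of the annual volume, rounded); it is the only row where cost moves.
ICER at an endpoint is (cost at endpoint)/(increment at endpoint).

## Monte Carlo probabilistic sensitivity analysis

10,000 draws by default; every parameter sampled independently from a
normal distribution centred on its base value (node SDs 0.0750 for
N1/N2, 0.0375 for N3–N6; scan volume mean 5,626, SD 287). Node draws
are bounded to [0, 1]; two policies are implemented:

* **clip** (default): out-of-range draws set to the nearest bound.
  For tree 1, whose N3 sits exactly at 1, this leaves ≈ half the draws
  at the bound and pulls the mean increment to ≈ 0.558, below the base
  0.5714 — the behaviour consistent with the reference summary
  statistics (truncated resampling would predict ≈ 0.53–0.54).
* **resample**: truncated-normal redraws, exposed as a config switch.

Scan-volume draws are floored at one scan. Draws with a non-positive
increment (or a degenerate conditional stratum) are excluded from the
ICER summary and counted; with the default SDs they essentially never
occur. Summaries report mean, min, max and sample SD (ddof = 1). The
mean sampled ICER exceeds the base-case ICER because x ↦ 1/x is
convex (Jensen); the convergence helper shows the standard error of
the mean shrinking like 1/√draws. Randomness flows from a single
`numpy.random.default_rng(seed)`; fixed seed ⇒ bit-identical output.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: latent true
response states per endpoint drawn from configurable prevalences;
survival times from lognormal strata per state, rejection-sampled onto
the correct side of the clinical cut-off and constrained to PFS ≤ OS
(stratum medians 17/7 months for OS responders/non-responders, 11/4.5
for PFS, log-scale SD 0.30–0.35 — in the range of published
glioblastoma follow-up series); imaging calls drawn from configured
sensitivity/specificity against the true state of a designated call
endpoint (default OS); then continuous measurements synthesised inside
guard-banded ratio ranges (the PET ratio band excludes (0.78, 0.82))
so the classifier recovers every intended call exactly; finally
independent per-modality missingness. Consequently the empirical
chance nodes converge to closed-form Bayes targets computable from the
configuration (`expected_chance_nodes`), which the parameter-recovery
tests verify at n = 50,000 within three binomial standard errors.

What the generator does **not** emulate: correlated PET/MRI errors,
censoring, measurement noise at the rule boundaries, or any joint
distribution between survival time and imaging beyond the binary
response state. Passing recovery tests therefore validates the
estimator algebra and the pipeline plumbing, not the clinical realism
of any particular dataset.

## Problem sizes and determinism

The test suite runs the full pipeline at 1,000–2,000 Monte Carlo draws
and property checks over 1,000 random 30-patient cohorts plus single
50,000-patient recovery cohorts; the acceptance script uses the full
10,000 draws. Everything completes in seconds on one CPU. All
reported report files are byte-identical under a fixed seed; the run
report deliberately carries a config hash and seed but no timestamp,
so idempotent re-runs produce identical bytes.

## Known limitations

* The reference per-diagnosis ICER for the PFS tree is reported
  elsewhere as ≈ 2,427 EUR, which is inconsistent with its own inputs
  (cost 780.50 / accuracy increment 0.2277 ≈ 3,427 EUR — a constant
  1,000.07 EUR below the reproducible value, suggesting a
  transcription slip). The package reports the internally consistent
  value.
* The exact cost-volume function behind the three printed anchors is
  unrecoverable; piecewise-linear interpolation is a choice, and the
  Monte Carlo SD of the sampled *cost* depends on it (≈ 20 EUR here).
  Cost-distribution statistics should be read qualitatively.
* Chance nodes are point estimates from 25 patients; the sweep
  intervals are imported from external literature rather than
  estimated, and nodes are sampled independently in the PSA (no
  correlation structure is available).
* No QALYs, willingness-to-pay thresholds, discounting or currency-year
  adjustment: effectiveness is measured in identified non-responders
  and correct diagnoses only.
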