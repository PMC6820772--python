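# Methods

## Scope and data model

`blisscreen` analyses pairwise drug-combination screens laid out on
multi-well plates. The canonical container is a tidy *well table*
(pandas DataFrame, one row per measured well) with plate, well, cell
line, treatment annotation (drug A/B, concentrations in µM, treatment
kind), technical and biological replicate indices, readout kind
(viability or confluency) and the raw readout. Viability and confluency
flow through identical code paths; positive-control compounds dosed in
µg/ml carry an explicit unit tag and are excluded from synergy
arithmetic by construction.

Two dose layouts are supported. The *ray* design co-dilutes both drugs
along one equimolar series (default: five 5-fold steps from 10 µM, i.e.
10, 2, 0.4, 0.08, 0.016 µM); a combination well at ray dose c contains
c of *each* drug by default (`equimolar_split=True` halves the per-drug
dose for the alternative mixture reading). The *matrix* (checkerboard)
design crosses two concentration lists in full (default 10, 2, 0.4,
0.08, 0.02 µM each way, 25 dose pairs).

## Normalisation and aggregation

Every plate carries DMSO vehicle-control wells. Each well's relative
effect is its raw readout divided by the arithmetic mean of the plate's
non-missing control wells (median available as an option); control wells
are normalised too, so their per-plate mean is exactly 1. A plate with
no usable control well is rejected by name — there is no borrowing of
controls across plates, and no spatial/edge-effect correction is
applied.

Replicate aggregation is two-stage: technical replicates are averaged
within each biological replicate first, then biological replicates are
averaged across those technical means. With unbalanced technical counts
this deliberately differs from pooling all wells. Missingness is data,
not error: means and sample SDs are over non-missing contributors, a
condition with none keeps a missing mean with n = 0, and the missing
fraction is preserved end to end (no imputation).

## Bliss scoring

Relative viabilities are capped at 1 before any synergy arithmetic
(applied uniformly to single-drug and combination wells; a stricter
variant capping only single-drug arms is a one-line change in
`compute_bliss_samples` but is not exposed, as uniform capping keeps the
excess symmetric in its inputs). Within each (cell line, dose,
biological replicate), the Bliss expectation is the mean over all
|A|×|B| cross products of the two arms' capped technical replicates —
algebraically the product of the two arm means, an identity the test
suite verifies to 1e−12 — and each non-missing combination technical
replicate yields one excess sample against that shared expectation.
Expectations are never borrowed across biological replicates: if a
biological replicate lacks single-drug data at a dose, its combination
replicates at that dose produce no samples (logged).

Per (pair, cell line), `mean_bliss` pools all samples across doses and
replicates. The matrix-screen summary, the cumulative Bliss score,
averages per-dose-pair means with equal weight per dose pair, so
unbalanced replication cannot re-weight doses; only dose pairs with both
concentrations > 0 enter.

## Inference

Primary screen: a two-sided one-sample t-test of each hypothesis's
pooled excesses against zero (t = x̄/(s/√n), df = n−1), Bonferroni
adjustment over the family, and the dual rule mean excess ≤ −0.08 AND
adjusted p ≤ 0.05, both boundaries inclusive. The −0.08/0.05 thresholds
are the screen's operating point and are parameters of
`run_screen_inference`. The p-threshold applies to the *adjusted* p —
otherwise the correction would not affect calls. The family size m is
the number of hypotheses with a computable p in the current run (a
hypothesis needs ≥ 2 samples; those below keep a missing p and the
conservative label not_synergy); `m_override` fixes m externally (e.g.
1368 for the full 171-pair × 8-line design). Degenerate samples are
handled explicitly: identical values with zero mean give p = 1,
identical non-zero values give p = 0 with a warning. No variance
pooling, trimming or normality pre-test is applied; no
antagonism label is emitted (antagonism appears only as a display class
in reporting). A Benjamini–Hochberg alternative is deliberately absent
from the default path.

Secondary screen: synergy ⇔ cumulative Bliss score < 0, strict. The
looser cutoff reflects the 5× denser dose sampling of the matrix design.

## QC metrics

* **Replicate correlation**: Pearson r between biological replicates
  over shared conditions (per-condition technical means, all cell lines
  pooled into one vector per replicate; a well-level variant is
  available). Requires ≥ 3 complete pairs and non-zero variance.
* **Coefficient of variation**: per condition, sample SD / mean. The
  default pools each condition's individual replicate wells (technical ×
  biological), so the screen-wide mean CV estimates the per-well assay
  noise directly — this is the variant whose calibration the test suite
  checks against the simulator. A `level="bio"` option computes CV
  across per-biological-replicate technical means instead; note it is
  attenuated by roughly √(technical replicates). Conditions with mean
  ≤ 0.01 are excluded (CV diverges near full kill).
* **Control dispersion**: sample SD of each plate's normalised control
  wells, flagged above a threshold (default 0.10).

## Reporting

The synergy matrix has one row per pair and one column per cell line of
mean Bliss excess. Rows are sorted by missing-aware row mean, ascending,
with stable ties; columns are ordered by hierarchical clustering
(complete linkage by default — deterministic and a common heatmap
choice; configurable) on Euclidean distances computed over
pairwise-complete rows, so cell lines with missing combinations still
cluster; column ties are made deterministic by starting from an
alphabetical order. The display colour classes use ±0.11 (inclusive):
blue synergy, red antagonism, neutral between — every blue cell is
strictly inside the −0.08 call threshold. Volcano coordinates are
(mean excess, −log10 adjusted p) with p = 0 mapped to a configurable
ceiling. Combination-plot tables are tidy (arm, conc_a, conc_b, mean,
sd) rows for the A, B and A+B arms. Rendered figures are a thin
matplotlib layer over these tables; the tables are the tested surface.

## Synthetic screens

Single-drug response follows a Hill curve
v(c) = 1 − Emax·c^h/(c^h + EC50^h); a combination's true viability is
the Bliss product of its singles plus an additive interaction shift
delta (negative = synergy), floored at 0, so delta = 0 reproduces exact
Bliss independence and the pipeline is unbiased at the null by
construction. Noise is multiplicative log-normal with σ chosen so the
noise factor's CV equals `noise_cv` and its mean is 1 — luminescence
noise scales with signal and stays positive. Technical replicates share
their biological replicate's plate (hence its control normalisation);
biological replicates get independent control draws. Missing wells are
injected at `na_rate` among treated wells only, so plates always remain
normalisable. A ground-truth sidecar (true viability and delta per
condition) is always produced.

The full-scale fixture (`default_screen_config`) emulates a realistic
primary screen: 8 cell lines × 19 drugs × 171 pairs on the 5-dose ray,
3 biological × 2 technical replicates, 16 control wells and a 9-point
positive-control dilution series per plate, 6% noise CV and 14% missing
wells. Hill parameters are drawn once per (drug, cell line) from wide
ranges (EC50 log-uniform in [0.05, 20] µM, slope in [0.8, 2.5], Emax in
[0.3, 1.0]); six drug pairs carry injected synergies (delta in
[−0.25, −0.1]) across all cell lines, giving the few-percent synergy
prevalence typical of such screens.

What the generator does *not* emulate: plate spatial effects (edge
evaporation, gradients), cell-growth kinetics over the incubation
window, drug-specific off-target structure, batch drift between
biological replicates, or non-log-normal outliers. Passing tests
therefore demonstrate the correctness and calibration of the analysis
chain, not robustness to those real-data pathologies.

## Calibration studies and their sizes

Two canned reduced configurations define the validation studies run by
the test suite and `scripts/acceptance.py`:

* **Null calibration** (`null_screen_config`): 5 drugs × 2 cell lines =
  20 hypotheses per screen, delta = 0 everywhere, 6% CV, all drugs at
  mid-range Hill parameters (EC50 2 µM, slope 1, Emax 0.6). Across 200
  screens the family-wise rate of any synergy call must stay within the
  binomial 95% band around 5%; with Bonferroni plus the −0.08 effect
  threshold the observed rate is near zero.
* **Parameter recovery** (`recovery_screen_config`): 4 drugs, 1 cell
  line, 6 pairs of which two carry delta = −0.15, 5-dose ray, 3
  biological × 2 technical replicates, 6% CV. The mid-range Hill
  parameters keep the Bliss product above the zero floor at every dose,
  so the injected shift is recoverable; capping at 1 still attenuates
  the estimate slightly (≈ +0.015 at the low-dose end where single-arm
  viabilities approach 1). Over 50 seeds the mean estimate must lie
  within ±0.03 of −0.15, detection ≥ 90%, specificity on null pairs
  ≥ 95%; observed values are ≈ −0.134, 100%, 100%.

Clipping at the zero floor biases strong synergies on near-full-kill
curves toward zero; this is asserted as attenuation (never
amplification) and is the reason the recovery study uses mid-range
curves.

## Numerical choices

Floats are written with 6 significant digits (8 for raw tables);
missing values are "NA" on disk. Control-mean normalisation and the
expectation identity are exact to machine precision; the control-well
self-normalisation invariant is tested at 1e−12. Sample SDs use ddof=1
throughout. Zero-variance t-statistics are detected by exact value
identity rather than an epsilon. All randomness flows from
`numpy.random.default_rng(seed)`; a fixed config reproduces
byte-identical output tables.
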