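# Methods

`pisascreen` implements the computational core of integral thermal-shift
drug-target screening: a generative model of thermal-denaturation
proteomics data, melting-curve (TPP) analysis, the pooled-temperature
(PISA) differential screen with an all-other-drugs control design, and
target-network assembly. This note documents the models, the defaults
and why they were chosen, and what the synthetic data does and does not
capture.

## The melting model

Each protein's soluble fraction after 3 min of heating at temperature
*T* is modeled as a descending logistic

s(T) = (1 − p) / (1 + exp(k (T − Tm))) + p

with melting point Tm (°C), steepness k (1/°C, k > 0) and a
non-denaturing plateau p ∈ [0, 1). Tm is defined as the 0.5 crossing of
the plateau-free normalized curve (s − p)/(1 − p) — i.e. the temperature
at which half of the *meltable* protein remains soluble — which makes Tm
independent of p and equal to the logistic's location parameter. The
classical TPP literature often writes the same sigmoid as
(1 − p)/(1 + exp(−(a/T − b))) + p; the two parameterizations are
interchangeable over the 30 °C span of a gradient, and the direct
(Tm, k, p) form is used because Tm is the quantity every downstream step
reasons about.

A drug that engages a protein shifts its Tm by ΔTm (°C): positive for
thermal stabilization, negative for destabilization. In the integral
(PISA) layout the soluble fractions at a few temperatures T₁…T_m are
pooled before measurement, so the expected intensity is the baseline
abundance times the arithmetic mean of s(T_j) — no curve fitting is
needed, and a Tm shift shows up as a pooled-abundance change.

## Synthetic data: what it emulates

The generator produces the two matrix layouts the analysis consumes:

* **TPP**: ten temperatures (37, 41, 44, 47, 50, 53, 56, 59, 63, 67 °C),
  one column per (condition, replicate, temperature);
* **PISA**: pooling at 53/56/59 °C, one column per (condition,
  replicate).

Defaults emulate the study conditions the method is designed for:
4 replicates per condition; ground-truth melting points drawn from
N(52.5 °C, 3 °C²) truncated to [40, 70] °C (proteome median melting
points empirically fall between 50 and 55 °C, which is also why the
pooling temperatures sit just *above* the median — stabilization, the
commoner and more detectable effect, increases solubility most there);
slopes uniform on [0.6, 1.5] /°C and plateaus uniform on [0, 0.2],
typical of sigmoidal melters; baseline abundances log-normal over ~2
orders of magnitude. Noise is multiplicative log-normal with unit mean,
parameterized by a coefficient of variation (default cv = 0.1 for
screen-like data; the source experiments publish no explicit noise
magnitudes, so this is a calibration choice representative of replicate
variation in modern label-free quantification). Log-normal noise is used
because MS intensities are approximately log-normal and all statistics
operate in log2 space, where the noise becomes exactly Gaussian.

Missing values are injected completely at random by default (the
mechanism behind missingness in real data is not modeled); an optional
intensity-dependent mode (logistic in log-intensity, matched marginal
rate) exists for sensitivity checks but is off by default. No
peptide-level identification, chromatography or isobaric-label impurity
is simulated — the generator starts at protein-group intensities.
Consequently, passing tests demonstrate the *statistical* behavior of
the pipeline under its stated model (calibration, power ordering,
threshold semantics), not robustness to search-engine artifacts, batch
effects, or structured missingness in real data.

Every simulation is a pure function of its seed (NumPy `default_rng`).

## Preprocessing

The canonical order is: remove reverse hits, contaminants and groups
without proteotypic peptides → log2 → normalization → exclusion of runs
with more than 40 % missing values (strictly greater; a run at exactly
40 % is kept). Quantile normalization is used for isobaric (TMT) data
and median re-alignment for label-free (DIA) data. Quantile
normalization maps each run's observed values onto the across-run mean
of sorted values (interpolated when runs have unequal numbers of
observations, all observed values participating); ties receive the mean
of their candidate quantile targets. Zeros in input files encode "not
quantified" and become missing at read time; missing values are never
imputed anywhere. Full-gradient data are converted to ratios against the
37 °C channel within each (condition, replicate) before curve fitting;
a protein missing its 37 °C value contributes no ratios for that
replicate. Replicate averaging exists for reporting and network
annotation only — tests always consume replicate-level data, since a
t-test needs within-group variance.

## Curve fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`, TRF,
analytic Jacobian) with Tm ∈ [T_min − 5, T_max + 5], k ∈ [10⁻³, 10],
p ∈ [0, 1). The sigmoid objective is multimodal under noise, so the fit
starts from a data-driven guess — the interpolated temperature at which
the min–max-normalized profile crosses 0.5 — and falls back to a fixed
grid of starts Tm ∈ {45, 50, 55, 60} °C whenever the current best
solution still fails quality control; the best sum of squares among the
starts tried wins. This ordering makes replicate-level fitting of
thousands of profiles cheap without changing results on well-behaved
curves.

Quality control: r² ≥ 0.8, fitted plateau < 0.3, and Tm inside the
measured temperature range (all configurable). Flat profiles
(non-melters) and profiles without a sigmoidal decline fail QC and are
flagged invalid rather than raising; invalid fits are dropped from
Tm-shift tests, and a group with fewer than two valid fits makes the
protein untestable. The thresholds follow common TPP-package practice;
they are assumptions, not published values.

## The screen statistics

Per (drug, concentration) condition and protein, treated replicates are
compared against the pooled replicates of all other conditions in the
same experiment (extract/cell line), excluding (i) the same drug at
other concentrations, (ii) drugs with Tanimoto similarity ≥ 0.6
(inclusive), and (iii) drugs sharing at least one known target —
otherwise a true target would sit inside its own control distribution.
The statistic is a two-sided unpaired t-test with pooled (equal)
variance on log2 intensities; log2FC is the difference of group means
over observed values only. Minimum two observed replicates per group
(the smallest size with positive degrees of freedom); zero pooled
variance with equal means gives t = 0, p = 1, with unequal means the
row is untestable.

Multiple testing uses Storey q-values, one family per (drug,
concentration, extract) — i.e. per volcano plot, matching how such
screens are reported. π0 is estimated on the λ grid 0.05…0.95 (step
0.05) via a cubic polynomial smoother evaluated at λ = 0.95 and clamped
to (0, 1]; families smaller than 100 tests, or a non-positive smoother
value, fall back to π0 = 1, which makes the q-values coincide with
Benjamini–Hochberg (the small-sample safeguard of the reference R
implementation). Significance: q ≤ 0.05 **and** |log2FC| ≥ 0.5, both
inclusive; direction is "stabilized" iff log2FC > 0.

Note the deliberate asymmetry of the two Tanimoto thresholds: control
*exclusion* is inclusive at 0.6 (conservative — when in doubt, drop the
control), while drug-similarity *edges* in the network require strictly
more than 0.6 (conservative the other way — when in doubt, draw no
edge). Both conventions are preserved as published.

## Network assembly

Drug and protein nodes; one association edge per significant (drug,
concentration, protein, extract) result — the same target found in
several extracts yields parallel edges — attributed with extract,
direction, log2FC and q. Curated known-target edges are added for
tested drugs, with their target proteins added as nodes and flagged, so
an expected-but-missed target is visible; homology edges (scored
protein pairs, no score cutoff) are restricted to proteins already
present, providing context around tested targets rather than importing
the whole interactome. Rat results are harmonized to human gene symbols
first, using the first identifier of each ";"-joined protein group as
representative; unmapped identifiers are retained and flagged. A
significant association cannot have log2FC = 0 (it would fail the
fold-change threshold), so edge direction is always defined; this is
asserted. Exports: GraphML (lossless round-trip), SIF, and paired
node/edge TSVs, all with deterministic ordering.

## Numerical and design choices

* Tanimoto over bit sets: |A∩B|/|A∪B|, with τ = 0 when both sets are
  empty — an unfingerprintable drug must not lose controls to
  similarity. Fingerprint generation is pluggable (rdkit path-based
  fingerprints from SMILES); precomputed bit sets in the drug table are
  the primary contract.
* Exclusion sets are keyed by the tested drug and are symmetric for the
  similarity and shared-target rules; the output is invariant to
  drug-table row order.
* Protein groups are keyed by their exact ";"-joined identifier string;
  no cross-search-engine reconciliation beyond exact matching is
  attempted.
* Suggested pooling temperatures from a Tm distribution: three values
  spaced 3 °C starting at the smallest integer strictly above the
  median — above the median by design, to favor stabilization
  detection.
* Logistic exponents are clipped at ±500 to avoid overflow; the curve
  is then non-strictly monotone only in the far tails where double
  precision saturates anyway.

## Problem sizes in the tests and acceptance script

Verification uses simulations sized for a single CPU: 200 proteins for
melting-point recovery (median |ΔTm| error ≤ 0.5 °C at ratio noise
sd 0.03), 1 000 proteins × 12 conditions for the null-screen type-I
calibration (12 000 tests), and matched 1 000-protein panels with 50
planted ΔTm = +3 °C targets for the PISA-vs-TPP power comparison (five
seeds in the test suite; two in the acceptance script, which reports
summed detections). These sizes give stable estimates of the calibration
and power properties being checked while keeping a full run in minutes.

## Known limitations

* The noise model is homoscedastic on the log scale and independent
  across runs; real screens show correlated batch structure that the
  pipeline's normalizations only partly remove.
* The equal-variance t-test is the published choice; no moderated
  (limma-style) variance shrinkage is offered.
* Missing-value handling is listwise per test (observed values only);
  low-abundance proteins with informative missingness will lose power
  rather than gain bias.
* Destabilized targets are intrinsically harder to detect at pooling
  temperatures above the Tm median; the generator and screen reproduce
  this asymmetry, they do not correct it.
* Curve-fit QC thresholds and the minimum-replicate rule are
  conventions, not fitted to data.
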