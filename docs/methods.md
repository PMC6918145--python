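# Methods

## The problem

When the same two biological samples are measured by many independently
developed targeted-metabolomics methods — different laboratories, different
separation techniques (CE, LC, GC, IC, SFC), different mass spectrometers —
the absolute signal intensities are incomparable, but the *relative*
quantification (the ratio of the two samples) should agree if every method
is measuring what it claims to measure. `metaconcord` formalizes that
agreement check as a per-metabolite statistical cascade and provides a
simulator of the error mechanisms that break it, so the whole pipeline can
be validated against known ground truth.

Throughout, the two samples are cell-extract pools from HT-29 (colorectal
adenocarcinoma) and AsPc-1 (pancreatic cancer) cell lines, each measured in
triplicate by every method; the quantity of interest is the HT-29/AsPc-1
intensity ratio.

## Identifier harmonization

Different sites report the same compound under different names, and lipids
under different annotation levels. The nomenclature module resolves raw
names in a fixed order: exact synonym-table match, then case- and
whitespace-normalized match, then lipid-shorthand canonicalization. Names
that survive none of the three are returned on an unresolved list and
excluded with a logged warning count — silent loss of identity is the
precise failure mode this package exists to expose, so nothing is dropped
quietly.

The lipid grammar covers `CLASS C:D` (sum composition), `CLASS
C1:D1/C2:D2[/C3:D3]` (molecular species) and a trailing `(sn-1)`/`(sn-2)`
positional token for single-chain (lyso) classes. The class registry — 21
default classes, each with its chain arity and whether sn annotation is
meaningful — is configuration loaded from TSV, not a code constant, as is
the default panel of 20 fatty acyl chains; both defaults are common-usage
choices, not an authoritative target list, and any registry/panel can be
substituted. Ether and plasmalogen (`O-`/`P-`) shorthand is outside the
grammar and rejected with a specific error rather than misparsed. MG is
registered as supporting sn annotation (monoacylglycerol positional isomers
are real), a judgment call with no effect on any other class.

Structural isomers that share a sum composition (e.g. PI 18:0/20:2 and
PI 18:1/20:1, both PI 38:2) are the unit at which chromatographic coelution
merges peaks, so `isomer_groups` partitions compounds by (class, total
carbons, total double bonds). Hydrophilic isomer sets (e.g. the hexoses
glucose/fructose) have no structural grammar to infer from and must be
declared explicitly in configuration.

## Detection and coverage

A method *detects* a metabolite in a sample when at least 2 of its 3
replicate intensities are present. The rule tolerates one failed run while
excluding singleton artifacts; the threshold is configurable. Missing
intensities are empty fields, never zeros: a zero is a valid
below-detection-limit signal, while a missing field means the method did
not report the compound — keeping the two distinct lets sensitivity
differences between methods surface as missingness.

Coverage bookkeeping counts (1) metabolites detected in at least one sample
by at least one method and (2) metabolites detected in *both* samples by at
least two methods — the population on which cross-method comparison is
possible at all.

## The concordance cascade

For each metabolite, per method:

* **Ratios.** HT-29 and AsPc-1 replicates are paired by replicate index
  (run order) and divided, giving up to three ratio observations per
  method. Pairing by index is what makes a per-method *sample* of ratios
  available to the cross-method ANOVA; the alternative (a single ratio of
  means, available via `ratio_mode="ratio_of_means"`) yields one
  observation per method and therefore cannot feed the ANOVA — it exists
  for export and sensitivity checks, not for classification. Pairs with a
  zero denominator are dropped with a warning; a method with fewer than two
  surviving pairs is excluded for that metabolite.
* **Student's t-test.** Two-sided, pooled variance, on the raw HT-29 vs
  AsPc-1 intensities at α = 0.05. Pooling (rather than Welch) is the
  deliberate choice for n = 3 vs 3 triplicates; a log-scale option exists
  for sensitivity analysis but raw intensities are the default. Degenerate
  zero-variance inputs resolve by convention: equal means → p = 1, unequal
  means → p = 0. Direction (up/down) is read from the mean ratio against 1,
  only when significant.

Across methods:

* **Direction discordance** flags a metabolite when one method is
  significantly up while another is significantly down — the starkest
  cross-method contradiction, computed independently of the ANOVA verdict.
* **One-way ANOVA** on the replicate ratios tests homogeneity of the
  relative level across methods (concordant iff p > α). Groups with fewer
  than two ratios are excluded; fewer than two surviving groups means no
  ANOVA and the metabolite is classed `single_method`.
* **Leave-one-method-out rescue.** When the full ANOVA rejects, it is
  re-run omitting each method in turn. If any omission restores p > α the
  metabolite is `rescued_one_outlier` and the omission maximizing p is
  reported as the outlier method (ties broken deterministically by method
  id; all rescuing candidates are retained in the record). At least three
  methods are required: with exactly two discordant methods no outlier is
  identifiable, and the metabolite stays `discordant`.

No multiple-testing correction is applied at any stage; every test runs at
its nominal α. That mirrors the majority-rule screening design this
pipeline implements — the output is a triage of metabolites by
cross-method agreement, not a calibrated family of hypothesis tests — and
is a fidelity choice, not an endorsement.

### Summary table

Counts are aggregated into six rows (identified / multi-method /
t-significant in ≥ 2 methods / direction-discordant / ANOVA-concordant /
concordant-with-rescue) per category (hydrophilic, hydrophobic) and in
total. Percentages are derived as row2/row1, row4/row3, row5/row2 and
row6/row2, rounded half-away-from-zero to one decimal. Note one rounding
consequence: 170/433 = 39.26 % reports as 39.3 under this (or any standard)
rounding rule. "t-significant" requires significance in at least two
methods, matching the "among two or more methods" reading of the row; this
guarantees the count cascade row4 ≤ row3 ≤ row2 ≤ row1 and
row5 ≤ row6 ≤ row2.

## The study simulator

`synthetic_data` generates a full multi-laboratory study with ground truth.
Per covered metabolite, replicate and sample:

    intensity = response × abundance(sample) × exp(ε),   ε ~ N(0, σ)

* **Abundances** are log-normal (default log-mean 11.5, log-sd 1.0 —
  arbitrary signal units around 10⁵ with a realistic dynamic range);
  `abundance(HT29) = base × true_ratio`.
* **True ratios** are 1 for null metabolites; non-null metabolites (default
  30 %) draw a log-normal effect symmetric on the log scale (default log-sd
  0.7, i.e. typical 2-fold changes), so up- and down-effects are equally
  reachable.
* **Response factors** are per-method, per-metabolite log-normal factors
  (default log-sd 0.5). The cascade is exactly invariant to them (a
  property test multiplies one method's intensities by a constant and
  asserts identical output), so they only matter through LOD censoring.
* **Noise** is multiplicative log-normal with σ set equal to the method's
  replicate CV (drawn from a configurable range, default 0.05–0.15 —
  typical triplicate repeatability for targeted MS). σ = CV is the
  first-order approximation of a log-normal with that CV; at CV ≤ 0.15 the
  difference from the exact relation √log(1+CV²) is under 2 % and not worth
  the opacity.
* **LOD censoring**: each method's limit of detection is a quantile
  (default 0.02) of its own noiseless intensities; values below it are
  reported missing, feeding the detection rule — sensitivity differences
  become dropped methods, not zeros.
* **Coverage**: each metabolite enters each method's panel independently
  with probability mean_methods_per_metabolite / n_methods, emulating the
  partially overlapping target lists of real laboratories.

Four fault mechanisms can be injected per method, applied in the fixed
order coelution → isobaric overlap → misidentification → derivatization
bias (identification errors before sample-dependent recovery bias; the
order matters only when faults co-occur on one cell):

* **coelution** sums an isomer group's (noisy) signals into one reported
  peak — the reported ratio becomes the denominator-intensity-weighted mean
  of the members' true ratios, so it always lies between the extremes;
* **isobaric_overlap** leaks a fraction of a contaminant's signal into a
  target peak (overlapping MRM transitions);
* **misidentification** reports compound X with compound Y's integrated
  signal;
* **derivatization_bias** multiplies one sample's intensities by a recovery
  factor (an incomplete derivatization that hits one matrix harder),
  directly scaling the reported ratio.

Fault magnitudes have no authoritative reference values; the defaults in
the demo configuration are illustrative. All randomness flows through one
`numpy` generator seeded from the mandatory config seed, making output
files byte-identical across reruns.

### What the simulator does and does not emulate

It reproduces the *structure* of a ring-trial dataset (triplicates, two
samples, partial coverage, heterogeneous sensitivity and precision) and the
*algebra* of the diagnosed error mechanisms. It does not simulate
chromatograms, retention times, spectra, peak picking, extraction chemistry
or correlated drift between replicates. Passing the simulator-based tests
therefore demonstrates that the cascade detects these error mechanisms when
they occur as modeled — not that real data contain no other failure modes.

## Validation design

* The t and F statistics are checked against independent from-scratch
  implementations of the definitional formulas (pooled variance;
  between/within sums of squares) to 1e-10 on 1,000 random instances, plus
  the exact F = t² identity on two groups.
* On fault-free null studies (1,000 null metabolites × 5 methods,
  CV = 0.05, 20 seeds) the ANOVA-significant fraction must sit inside the
  99.9 % binomial band around α = 0.05, and the unrescued discordant
  fraction must not exceed that band's upper edge.
* With one derivatization-biased method among five clean ones, the
  leave-one-out detection rate must reach ≥ 0.9 at 3-fold bias and be
  monotone over the bias grid {1.0, 1.5, 2.0, 3.0}. The true detection
  probability plateaus near 1 − α once the bias is large (rescue also
  requires the clean-subset ANOVA to accept, a bias-independent ~0.95
  event), so monotonicity of adjacent empirical rates is asserted with a
  one-sided 3σ two-proportion binomial margin rather than raw inequality.
* The coelution weighted-mean identity is asserted exactly (zero noise,
  tolerance 1e-12).

Problem sizes above (20 × 1,000 null metabolites; 250 metabolites per bias
point; 1,000 oracle instances) are the package's chosen validation scale:
large enough for the binomial bands to be narrow, small enough to keep the
full suite fast on one CPU.

## Known limitations

* The lipid grammar deliberately excludes ether/plasmalogen, oxidized and
  branched species; extending it means extending the registry and the
  parser together.
* `ratio_of_means` mode produces one ratio per method and thus degrades
  classification to `single_method`; it is an export/sensitivity option
  only.
* With exactly two disagreeing methods the cascade cannot identify an
  outlier, by construction.
* The simulator's fault magnitudes and the 20-chain fatty-acyl panel are
  plausible defaults, not measured values.
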