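# Methods

This note documents the models, defaults, and numerical choices behind
`mficyto`, and what the synthetic validation does and does not demonstrate.

## Synthetic-study generator

The generator emulates a congenic-cross, injected-antibody CyTOF study of
the pregnant mouse. Its unit of generation is the (treatment arm, embryonic
day, mouse, compartment) sample.

**Marker model.** Every population is a Gaussian archetype on the
arcsinh(x/5) scale: each marker has a mean and sd (default background mean
0.3, sd 0.3; signature markers sit at 3.5–5.0 with sd 0.35). Values are
inverse-transformed (`5·sinh`) to the raw scale and floored at 0, matching
the cofactor-5 transform used throughout the analysis. The archetype means
are the package's own choices — no per-population intensity distributions
are published for this design — and were picked so that signature markers
separate populations by ~10 pooled sds while background channels overlap.

**Gating-utility channels** are set by ground truth rather than archetype:
DNA (mean 5.5), cisplatin viability (live 0.5 / dead 4.0), Ter119 (0.3 for
leukocytes), CD45.2 (5.0 for all immune cells), CD45.1 (4.5 fetal / 0.3
maternal), injected anti-CD45 (6.0 in PB and EV, 0.5 in TIS, sd 0.5). With
the default gate thresholds every rule sits ≥ 5 sds from both flanking
distributions, so per-event misclassification is ≪ 1%.

**Abundance model.** Each population carries, per compartment, an expected
fraction `intercept + slope·t + quad·t²` with `t = day − 10.5` (fraction
units per embryonic day). At generation time values are clipped at 0,
multiplied by per-arm effect multipliers and per-mouse log-normal intercepts
(`exp(N(0, mouse_sd))`, default sd 0.15, shared across compartments of a
mouse), renormalized to a simplex, and fed to a multinomial over
`events_per_sample` (default 2000). The defaults encode the field's
expectations: MPs dominate EV and decline with day while neutrophils rise
(crossing mid-gestation); T and B cells dominate blood; neutrophils are
tissue-enriched; fetal cells appear only at the MFI and ramp from ~0.1% to
~0.8% of immune cells. The clip-then-renormalize construction is the
simplest compositional model consistent with those facts; the underlying
study has no published generative model.

**Injected effects.**

- `inject_crossover(cell_a, cell_b, day_star, compartment)` replaces the two
  abundance models with lines of slope ∓δ through a common level at
  `day_star`, where δ = 0.8·level/max-span keeps both trajectories positive
  over the day range. Pre-normalization abundances are equal exactly at
  `day_star`; because the other populations are constant in that
  compartment, the renormalized fractions also cross there.
- `inject_perturbation` scales named populations' abundance models by
  positive multipliers (per compartment) before renormalization; the
  configured multipliers are recorded in the ground truth.
- `add_batch_effect` applies per-batch strictly monotone affine distortions
  on the arcsinh scale (`y = a·x + c`, a > 0, optionally per marker).
  Anchor (splenocyte) samples — identical material replicated into every
  batch — receive their batch's distortion, which is what anchor-based
  normalization assumes.
- `simulate_leakage_mouse` emits a lymph-node control in which a configured
  fraction of events carries the injected channel above the EV threshold.

**What the generator does not emulate:** mass-channel spillover, bead
normalization drift, barcode collisions, doublets (beyond an optional
broad-positive contaminant archetype), acquisition-time drift, or
non-Gaussian heavy tails of real CyTOF intensities. Passing recovery tests
therefore demonstrates correctness of the analysis logic under the stated
generative assumptions, not robustness to every artifact of real data.

## Preprocessing

The arcsinh transform uses cofactor 5 and records its state; double
transformation is an error. Quantile normalization operates on the
transformed scale (the alternative — raw scale — is mathematically
equivalent for a monotone map built and applied consistently; the choice is
recorded in output metadata). For each batch and marker, the map sends the
batch anchor's empirical quantiles (101 knots by default) onto the
reference anchor's quantiles with linear interpolation; beyond the anchor's
observed range the terminal segment's slope is continued, which keeps the
map strictly increasing (no rank ties among extreme events) while bounding
its slope. The reference batch passes through untouched. Subsampling keeps
`min(cap, n)` events per mouse × organ, uniformly without replacement and
seeded ("up to N" semantics: groups under the cap are kept whole; defaults
500 for maternal and 150 for fetal rounds).

## Gating

Gates are pure functions of arcsinh intensities and a `GateConfig`:
viable = DNA ≥ 3.0 ∧ cisplatin < 2.0 ∧ Ter119 < 2.0; maternal = CD45.2 ≥
2.5 ∧ CD45.1 < 2.0; fetal = both high. The endovascular rule applies the
per-event injected-channel value against a fixed threshold of 3.5
(boundary-inclusive) in placental samples; PB samples are labeled PB. The
3.5 cutoff is interpreted per event — each event contributes its own channel
value — since a per-sample median could not classify individual cells. The
manual viability/origin thresholds of the original workflow are not
reproducible as code; they are config values here, with an optional
two-component Gaussian-mixture valley fit (`auto_thresholds`) that falls
back to the config default when a channel looks unimodal. Leakage QC fails a
mouse when more than 5% (configurable; "significant leakage" is otherwise
undefined) of its viable lymph-node immune events exceed the EV threshold;
mice without an LN control pass with a warning.

## Clustering and annotation

Events are clustered by Leiden community detection (RB-configuration
partition, seeded, 2 iterations) on a symmetrized k-nearest-neighbor graph
(k = 20) of the lineage-marker panel; the backend is pluggable behind
`cluster_events`. Cluster counts from community detection are stochastic
and data-dependent, so validation is by ground-truth recovery (adjusted Rand
index), never by cluster count. Metaclustering takes per-cluster marker
medians, excludes clusters whose min-max-scaled medians are all above 0.9
(doublet-like, broad-positive) or all below 0.1 (all-negative) — the
published exclusions were visual; these quantiles codify them — then merges
the rest by agglomerative average linkage (Euclidean on median profiles by
default, correlation available) cut at a configured height, with ordered,
replayable manual merge/split/exclude rules on top. Min-max scaling maps a
constant marker to 0 and flags it degenerate. Threshold rules are
boundary-inclusive exactly as specified: FcεRI ≥ 1.0 splits basophils from
eosinophils; Ly-6C ≥ 4.5 ⇒ classical, ≥ 3.0 ⇒ intermediate, < 3.0 ⇒
non-classical monocytes.

## Compositional statistics

Fraction tables declare their denominator (all immune cells in compartment,
a parent type, or a marker-positive subset); zero-count types appear with
fraction 0 and empty-denominator groups are dropped with a warning.
Bray-Curtis is computed on counts when available and fractions otherwise
(identical when per-sample totals are equal; the choice is recorded).
Pairwise compartment dissimilarities pair samples within mouse by default
(matched design) with an all-pairs mode available — the original pairing is
unstated, so both are provided and neither asserted.

The discriminant is the Fisher formulation: the generalized eigenproblem of
between-class versus pooled within-class scatter, with the within-class
matrix ridged by `1e-8·trace(Sw)/p` on the diagonal, which keeps an 8-
feature scatter invertible at small sample counts without materially moving
the axes. Axes are defined up to sign and scale; tests compare subspaces,
not raw coefficients.

Z-score trajectories standardize per-day mean fractions with the sample
(n−1) sd; a constant series is an error. `detect_crossover` reports every
consecutive day pair where the sign of the difference changes and exact
zeros as point crossings. One caveat worth knowing: standardization removes
location and scale, so the z-series of any two opposite *linear* trends
cross at the mean of the day grid regardless of where the underlying
fractions cross. Recovering a configured crossing day from noisy linear
trends therefore uses `day_trend_series` — per-day values of the pooled OLS
day fit, i.e. the linear-intersection estimate — which also pools noise
across all samples rather than relying on per-day means of 3 mice.

Condition contrasts report `log2(mean treated / mean control)` per cell
type with uncorrected two-sample t flags at p < 0.05 (matching how
perturbation panels are conventionally reported); zero control means are
replaced by a declared pseudo-fraction and logged.

## Gestational models

Day regression is OLS of embryonic day on cell-type fractions (scikit-learn
backend), reporting training R² and seeded 5-fold cross-validated R² as
distinct labeled quantities — they are never conflated. Windows: early
E10.5–E13.5, late E14.5–E18.5. Designs with more features than samples are
refused unless a ridge penalty is enabled. `compare_windows` takes the ratio
of mean R² and a two-sample t test across cross-validation folds (the
original early-vs-late test's inputs are unstated; the fold-based mode is
the default and recorded).

Robust trend fits use OLS point estimates with the HC0 sandwich covariance
and Wald z p-values; HC0 (no small-sample factor) is the default because it
is algebraically identical to a GEE with independence working correlation
and cluster size 1; HC1 is available by option. Compartment enters as
treatment-coded dummies with PB as reference so coefficients compare each
compartment against blood. Day is mean-centered before squaring to reduce
collinearity with the quadratic term (whether the original analysis centered
is unstated; the choice is recorded here).

The ANOVA dispatcher uses Levene's test to choose classic ANOVA (with Tukey
HSD post hocs) versus Welch ANOVA (Welch-Satterthwaite df, Games-Howell post
hocs), via pingouin; a zero-variance group forces the Welch branch.
Differential expression runs per-marker two-sample t tests on per-mouse
medians with Bonferroni adjustment, skipping markers with fewer than two
mice per group.

The ratio test applies the Taylor-series identity
`V(X/Y) = E(X²)·E(1/Y²) − [E(X)·E(1/Y)]²` to the sampling distribution of
the two arm means: plug-in moments `E[X̄²] = x̄² + s²ₓ/n`,
`E[1/Ȳ] ≈ (1/ȳ)(1 + v_y/ȳ²)`, `E[1/Ȳ²] ≈ (1/ȳ²)(1 + 3v_y/ȳ²)` with
`v_y = s²ᵧ/m`, whose expansion equals the delta-method variance of a ratio
of independent means. It is accurate for control coefficients of variation
below ~0.2 and is validated against a Monte-Carlo reference to 5%. Zeros in
the control arm trigger a logged 0.5 pseudo-count shift of both arms (the
conventional continuity correction). Two ratios are compared by a t test
from descriptive statistics (ratio, Taylor sd, n = smaller arm size).

## Validation problem sizes

The recovery and calibration studies in `tests/test_acceptance.py` and
`scripts/acceptance.py` use these sizes, chosen so each property is measured
with comfortable statistical margin at desk scale:

- gating/clustering studies: 2,000 (gating) or 1,200 (clustering) events per
  sample, 2 mice/day over E10.5/E14.5/E18.5; fraction-level studies
  (cross-over, windows, quadratic trends): 5,000 events per sample, 3
  mice/day over the full E10.5–E18.5 grid, 20 seeds each;
- null calibrations: 2,000 replicates of n = 400 observations for the
  robust-trend z test (the HC0/z combination is asymptotic and genuinely
  anti-conservative at small n — about 0.057 at n = 120 versus 0.051 at
  n = 400 — so the calibration property is checked in its asymptotic
  regime); 1,000 replicates of 3 × 15 observations for the ANOVA dispatch;
  1,000 Monte-Carlo replicates of n = 10,000 for the ratio variance;
- differential expression: 40 null markers × 5 mice per group × 20 seeds.

## Known limitations

- The generator's Gaussian-on-arcsinh archetypes understate the zero
  inflation and heavy tails of real CyTOF counts; gate thresholds tuned on
  real data may need the mixture-based auto-fit.
- Full-event composition tables are computed from the clustered subsample
  (500 cells per mouse × organ), mirroring the subsampled clustering design;
  with very rare subsets, fraction estimates inherit that cap's noise.
- The GEE machinery is deliberately limited to the singleton-cluster
  independence case (≡ HC0); repeated-measures correlation structures are
  out of scope.
- `detect_crossover` is a sign-change detector on whatever series it is
  given; on standardized linear trends it reflects the day-grid midpoint,
  as discussed above.
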