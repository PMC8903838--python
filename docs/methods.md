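# Methods

## Scope and data model

`synmorph` analyses longitudinal, two-channel synaptic morphometry: for each
dendritic spine observed at a set of time points (minutes apart), the area of
the spine head and the area of the PSD95 assembly it bears, both in µm², with
the rearing condition (environmental enrichment, `EE`, vs standard-cage
control, `Ctr`) as the between-group factor. Records carry spine, mouse and
field-of-view identifiers; records of one spine link into a trajectory with
strictly increasing times. Spines without a PSD95 measurement are dropped at
ingestion (the analysis concerns spines that form identifiable synapses);
missing brightness is allowed and simply excluded from brightness summaries.

Tables are plain CSV with a header. Because deposited tables rarely share a
column layout, readers take a schema map (canonical name → actual header) so
adaptation happens in configuration, not code.

## Size distributions

Spine-head and PSD95 area distributions are positively skewed and
approximately log-normal, as expected when sizes evolve multiplicatively.
Summaries therefore report median and quartiles (linear interpolation,
"type 7") plus the adjusted Fisher–Pearson sample skewness, and all
location/scale inference runs on base-10 logarithms: mean and unbiased (n−1)
variance of log10(area), a least-squares Gaussian fit to the log10 histogram
(fixed bin width, default 0.1 on the log axis, fitted at bin centers), the
two-sample Kolmogorov–Smirnov test on raw areas (appropriate for skewed
samples) and Welch's unequal-variance t-test on log areas. Base 10 is forced
by internal consistency of the study-scale numbers: a log-mean near −0.26
matches a median near 0.55 µm² only in base 10. Moment-based and
histogram-fit estimates of the log-Gaussian parameters are both computed and
reported side by side; they agree within ~2 % on well-sampled log-normal data
and their discrepancy is a useful diagnostic for binning artifacts.

## Change measures and their decomposition

For two observations of one structure at times t and t+Δt:

* ΔA_abs = A(t+Δt) − A(t) (µm²),
* ΔA_norm = (A(t+Δt) − A(t)) / (A(t+Δt) + A(t)), bounded in [−1, 1] and
  exactly antisymmetric under time reversal,
* ΔA_% = 100 · (A(t+Δt) − A(t)) / A(t).

Lags pool all start times: Δt = 30 min collects the 0–30 and 30–60 min pairs
of a 0/30/60 trajectory. Pairs are formed from any two observations exactly
Δt apart (not only adjacent samples), which coincides with the pooling rule
on three-point schedules and extends it consistently to denser grids.
Overlapping windows of one spine are treated as independent observations in
the pooled statistics — matching how pooled sample sizes are counted — while
spine identity is retained so bootstrap resampling can operate at the spine
level. Median percent changes are reported separately for growth (Δ > 0) and
shrinkage (Δ < 0).

The 2-D scatter of paired normalized changes (PSD95 on x, spine head on y) is
decomposed by PCA: eigenvalues of the unbiased 2×2 covariance are the
variances along PC1 (correlated-change axis) and PC2 (anti-correlated axis);
raw eigenvalues are used, not normalized ones. PC1 is oriented into the first
quadrant when its span permits, ties broken toward a positive first
coordinate.

## Multiplicative downscaling and ANCOVA

OLS of A(t+Δt) on A(t) yields a slope < 1 with positive intercept when large
structures tend to shrink and small ones to grow; the slope acts as the
time-dependent multiplicative downscaling factor of a Kesten-type size
process, and 1 − slope equals the regression-to-the-mean slope of ΔA_abs on
A(t). Slope equality between conditions is tested with the classical
two-group ANCOVA statistic: t = (b₁ − b₂)/SE_diff with the pooled residual
variance of the two separate fits and n₁ + n₂ − 4 degrees of freedom. This is
algebraically the Wald test on the interaction term of a joint
`y ~ x * group` OLS fit, which the test suite uses as an independent
cross-check.

## Cross-correlation and bootstrap

The lagged spine×PSD correlation is

    CC(Δt) = Σ (A1(t+Δt) − Ā1)(A2(t) − Ā2)
             / sqrt( Σ (A1(t) − Ā1)² · Σ (A2(t) − Ā2)² )

summed over spines and start times with both observations present (A1 spine
head, A2 PSD95; negative lags shift the PSD channel instead). Two conventions
are deliberately exposed:

* **Means.** Ā1/Ā2 default to means over the observations entering the given
  lag's sums. This makes CC(0) coincide exactly with the Pearson correlation
  of the pooled size pairs — a property the tests assert at 1e−9. A global
  per-channel mean is available behind a flag.
* **Denominator time index.** The formula above indexes A1 at t in the
  denominator but at t+Δt in the numerator. Whether that asymmetry is
  intended or a typesetting artifact cannot be decided from the formula
  alone, so both the literal form (default) and a symmetrized variant using
  A1(t+Δt) in the denominator are computed; both are reported whenever they
  differ by more than 0.01.

Bootstrap SDs resample whole trajectories (spines) with replacement,
recompute the statistic per replicate, and report the SD across replicates.
Replicates where the statistic is undefined are dropped and counted; more
than 20 % failures aborts the bootstrap.

## Morphometry

ROI areas use the shoelace formula on sub-pixel polygon vertices times the
squared pixel size (default 30 nm/px); orientation-independent, exact for
simple polygons, no rasterization. Brightness is the raw integrated density
(sum of intensities under a mask). Spine density along a dendrite is
(n − 1)/(span between first and last spine), branched spines counted once.

Nanopattern topology uses 8-connected foreground and 4-connected background
(the standard dual pair, so a diagonally-closed ring keeps its hole):
`macular` = one component, no holes; `perforated` = one component, ≥ 1 hole;
`clustered` = ≥ 2 components (count reported). Strict topology classifies an
*open* horseshoe as macular, whereas visual convention groups it with
perforated shapes; an optional "concavity rescue" (solidity < 0.75 promotes
macular → perforated, flagged in the output) bridges the two, and is off by
default. Components minus holes is checked in the tests against the
integral-geometry Euler number computed by scikit-image — an independent
route over the same masks.

## Categorical change annotations

Morphological change of an assembly relative to t = 0 is a 3-level ordinal
label (no / subtle / strong change) per annotator. Consensus is majority
vote; a full 3-way tie resolves to the middle category with a tie flag (the
merging rule is this package's choice — how multiple annotators were merged
is not specified in the source protocol). Stacked relative-frequency tables
are produced per condition × interval; Fleiss' kappa is available as an
agreement diagnostic. Standard intervals are {30, 60, 120} min; other values
pass through with a warning.

## Synthetic-data generator

Each channel follows a Kesten recursion per imaging step,
A(t+1) = η·A(t) + ε, with η ~ N(η̄, σ_η) truncated at zero and
ε ~ N(ε̄, σ_ε); any non-positive next size is jointly resampled rather than
clipped, keeping the size distribution continuous and positive. Initial
areas are log-normal. Two correlations couple the channels:

* `init_rho` (default 0.88) correlates the initial log-sizes — the slow,
  shared component that makes *absolute* spine and PSD sizes correlate near
  0.8;
* `coupling_rho` (default 0.30) correlates the standardized per-step
  innovations of (η, ε) — the fast component that gives paired *changes* a
  moderate correlation and a PC1/PC2 variance ratio near 3.

A single coupling knob cannot do both jobs: driving the size correlation to
0.8 through the innovations alone forces the change correlation to ~0.8 and
the PC ratio toward 8, far from what paired-change data of this kind show.
The two-correlation structure is the minimal model reproducing strong size
coupling with weak change coupling.

Defaults are calibrated once to the study conditions the generator emulates:
spine-head median ≈ 0.52 µm², PSD95 median ≈ 0.16 µm² (initial log10 means
−0.28 / −0.80, SDs 0.25 / 0.24), η̄ = 0.82 per 30-min step, σ_η = 0.12/0.16
(spine/PSD), ε̄ set to (1 − η̄) × the stationary mean so cohorts are
size-stationary over the 0/30/60/120 min imaging grid, and the two coupling
defaults above. The EE/Ctr presets shift these: EE has larger spine heads
with narrower log-distributions and stronger PSD95 downscaling
(η̄_psd = 0.76) than Ctr (η̄_psd = 0.88). Because paired changes at long lags
inherit the initial-size correlation through mean reversion, the PC ratio
grows with lag (≈ 3.1/3.7/5.2 at 30/60/120 min at the defaults); the
calibration targets the compiled-over-intervals ratio, the analog of the
compiled-changes view.

With these defaults the long-run (≥ 50 steps) stationary sizes are positively
skewed and their base-10 logs are close to symmetric (|skew| reduced more
than five-fold) — the qualitative signature of multiplicative size dynamics.
The generator emulates the *statistical* structure of the measurements only:
it produces no images, no point-spread function, no segmentation noise, no
annotator variability, and its spines never appear or vanish mid-series.
Passing tests on synthetic cohorts therefore validate the computational
pipeline, not the biology of any particular dataset.

Nanopattern masks are generated directly in the declared topology class
(jittered filled disc, annulus, or k disjoint discs on a ring; default grid
64×64 px at 30 nm/px) and are guaranteed, by construction and by test, to
round-trip through the classifier. Categorical change annotations are drawn
from per-interval probability vectors.

## Numerical and statistical choices

* Quartiles: linear interpolation; skewness: adjusted Fisher–Pearson
  (NaN for n < 3 or constant samples).
* Gaussian histogram fit: `scipy.optimize.curve_fit`, initialized at the
  moment estimates; requires ≥ 5 non-empty bins; |σ| is reported.
* KS p-values are asymptotic; Welch df by Welch–Satterthwaite.
* PCA: `numpy.linalg.eigh` on the unbiased covariance; trace is conserved to
  1e−12 and the decomposition matches a rotation-scan oracle to 1e−9.
* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give bit-identical tables and reports.
* The slope-recovery validation grid (E[η] ∈ {0.6, 0.8, 1.0}, n = 5000, 200
  runs, slope within 3 OLS SE ≥ 95 % of runs) is run under
  additive-noise-dominated, truncation-free conditions (σ_η = 0.03,
  σ_ε = 0.04, ε̄ = 0.08, initial log10 SD 0.15). Under dominantly
  multiplicative noise the residual variance grows with A(t)², the nominal
  homoscedastic OLS SE undercovers (measured ≈ 87–90 %), and under strong
  downscaling the positivity resampling truncates the small-spine tail and
  biases the slope low — both effects are properties of the estimator, not
  defects of the simulation, and the near-homoscedastic regime is the one in
  which the 3-SE band is statistically meaningful.

## Problem sizes

Default analysis cohorts use 800 spines per condition at 4 time points;
validation simulations use 1500–5000 spines (80 steps for stationary-shape
checks). These sizes put Monte-Carlo noise well below the effect sizes under
study while keeping any single analysis run in seconds.

## Known limitations

* No segmentation: polygon ROIs and binary masks are taken as given.
* No mixed-effects structure across mice; conditions are compared by pooled
  per-spine statistics, as in the source analyses.
* No likelihood-based fitting of Kesten parameters to data; the regression
  slope is the only estimator of the multiplicative factor.
* The strict-topology nanopattern classifier operationalizes a visual
  taxonomy; continuous-but-twisted shapes are only captured via the optional
  concavity rescue.
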