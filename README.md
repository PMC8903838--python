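# synmorph

Analysis toolkit for **longitudinal two-channel synaptic morphometry**: paired
measurements of dendritic spine-head area and PSD95-assembly area from
time-lapse superresolution imaging of the mouse cortex, compared between
environmentally enriched (EE) and standard-cage control (Ctr) rearing.

It is written for researchers who have per-spine area tables (or polygon ROIs
and binary nanopattern masks) and want the complete quantitative pipeline:
size-distribution statistics, paired temporal-change statistics, the
multiplicative-downscaling view of size dynamics, and PSD95 nanopattern
topology — plus a synthetic-data generator so every stage is testable without
raw images.

## The model and the statistics

Synaptic sizes are approximately log-normal, the signature of multiplicative
dynamics. The package models a size A (spine head or PSD95 area, µm²) as a
**Kesten process** per imaging step,

    A(t+1) = η·A(t) + ε,    η ~ N(η̄, σ_η),  ε ~ N(ε̄, σ_ε),

where η̄ < 1 is the *multiplicative downscaling factor* and ε a noisy additive
term. Stationary sizes under this recursion are positively skewed with
near-Gaussian logarithms. The two channels are coupled: initial log-sizes
correlate strongly (r ≈ 0.8, like real spine/PSD pairs) and per-step
innovations correlate moderately, so paired changes mix correlated and
anti-correlated fluctuations.

Analyses on measured or simulated trajectories:

* **Distributions** — median/IQR, skewness; mean and unbiased variance of
  log10(area); Gaussian fit to the log-histogram; two-sample KS on raw areas
  and Welch's t-test on log areas.
* **Changes** — ΔA_abs = A(t+Δt) − A(t), ΔA_norm = ΔA_abs/(A(t+Δt)+A(t)) ∈
  [−1, 1], ΔA_% = 100·ΔA_abs/A(t), pooled over start times per lag; PCA of the
  (ΔA_norm^PSD, ΔA_norm^spine) scatter splits variance into correlated (PC1)
  and anti-correlated (PC2) change axes.
* **Downscaling** — OLS slope of A(t+Δt) on A(t) (± SE, Pearson r) as the
  time-dependent multiplicative factor; two-group ANCOVA for slope equality.
* **Cross-correlation** — CC(Δt) between spine and PSD95 sizes over signed
  lags, with spine-level bootstrap SDs; CC(0) equals the pooled Pearson r.
* **Nanopattern** — binary-mask topology (macular / perforated / clustered-k
  via 8/4-connected components and holes) and tabulation of no/subtle/strong
  change annotations.

## Worked example

```python
from synmorph import KestenParams, simulate_kesten_pair
from synmorph.dynamics import compute_changes, pca_changes, cross_correlation

trajs = simulate_kesten_pair(KestenParams(n_spines=1500, seed=31))

changes = []
for dt in (30, 60, 120):
    changes.extend(compute_changes(trajs, dt))
pca = pca_changes(changes)
print(f"var(PC1)/var(PC2) = {pca.var_pc1 / pca.var_pc2:.2f}, PC1 = {pca.pc1}")
print(f"CC(0) = {cross_correlation(trajs, 0).cc:.3f}")
```

prints

```
var(PC1)/var(PC2) = 4.02, PC1 = (0.7554990792853028, 0.6551497089971572)
CC(0) = 0.797
```

i.e. paired normalized changes concentrate on a first/third-quadrant axis
(correlated growth/shrinkage) with roughly 3–4× the variance of the
anti-correlated axis, while absolute spine and PSD95 sizes correlate at ~0.8.

The numbered drivers under `analysis/` run the full study on synthetic EE/Ctr
cohorts and write tidy tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py --seed 0
python analysis/02_size_distributions.py
python analysis/03_change_dynamics.py
python analysis/04_downscaling_crosscorr.py --seed 0
python analysis/05_nanopattern.py --seed 0
```

`02` prints, for example (seed 0):

```
 EE spine: median 0.536 (IQR 0.381-0.783) um^2, skew 1.58, log10 mean -0.266 var 0.0530
Ctr spine: median 0.458 (IQR 0.300-0.680) um^2, skew 2.23, log10 mean -0.348 var 0.0706
EE vs Ctr spine: KS D=0.150 (p=2.5e-08), Welch t=6.63 (p=4.6e-11)
```

— the EE cohort has larger spine heads with a narrower log-distribution,
while (see the `psd` rows) PSD95 medians are nearly identical between
conditions and differ mainly in variance.

The same pipeline runs from a real CSV size table through a YAML config:

```bash
synmorph run --config config.yaml       # full report: CSVs + report.json
synmorph simulate --out cohort/         # synthetic size table
synmorph downscaling cohort/size_table.csv --dt 30 --channel psd
```

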