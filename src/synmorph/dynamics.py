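"""Temporal-change statistics for paired spine/PSD95 size trajectories.

Change measures between two observations of the same structure at times t and
t + Δt (``A`` the area of either channel):

* absolute        ΔA_abs  = A(t+Δt) − A(t)                      [µm²]
* normalized      ΔA_norm = (A(t+Δt) − A(t)) / (A(t+Δt) + A(t)) [−1, 1]
* percent         ΔA_%    = (A(t+Δt) − A(t)) / A(t) · 100       [%]

Lags are pooled: Δt = 30 min collects 0–30 and 30–60 min pairs alike. On the
2-D scatter of paired normalized changes (PSD95 on x, spine head on y) a PCA
splits the variance into a correlated-change axis (PC1, first/third quadrant)
and an anti-correlated axis (PC2). Regressing A(t+Δt) on A(t) gives a slope
< 1 — the time-dependent multiplicative downscaling factor of a Kesten-type
size process — equivalently 1 − slope is the regression-to-the-mean slope of
ΔA_abs vs A(t). Slope equality between conditions is tested by a two-group
ANCOVA; the temporal symmetry of the spine–PSD relation is probed by a lagged
cross-correlation with a spine-level bootstrap SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Trajectory, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PairedChange",
    "PCAResult",
    "RegressionResult",
    "AncovaResult",
    "CrossCorrelation",
    "compute_changes",
    "changes_to_frame",
    "pca_changes",
    "size_regression",
    "ancova_equal_slopes",
    "size_pairs",
    "cross_correlation",
    "bootstrap_sd",
    "percent_change_medians",
]


class InsufficientDataError(ValueError):
    """Too few usable observations for the requested statistic."""


class DegeneracyError(ValueError):
    """Zero-variance input makes the statistic undefined."""


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed."""


@dataclass(frozen=True)
class PairedChange:
    """Per-spine change of both channels over one lag Δt."""

    spine_id: str
    condition: str
    dt_min: int
    t_start_min: int
    d_abs_spine: float
    d_abs_psd: float
    d_norm_spine: float
    d_norm_psd: float
    d_pct_spine: float
    d_pct_psd: float


@dataclass(frozen=True)
class PCAResult:
    """2-D covariance eigendecomposition of paired changes."""

    pc1: tuple[float, float]  # unit vector
    pc2: tuple[float, float]
    var_pc1: float
    var_pc2: float
    n: int

    @property
    def total_var(self) -> float:
        return self.var_pc1 + self.var_pc2


@dataclass(frozen=True)
class RegressionResult:
    """OLS of A(t+Δt) on A(t); slope is the multiplicative downscaling factor."""

    slope: float
    intercept: float  # µm²
    slope_se: float
    r: float
    n: int

    @property
    def regression_to_mean_slope(self) -> float:
        """Slope of ΔA_abs vs A(t); equals slope − 1."""
        return self.slope - 1.0


@dataclass(frozen=True)
class AncovaResult:
    slope_diff: float
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class CrossCorrelation:
    """Lagged correlation of spine-head (A1) vs PSD95 (A2) sizes."""

    dt_min: int
    cc: float
    cc_symmetrized: float
    bootstrap_sd: float | None
    n_pairs: int

    @property
    def variants_differ(self) -> bool:
        return abs(self.cc - self.cc_symmetrized) > 0.01


# ---------------------------------------------------------------------------
# change measures


def _change_triplet(a0: float, a1: float) -> tuple[float, float, float]:
    return a1 - a0, (a1 - a0) / (a1 + a0), (a1 - a0) / a0 * 100.0


def compute_changes(
    trajectories: Iterable[Trajectory], dt_min: int
) -> list[PairedChange]:
    """All paired changes at exactly the lag ``dt_min``, pooled over start times.

    Every pair of observations of one spine separated by exactly ``dt_min``
    contributes one :class:`PairedChange` (so a 0/30/60 trajectory yields the
    0–30 and 30–60 pairs at Δt = 30). No qualifying pair anywhere gives an
    empty list with a warning, not an error.
    """
    if dt_min <= 0:
        raise ValidationError(f"dt_min must be > 0, got {dt_min}")
    out: list[PairedChange] = []
    for traj in trajectories:
        by_time = {s[0]: s for s in traj.samples}
        for t0 in sorted(by_time):
            s0, s1 = by_time.get(t0), by_time.get(t0 + dt_min)
            if s1 is None:
                continue
            da_s, dn_s, dp_s = _change_triplet(s0[1], s1[1])
            da_p, dn_p, dp_p = _change_triplet(s0[2], s1[2])
            out.append(
                PairedChange(
                    spine_id=traj.spine_id,
                    condition=traj.condition,
                    dt_min=dt_min,
                    t_start_min=t0,
                    d_abs_spine=da_s,
                    d_abs_psd=da_p,
                    d_norm_spine=dn_s,
                    d_norm_psd=dn_p,
                    d_pct_spine=dp_s,
                    d_pct_psd=dp_p,
                )
            )
    if not out:
        warnings.warn(f"no observation pairs at lag {dt_min} min", stacklevel=2)
    return out


def changes_to_frame(changes: Iterable[PairedChange]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in changes])


def percent_change_medians(changes: Sequence[PairedChange], channel: str
                           ) -> tuple[float, float]:
    """Median percent growth (Δ > 0) and shrinkage (Δ < 0), separately."""
    attr = f"d_pct_{channel}"
    vals = np.array([getattr(c, attr) for c in changes])
    growth = vals[vals > 0]
    shrink = vals[vals < 0]
    med = lambda x: float(np.median(x)) if x.size else float("nan")
    return med(growth), med(shrink)


# ---------------------------------------------------------------------------
# PCA of paired changes


def pca_changes(
    changes: Sequence[PairedChange],
    fields: tuple[str, str] = ("d_norm_psd", "d_norm_spine"),
) -> PCAResult:
    """Eigendecomposition of the 2×2 covariance of paired changes.

    ``fields`` selects the (x, y) coordinates, by default the normalized
    PSD95 change vs the normalized spine-head change. Eigenvalues are the
    variances along PC1/PC2 (unbiased covariance); PC1 is oriented into the
    first quadrant when its span permits, ties broken toward a positive
    first coordinate.
    """
    pts = np.array([[getattr(c, fields[0]), getattr(c, fields[1])] for c in changes])
    return _pca_points(pts)


def _pca_points(pts: np.ndarray) -> PCAResult:
    if pts.shape[0] < 3:
        raise InsufficientDataError(f"PCA needs >= 3 points, got {pts.shape[0]}")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / (pts.shape[0] - 1)
    if np.trace(cov) == 0:
        raise DegeneracyError("zero total variance: PCA undefined")
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = [1, 0]
    evals = evals[order]
    evecs = evecs[:, order]
    vecs = []
    for k in range(2):
        v = evecs[:, k]
        # orient into the first quadrant when possible; else positive x, then +y
        if (v < 0).all() or (v[0] < 0) or (v[0] == 0 and v[1] < 0):
            v = -v
        vecs.append((float(v[0]), float(v[1])))
    return PCAResult(
        pc1=vecs[0],
        pc2=vecs[1],
        var_pc1=float(max(evals[0], 0.0)),
        var_pc2=float(max(evals[1], 0.0)),
        n=pts.shape[0],
    )


# ---------------------------------------------------------------------------
# time-lagged size regression and ANCOVA


def size_pairs(
    trajectories: Iterable[Trajectory], dt_min: int, channel: str
) -> list[tuple[float, float]]:
    """(A(t), A(t+Δt)) pairs of one channel at exactly the lag ``dt_min``."""
    if channel not in ("spine", "psd"):
        raise ValidationError(f"channel must be 'spine' or 'psd', got {channel!r}")
    idx = 1 if channel == "spine" else 2
    pairs: list[tuple[float, float]] = []
    for traj in trajectories:
        by_time = {s[0]: s for s in traj.samples}
        for t0 in sorted(by_time):
            s1 = by_time.get(t0 + dt_min)
            if s1 is not None:
                pairs.append((by_time[t0][idx], s1[idx]))
    return pairs


def size_regression(pairs: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS of the later size on the initial size over (A(t), A(t+Δt)) pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.shape[0] < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {arr.shape[0]}")
    x, y = arr[:, 0], arr[:, 1]
    if np.var(x) == 0:
        raise DegeneracyError("zero variance in initial sizes")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r=float(res.rvalue),
        n=arr.shape[0],
    )


def _slope_se_parts(pairs: np.ndarray):
    x, y = pairs[:, 0], pairs[:, 1]
    n = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    rss = ((y - slope * x - intercept) ** 2).sum()
    return slope, sxx, rss, n


def ancova_equal_slopes(
    group_a: Sequence[tuple[float, float]], group_b: Sequence[tuple[float, float]]
) -> AncovaResult:
    """Two-group test of regression-slope equality (classical ANCOVA).

    The slope difference is scaled by its standard error from the pooled
    residual variance of the two separate fits, with n_a + n_b − 4 degrees
    of freedom; two-sided p.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for g, name in ((a, "a"), (b, "b")):
        if g.shape[0] < 3:
            raise InsufficientDataError(f"group {name}: need >= 3 pairs")
        if np.var(g[:, 0]) == 0:
            raise DegeneracyError(f"group {name}: zero variance in initial sizes")
    slope_a, sxx_a, rss_a, n_a = _slope_se_parts(a)
    slope_b, sxx_b, rss_b, n_b = _slope_se_parts(b)
    df = n_a + n_b - 4
    s2 = (rss_a + rss_b) / df
    se_diff = np.sqrt(s2 * (1.0 / sxx_a + 1.0 / sxx_b))
    diff = slope_a - slope_b
    if se_diff == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / se_diff
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return AncovaResult(slope_diff=float(diff), t=float(t), df=float(df), p=p)


# ---------------------------------------------------------------------------
# cross-correlation


def _lag_pairs(trajectories: Sequence[Trajectory], dt_min: int):
    """(A1_lagged, A1_base, A2_base) for every spine/time with both obs.

    For dt >= 0 the spine-head channel (A1) is taken at t + Δt against the
    PSD95 channel (A2) at t; for dt < 0 the PSD95 channel is lagged instead.
    """
    a1_lag, a1_base, a2_base = [], [], []
    spine_idx = []
    for i, traj in enumerate(trajectories):
        by_time = {s[0]: s for s in traj.samples}
        for t0 in sorted(by_time):
            if dt_min >= 0:
                s_lag = by_time.get(t0 + dt_min)
                s_base = by_time[t0]
                if s_lag is None:
                    continue
                a1_lag.append(s_lag[1])
                a1_base.append(s_base[1])
                a2_base.append(s_base[2])
            else:
                s_lag = by_time.get(t0 - dt_min)  # dt < 0: lag A2 forward
                s_base = by_time[t0]
                if s_lag is None:
                    continue
                a1_lag.append(s_base[1])
                a1_base.append(s_base[1])
                a2_base.append(s_lag[2])
            spine_idx.append(i)
    return (
        np.array(a1_lag),
        np.array(a1_base),
        np.array(a2_base),
        np.array(spine_idx),
    )


def cross_correlation(
    trajectories: Sequence[Trajectory],
    dt_min: int,
    mean_scope: str = "per_lag",
    denominator: str = "printed",
) -> CrossCorrelation:
    """Lagged spine-head × PSD95 size correlation

        CC(Δt) = Σ (A1(t+Δt) − Ā1)(A2(t) − Ā2)
                 / sqrt( Σ (A1(t) − Ā1)² · Σ (A2(t) − Ā2)² )

    summed over spines and start times where both observations exist. With
    ``mean_scope="per_lag"`` (default) Ā1/Ā2 are means over the observations
    entering this lag's sums, which makes CC(0) coincide with the Pearson r
    of the pooled size pairs; ``"global"`` uses means over all observations
    of each channel. The printed form indexes A1 at t in the denominator;
    the ``cc_symmetrized`` variant uses A1(t+Δt) there. Both are returned.
    """
    trajectories = list(trajectories)
    a1_lag, a1_base, a2_base, _ = _lag_pairs(trajectories, dt_min)
    if a1_lag.size < 3:
        raise InsufficientDataError(
            f"only {a1_lag.size} usable observation pair(s) at lag {dt_min} min"
        )
    if mean_scope == "per_lag":
        m1 = np.concatenate([a1_lag, a1_base]).mean()
        m2 = a2_base.mean()
    elif mean_scope == "global":
        all1 = np.array([s[1] for tr in trajectories for s in tr.samples])
        all2 = np.array([s[2] for tr in trajectories for s in tr.samples])
        m1, m2 = all1.mean(), all2.mean()
    else:
        raise ValidationError(f"unknown mean_scope {mean_scope!r}")

    num = ((a1_lag - m1) * (a2_base - m2)).sum()
    den_printed = np.sqrt(((a1_base - m1) ** 2).sum() * ((a2_base - m2) ** 2).sum())
    den_sym = np.sqrt(((a1_lag - m1) ** 2).sum() * ((a2_base - m2) ** 2).sum())
    if den_printed == 0 or den_sym == 0:
        raise DegeneracyError("zero variance at this lag")
    cc_printed = float(num / den_printed)
    cc_sym = float(num / den_sym)
    cc = cc_printed if denominator == "printed" else cc_sym
    if denominator not in ("printed", "symmetrized"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    if abs(cc_printed - cc_sym) > 0.01:
        logger.info(
            "lag %d min: printed vs symmetrized CC differ by %.3f "
            "(%.3f vs %.3f); reporting both",
            dt_min, abs(cc_printed - cc_sym), cc_printed, cc_sym,
        )
    return CrossCorrelation(
        dt_min=dt_min,
        cc=cc,
        cc_symmetrized=cc_sym,
        bootstrap_sd=None,
        n_pairs=int(a1_lag.size),
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_sd(
    statistic: Callable[[Sequence[Trajectory]], float],
    trajectories: Sequence[Trajectory],
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """SD of a trajectory-level statistic under spine resampling.

    Spines (whole trajectories) are resampled with replacement ``n_boot``
    times; the statistic is recomputed per replicate and the SD across
    replicates returned. Replicates on which the statistic raises are
    dropped and counted; more than 20 % failures aborts.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    trajectories = list(trajectories)
    rng = np.random.default_rng(seed)
    values = []
    failures = 0
    n = len(trajectories)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = [trajectories[i] for i in idx]
        try:
            values.append(float(statistic(sample)))
        except Exception:
            failures += 1
    if failures > 0.2 * n_boot:
        raise BootstrapError(
            f"{failures}/{n_boot} bootstrap replicates failed (> 20 %)"
        )
    if failures:
        logger.info("bootstrap: dropped %d failed replicate(s)", failures)
    return float(np.std(values, ddof=1))
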