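"""Synthetic data with the statistical structure of two-channel spine imaging.

The size generator is a pair of coupled Kesten processes: per imaging step the
area of each channel (spine head, PSD95 assembly) evolves as

    A(t+1) = eta * A(t) + eps,

with a noisy multiplicative factor ``eta`` (mean < 1: multiplicative
downscaling) and a noisy additive term ``eps``. Such a recursion produces the
positively skewed, approximately log-normal stationary size distributions seen
for spine heads and post-synaptic densities. The spine and PSD95 channels are
coupled twice: their log-normal initial sizes correlate strongly
(``init_rho``, the slow shared size component) while their per-step
innovations correlate moderately (``coupling_rho``), so absolute sizes
correlate near 0.8 while paired changes show a mix of correlated and
anti-correlated fluctuations.

Defaults are calibrated to the study conditions this generator emulates:
median spine-head area near 0.5 µm², median PSD95 area near 0.16 µm²,
spine–PSD size correlation near 0.8, and imaging at 0/30/60/120 min.

Also provided: binary nanopattern masks of known topology (macular /
perforated / clustered) and categorical morphological-change annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Trajectory, ValidationError
from .morphometry import NanopatternMask

__all__ = [
    "KestenParams",
    "ChangeTransitionModel",
    "simulate_kesten_pair",
    "generate_nanopattern_mask",
    "simulate_change_annotations",
    "EE_PARAMS",
    "CTR_PARAMS",
]

PairF = float | tuple[float, float]

CHANGE_CATEGORIES = ("no change", "subtle change", "strong change")


def _pair(x: PairF) -> tuple[float, float]:
    """Broadcast a scalar parameter to the (spine, psd) channel pair."""
    if isinstance(x, (tuple, list)):
        if len(x) != 2:
            raise ValidationError(f"channel pair must have 2 entries, got {x!r}")
        return float(x[0]), float(x[1])
    return float(x), float(x)


@dataclass(frozen=True)
class KestenParams:
    """Parameters of the coupled multiplicative–additive size process.

    Each per-channel field takes a scalar (both channels) or a
    ``(spine, psd)`` pair. ``eta_*`` are dimensionless per imaging step,
    ``eps_*`` and the initial-size parameters are in µm² (log10 µm² for the
    initial log-normal). ``coupling_rho`` correlates the per-step spine- and
    PSD-channel innovations (fast shared fluctuations), ``init_rho`` the
    initial log-sizes (the slow shared size component): absolute sizes can
    correlate strongly while paired changes correlate only moderately, as
    observed.
    """

    eta_mean: PairF = 0.82
    eta_sd: PairF = (0.12, 0.16)
    eps_mean: PairF = (0.115, 0.033)  # ~ (1 - eta_mean) * stationary mean
    eps_sd: PairF = (0.030, 0.010)
    coupling_rho: float = 0.30
    init_rho: float = 0.88
    n_spines: int = 500
    time_points: tuple[int, ...] = (0, 30, 60, 120)
    init_log10_mean: PairF = (-0.28, -0.80)
    init_log10_sd: PairF = (0.25, 0.24)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(_pair(self.eta_sd)) < 0 or min(_pair(self.eps_sd)) < 0:
            raise ValidationError("eta_sd and eps_sd must be >= 0")
        if abs(self.coupling_rho) > 1 or abs(self.init_rho) > 1:
            raise ValidationError("|coupling_rho| and |init_rho| must be <= 1")
        if self.n_spines < 1:
            raise ValidationError("n_spines must be >= 1")
        tp = tuple(self.time_points)
        if any(b <= a for a, b in zip(tp, tp[1:])) or len(tp) < 1:
            raise ValidationError("time_points must be non-empty, strictly increasing")
        if min(_pair(self.init_log10_sd)) < 0:
            raise ValidationError("init_log10_sd must be >= 0")


#: calibration presets emulating the two rearing conditions: enriched (EE)
#: cohorts have larger spine heads, narrower log-size distributions and
#: stronger PSD95 downscaling than standard-cage controls (Ctr).
EE_PARAMS = KestenParams(
    eta_mean=(0.82, 0.76),
    init_log10_mean=(-0.26, -0.79),
    init_log10_sd=(0.23, 0.22),
    eps_mean=(0.112, 0.044),
    eps_sd=(0.028, 0.010),
    seed=11,
)
CTR_PARAMS = KestenParams(
    eta_mean=(0.82, 0.88),
    init_log10_mean=(-0.33, -0.79),
    init_log10_sd=(0.27, 0.26),
    eps_mean=(0.100, 0.022),
    eps_sd=(0.032, 0.011),
    seed=12,
)


def _correlated_pair(rng: np.random.Generator, rho: float, size: int) -> np.ndarray:
    """(2, size) standard-normal draws with cross-row correlation rho."""
    z = rng.standard_normal((2, size))
    out = np.empty_like(z)
    out[0] = z[0]
    out[1] = rho * z[0] + np.sqrt(max(0.0, 1.0 - rho * rho)) * z[1]
    return out


def simulate_kesten_pair(
    params: KestenParams, condition: str = "EE", id_prefix: str | None = None
) -> list[Trajectory]:
    """Simulate coupled spine/PSD95 area trajectories.

    Initial areas are log-normal: ``log10 A(0) ~ N(init_log10_mean,
    init_log10_sd)`` with the two channels correlated at ``init_rho``.
    Each consecutive interval of ``time_points`` is one Kesten step
    ``A_next = eta * A + eps`` with fresh per-spine draws of ``eta``
    (Gaussian truncated at 0) and ``eps``; the standardized innovations of
    the two channels are correlated at ``coupling_rho``. Any step producing
    a non-positive area is resampled (jointly for the offending spine) so
    areas stay on a continuous positive distribution. Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_spines
    prefix = id_prefix if id_prefix is not None else condition

    m0 = _pair(params.init_log10_mean)
    s0 = _pair(params.init_log10_sd)
    z0 = _correlated_pair(rng, params.init_rho, n)
    areas = np.empty((2, n))
    for c in range(2):
        areas[c] = 10.0 ** (m0[c] + s0[c] * z0[c])

    em = np.array(_pair(params.eta_mean))[:, None]
    es = np.array(_pair(params.eta_sd))[:, None]
    am = np.array(_pair(params.eps_mean))[:, None]
    asd = np.array(_pair(params.eps_sd))[:, None]

    history = [areas.copy()]
    for _ in params.time_points[1:]:
        cur = history[-1]
        nxt = np.full((2, n), -1.0)
        pending = np.ones(n, dtype=bool)
        # joint redraw for spines whose eta or next area came out non-positive
        while pending.any():
            k = int(pending.sum())
            u_eta = _correlated_pair(rng, params.coupling_rho, k)
            u_eps = _correlated_pair(rng, params.coupling_rho, k)
            eta = em + es * u_eta
            eps = am + asd * u_eps
            cand = eta * cur[:, pending] + eps
            ok = (eta > 0).all(axis=0) & (cand > 0).all(axis=0)
            idx = np.flatnonzero(pending)[ok]
            nxt[:, idx] = cand[:, ok]
            pending[idx] = False
        history.append(nxt)

    stacked = np.stack(history)  # (n_times, 2, n_spines)
    out: list[Trajectory] = []
    width = len(str(n - 1)) if n > 1 else 1
    for i in range(n):
        samples = tuple(
            (int(t), float(stacked[j, 0, i]), float(stacked[j, 1, i]))
            for j, t in enumerate(params.time_points)
        )
        out.append(
            Trajectory(
                spine_id=f"{prefix}-{i:0{width}d}",
                condition=condition,
                samples=samples,
            )
        )
    return out


# ---------------------------------------------------------------------------
# nanopattern masks


class GeometryError(ValueError):
    """Requested mask geometry cannot be realized on the grid."""


def _disc(shape: tuple[int, int], center: tuple[float, float], r: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r * r


def generate_nanopattern_mask(
    kind: str,
    *,
    shape: tuple[int, int] = (64, 64),
    radius: float = 10.0,
    inner_radius: float = 4.0,
    n_clusters: int = 3,
    cluster_radius: float = 5.0,
    pixel_size_nm: float = 30.0,
    seed: int = 0,
) -> NanopatternMask:
    """Binary PSD95 assembly mask of a known topology class.

    ``macular``: one filled disc (no holes). ``perforated``: one annulus —
    a continuous shape whose interior hole encodes the ring-like
    sub-structure. ``clustered``: ``n_clusters`` (≥ 2) disjoint discs.
    Centers are jittered per seed; geometry that cannot fit (or would merge
    requested clusters) raises :class:`GeometryError`. Masks round-trip
    through :func:`synmorph.morphometry.classify_nanopattern`.
    """
    if pixel_size_nm <= 0:
        raise GeometryError("pixel_size_nm must be > 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = (h - 1) / 2, (w - 1) / 2

    if kind in ("macular", "perforated"):
        if radius >= min(h, w) / 2 - 1:
            raise GeometryError(f"radius {radius} does not fit in grid {shape}")
        jitter = rng.uniform(-1.5, 1.5, size=2)
        center = (cy + jitter[0], cx + jitter[1])
        grid = _disc(shape, center, radius)
        if kind == "perforated":
            if not 0 < inner_radius < radius - 1:
                raise GeometryError(
                    f"inner_radius {inner_radius} must be in (0, radius-1)"
                )
            grid &= ~_disc(shape, center, inner_radius)
    elif kind == "clustered":
        if n_clusters < 2:
            raise GeometryError("clustered masks need n_clusters >= 2")
        # clusters on a ring around the grid center, separated by construction
        ring_r = min(h, w) / 2 - cluster_radius - 2
        min_sep_r = (cluster_radius + 1.5) / np.sin(np.pi / n_clusters)
        if ring_r < min_sep_r:
            raise GeometryError(
                f"{n_clusters} clusters of radius {cluster_radius} would overlap "
                f"on grid {shape}"
            )
        grid = np.zeros(shape, dtype=bool)
        phase = rng.uniform(0, 2 * np.pi)
        for j in range(n_clusters):
            ang = phase + 2 * np.pi * j / n_clusters
            r_j = cluster_radius * rng.uniform(0.8, 1.0)
            c = (cy + ring_r * np.sin(ang), cx + ring_r * np.cos(ang))
            grid |= _disc(shape, c, r_j)
    else:
        raise ValidationError(f"unknown nanopattern kind {kind!r}")

    if not grid.any():
        raise GeometryError("generated mask is empty")
    return NanopatternMask(grid=grid, pixel_size_nm=pixel_size_nm)


# ---------------------------------------------------------------------------
# categorical change annotations


@dataclass(frozen=True)
class ChangeTransitionModel:
    """Per-interval probabilities of no/subtle/strong morphological change.

    ``probs`` maps an interval (minutes, referenced to t = 0) to a
    3-vector of probabilities over :data:`CHANGE_CATEGORIES`.
    """

    probs: dict[int, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for dt, p in self.probs.items():
            if len(p) != len(CHANGE_CATEGORIES):
                raise ValidationError(f"interval {dt}: need 3 probabilities")
            if any(x < 0 or x > 1 for x in p):
                raise ValidationError(f"interval {dt}: probabilities outside [0, 1]")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValidationError(
                    f"interval {dt}: probabilities sum to {sum(p)}, not 1"
                )


def simulate_change_annotations(
    model: ChangeTransitionModel,
    n: int,
    seed: int = 0,
    condition: str = "EE",
) -> pd.DataFrame:
    """Draw ``n`` categorical change annotations per interval of the model.

    Returns a tidy annotation table (psd_id, condition, interval_min,
    category, annotator_id) mirroring the annotation CSV schema.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for dt in sorted(model.probs):
        draws = rng.choice(len(CHANGE_CATEGORIES), size=n, p=model.probs[dt])
        for i, d in enumerate(draws):
            rows.append(
                {
                    "psd_id": f"{condition}-psd-{i}",
                    "condition": condition,
                    "interval_min": dt,
                    "category": CHANGE_CATEGORIES[d],
                    "annotator_id": "sim",
                }
            )
    return pd.DataFrame(rows)
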