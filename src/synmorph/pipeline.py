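"""Configuration-driven end-to-end analysis of a two-channel size study.

``run_pipeline`` takes a :class:`PipelineConfig` — either pointing at a real
size table (CSV + schema map) or at a synthetic-generation block — and runs
the full analysis bundle per condition: size-distribution statistics
(median/IQR, log moments, Gaussian log-histogram fit, KS and Welch
comparisons), per-interval change dynamics (PCA variance split, Pearson r,
downscaling regression ± SE, ANCOVA slope equality, cross-correlation with a
bootstrap SD), and nanopattern tables when annotations/masks are configured.

Every stage writes a tidy CSV under the output directory and contributes to a
single machine-readable ``report.json``. All randomness funnels through one
master seed; reruns are bit-identical. Intervals without qualifying pairs are
marked ``"insufficient data"`` rather than failing the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import distributions as dist
from . import dynamics as dyn
from .data_model import (
    Trajectory,
    ValidationError,
    link_trajectories,
    read_size_table,
    records_to_frame,
)
from .morphometry import classify_nanopattern, tabulate_morphometry
from .nanopattern import annotations_from_frame, tabulate_change_frequencies
from .synthetic import (
    CTR_PARAMS,
    EE_PARAMS,
    ChangeTransitionModel,
    KestenParams,
    generate_nanopattern_mask,
    simulate_change_annotations,
    simulate_kesten_pair,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, toggles and seeds of one end-to-end run.

    Exactly one of ``size_table`` (real data) or ``synthetic`` (generation
    block) must be set. ``synthetic`` maps condition name -> KestenParams
    field overrides; the calibrated EE/Ctr presets fill whatever is omitted.
    """

    output_dir: Path
    size_table: Path | None = None
    schema: Mapping[str, str] | None = None
    annotations: Path | None = None
    synthetic: Mapping[str, Mapping[str, Any]] | None = None
    synthetic_annotations: Mapping[str, Mapping[int, Sequence[float]]] | None = None
    synthetic_masks: Mapping[str, Mapping[str, int]] | None = None
    intervals: tuple[int, ...] = (30, 60, 120)
    n_boot: int = 200
    seed: int = 0
    log_bin_width: float = 0.1

    def __post_init__(self) -> None:
        if (self.size_table is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of size_table / synthetic must be configured"
            )
        if not self.intervals:
            raise ConfigError("intervals must be non-empty")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    kwargs: dict[str, Any] = {}
    kwargs["output_dir"] = Path(raw.get("output_dir", "synmorph_out"))
    for key in ("size_table", "annotations"):
        if raw.get(key):
            kwargs[key] = Path(raw[key])
    for key in ("schema", "synthetic", "synthetic_annotations", "synthetic_masks"):
        if raw.get(key):
            kwargs[key] = raw[key]
    if "intervals" in raw:
        kwargs["intervals"] = tuple(int(x) for x in raw["intervals"])
    for key in ("n_boot", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "log_bin_width" in raw:
        kwargs["log_bin_width"] = float(raw["log_bin_width"])
    return PipelineConfig(**kwargs)


_PRESETS = {"EE": EE_PARAMS, "Ctr": CTR_PARAMS}


def _tuplify(v: Any) -> Any:
    return tuple(v) if isinstance(v, list) else v


def _synthetic_trajectories(config: PipelineConfig) -> list[Trajectory]:
    trajs: list[Trajectory] = []
    for i, (condition, overrides) in enumerate(sorted(config.synthetic.items())):
        base = _PRESETS.get(condition, EE_PARAMS)
        fields = asdict(base)
        fields.update({k: _tuplify(v) for k, v in (overrides or {}).items()})
        fields["seed"] = int(config.seed * 1009 + i) % (2**31)
        params = KestenParams(**fields)
        trajs.extend(simulate_kesten_pair(params, condition=condition))
    return trajs


def _distribution_stage(trajs_by_cond, config, out_dir):
    """Fig-2-style block: per-condition summaries + EE/Ctr comparisons."""
    import pandas as pd

    block: dict[str, Any] = {}
    rows = []
    t0_areas: dict[str, dict[str, np.ndarray]] = {}
    for cond, trajs in trajs_by_cond.items():
        t0 = min(t for tr in trajs for t in tr.times)
        spine = np.array(
            [tr.area_at(t0, "spine") for tr in trajs if tr.area_at(t0, "spine")]
        )
        psd = np.array(
            [tr.area_at(t0, "psd") for tr in trajs if tr.area_at(t0, "psd")]
        )
        t0_areas[cond] = {"spine": spine, "psd": psd}
        cond_block: dict[str, Any] = {"n": int(spine.size)}
        for channel, areas in (("spine", spine), ("psd", psd)):
            summ = dist.summarize_areas(areas)
            ls = dist.log_stats(areas)
            ch: dict[str, Any] = {
                "median_um2": summ.median,
                "q1_um2": summ.q1,
                "q3_um2": summ.q3,
                "skewness": summ.skewness,
                "mean_log10": ls.mean_log10,
                "var_log10": ls.var_log10,
            }
            try:
                gf = dist.fit_gaussian_to_log_histogram(
                    areas, bin_width=config.log_bin_width
                )
                ch["gauss_mu"] = gf.mu
                ch["gauss_sigma"] = gf.sigma
            except dist.FitError as exc:
                ch["gauss_mu"] = ch["gauss_sigma"] = None
                logger.warning("%s/%s: %s", cond, channel, exc)
            cond_block[channel] = ch
            rows.append({"condition": cond, "channel": channel, **ch})
        r = float(np.corrcoef(spine, psd)[0, 1]) if spine.size > 2 else None
        cond_block["spine_psd_pearson_r"] = r
        block[cond] = cond_block

    conds = sorted(t0_areas)
    if len(conds) == 2:
        ca, cb = conds
        comp: dict[str, Any] = {}
        for channel in ("spine", "psd"):
            d, p_ks = dist.compare_distributions_ks(
                t0_areas[ca][channel], t0_areas[cb][channel]
            )
            t, df_w, p_w = dist.compare_log_means_welch(
                t0_areas[ca][channel], t0_areas[cb][channel]
            )
            comp[channel] = {
                "ks_D": d, "ks_p": p_ks,
                "welch_t": t, "welch_df": df_w, "welch_p": p_w,
            }
        block[f"{ca}_vs_{cb}"] = comp
    pd.DataFrame(rows).to_csv(out_dir / "distributions.csv", index=False)
    return block


def _dynamics_stage(trajs_by_cond, config, out_dir):
    """Fig-3/4-style block: per-interval changes, PCA, regression, CC."""
    import pandas as pd

    block: dict[str, Any] = {}
    change_rows, reg_rows, cc_rows = [], [], []
    pairs_by = {}  # (cond, dt, channel) -> pairs, for ANCOVA
    for cond, trajs in trajs_by_cond.items():
        cond_block: dict[str, Any] = {}
        for dt in config.intervals:
            cell: dict[str, Any] = {}
            changes = dyn.compute_changes(trajs, dt)
            if len(changes) < 3:
                cond_block[str(dt)] = "insufficient data"
                continue
            cell["n_pairs"] = len(changes)
            pca = dyn.pca_changes(changes)
            cell["pc1"] = list(pca.pc1)
            cell["var_pc1"] = pca.var_pc1
            cell["var_pc2"] = pca.var_pc2
            xs = np.array([c.d_norm_psd for c in changes])
            ys = np.array([c.d_norm_spine for c in changes])
            cell["pearson_r_norm_changes"] = float(np.corrcoef(xs, ys)[0, 1])
            for channel in ("spine", "psd"):
                grow, shrink = dyn.percent_change_medians(changes, channel)
                pairs = dyn.size_pairs(trajs, dt, channel)
                pairs_by[(cond, dt, channel)] = pairs
                reg = dyn.size_regression(pairs)
                cell[channel] = {
                    "median_pct_growth": grow,
                    "median_pct_shrinkage": shrink,
                    "slope": reg.slope,
                    "slope_se": reg.slope_se,
                    "intercept": reg.intercept,
                    "pearson_r": reg.r,
                }
                reg_rows.append(
                    {"condition": cond, "dt_min": dt, "channel": channel,
                     "slope": reg.slope, "slope_se": reg.slope_se,
                     "intercept": reg.intercept, "r": reg.r, "n": reg.n}
                )
            cond_block[str(dt)] = cell
            change_rows.extend(
                {**c.__dict__} for c in changes
            )

        # cross-correlation over signed lags, bootstrap SD at spine level
        cc_block = {}
        lags = sorted({0, *config.intervals, *(-dt for dt in config.intervals)})
        for k, lag in enumerate(lags):
            try:
                cc = dyn.cross_correlation(trajs, lag)
            except dyn.InsufficientDataError:
                cc_block[str(lag)] = "insufficient data"
                continue
            sd = dyn.bootstrap_sd(
                lambda ts, lag=lag: dyn.cross_correlation(ts, lag).cc,
                trajs,
                n_boot=config.n_boot,
                seed=(config.seed * 7919 + k) % (2**31),
            )
            cc_block[str(lag)] = {
                "cc": cc.cc,
                "cc_symmetrized": cc.cc_symmetrized,
                "bootstrap_sd": sd,
                "n_pairs": cc.n_pairs,
            }
            cc_rows.append(
                {"condition": cond, "dt_min": lag, "cc": cc.cc,
                 "cc_symmetrized": cc.cc_symmetrized, "bootstrap_sd": sd,
                 "n_pairs": cc.n_pairs}
            )
        cond_block["cross_correlation"] = cc_block
        block[cond] = cond_block

    # ANCOVA between the two conditions per interval × channel
    conds = sorted(trajs_by_cond)
    if len(conds) == 2:
        ca, cb = conds
        comp: dict[str, Any] = {}
        for dt in config.intervals:
            for channel in ("spine", "psd"):
                key_a, key_b = (ca, dt, channel), (cb, dt, channel)
                if key_a not in pairs_by or key_b not in pairs_by:
                    comp[f"{channel}_{dt}"] = "insufficient data"
                    continue
                anc = dyn.ancova_equal_slopes(pairs_by[key_a], pairs_by[key_b])
                comp[f"{channel}_{dt}"] = {
                    "slope_diff": anc.slope_diff, "t": anc.t,
                    "df": anc.df, "p": anc.p,
                }
        block[f"ancova_{ca}_vs_{cb}"] = comp

    if change_rows:
        pd.DataFrame(change_rows).to_csv(out_dir / "changes.csv", index=False)
    if reg_rows:
        pd.DataFrame(reg_rows).to_csv(out_dir / "regression.csv", index=False)
    if cc_rows:
        pd.DataFrame(cc_rows).to_csv(out_dir / "cross_correlation.csv", index=False)
    return block


def _nanopattern_stage(config, out_dir):
    import pandas as pd

    block: dict[str, Any] = {}
    ann_frames = []
    if config.annotations is not None:
        ann_frames.append(pd.read_csv(config.annotations))
    if config.synthetic_annotations:
        for j, (cond, probs) in enumerate(sorted(config.synthetic_annotations.items())):
            model = ChangeTransitionModel(
                probs={int(dt): tuple(p) for dt, p in probs.items()}
            )
            n = 200
            ann_frames.append(
                simulate_change_annotations(
                    model, n=n, seed=(config.seed * 4409 + j) % (2**31),
                    condition=cond,
                )
            )
    if ann_frames:
        df = pd.concat(ann_frames, ignore_index=True)
        table = tabulate_change_frequencies(annotations_from_frame(df))
        table.to_csv(out_dir / "nanopattern_changes.csv", index=False)
        block["change_frequencies"] = table.to_dict(orient="records")

    if config.synthetic_masks:
        rows = []
        for cond, mix in sorted(config.synthetic_masks.items()):
            classes = []
            i = 0
            for kind, count in sorted(mix.items()):
                for _ in range(int(count)):
                    mask = generate_nanopattern_mask(
                        kind, seed=(config.seed * 271 + i) % (2**31)
                    )
                    classes.append(classify_nanopattern(mask))
                    i += 1
            table = tabulate_morphometry(classes)
            table.insert(0, "condition", cond)
            rows.append(table)
        morph = pd.concat(rows, ignore_index=True)
        morph.to_csv(out_dir / "nanopattern_morphometry.csv", index=False)
        block["morphometry"] = morph.to_dict(orient="records")
    return block


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all configured stages; returns (and writes) the report dict."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.size_table is not None:
        records = read_size_table(config.size_table, schema=config.schema)
        trajs = link_trajectories(records)
    else:
        trajs = _synthetic_trajectories(config)
        records = None

    trajs_by_cond: dict[str, list[Trajectory]] = {}
    for tr in trajs:
        trajs_by_cond.setdefault(tr.condition, []).append(tr)
    if records is None:
        # persist the generated cohort for traceability
        from .data_model import SizeRecord, write_size_table

        gen = [
            SizeRecord(
                spine_id=tr.spine_id, mouse_id="sim", condition=tr.condition,
                fov_id="sim", time_min=s[0], spine_head_area=s[1], psd95_area=s[2],
            )
            for tr in trajs for s in tr.samples
        ]
        write_size_table(gen, out_dir / "size_table.csv")

    report: dict[str, Any] = {
        "seed": config.seed,
        "intervals_min": list(config.intervals),
        "n_trajectories": {c: len(v) for c, v in trajs_by_cond.items()},
    }
    report["distributions"] = _distribution_stage(trajs_by_cond, config, out_dir)
    report["dynamics"] = _dynamics_stage(trajs_by_cond, config, out_dir)
    nano = _nanopattern_stage(config, out_dir)
    if nano:
        report["nanopattern"] = nano

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
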