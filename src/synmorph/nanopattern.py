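"""Tabulation of categorical PSD95 nanopattern-change annotations.

Morphological change of each PSD95 assembly relative to its first observation
(t = 0) is scored on a 3-level ordinal scale — ``no change``, ``subtle
change``, ``strong change`` — by one or more annotators. This module merges
per-annotator labels into a consensus (majority vote; 3-way ties resolve to
the middle category, flagged), builds stacked relative-frequency tables per
condition × interval, and computes Fleiss' kappa as an agreement diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats import inter_rater

from .data_model import ValidationError

CATEGORIES = ("no change", "subtle change", "strong change")
STANDARD_INTERVALS = (30, 60, 120)


@dataclass(frozen=True)
class ChangeAnnotation:
    """One annotator's change call for one PSD at one interval (vs t = 0)."""

    psd_id: str
    condition: str
    interval_min: int
    category: str
    annotator_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"psd {self.psd_id!r}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.interval_min <= 0:
            raise ValidationError("interval_min must be > 0")
        if self.interval_min not in STANDARD_INTERVALS:
            warnings.warn(
                f"interval {self.interval_min} min outside the standard bins "
                f"{STANDARD_INTERVALS}; passed through unbinned",
                stacklevel=2,
            )


def annotations_from_frame(df: pd.DataFrame) -> list[ChangeAnnotation]:
    """Validate a tidy annotation table into :class:`ChangeAnnotation` rows."""
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ChangeAnnotation(
                    psd_id=str(row["psd_id"]),
                    condition=str(row["condition"]),
                    interval_min=int(row["interval_min"]),
                    category=str(row["category"]),
                    annotator_id=(
                        str(row["annotator_id"]) if "annotator_id" in row else None
                    ),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return out


def tabulate_change_frequencies(
    annotations: Iterable[ChangeAnnotation],
) -> pd.DataFrame:
    """Counts and relative frequencies per (condition, interval, category).

    Frequencies sum to 1 within every (condition, interval) cell holding at
    least one annotation — the stacked-histogram layout.
    """
    rows = [
        {
            "condition": a.condition,
            "interval_min": a.interval_min,
            "category": a.category,
        }
        for a in annotations
    ]
    if not rows:
        return pd.DataFrame(
            columns=["condition", "interval_min", "category", "count", "frequency"]
        )
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["condition", "interval_min", "category"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(["condition", "interval_min"])["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    return counts


def consensus_category(categories: Sequence[str]) -> tuple[str, bool]:
    """Majority vote over annotator labels; returns (category, tie_flag).

    A full 3-way tie resolves to the middle category ``subtle change`` with
    the tie flag set; a 2-way tie for the top count likewise resolves to the
    more moderate (lower-rank) of the tied categories, flagged.
    """
    if not categories:
        raise ValidationError("need at least one annotator")
    for c in categories:
        if c not in CATEGORIES:
            raise ValidationError(f"unknown category {c!r}")
    counts = {c: 0 for c in CATEGORIES}
    for c in categories:
        counts[c] += 1
    top = max(counts.values())
    winners = [c for c in CATEGORIES if counts[c] == top]
    if len(winners) == 1:
        return winners[0], False
    if len(winners) == 3:
        return "subtle change", True
    # 2-way tie: prefer the less extreme call, flagged
    return winners[0], True


def fleiss_kappa_diagnostic(df: pd.DataFrame) -> float:
    """Fleiss' kappa over a (psd_id × interval) × annotator label table.

    Diagnostic only; expects tidy columns psd_id, interval_min, category,
    annotator_id with a constant annotator count per item.
    """
    pivot = (
        df.assign(item=df["psd_id"].astype(str) + "@" + df["interval_min"].astype(str))
        .groupby(["item", "category"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    return float(inter_rater.fleiss_kappa(pivot.to_numpy()))
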