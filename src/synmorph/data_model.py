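"""Domain types and table I/O for longitudinal two-channel synapse size data.

A *size record* is one measurement of one dendritic spine at one time point:
the spine-head area and the area of the PSD95 assembly it bears (both in µm²),
plus identifiers (mouse, field of view) and the rearing condition (environmental
enrichment ``EE`` vs standard-cage control ``Ctr``). Records of the same spine
across time points link into a :class:`Trajectory`.

Tables are comma-separated UTF-8 with a header row. Column names are mapped to
the canonical schema through a ``schema`` dict so deposited tables with
arbitrary headers can be ingested without code changes. Spines lacking a PSD95
measurement are dropped at ingestion (the analysis considers only spines that
also bear a PSD), with the dropped count logged.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("EE", "Ctr")

#: canonical column order of a size table
CANONICAL_COLUMNS = (
    "spine_id",
    "mouse_id",
    "condition",
    "fov_id",
    "time_min",
    "spine_head_area",
    "psd95_area",
    "brightness",
)

REQUIRED_COLUMNS = CANONICAL_COLUMNS[:-1]  # brightness is optional


class SchemaError(ValueError):
    """A required column cannot be resolved in the input table."""


class ValidationError(ValueError):
    """A row violates a domain invariant (e.g. non-positive area)."""


class DuplicationError(ValueError):
    """The same spine was recorded twice at the same time point."""


@dataclass(frozen=True)
class SizeRecord:
    """One spine, one time point: areas of the head and its PSD95 assembly."""

    spine_id: str
    mouse_id: str
    condition: str
    fov_id: str
    time_min: int
    spine_head_area: float  # µm²
    psd95_area: float  # µm²
    brightness: float | None = None  # RawIntDen, arbitrary units

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.time_min < 0:
            raise ValidationError(f"time_min must be >= 0, got {self.time_min}")
        if not self.spine_head_area > 0:
            raise ValidationError(
                f"spine_head_area must be > 0, got {self.spine_head_area}"
            )
        if not self.psd95_area > 0:
            raise ValidationError(f"psd95_area must be > 0, got {self.psd95_area}")
        if self.brightness is not None and self.brightness < 0:
            raise ValidationError(f"brightness must be >= 0, got {self.brightness}")


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered observations of a single spine/PSD95 pair.

    ``samples`` is a tuple of ``(time_min, spine_head_area, psd95_area)``
    with strictly increasing times; length 1 is legal (spine seen once).
    """

    spine_id: str
    condition: str
    samples: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ValidationError("a trajectory needs at least one sample")
        times = [s[0] for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(f"times must be strictly increasing, got {times}")

    @property
    def times(self) -> tuple[int, ...]:
        return tuple(s[0] for s in self.samples)

    def area_at(self, time_min: int, channel: str) -> float | None:
        """Area at an exact time point, or None if not observed then."""
        idx = 1 if channel == "spine" else 2
        for s in self.samples:
            if s[0] == time_min:
                return s[idx]
        return None


@dataclass(frozen=True)
class DendriteRecord:
    """Spine positions (µm) along one parent dendrite, sorted ascending."""

    dendrite_id: str
    positions_um: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.positions_um):
            raise ValidationError("spine positions must be non-negative")
        if any(
            b < a for a, b in zip(self.positions_um, self.positions_um[1:])
        ):
            raise ValidationError("spine positions must be sorted ascending")

    @property
    def spine_count(self) -> int:
        return len(self.positions_um)


# ---------------------------------------------------------------------------
# table I/O


def _resolve_schema(columns: Sequence[str], schema: Mapping[str, str] | None):
    """Map canonical names to actual column names; raise on missing required."""
    schema = dict(schema or {})
    resolved: dict[str, str | None] = {}
    for canon in CANONICAL_COLUMNS:
        actual = schema.get(canon, canon)
        if actual in columns:
            resolved[canon] = actual
        elif canon in REQUIRED_COLUMNS:
            raise SchemaError(
                f"required column {canon!r} (mapped to {actual!r}) not found; "
                f"table has columns {list(columns)}"
            )
        else:
            resolved[canon] = None
    return resolved


def read_size_table(
    source: str | Path | io.IOBase,
    schema: Mapping[str, str] | None = None,
) -> list[SizeRecord]:
    """Read a CSV size table into validated :class:`SizeRecord` objects.

    Parameters
    ----------
    source
        Path or open text stream of a comma-separated table with a header.
    schema
        Optional mapping of canonical column names
        (``spine_id`` ... ``brightness``) to the table's actual headers.

    Rows with an empty ``psd95_area`` are dropped (spines without a PSD95
    label are excluded from the analysis); the dropped count is logged.
    Row order is preserved.
    """
    df = pd.read_csv(source)
    cols = _resolve_schema(df.columns, schema)

    psd_col = cols["psd95_area"]
    n_missing_psd = int(df[psd_col].isna().sum())
    if n_missing_psd:
        logger.info(
            "dropping %d row(s) without a PSD95 area (spines without PSD excluded)",
            n_missing_psd,
        )
        df = df[df[psd_col].notna()]

    records: list[SizeRecord] = []
    seen: set[tuple[str, int]] = set()
    for row_index, row in df.iterrows():
        try:
            brightness = None
            if cols["brightness"] is not None:
                raw = row[cols["brightness"]]
                brightness = None if pd.isna(raw) else float(raw)
            rec = SizeRecord(
                spine_id=str(row[cols["spine_id"]]),
                mouse_id=str(row[cols["mouse_id"]]),
                condition=str(row[cols["condition"]]),
                fov_id=str(row[cols["fov_id"]]),
                time_min=int(row[cols["time_min"]]),
                spine_head_area=float(row[cols["spine_head_area"]]),
                psd95_area=float(row[psd_col]),
                brightness=brightness,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {row_index}: {exc}") from exc
        key = (rec.spine_id, rec.time_min)
        if key in seen:
            raise DuplicationError(
                f"row {row_index}: duplicate (spine_id, time_min) = {key}"
            )
        seen.add(key)
        records.append(rec)
    return records


def write_size_table(
    records: Iterable[SizeRecord], sink: str | Path | io.IOBase
) -> int:
    """Write records as a canonical CSV size table; returns the row count."""
    records = list(records)
    df = pd.DataFrame(
        [
            {
                "spine_id": r.spine_id,
                "mouse_id": r.mouse_id,
                "condition": r.condition,
                "fov_id": r.fov_id,
                "time_min": r.time_min,
                "spine_head_area": repr(r.spine_head_area),
                "psd95_area": repr(r.psd95_area),
                "brightness": "" if r.brightness is None else repr(r.brightness),
            }
            for r in records
        ],
        columns=list(CANONICAL_COLUMNS),
    )
    df.to_csv(sink, index=False)
    return len(records)


def records_to_frame(records: Iterable[SizeRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame (one row per record, canonical columns)."""
    return pd.DataFrame(
        [
            {
                "spine_id": r.spine_id,
                "mouse_id": r.mouse_id,
                "condition": r.condition,
                "fov_id": r.fov_id,
                "time_min": r.time_min,
                "spine_head_area": r.spine_head_area,
                "psd95_area": r.psd95_area,
                "brightness": math.nan if r.brightness is None else r.brightness,
            }
            for r in records
        ],
        columns=list(CANONICAL_COLUMNS),
    )


def link_trajectories(records: Iterable[SizeRecord]) -> list[Trajectory]:
    """Group records by spine into time-sorted trajectories.

    Partitions the input: every record lands in exactly one trajectory, so
    the sum of trajectory lengths equals the record count. Spines observed
    once give length-1 trajectories. Duplicate (spine_id, time_min) raises.
    """
    by_spine: dict[str, list[SizeRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.spine_id not in by_spine:
            by_spine[rec.spine_id] = []
            order.append(rec.spine_id)
        by_spine[rec.spine_id].append(rec)

    out: list[Trajectory] = []
    for spine_id in order:
        group = sorted(by_spine[spine_id], key=lambda r: r.time_min)
        times = [r.time_min for r in group]
        if len(set(times)) != len(times):
            raise DuplicationError(
                f"spine {spine_id!r} has duplicate time points: {times}"
            )
        conditions = {r.condition for r in group}
        if len(conditions) > 1:
            raise ValidationError(
                f"spine {spine_id!r} appears under multiple conditions {conditions}"
            )
        out.append(
            Trajectory(
                spine_id=spine_id,
                condition=group[0].condition,
                samples=tuple(
                    (r.time_min, r.spine_head_area, r.psd95_area) for r in group
                ),
            )
        )
    return out
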