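"""Geometric and topological morphometry of spine/PSD95 measurements.

Areas come from manually drawn polygon ROIs (shoelace formula, sub-pixel
vertices allowed), brightness is the raw integrated density (sum of pixel
intensities inside a mask), spine density is spines-per-µm along the parent
dendrite, and PSD95 nanopatterns are classified from binary masks by strict
pixel topology:

* ``macular``    — one connected assembly, no holes;
* ``perforated`` — one connected assembly with ≥ 1 hole (ring, closed
  horseshoe, or more complex perforation);
* ``clustered``  — two or more disjoint assemblies (cluster count reported).

Foreground components use 8-connectivity and background (hole) components
4-connectivity, the standard dual pair, so a diagonally-touching ring still
encloses its hole.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

from .data_model import DendriteRecord, ValidationError

__all__ = [
    "PolygonROI",
    "NanopatternMask",
    "MorphClass",
    "GeometryError",
    "polygon_area",
    "roi_brightness",
    "spine_density",
    "classify_nanopattern",
    "tabulate_morphometry",
]

#: 8-connectivity structuring element for foreground labelling
_STRUCT8 = np.ones((3, 3), dtype=int)
#: 4-connectivity for background (hole) labelling
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


class GeometryError(ValueError):
    """Degenerate or invalid geometry (too few vertices, self-intersection...)."""


@dataclass(frozen=True)
class PolygonROI:
    """Simple polygon in pixel coordinates with a physical pixel size."""

    vertices: tuple[tuple[float, float], ...]  # (x, y) in px
    pixel_size_nm: float = 30.0

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError(
                f"a polygon needs >= 3 vertices, got {len(self.vertices)}"
            )
        if self.pixel_size_nm <= 0:
            raise GeometryError("pixel_size_nm must be > 0")
        if not Polygon(self.vertices).is_simple:
            raise GeometryError("polygon is self-intersecting")


@dataclass(frozen=True)
class NanopatternMask:
    """Binary pixel grid of one PSD95 assembly."""

    grid: np.ndarray  # 2-D bool
    pixel_size_nm: float = 30.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got {g.ndim}-D")
        object.__setattr__(self, "grid", g.astype(bool))
        if not self.grid.any():
            raise ValidationError("mask has no foreground pixels")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be > 0")

    @property
    def area_um2(self) -> float:
        """Foreground area in µm² (pixel count × pixel area)."""
        return float(self.grid.sum()) * (self.pixel_size_nm / 1000.0) ** 2


@dataclass(frozen=True)
class MorphClass:
    """Topology class of one assembly: category + component/hole counts."""

    category: str  # macular | perforated | clustered
    n_components: int
    n_holes: int
    concavity_rescued: bool = False

    def __post_init__(self) -> None:
        ok = (
            (self.category == "clustered" and self.n_components >= 2)
            or (
                self.category == "perforated"
                and self.n_components == 1
                and (self.n_holes >= 1 or self.concavity_rescued)
            )
            or (
                self.category == "macular"
                and self.n_components == 1
                and self.n_holes == 0
            )
        )
        if not ok:
            raise ValidationError(
                f"inconsistent MorphClass: {self.category}, "
                f"{self.n_components} component(s), {self.n_holes} hole(s)"
            )


def polygon_area(roi: PolygonROI) -> float:
    """ROI area in µm² by the shoelace formula (orientation-independent).

    Area in px² is ``|Σ x_i·y_{i+1} − x_{i+1}·y_i| / 2``, converted with the
    squared pixel size.
    """
    v = np.asarray(roi.vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    px2 = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    return px2 * (roi.pixel_size_nm / 1000.0) ** 2


def roi_brightness(image: np.ndarray, mask: NanopatternMask) -> float:
    """Raw integrated density: sum of image intensities under the mask."""
    img = np.asarray(image, dtype=float)
    if img.shape != mask.grid.shape:
        raise ValidationError(
            f"image shape {img.shape} != mask shape {mask.grid.shape}"
        )
    return float(img[mask.grid].sum())


def spine_density(dendrite: DendriteRecord) -> float:
    """Spines per µm: (n − 1) over the first-to-last spine span.

    Branched spines are expected to be counted once upstream, i.e. appear as
    a single position.
    """
    n = dendrite.spine_count
    if n < 2:
        raise ValidationError(f"density undefined for {n} spine(s); need >= 2")
    span = dendrite.positions_um[-1] - dendrite.positions_um[0]
    if span <= 0:
        raise GeometryError("zero span between first and last spine")
    return (n - 1) / span


def _count_holes(grid: np.ndarray) -> int:
    """Background components not connected (4-conn) to the grid border."""
    labels, n = ndimage.label(~grid, structure=_STRUCT4)
    if n == 0:
        return 0
    border = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border = set(int(b) for b in border if b != 0)
    return n - len(border)


def classify_nanopattern(
    mask: NanopatternMask, concavity_rescue: bool = False
) -> MorphClass:
    """Classify a binary assembly mask as macular / perforated / clustered.

    Components are 8-connected foreground; holes are 4-connected background
    components that do not touch the image border. With ``concavity_rescue``
    a single-component, hole-free mask of low solidity (< 0.75) — an open
    horseshoe — is promoted to perforated, mimicking the visual convention
    of grouping horseshoes with rings; off by default.
    """
    grid = mask.grid
    _, n_components = ndimage.label(grid, structure=_STRUCT8)
    n_holes = _count_holes(grid)

    if n_components >= 2:
        return MorphClass("clustered", n_components, n_holes)
    if n_holes >= 1:
        return MorphClass("perforated", n_components, n_holes)
    if concavity_rescue:
        from skimage.morphology import convex_hull_image

        solidity = grid.sum() / max(1, convex_hull_image(grid).sum())
        if solidity < 0.75:
            return MorphClass(
                "perforated", n_components, n_holes, concavity_rescued=True
            )
    return MorphClass("macular", n_components, n_holes)


def tabulate_morphometry(classes: Iterable[MorphClass]) -> pd.DataFrame:
    """Counts and relative frequencies per category (clustered split by k).

    Returns a tidy table with columns ``category`` (macular, perforated,
    clustered-2, clustered-3, ...), ``count`` and ``frequency``; frequencies
    sum to 1 over a non-empty input.
    """
    labels = []
    for c in classes:
        if c.category == "clustered":
            labels.append(f"clustered-{c.n_components}")
        else:
            labels.append(c.category)
    if not labels:
        return pd.DataFrame(columns=["category", "count", "frequency"])
    counts = pd.Series(labels).value_counts().sort_index()
    return pd.DataFrame(
        {
            "category": counts.index,
            "count": counts.values,
            "frequency": counts.values / counts.sum(),
        }
    ).reset_index(drop=True)
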