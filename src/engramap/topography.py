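"""Binning of neuron coordinates into matrices over an ROI contour.

The micro-topographic mapping workflow starts from the (x, y) positions of
activated (pERK-immunopositive) neurons recorded per animal inside a traced
region-of-interest contour (here the lateral amygdala, LA). The contour's
axis-aligned bounding box is tiled with a fixed rows x cols rectangular bin
grid so that every animal's point pattern becomes an integer count matrix at
the same resolution, making bins comparable across animals and groups.
Group-level summaries are the per-bin mean count (density map) and the per-bin
coefficient of variation, CV = sample SD / mean.

Conventions
-----------
* Bins are half-open rectangles ``[x0 + c*w, x0 + (c+1)*w) x [y0 + r*h,
  y0 + (r+1)*h)``; the far row/column is closed so every bounding-box point
  maps to exactly one bin.
* A bin belongs to the analysis family ("unmasked") iff its center lies inside
  the contour (boundary inclusive).
* Counts are raw (all bins share the same area); the ROI area is kept for
  reporting only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon


__all__ = [
    "RoiContour",
    "NeuronMap",
    "BinGrid",
    "CountMatrix",
    "DensityMap",
    "CvMap",
    "build_bin_grid",
    "assign_counts",
    "density_cv_maps",
    "group_density_map",
    "suggest_grid",
]


@dataclass(frozen=True)
class RoiContour:
    """A traced ROI outline: ordered polygon vertices in micrometres.

    The polygon must be simple (non self-intersecting) with positive area.
    The closing edge back to the first vertex is implicit.
    """

    vertices: np.ndarray  # (n, 2) float array, micrometres

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("ROI contour needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("ROI contour vertices must be finite")
        object.__setattr__(self, "vertices", v)
        poly = Polygon(v)
        if not poly.is_valid:
            raise ValueError("ROI contour must be a simple (non-self-intersecting) polygon")
        if poly.area <= 0.0:
            raise ValueError("ROI contour has zero area (degenerate polygon)")
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon  # type: ignore[attr-defined]

    @property
    def area(self) -> float:
        """Enclosed area in square micrometres."""
        return float(self.polygon.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the axis-aligned bounding box."""
        return self.polygon.bounds

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership test for an (n, 2) coordinate array."""
        xy = np.asarray(xy, dtype=float)
        if xy.size == 0:
            return np.zeros(0, dtype=bool)
        return shapely.intersects_xy(self.polygon, xy[:, 0], xy[:, 1])


@dataclass(frozen=True)
class NeuronMap:
    """One animal's activated-neuron coordinates within one ROI section.

    Duplicate coordinates are permitted and counted twice.
    """

    animal_id: str
    group: str
    coordinates: np.ndarray  # (n, 2) float, micrometres

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "coordinates", c)

    @property
    def n_neurons(self) -> int:
        return int(self.coordinates.shape[0])


@dataclass(frozen=True)
class BinGrid:
    """Rectangular bin tessellation of an ROI bounding box.

    ``mask[r, c]`` is True when bin (r, c) belongs to the analysis family,
    i.e. its center lies inside the ROI contour.
    """

    rows: int
    cols: int
    origin: tuple[float, float]  # bounding-box minimum corner (x, y)
    bin_width: float
    bin_height: float
    mask: np.ndarray  # (rows, cols) bool

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid needs rows >= 1 and cols >= 1")
        if self.bin_width <= 0 or self.bin_height <= 0:
            raise ValueError("bin width and height must be positive")
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != (self.rows, self.cols):
            raise ValueError("mask shape must be (rows, cols)")
        if not m.any():
            raise ValueError("empty family: no bin center falls inside the ROI")
        object.__setattr__(self, "mask", m)

    @property
    def n_bins(self) -> int:
        return self.rows * self.cols

    @property
    def n_family(self) -> int:
        """Number of bins inside the ROI family."""
        return int(self.mask.sum())

    def bin_centers(self) -> np.ndarray:
        """(rows, cols, 2) array of bin-center coordinates."""
        x0, y0 = self.origin
        cx = x0 + (np.arange(self.cols) + 0.5) * self.bin_width
        cy = y0 + (np.arange(self.rows) + 0.5) * self.bin_height
        out = np.empty((self.rows, self.cols, 2))
        out[..., 0] = cx[None, :]
        out[..., 1] = cy[:, None]
        return out

    def bin_of(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices under the half-open convention.

        Points exactly on the far edge of the bounding box fall into the last
        row/column (far-edge closure).
        """
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        x0, y0 = self.origin
        c = np.floor((xy[:, 0] - x0) / self.bin_width).astype(int)
        r = np.floor((xy[:, 1] - y0) / self.bin_height).astype(int)
        # far-edge closure: the bbox maximum belongs to the last bin
        c = np.clip(c, 0, self.cols - 1)
        r = np.clip(r, 0, self.rows - 1)
        return r, c


@dataclass(frozen=True)
class CountMatrix:
    """Per-animal integer neuron counts per bin.

    Every in-ROI coordinate increments exactly one bin, including bins whose
    center falls outside the contour (those are reported via
    ``n_in_masked_bins``); coordinates outside the ROI are excluded and
    counted in ``n_excluded``. Hence ``counts.sum()`` equals the number of
    in-ROI coordinates.
    """

    animal_id: str
    group: str
    counts: np.ndarray  # (rows, cols) int
    n_excluded: int = 0
    n_in_masked_bins: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DensityMap:
    """Per-bin mean neuron count across the animals of one group."""

    group: str
    values: np.ndarray  # (rows, cols) float
    n_animals: int


@dataclass(frozen=True)
class CvMap:
    """Per-bin coefficient of variation (sample SD / mean) for one group.

    ``defined[r, c]`` is False (and ``values`` NaN) where the bin mean is zero;
    a CV requires at least two animals.
    """

    group: str
    values: np.ndarray  # (rows, cols) float, NaN where undefined
    defined: np.ndarray  # (rows, cols) bool
    n_animals: int


def build_bin_grid(roi: RoiContour, rows: int = 7, cols: int = 9) -> BinGrid:
    """Tile the ROI bounding box with a rows x cols grid and mask it.

    The default 7 x 9 = 63-bin family matches the resolution used for LA
    sections; a bin is kept in the family iff its center lies inside the
    contour (boundary inclusive).

    Raises
    ------
    ValueError
        If the grid is degenerate or no bin center falls inside the ROI
        ("empty family", e.g. an absurdly fine grid over a thin polygon).
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    xmin, ymin, xmax, ymax = roi.bounds
    w = (xmax - xmin) / cols
    h = (ymax - ymin) / rows
    if w <= 0 or h <= 0:
        raise ValueError("degenerate ROI bounding box")
    cx = xmin + (np.arange(cols) + 0.5) * w
    cy = ymin + (np.arange(rows) + 0.5) * h
    gx, gy = np.meshgrid(cx, cy)
    inside = shapely.intersects_xy(roi.polygon, gx.ravel(), gy.ravel())
    mask = inside.reshape(rows, cols)
    if not mask.any():
        raise ValueError(
            "empty family: no bin center lies inside the ROI "
            f"(grid {rows}x{cols} too fine for this contour)"
        )
    return BinGrid(rows=rows, cols=cols, origin=(xmin, ymin), bin_width=w, bin_height=h, mask=mask)


def assign_counts(neuron_map: NeuronMap, grid: BinGrid, roi: RoiContour) -> CountMatrix:
    """Bin one animal's neuron coordinates into a count matrix.

    Coordinates outside the ROI contour are excluded (their number is
    recorded); every in-ROI coordinate increments exactly one bin.

    Raises
    ------
    ValueError
        If any coordinate is non-finite (the offending row index is named).
    """
    xy = neuron_map.coordinates
    bad = ~np.all(np.isfinite(xy), axis=1) if xy.size else np.zeros(0, bool)
    if bad.any():
        raise ValueError(
            f"non-finite coordinate for animal {neuron_map.animal_id!r} "
            f"at row(s) {np.flatnonzero(bad).tolist()}"
        )
    counts = np.zeros((grid.rows, grid.cols), dtype=int)
    n_excluded = 0
    n_in_masked = 0
    if xy.shape[0] > 0:
        in_roi = roi.contains_points(xy)
        n_excluded = int((~in_roi).sum())
        kept = xy[in_roi]
        if kept.shape[0] > 0:
            r, c = grid.bin_of(kept)
            np.add.at(counts, (r, c), 1)
            n_in_masked = int(counts[~grid.mask].sum())
    return CountMatrix(
        animal_id=neuron_map.animal_id,
        group=neuron_map.group,
        counts=counts,
        n_excluded=n_excluded,
        n_in_masked_bins=n_in_masked,
    )


def density_cv_maps(
    matrices: Sequence[CountMatrix], group: str
) -> tuple[DensityMap, CvMap]:
    """Group density map (per-bin mean) and CV map (sample SD / mean).

    The CV uses the n-1 (sample) standard deviation since groups are small
    samples; it is flagged undefined where the bin mean is zero. At least two
    animals are required (a single animal has no dispersion to report).

    Raises
    ------
    ValueError
        If the group has fewer than two matrices or matrices disagree in shape.
    """
    sel = [m for m in matrices if m.group == group]
    if len(sel) < 2:
        raise ValueError(
            f"CV map needs >= 2 animals in group {group!r}, got {len(sel)}"
        )
    shapes = {m.counts.shape for m in sel}
    if len(shapes) != 1:
        raise ValueError(f"mixed grids in group {group!r}: shapes {sorted(shapes)}")
    stack = np.stack([m.counts for m in sel]).astype(float)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    defined = mean > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(defined, sd / np.where(defined, mean, 1.0), np.nan)
    return (
        DensityMap(group=group, values=mean, n_animals=len(sel)),
        CvMap(group=group, values=cv, defined=defined, n_animals=len(sel)),
    )


def group_density_map(matrices: Sequence[CountMatrix], group: str) -> DensityMap:
    """Density map alone; unlike the CV map this is defined for one animal."""
    sel = [m for m in matrices if m.group == group]
    if not sel:
        raise ValueError(f"no matrices for group {group!r}")
    shapes = {m.counts.shape for m in sel}
    if len(shapes) != 1:
        raise ValueError(f"mixed grids in group {group!r}: shapes {sorted(shapes)}")
    stack = np.stack([m.counts for m in sel]).astype(float)
    return DensityMap(group=group, values=stack.mean(axis=0), n_animals=len(sel))


def suggest_grid(roi: RoiContour, expected_neurons: float, min_per_bin: float = 1.0) -> tuple[int, int]:
    """Suggest (rows, cols) targeting >= ``min_per_bin`` expected neurons per bin.

    The aspect ratio follows the ROI bounding box so bins stay near-square.
    """
    if expected_neurons <= 0 or min_per_bin <= 0:
        raise ValueError("expected_neurons and min_per_bin must be positive")
    xmin, ymin, xmax, ymax = roi.bounds
    aspect = (xmax - xmin) / (ymax - ymin)
    n_target = max(1.0, expected_neurons / min_per_bin)
    rows = max(1, int(round(np.sqrt(n_target / aspect))))
    cols = max(1, int(round(rows * aspect)))
    while rows * cols > n_target and rows * cols > 1:
        if rows >= cols and rows > 1:
            rows -= 1
        elif cols > 1:
            cols -= 1
        else:
            break
    return rows, cols
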