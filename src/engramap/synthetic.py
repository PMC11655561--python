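"""Synthetic neuron point patterns and freezing cohorts with known ground truth.

The generator emulates the data a reconsolidation histology/behavior study
produces after manual counting and behavioral scoring, so the full analysis
pipeline (binning, per-bin statistics, FDR hotspot detection, behavioral
ANOVA) can be exercised and calibrated at desk scale.

Point patterns follow an inhomogeneous Poisson process per animal:

* a spatially uniform baseline over the ROI contour (rejection sampling from
  the bounding box), expected count ``baseline_count`` per animal; plus
* one isotropic 2-D Gaussian component per hotspot, truncated to the ROI,
  contributing an expected ``hotspot_multiplier * amplitude`` points.

Group differences are encoded entirely by ``hotspot_multiplier`` (a strong
fear-memory group keeps multiplier 1, an effective reconsolidation-blocking
drug reduces it toward 0) and, optionally, by different baselines.

Freezing percentages are drawn per animal and phase from a Normal and clamped
to [0, 100] (freezing is a bounded percentage of observation time).

Reproducibility: one seed in the config; per-animal generators are derived by
the documented counter scheme ``default_rng([seed, stream, animal_index])``
with stream 0 for point patterns and stream 1 for freezing, so regenerating
any single animal is stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .behavior import PHASES, FreezingRecord
from .topography import NeuronMap, RoiContour

__all__ = [
    "Hotspot",
    "GroupSpatialSpec",
    "GroupFreezingSpec",
    "SimConfig",
    "simulate_neuron_maps",
    "simulate_freezing",
    "default_la_contour",
    "demo_config",
]

_MAX_PROPOSALS = 10**6  # hard cap for rejection sampling; fail loudly beyond


@dataclass(frozen=True)
class Hotspot:
    """A localized focus of extra activated neurons.

    ``radius`` is the isotropic Gaussian kernel scale (micrometres);
    ``amplitude`` is the expected number of extra neurons the hotspot
    contributes per animal before any group multiplier.
    """

    center: tuple[float, float]
    radius: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("hotspot radius must be > 0")
        if self.amplitude < 0:
            raise ValueError("hotspot amplitude must be >= 0")


@dataclass(frozen=True)
class GroupSpatialSpec:
    """Spatial intensity parameters for one experimental group."""

    label: str
    baseline_count: float
    hotspot_multiplier: float

    def __post_init__(self) -> None:
        if self.baseline_count < 0:
            raise ValueError("baseline_count must be >= 0")
        if self.hotspot_multiplier < 0:
            raise ValueError("hotspot_multiplier must be >= 0")


@dataclass(frozen=True)
class GroupFreezingSpec:
    """Per-phase freezing mean and SD (percent) for one group.

    ``phases`` maps each phase label in :data:`engramap.behavior.PHASES`
    (training-post, reactivation, test) to a (mean, sd) pair.
    """

    label: str
    phases: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for phase, (mean, sd) in self.phases.items():
            if not 0.0 <= mean <= 100.0:
                raise ValueError(f"{self.label}/{phase}: mean {mean} outside [0, 100]")
            if sd < 0:
                raise ValueError(f"{self.label}/{phase}: SD {sd} must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic cohort."""

    roi: RoiContour
    hotspots: Sequence[Hotspot]
    spatial_specs: Sequence[GroupSpatialSpec]
    freezing_specs: Sequence[GroupFreezingSpec]
    n_per_group: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        labels = [s.label for s in self.spatial_specs]
        if len(set(labels)) != len(labels):
            raise ValueError("spatial group labels must be unique")
        flabels = [s.label for s in self.freezing_specs]
        if len(set(flabels)) != len(flabels):
            raise ValueError("freezing group labels must be unique")

    @property
    def group_labels(self) -> list[str]:
        return [s.label for s in self.spatial_specs]


def _sample_uniform_in_roi(rng: np.random.Generator, roi: RoiContour, n: int) -> np.ndarray:
    """Rejection-sample n uniform points inside the contour from its bbox."""
    if n == 0:
        return np.zeros((0, 2))
    xmin, ymin, xmax, ymax = roi.bounds
    out: list[np.ndarray] = []
    got = 0
    proposed = 0
    while got < n:
        batch = max(64, 2 * (n - got))
        if proposed + batch > _MAX_PROPOSALS:
            raise RuntimeError(
                "rejection sampling exceeded the proposal cap; "
                "the ROI occupies too small a fraction of its bounding box"
            )
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, batch), rng.uniform(ymin, ymax, batch)]
        )
        proposed += batch
        acc = pts[roi.contains_points(pts)]
        out.append(acc)
        got += acc.shape[0]
    return np.concatenate(out)[:n]


def _sample_gaussian_in_roi(
    rng: np.random.Generator, roi: RoiContour, center: tuple[float, float], radius: float, n: int
) -> np.ndarray:
    """Truncated isotropic Gaussian: sample and reject points outside the ROI."""
    if n == 0:
        return np.zeros((0, 2))
    out: list[np.ndarray] = []
    got = 0
    proposed = 0
    while got < n:
        batch = max(64, 2 * (n - got))
        if proposed + batch > _MAX_PROPOSALS:
            raise RuntimeError(
                "rejection sampling exceeded the proposal cap; "
                "hotspot has negligible overlap with the ROI"
            )
        pts = rng.normal(loc=center, scale=radius, size=(batch, 2))
        proposed += batch
        acc = pts[roi.contains_points(pts)]
        out.append(acc)
        got += acc.shape[0]
    return np.concatenate(out)[:n]


def simulate_neuron_maps(config: SimConfig) -> list[NeuronMap]:
    """Draw one neuron point pattern per animal.

    Per animal the in-ROI count is Poisson with mean
    ``baseline_count + hotspot_multiplier * sum(amplitudes)`` (baseline and
    hotspot components drawn as independent Poissons). Identical config and
    seed give bit-identical output.

    A hotspot center outside the contour triggers a warning; its points are
    still truncated to the ROI.
    """
    for hs in config.hotspots:
        if not config.roi.contains_points(np.array([hs.center]))[0]:
            warnings.warn(
                f"hotspot center {hs.center} lies outside the ROI contour; "
                "its points will be truncated to the ROI",
                stacklevel=2,
            )
    maps: list[NeuronMap] = []
    stream = 0
    for spec in config.spatial_specs:
        for a in range(config.n_per_group):
            rng = np.random.default_rng([config.seed, 0, stream])
            stream += 1
            parts = []
            n_base = rng.poisson(spec.baseline_count)
            parts.append(_sample_uniform_in_roi(rng, config.roi, n_base))
            for hs in config.hotspots:
                n_hs = rng.poisson(spec.hotspot_multiplier * hs.amplitude)
                parts.append(
                    _sample_gaussian_in_roi(rng, config.roi, hs.center, hs.radius, n_hs)
                )
            coords = np.concatenate(parts) if parts else np.zeros((0, 2))
            maps.append(
                NeuronMap(
                    animal_id=f"{spec.label}-{a + 1:02d}",
                    group=spec.label,
                    coordinates=coords,
                )
            )
    return maps


def simulate_freezing(config: SimConfig) -> list[FreezingRecord]:
    """Draw freezing percentages, one record per animal x phase.

    Values are Normal(mean, SD) clamped to [0, 100]. Every group present in
    ``spatial_specs`` must have a freezing spec covering every phase.

    Raises
    ------
    ValueError
        Naming the group and phase if a spec is missing.
    """
    fspecs = {s.label: s for s in config.freezing_specs}
    for label in config.group_labels:
        if label not in fspecs:
            raise ValueError(f"missing freezing spec for group {label!r}")
        for phase in PHASES:
            if phase not in fspecs[label].phases:
                raise ValueError(
                    f"missing freezing spec for group {label!r}, phase {phase!r}"
                )
    records: list[FreezingRecord] = []
    stream = 0
    for label in config.group_labels:
        spec = fspecs[label]
        for a in range(config.n_per_group):
            rng = np.random.default_rng([config.seed, 1, stream])
            stream += 1
            animal = f"{label}-{a + 1:02d}"
            for phase in PHASES:
                mean, sd = spec.phases[phase]
                value = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
                records.append(
                    FreezingRecord(
                        animal_id=animal, group=label, phase=phase, percent_freezing=value
                    )
                )
    return records


def default_la_contour() -> RoiContour:
    """A lateral-amygdala-like contour, ~900 x 760 um, vertices in um.

    A rounded wedge approximating an LA section outline (dorsolateral part
    broad, tapering ventromedially); purely illustrative geometry.
    """
    verts = np.array(
        [
            (0.0, 380.0),
            (0.0, 520.0),
            (140.0, 680.0),
            (420.0, 760.0),
            (700.0, 700.0),
            (880.0, 540.0),
            (920.0, 320.0),
            (820.0, 120.0),
            (560.0, 0.0),
            (300.0, 40.0),
            (80.0, 200.0),
        ]
    )
    return RoiContour(verts)


def demo_config(seed: int = 0, n_per_group: int = 6) -> SimConfig:
    """Bundled six-arm demo cohort.

    Mirrors a reconsolidation pharmacology design: vehicle, three doses of a
    MEK inhibitor (mirdametinib), a positive control (SL327) and a negative
    control (trametinib), six animals per arm. Effective drugs shrink the
    hotspot contribution (multiplier < 1) and the test-day freezing mean;
    the negative control matches vehicle. Two hotspots sit in the
    dorsolateral and ventrolateral parts of the contour. All intensity and
    freezing numbers are qualitative defaults, not fits to any dataset.
    """
    roi = default_la_contour()
    hotspots = [
        Hotspot(center=(650.0, 550.0), radius=60.0, amplitude=40.0),
        Hotspot(center=(350.0, 200.0), radius=60.0, amplitude=25.0),
    ]
    arms = [
        # label, hotspot multiplier, test-day freezing mean
        ("vehicle", 1.00, 65.0),
        ("mird-5", 0.50, 45.0),
        ("mird-10", 0.35, 40.0),
        ("mird-25", 0.20, 35.0),
        ("sl327", 0.25, 38.0),
        ("trametinib", 1.00, 62.0),
    ]
    spatial = [
        GroupSpatialSpec(label=lab, baseline_count=180.0, hotspot_multiplier=mult)
        for lab, mult, _ in arms
    ]
    freezing = [
        GroupFreezingSpec(
            label=lab,
            phases={
                "training-post": (35.0, 8.0),
                "reactivation": (65.0, 10.0),
                "test": (test_mean, 10.0),
            },
        )
        for lab, _, test_mean in arms
    ]
    return SimConfig(
        roi=roi,
        hotspots=hotspots,
        spatial_specs=spatial,
        freezing_specs=freezing,
        n_per_group=n_per_group,
        seed=seed,
    )
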