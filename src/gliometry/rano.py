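"""RANO-style filtering and aggregation of per-lesion measurements.

The defaults apply NO filters: every segmented lesion contributes to the
burden, which is the recommended mode for automated segmentations. The 10 mm
measurability threshold (on both bidimensional diameters) and the
five-target-lesion cap can be switched on to emulate the guideline
requirements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry3d import VolumeMeasurement
from .planimetry import BidimensionalMeasurement


@dataclass
class RanoConfig:
    """Thresholds and switches for RANO-style burden aggregation.

    measurability_mm : both bidimensional diameters must reach this (mm).
    max_target_lesions : cap on target lesions entering the SPD.
    threshold_2d / threshold_volume : fractional increase over the nadir
        calling progression (0.25 / 0.40 per the guidelines).
    apply_measurability / apply_target_limit : opt-in filters, both off by
        default (all segmented lesions are considered).
    """

    measurability_mm: float = 10.0
    max_target_lesions: int = 5
    threshold_2d: float = 0.25
    threshold_volume: float = 0.40
    apply_measurability: bool = False
    apply_target_limit: bool = False

    def __post_init__(self) -> None:
        if self.measurability_mm <= 0 or self.threshold_2d <= 0 or self.threshold_volume <= 0:
            raise ValueError("thresholds must be > 0")
        if self.max_target_lesions < 1:
            raise ValueError("max_target_lesions must be >= 1")

    def threshold_for(self, metric: str) -> float:
        return self.threshold_volume if metric == "volume" else self.threshold_2d


@dataclass
class LesionRecord:
    """Per-lesion measurement bundle consumed by the aggregation rules."""

    lesion_id: int
    m2d: BidimensionalMeasurement | None = None
    m25d: BidimensionalMeasurement | None = None
    volume: VolumeMeasurement | None = None

    def value(self, metric: str) -> float:
        if metric == "spd2d":
            return self.m2d.product_mm2 if self.m2d else 0.0
        if metric == "spd25d":
            return self.m25d.product_mm2 if self.m25d else 0.0
        if metric == "volume":
            return self.volume.volume_mm3 if self.volume else 0.0
        raise KeyError(metric)


def is_measurable(m: BidimensionalMeasurement | None, cfg: RanoConfig) -> bool:
    """True iff BOTH bidimensional diameters reach the measurability threshold.

    The boundary is inclusive (a 10.0 x 10.0 mm lesion is measurable).
    """
    if m is None:
        return False
    return (
        m.longest.length_mm >= cfg.measurability_mm
        and m.perpendicular is not None
        and m.perpendicular.length_mm >= cfg.measurability_mm
    )


def select_targets(
    records: list[LesionRecord], cfg: RanoConfig, metric: str = "spd2d"
) -> list[LesionRecord]:
    """Apply the configured filters and return the target-lesion subset.

    With the measurability filter on, non-measurable lesions (judged on the
    2D diameters) are dropped; with the target limit on, the
    ``max_target_lesions`` largest lesions by the aggregation metric's
    per-lesion value are kept (ties by lesion_id). Default config returns the
    input unchanged.
    """
    out = list(records)
    if cfg.apply_measurability:
        out = [r for r in out if is_measurable(r.m2d, cfg)]
    if cfg.apply_target_limit and len(out) > cfg.max_target_lesions:
        out.sort(key=lambda r: (-r.value(metric), r.lesion_id))
        out = out[: cfg.max_target_lesions]
        out.sort(key=lambda r: r.lesion_id)
    return out


def aggregate_spd(records: list[LesionRecord], metric: str = "spd2d") -> float:
    """Sum of products of perpendicular diameters over the selected lesions."""
    if metric not in ("spd2d", "spd25d"):
        raise KeyError(f"SPD aggregation is defined for spd2d/spd25d, got {metric!r}")
    return float(sum(r.value(metric) for r in records))


def aggregate_volume(records: list[LesionRecord]) -> float:
    return float(sum(r.value("volume") for r in records))


def count_nonmeasurable(records: list[LesionRecord], cfg: RanoConfig) -> int:
    """Number of lesions failing the measurability rule."""
    return sum(1 for r in records if not is_measurable(r.m2d, cfg))


def nonmeasurable_burden_fraction(records: list[LesionRecord], cfg: RanoConfig) -> dict[str, float]:
    """Fraction of the total burden held by non-measurable lesions.

    Reported for the 2D SPD and the volume so a constant offset introduced by
    small spurious lesions can be quantified. NaN when the total burden is 0.
    """
    out = {}
    for metric in ("spd2d", "volume"):
        total = sum(r.value(metric) for r in records)
        nm = sum(r.value(metric) for r in records if not is_measurable(r.m2d, cfg))
        out[metric] = nm / total if total > 0 else float("nan")
    return out
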