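"""Measurement-to-assessment orchestration shared by the CLI and library users."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry3d import lesion_volume, measure_lesion_25d, sphericity
from .lesions import extract_lesions
from .longitudinal import pooled_trend_agreement, spearman_rho
from .mask import SegmentationMask, load_mask, resample_iso
from .planimetry import measure_lesion_2d
from .rano import (
    LesionRecord,
    RanoConfig,
    aggregate_spd,
    aggregate_volume,
    count_nonmeasurable,
    is_measurable,
    nonmeasurable_burden_fraction,
    select_targets,
)
from .series import METRICS, PatientSeries


def measure_mask(
    mask: SegmentationMask,
    cfg: RanoConfig | None = None,
    *,
    include_2d: bool = True,
    include_25d: bool = True,
    include_sphericity: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Measure every lesion of one time point and aggregate the burden.

    Returns a per-lesion table (one row per lesion: d1/d2/product for the 2D
    and 2.5D modes, volume, sphericity, measurability) and an aggregate dict
    with filtered and unfiltered SPD/volume plus lesion counts.
    """
    cfg = cfg or RanoConfig()
    lesions = extract_lesions(mask)
    records: list[LesionRecord] = []
    rows = []
    for les in lesions:
        m2d = measure_lesion_2d(les, mask) if include_2d else None
        m25d = measure_lesion_25d(les, mask) if include_25d else None
        vol = lesion_volume(les)
        if include_sphericity:
            vol.sphericity = sphericity(les, mask)
        rec = LesionRecord(lesion_id=les.lesion_id, m2d=m2d, m25d=m25d, volume=vol)
        records.append(rec)
        row = {
            "lesion_id": les.lesion_id,
            "voxel_count": les.voxel_count,
            "volume_mm3": vol.volume_mm3,
            "sphericity": vol.sphericity,
            "measurable": is_measurable(m2d, cfg),
        }
        if m2d is not None:
            row.update(
                {
                    "d1_2d_mm": m2d.d1,
                    "d2_2d_mm": m2d.d2,
                    "product_2d_mm2": m2d.product_mm2,
                    "slice_index": m2d.longest.slice_index,
                }
            )
        if m25d is not None:
            d = m25d.direction if m25d.direction is not None else (np.nan,) * 3
            row.update(
                {
                    "d1_25d_mm": m25d.d1,
                    "d2_25d_mm": m25d.d2,
                    "product_25d_mm2": m25d.product_mm2,
                    "d1_dir_x": d[0],
                    "d1_dir_y": d[1],
                    "d1_dir_z": d[2],
                }
            )
        rows.append(row)
    lesion_df = pd.DataFrame(rows)

    aggregates = {
        "volume": aggregate_volume(records),
        "lesion_count": len(records),
        "lesion_count_measurable": len(records) - count_nonmeasurable(records, cfg),
        "lesion_count_nonmeasurable": count_nonmeasurable(records, cfg),
    }
    if include_2d:
        aggregates["spd2d"] = aggregate_spd(records, "spd2d")
        sel2d = select_targets(records, cfg, metric="spd2d")
        aggregates["spd2d_filtered"] = aggregate_spd(sel2d, "spd2d")
    if include_25d:
        aggregates["spd25d"] = aggregate_spd(records, "spd25d")
    selv = select_targets(records, cfg, metric="volume")
    aggregates["volume_filtered"] = aggregate_volume(selv)
    if include_25d:
        sel25 = select_targets(records, cfg, metric="spd25d")
        aggregates["spd25d_filtered"] = aggregate_spd(sel25, "spd25d")
    aggregates.update(
        {f"nonmeasurable_fraction_{k}": v for k, v in nonmeasurable_burden_fraction(records, cfg).items()}
    )
    return lesion_df, aggregates


def prepare_mask(
    path: str,
    label_map: dict[int, str] | None = None,
    *,
    resample: bool = True,
    resample_mm: float = 1.0,
    axial_axis: int | None = None,
) -> SegmentationMask:
    """Load a NIfTI label map and apply the default 1 mm iso preprocessing."""
    mask = load_mask(path, label_map, axial_axis=axial_axis)
    if resample:
        mask = resample_iso(mask, resample_mm)
    return mask


def measure_series(
    series: PatientSeries,
    masks: list[SegmentationMask] | None = None,
    cfg: RanoConfig | None = None,
    *,
    label_map: dict[int, str] | None = None,
    resample: bool = True,
    resample_mm: float = 1.0,
    include_2d: bool = True,
    include_25d: bool = True,
    use_filtered: bool = False,
) -> pd.DataFrame:
    """Fill each time point's burden measurements; returns the tidy table.

    ``masks`` overrides loading from each record's ``mask_ref`` (useful for
    phantom series). With ``use_filtered`` the RANO-filtered aggregates are
    stored as the time point's measurements instead of the defaults.
    """
    cfg = cfg or RanoConfig()
    rows = []
    for i, tp in enumerate(series.timepoints):
        if masks is not None:
            mask = masks[i]
        else:
            if tp.mask_ref is None:
                raise ValueError(f"{series.patient_id}: time point {i} has no mask")
            mask = prepare_mask(
                tp.mask_ref, label_map, resample=resample, resample_mm=resample_mm
            )
        if mask.foreground_count() == 0:
            agg = {"volume": 0.0, "volume_filtered": 0.0, "lesion_count": 0,
                   "lesion_count_measurable": 0, "lesion_count_nonmeasurable": 0}
            if include_2d:
                agg.update(spd2d=0.0, spd2d_filtered=0.0)
            if include_25d:
                agg.update(spd25d=0.0, spd25d_filtered=0.0)
        else:
            _, agg = measure_mask(
                mask, cfg, include_2d=include_2d, include_25d=include_25d,
                include_sphericity=False,
            )
        suffix = "_filtered" if use_filtered else ""
        for m in METRICS:
            key = f"{m}{suffix}"
            if key in agg:
                tp.measurements[m] = float(agg[key])
        tp.lesion_count_measurable = agg["lesion_count_measurable"]
        tp.lesion_count_nonmeasurable = agg["lesion_count_nonmeasurable"]
        row = {"patient_id": series.patient_id, "days_from_surgery": tp.days_from_surgery}
        row.update(agg)
        rows.append(row)
    return pd.DataFrame(rows)


def agreement_matrices(
    values_by_method: dict[str, dict[str, list[float]]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise pooled trend agreement (%) and Spearman rho between methods.

    ``values_by_method[method][patient_id]`` is the aligned value sequence of
    that patient. All patients' transitions are pooled per method pair.
    """
    methods = sorted(values_by_method)
    agree = pd.DataFrame(index=methods, columns=methods, dtype=float)
    rho = pd.DataFrame(index=methods, columns=methods, dtype=float)
    for a, b in itertools.product(methods, methods):
        pa, pb = values_by_method[a], values_by_method[b]
        shared = sorted(set(pa) & set(pb))
        pairs = [(pa[p], pb[p]) for p in shared]
        agree.loc[a, b] = pooled_trend_agreement(pairs)
        xa = [v for p in shared for v in pa[p]]
        xb = [v for p in shared for v in pb[p]]
        rho.loc[a, b] = spearman_rho(xa, xb)
    return agree, rho
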