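"""Per-patient longitudinal series: time-point records, manifest loading."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

RATINGS = ("PD", "SD", "PR", "CR")

#: metric keys used throughout the package
METRICS = ("spd2d", "spd25d", "volume")


class ManifestError(ValueError):
    """Aggregated row-level validation errors for a series manifest."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("manifest validation failed:\n" + "\n".join(self.errors))


@dataclass
class TimePointRecord:
    """One follow-up: aggregate burden measurements plus expert annotations."""

    days_from_surgery: int
    mask_ref: str | None = None
    measurements: dict[str, float] = field(default_factory=dict)
    lesion_count_measurable: int | None = None
    lesion_count_nonmeasurable: int | None = None
    expert_spd: float | None = None
    expert_is_nadir: bool | None = None
    expert_rating: str | None = None

    def __post_init__(self) -> None:
        self.days_from_surgery = int(self.days_from_surgery)
        if self.days_from_surgery < 0:
            raise ValueError("days_from_surgery must be >= 0")
        for k, v in self.measurements.items():
            if v < 0:
                raise ValueError(f"measurement {k!r} negative: {v}")
        if self.expert_spd is not None and self.expert_spd < 0:
            raise ValueError("expert_spd must be non-negative")
        if self.expert_rating is not None and self.expert_rating not in RATINGS:
            raise ValueError(f"expert_rating must be one of {RATINGS}")


@dataclass
class PatientSeries:
    """Ordered time points of one patient plus overall survival.

    The unit of time-to-progression computation. ``os_days`` counts from the
    first resection, the same clock as ``days_from_surgery``.
    """

    patient_id: str
    timepoints: list[TimePointRecord]
    os_days: int

    def __post_init__(self) -> None:
        self.os_days = int(self.os_days)
        if self.os_days <= 0:
            raise ValueError("os_days must be > 0")
        days = [tp.days_from_surgery for tp in self.timepoints]
        if sorted(days) != days:
            self.timepoints = sorted(self.timepoints, key=lambda t: t.days_from_surgery)
            days = sorted(days)
        if len(set(days)) != len(days):
            raise ValueError(f"{self.patient_id}: duplicate days_from_surgery {days}")
        if days and self.os_days < days[-1]:
            raise ValueError(
                f"{self.patient_id}: os_days {self.os_days} precedes last time point {days[-1]}"
            )

    @property
    def days(self) -> list[int]:
        return [tp.days_from_surgery for tp in self.timepoints]

    def metric_values(self, metric: str) -> list[float]:
        out = []
        for tp in self.timepoints:
            if metric not in tp.measurements:
                raise KeyError(
                    f"{self.patient_id} day {tp.days_from_surgery}: metric {metric!r} missing"
                )
            out.append(float(tp.measurements[metric]))
        return out

    def has_expert_nadir_flags(self) -> bool:
        return any(tp.expert_is_nadir for tp in self.timepoints)


MANIFEST_REQUIRED = ("patient_id", "days_from_surgery", "mask_file", "os_days")
MANIFEST_OPTIONAL = ("expert_spd", "expert_is_nadir", "expert_rating")


def _opt(row, col, cast):
    if col not in row or pd.isna(row[col]):
        return None
    return cast(row[col])


def load_series(manifest: str | os.PathLike | pd.DataFrame, mask_dir: str | None = None) -> list[PatientSeries]:
    """Assemble per-patient series from a CSV manifest.

    Required columns: ``patient_id, days_from_surgery, mask_file, os_days``;
    optional: ``expert_spd, expert_is_nadir, expert_rating``. Rows may appear
    in any order; validation problems are aggregated into one
    :class:`ManifestError` listing every offending row.
    """
    if isinstance(manifest, pd.DataFrame):
        df = manifest.copy()
    else:
        df = pd.read_csv(manifest)
    errors: list[str] = []
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ManifestError([f"missing required columns: {missing}"])

    dup = df.duplicated(subset=["patient_id", "days_from_surgery"], keep=False)
    for i in df.index[dup]:
        errors.append(
            f"row {i}: duplicate (patient, day) = "
            f"({df.at[i, 'patient_id']}, {df.at[i, 'days_from_surgery']})"
        )

    series: list[PatientSeries] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        os_vals = set(int(v) for v in grp["os_days"])
        if len(os_vals) > 1:
            errors.append(f"patient {pid}: inconsistent os_days {sorted(os_vals)}")
            continue
        tps = []
        ok = True
        for i, row in grp.iterrows():
            mask_ref = str(row["mask_file"])
            if mask_dir is not None:
                full = os.path.join(mask_dir, mask_ref)
                if not os.path.exists(full):
                    errors.append(f"row {i}: mask file not found: {full}")
                    ok = False
                    continue
                mask_ref = full
            try:
                tps.append(
                    TimePointRecord(
                        days_from_surgery=int(row["days_from_surgery"]),
                        mask_ref=mask_ref,
                        expert_spd=_opt(row, "expert_spd", float),
                        expert_is_nadir=_opt(row, "expert_is_nadir", lambda v: bool(int(v))),
                        expert_rating=_opt(row, "expert_rating", str),
                    )
                )
            except ValueError as e:
                errors.append(f"row {i}: {e}")
                ok = False
        if not ok or grp.index[dup.reindex(grp.index, fill_value=False)].size:
            continue
        try:
            series.append(PatientSeries(patient_id=str(pid), timepoints=tps, os_days=os_vals.pop()))
        except ValueError as e:
            errors.append(f"patient {pid}: {e}")
    if errors:
        raise ManifestError(errors)
    return series
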