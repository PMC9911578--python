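"""CSV table dialect and JSON run configuration.

The time-activity table is a plain UTF-8 CSV with '.' decimal separator and
the columns ``patient_id, voi_id, voi_type, time_h, activity_MBq, volume_ml,
mean_HU`` — one row per (VOI, time point).  Reading applies the 5-ml mean
volume filter to isocontour-segmented lesions and logs every exclusion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields

import pandas as pd

from .data import LESION_VOLUME_THRESHOLD_ML, TimeActivitySample, VoiSeries
from .exceptions import ConfigError, TacTableError

log = logging.getLogger("tacdose")

TAC_TABLE_COLUMNS = ("patient_id", "voi_id", "voi_type", "time_h",
                     "activity_MBq", "volume_ml", "mean_HU")
_NUMERIC = ("time_h", "activity_MBq", "volume_ml", "mean_HU")


def read_tac_table(path, lesion_volume_threshold_ml: float = LESION_VOLUME_THRESHOLD_ML
                   ) -> list[VoiSeries]:
    """Read a time-activity CSV table into per-VOI series.

    Rows are grouped by (patient_id, voi_id) and time-sorted.  Lesions whose
    mean volume is below the threshold are excluded with a logged warning.
    Malformed numeric fields and duplicate (VOI, time) rows raise
    :class:`TacTableError` naming the offending row (1-based, header = row 1).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TAC_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TacTableError(f"{path}: missing column(s) {missing}")
    for col in _NUMERIC:
        parsed = []
        for idx, raw in df[col].items():
            try:
                parsed.append(float(raw))  # correctly-rounded parse: CSV round-trips
            except (TypeError, ValueError):
                raise TacTableError(
                    f"{path}: row {idx + 2}: malformed {col} value {raw!r}"
                ) from None
        df[col] = parsed
    dup = df.duplicated(subset=["patient_id", "voi_id", "time_h"], keep=False)
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise TacTableError(f"{path}: row {row}: duplicate (voi, time) entry")

    series_list: list[VoiSeries] = []
    for (patient, voi), group in df.groupby(["patient_id", "voi_id"], sort=True):
        group = group.sort_values("time_h")
        voi_type = str(group["voi_type"].iloc[0])
        samples = [TimeActivitySample(r.time_h, r.activity_MBq, r.volume_ml, r.mean_HU)
                   for r in group.itertuples()]
        series = VoiSeries(str(patient), str(voi), voi_type, samples)
        if voi_type == "lesion" and series.mean_volume_ml < lesion_volume_threshold_ml:
            log.warning("excluding lesion %s: mean volume %.2f ml < %.1f ml",
                        voi, series.mean_volume_ml, lesion_volume_threshold_ml)
            continue
        series_list.append(series)
    return series_list


def write_tac_table(series_list: list[VoiSeries], path) -> None:
    """Write series to the CSV dialect (stable after one read/write cycle)."""
    rows = [
        {"patient_id": s.patient_id, "voi_id": s.voi_id, "voi_type": s.voi_type,
         "time_h": smp.time_h, "activity_MBq": smp.activity_MBq,
         "volume_ml": smp.volume_ml, "mean_HU": smp.mean_HU}
        for s in series_list for smp in s.samples
    ]
    df = pd.DataFrame(rows, columns=list(TAC_TABLE_COLUMNS))
    df = df.sort_values(["patient_id", "voi_id", "time_h"], kind="stable")
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """JSON-serialisable pipeline configuration (unknown keys rejected)."""

    lesion_model: str = "mono"
    kidney_model: str = "bi1_sgamma"
    kidney_shared_gamma: float = 0.963
    schedules: list[str] = field(default_factory=lambda: ["1,2,3", "1,2,7", "1,3,7",
                                                          "2,3,7", "1,2", "1,3", "1,7"])
    seed: int = 0
    calibration_slope: float = 7.94e-5
    calibration_intercept: float = 9.64e-1
    lesion_volume_threshold_ml: float = LESION_VOLUME_THRESHOLD_ML
    schedule_match_tolerance_h: float = 6.0
    tissue_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
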