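"""In-memory containers for serial SPECT/CT VOI measurements."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import TacTableError

#: Lesions segmented by isocontour below this mean volume are unreliable
#: (partial-volume driven volume overestimation) and are excluded upstream.
LESION_VOLUME_THRESHOLD_ML: float = 5.0


@dataclass(frozen=True)
class TimeActivitySample:
    """One measurement of one VOI at one time point post-injection."""

    time_h: float
    activity_MBq: float
    volume_ml: float
    mean_HU: float

    def __post_init__(self):
        if not self.time_h > 0:
            raise TacTableError(f"time_h must be > 0, got {self.time_h}")
        if self.activity_MBq < 0:
            raise TacTableError(f"activity_MBq must be >= 0, got {self.activity_MBq}")
        if not self.volume_ml > 0:
            raise TacTableError(f"volume_ml must be > 0, got {self.volume_ml}")

    @property
    def concentration_kBq_ml(self) -> float:
        """Activity concentration in kBq/ml."""
        return 1000.0 * self.activity_MBq / self.volume_ml


@dataclass
class VoiSeries:
    """All samples of one lesion or kidney of one patient, time-sorted."""

    patient_id: str
    voi_id: str
    voi_type: str  # "lesion" | "kidney"
    samples: list[TimeActivitySample] = field(default_factory=list)

    def __post_init__(self):
        if self.voi_type not in ("lesion", "kidney"):
            raise TacTableError(f"voi_type must be lesion|kidney, got {self.voi_type}")
        if len(self.samples) < 2:
            raise TacTableError(
                f"VOI {self.voi_id}: at least 2 samples required, got {len(self.samples)}"
            )
        times = [s.time_h for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise TacTableError(f"VOI {self.voi_id}: times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_h for s in self.samples])

    @property
    def activities(self) -> np.ndarray:
        return np.array([s.activity_MBq for s in self.samples])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([s.volume_ml for s in self.samples])

    @property
    def mean_hus(self) -> np.ndarray:
        return np.array([s.mean_HU for s in self.samples])

    @property
    def mean_volume_ml(self) -> float:
        return float(np.mean(self.volumes))

    def subset(self, indices) -> "VoiSeries":
        """Sub-series at the given sample indices (order preserved)."""
        return VoiSeries(
            patient_id=self.patient_id,
            voi_id=self.voi_id,
            voi_type=self.voi_type,
            samples=[self.samples[i] for i in indices],
        )
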