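"""ROI statistics, repeated-measurement averaging and tumor volume.

The study protocol draws one ROI per subject on the maximum-diameter slice
of the ADC map and reuses it on every parameter map; two observers each
measure twice (sessions four weeks apart), per-observer means are averaged
into the final value.  Tumor volume integrates per-slice contour areas over
the slice spacing (thickness + gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import ParameterMap

__all__ = ["RoiMask", "MeasurementSet", "roi_mean", "average_measurements", "tumor_volume"]


@dataclass
class RoiMask:
    """Single-slice 2-D ROI with provenance (e.g. 'max-diameter slice on ADC map')."""

    slice_index: int
    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


@dataclass
class MeasurementSet:
    """One parameter's repeated measurements for one subject.

    ``values[(observer, session)]`` holds a scalar; the expected design is
    2 observers × 2 sessions but missing cells are tolerated (flagged by
    :meth:`missing_cells`).
    """

    values: dict[tuple[str, str], float] = field(default_factory=dict)

    def observers(self) -> list[str]:
        return sorted({obs for obs, _ in self.values})

    def missing_cells(self, n_observers: int = 2, n_sessions: int = 2) -> bool:
        return len(self.values) < n_observers * n_sessions


def roi_mean(pmap: ParameterMap, roi: RoiMask) -> tuple[float, int]:
    """Mean of the fitted voxels inside the ROI; returns (mean, n_voxels).

    Only voxels with successful fits contribute; NaN padding and voxel
    ordering are irrelevant.  Raises when no fitted voxel lies in the ROI.
    """
    if pmap.values.ndim != 3:
        raise ValueError("parameter map must be 3-D")
    if roi.mask.shape != pmap.values.shape[:2]:
        raise ValueError("ROI grid does not match the map grid")
    if not 0 <= roi.slice_index < pmap.values.shape[2]:
        raise ValueError("ROI slice outside the map")
    sl = pmap.values[:, :, roi.slice_index]
    ok = pmap.fit_mask[:, :, roi.slice_index] & roi.mask & np.isfinite(sl)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no successfully fitted voxels inside the ROI")
    return float(sl[ok].mean()), n


def average_measurements(ms: MeasurementSet) -> float:
    """Final value: mean over sessions within each observer, then over observers.

    Equals the grand mean for a balanced design; for unbalanced designs the
    per-observer-first rule weights observers equally regardless of how many
    sessions each completed.
    """
    if not ms.values:
        raise ValueError("no measurements")
    per_observer = []
    for obs in ms.observers():
        vals = [v for (o, _), v in ms.values.items() if o == obs]
        per_observer.append(float(np.mean(vals)))
    return float(np.mean(per_observer))


def tumor_volume(areas_mm2, thickness_mm: float = 2.0, gap_mm: float = 0.2) -> float:
    """Tumor volume in cm³ from per-slice contour areas (mm²).

    Each slice contributes area × slice spacing, with spacing = thickness +
    intersection gap (2.0 + 0.2 mm for the study geometry).
    """
    areas = np.asarray(list(areas_mm2), dtype=float)
    if areas.size == 0:
        return 0.0
    if np.any(areas < 0):
        raise ValueError("slice areas must be non-negative")
    if thickness_mm <= 0 or gap_mm < 0:
        raise ValueError("invalid slice geometry")
    volume_mm3 = float(areas.sum() * (thickness_mm + gap_mm))
    return volume_mm3 / 1000.0
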