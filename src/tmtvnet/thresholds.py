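"""Within-ROI segmentation operators and the TMTV probability map.

Four segmentation rules in routine use for lymphoma TMTV are applied
inside each manual region of interest:

* relative 41% SUVmax (voxels >= 0.41 * the ROI's SUVmax),
* absolute cutoffs SUV > 2.5 and SUV > 4.0,
* the Otsu histogram threshold (between-class variance maximization).

Averaging the four binary masks voxel-by-voxel yields the TMTV
probability map (TMTVprob) — values on the exact grid
{0, 0.25, 0.5, 0.75, 1} — which serves as the continuous training target
for the segmentation network: it encodes where the methodologies agree
(lesion cores) and disagree (lesion edges) instead of committing to any
single threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import VolumeGrid, RoiSet

__all__ = [
    "ThresholdMethod",
    "PERCENT41",
    "CUTOFF25",
    "CUTOFF40",
    "OTSU",
    "GROUND_TRUTH_METHODS",
    "cutoff_segment",
    "percent41_segment",
    "otsu_segment",
    "build_tmtv_prob",
    "ground_truth_for_case",
    "segment_roi",
]


@dataclass(frozen=True)
class ThresholdMethod:
    """One TMTV segmentation methodology.

    kind: "percent_max" (relative threshold, ``value`` = fraction of
    SUVmax), "cutoff" (absolute SUV, strict >) or "otsu".
    """

    kind: str
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("percent_max", "cutoff", "otsu"):
            raise ValueError(f"unknown methodology kind {self.kind!r}")
        if self.kind == "cutoff" and (self.value is None or self.value <= 0):
            raise ValueError("cutoff value must be positive")
        if self.kind == "percent_max" and self.value != 0.41:
            raise ValueError("the relative methodology uses the fixed 41% fraction")

    @property
    def name(self) -> str:
        if self.kind == "percent_max":
            return "41pc"
        if self.kind == "cutoff":
            return f"suv{self.value:g}"
        return "otsu"


PERCENT41 = ThresholdMethod("percent_max", 0.41)
CUTOFF25 = ThresholdMethod("cutoff", 2.5)
CUTOFF40 = ThresholdMethod("cutoff", 4.0)
OTSU = ThresholdMethod("otsu")

#: the four operators averaged into TMTVprob, in conventional order
GROUND_TRUTH_METHODS = (PERCENT41, CUTOFF25, CUTOFF40, OTSU)


def _check_roi(pet: VolumeGrid, roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != pet.shape:
        raise ValueError(f"ROI shape {roi.shape} != PET shape {pet.shape}")
    if not roi.any():
        raise ValueError("ROI is empty")
    return roi


def cutoff_segment(pet: VolumeGrid, roi: np.ndarray, c: float) -> np.ndarray:
    """Voxels of the ROI with SUV strictly greater than the cutoff ``c``."""
    roi = _check_roi(pet, roi)
    return roi & (np.asarray(pet.values) > c)


def percent41_segment(pet: VolumeGrid, roi: np.ndarray, fraction: float = 0.41) -> np.ndarray:
    """Voxels with SUV >= fraction * SUVmax of the ROI.

    The inclusive comparison guarantees the SUVmax voxel itself is always
    kept; the rule is invariant under positive rescaling of the PET.
    """
    roi = _check_roi(pet, roi)
    values = np.asarray(pet.values)
    suvmax = float(values[roi].max())
    if suvmax <= 0:
        raise ValueError("ROI has SUVmax 0 (all-zero uptake): relative threshold undefined")
    return roi & (values >= fraction * suvmax)


def _otsu_threshold(inside: np.ndarray, n_bins: int) -> float:
    """Between-class-variance-maximizing bin-center threshold.

    With equal-width bins the between-class variance at split s is
    ``width^2 * (I0*w1 - I1*w0)^2 / (w0*w1)`` where w are class counts
    and I class sums of bin *indices* — both integers.  The maximum is
    therefore located with exact integer arithmetic (Python ints), which
    makes the tie-break (first maximal split) deterministic even when
    empty gap bins produce runs of exactly tied splits.
    """
    hist, edges = np.histogram(
        inside, bins=n_bins, range=(float(inside.min()), float(inside.max()))
    )
    centers = (edges[:-1] + edges[1:]) / 2
    total = int(hist.sum())
    i_total = int((np.arange(n_bins) * hist).sum())
    best: tuple[int, int] | None = None  # (numerator, denominator)
    best_s = 0
    w0 = 0
    i0 = 0
    for s in range(n_bins - 1):
        w0 += int(hist[s])
        i0 += s * int(hist[s])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (i0 * w1 - (i_total - i0) * w0) ** 2
        den = w0 * w1
        if best is None or num * best[1] > best[0] * den:
            best, best_s = (num, den), s
    assert best is not None  # guarded by the >= 2 distinct values precondition
    return float(centers[best_s])


def otsu_segment(pet: VolumeGrid, roi: np.ndarray, n_bins: int = 256,
                 roi_id: int | None = None) -> np.ndarray:
    """Otsu threshold of the within-ROI SUV histogram; keeps voxels
    strictly above the threshold.

    The histogram uses ``n_bins`` equal-width bins over the ROI's
    [min, max] range; the threshold maximizes between-class variance.
    """
    roi = _check_roi(pet, roi)
    inside = np.asarray(pet.values)[roi]
    if np.ptp(inside) == 0:
        tag = f" {roi_id}" if roi_id is not None else ""
        raise ValueError(f"ROI{tag} is single-valued (SUV {inside[0]:g}): Otsu undefined")
    t = _otsu_threshold(inside, n_bins)
    return roi & (np.asarray(pet.values) > t)


def segment_roi(pet: VolumeGrid, roi: np.ndarray, method: ThresholdMethod,
                roi_id: int | None = None) -> np.ndarray:
    """Apply one methodology within one ROI."""
    if method.kind == "cutoff":
        return cutoff_segment(pet, roi, method.value)
    if method.kind == "percent_max":
        return percent41_segment(pet, roi, method.value)
    return otsu_segment(pet, roi, roi_id=roi_id)


def build_tmtv_prob(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxel-by-voxel average of binary masks -> probability map.

    For the standard four masks the attained values are exact multiples
    of 0.25 (means of k booleans are exact in binary floating point for
    k = 4).
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    shapes = {np.asarray(m).shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks disagree on shape: {sorted(shapes)}")
    acc = np.zeros(shapes.pop(), dtype=np.float32)
    for m in masks:
        acc += np.asarray(m, dtype=bool)
    return acc / np.float32(len(masks))


def ground_truth_for_case(
    pet: VolumeGrid,
    roi_set: RoiSet,
    methods: Sequence[ThresholdMethod] = GROUND_TRUTH_METHODS,
) -> np.ndarray:
    """TMTVprob for a whole case: per-ROI masks are unioned across ROIs
    for each methodology, then the per-method masks are averaged.

    Unioning before averaging keeps every probability <= 1 even when
    manual ROIs overlap.  Voxels outside every ROI get probability 0.
    An operator failure inside one ROI is re-raised tagged with its id.
    """
    if tuple(roi_set.shape) != tuple(pet.shape):
        raise ValueError(f"RoiSet shape {roi_set.shape} != PET shape {pet.shape}")
    per_method = []
    for method in methods:
        union = np.zeros(pet.shape, dtype=bool)
        for rid, roi in roi_set.items():
            try:
                union |= segment_roi(pet, roi, method, roi_id=rid)
            except ValueError as exc:
                raise ValueError(f"ROI {rid}, method {method.name}: {exc}") from exc
        per_method.append(union)
    if not per_method:
        return np.zeros(pet.shape, dtype=np.float32)
    return build_tmtv_prob(per_method)
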