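"""Stripe-region partitioning and high-density-area (HDA) quantification.

A patellar MIP is cropped to the tight bounding box of its bone pixels and
split into four equally wide vertical stripes, labelled medial-to-lateral as
medial facet (MF), central ridge (CR), medial portion of the lateral facet
(MLF) and lateral portion of the lateral facet (LLF).  The HDA fraction of a
region is the number of its projection pixels strictly above an HU threshold
divided by the number of supra-threshold pixels across all four regions
combined.  Thresholding happens in the HU domain on the lossless MIP, never
on the quantized 8-bit rendering.

Counts are integers and fractions are exact rationals
(:class:`fractions.Fraction`), so defined fractions sum to exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .volume_mip import MipImage

__all__ = [
    "REGION_LABELS",
    "QUADRANT_LABELS",
    "BoundingBox",
    "RegionPartition",
    "HdaMeasurement",
    "UndefinedFractionsWarning",
    "compute_bounding_box",
    "partition_stripes",
    "hda_fraction",
    "sensitivity_analysis",
    "locate_maximum_region",
    "quadrant_localization",
]

#: Anatomical stripe labels, medial to lateral.
REGION_LABELS = ("MF", "CR", "MLF", "LLF")
QUADRANT_LABELS = ("superomedial", "superolateral", "inferomedial", "inferolateral")


class UndefinedFractionsWarning(UserWarning):
    """Emitted when no pixel exceeds the threshold and fractions are undefined."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class BoundingBox:
    """Tight half-open pixel box around the bone pixels of a MIP."""

    col_lo: int
    col_hi: int
    row_lo: int
    row_hi: int

    def __post_init__(self) -> None:
        if not (self.col_lo < self.col_hi and self.row_lo < self.row_hi):
            raise ValueError("bounding box must be non-empty")

    @property
    def width(self) -> int:
        return self.col_hi - self.col_lo

    @property
    def height(self) -> int:
        return self.row_hi - self.row_lo


@dataclass(frozen=True)
class RegionPartition:
    """Four contiguous half-open column intervals with anatomical labels.

    ``intervals[i]`` is the column interval of ``labels[i]``; label order in
    image space depends on side and orientation, but the mapping
    label -> interval is always anatomically correct.
    """

    box: BoundingBox
    intervals: tuple[tuple[int, int], ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if sorted(self.labels) != sorted(REGION_LABELS):
            raise ValueError(f"labels must be a permutation of {REGION_LABELS}")

    def interval_of(self, label: str) -> tuple[int, int]:
        return self.intervals[self.labels.index(label)]


@dataclass
class HdaMeasurement:
    """Per-region supra-threshold pixel counts and exact fractions.

    ``fractions`` maps region label to an exact rational; ``None`` when no
    pixel exceeds the threshold anywhere (undefined, flagged by a warning at
    computation time rather than silently reported as zeros).
    """

    threshold_hu: float
    counts: dict[str, int]
    total_count: int
    fractions: dict[str, Fraction] | None

    @property
    def defined(self) -> bool:
        return self.fractions is not None

    def fractions_float(self) -> dict[str, float]:
        if self.fractions is None:
            raise ValueError("fractions undefined: no pixel above threshold")
        return {k: float(v) for k, v in self.fractions.items()}


def compute_bounding_box(mip: MipImage, floor_hu: float | None = None) -> BoundingBox:
    """Tightest row/column range containing every pixel at or above
    ``floor_hu`` (default: the density-window floor)."""
    if floor_hu is None:
        floor_hu = mip.window.lo_hu
    bone = mip.pixels_hu >= floor_hu
    if not bone.any():
        raise ValueError(f"no pixel reaches the bone floor of {floor_hu} HU")
    rows = np.flatnonzero(bone.any(axis=1))
    cols = np.flatnonzero(bone.any(axis=0))
    return BoundingBox(int(cols[0]), int(cols[-1]) + 1, int(rows[0]), int(rows[-1]) + 1)


def partition_stripes(box: BoundingBox, side: str, orientation: str) -> RegionPartition:
    """Cut the box into four equally wide vertical stripes and label them.

    Stripe boundaries sit at ``col_lo + round(k*W/4)`` (round half up), so
    stripe widths differ by at most one pixel.  In standardized-right
    orientation (and for right patellae in anatomical orientation) medial is
    at the low-column side and image-space order is MF, CR, MLF, LLF; for
    left patellae in anatomical orientation the image-space order reverses.
    """
    w = box.width
    if w < 4:
        raise ValueError(f"box width {w} < 4: cannot form four nonempty stripes")
    offsets = [_round_half_up(k * w / 4) for k in range(5)]
    intervals = tuple((box.col_lo + offsets[k], box.col_lo + offsets[k + 1])
                      for k in range(4))
    medial_low = orientation == "standardized-right" or side == "right"
    labels = REGION_LABELS if medial_low else tuple(reversed(REGION_LABELS))
    return RegionPartition(box, intervals, labels)


def hda_fraction(mip: MipImage, partition: RegionPartition,
                 threshold_hu: float = 1000.0) -> HdaMeasurement:
    """Count pixels strictly above ``threshold_hu`` per stripe and normalize
    by the combined supra-threshold total.

    Rows are restricted to the bounding box; pixels exactly at the threshold
    are excluded.  When no pixel exceeds the threshold the fractions are
    undefined and an :class:`UndefinedFractionsWarning` is emitted.
    """
    box = partition.box
    crop = mip.pixels_hu[box.row_lo:box.row_hi, :]
    counts: dict[str, int] = {}
    for (lo, hi), label in zip(partition.intervals, partition.labels):
        counts[label] = int(np.count_nonzero(crop[:, lo:hi] > threshold_hu))
    total = sum(counts.values())
    if total == 0:
        warnings.warn(
            f"no pixel above {threshold_hu} HU: HDA fractions undefined",
            UndefinedFractionsWarning, stacklevel=2)
        return HdaMeasurement(threshold_hu, counts, 0, None)
    fractions = {k: Fraction(c, total) for k, c in counts.items()}
    return HdaMeasurement(threshold_hu, counts, total, fractions)


def sensitivity_analysis(mip: MipImage, partition: RegionPartition,
                         thresholds: tuple[float, ...] = (900.0, 1000.0, 1100.0),
                         ) -> list[HdaMeasurement]:
    """HDA measurements at several thresholds (default 900/1000/1100 HU)."""
    if len(thresholds) == 0:
        raise ValueError("threshold list must be nonempty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly ascending")
    return [hda_fraction(mip, partition, t) for t in thresholds]


def locate_maximum_region(m: HdaMeasurement, margin: float = 0.05) -> str:
    """Region holding the largest HDA fraction, or ``"indeterminate"`` when
    the top two fractions differ by no more than ``margin`` (absolute)."""
    if not m.defined:
        raise ValueError("fractions undefined: cannot locate a maximum region")
    ordered = sorted(m.fractions.items(), key=lambda kv: kv[1], reverse=True)
    if ordered[0][1] - ordered[1][1] <= Fraction(margin).limit_denominator(10**9):
        return "indeterminate"
    return ordered[0][0]


def quadrant_localization(mip: MipImage, box: BoundingBox, threshold_hu: float = 1000.0,
                          margin: float = 0.05) -> str:
    """Anatomical quadrant holding the most supra-threshold pixels.

    The box is split at its column and row midpoints (half-open; the extra
    row of an odd-height box goes to the inferior half and the extra column
    to the lateral half).  Returns ``"indeterminate"`` when the top two
    quadrant counts are within ``margin`` of the total, or when no pixel
    exceeds the threshold.
    """
    lateral_high = mip.orientation == "standardized-right" or mip.side == "right"
    w, h = box.width, box.height
    # medial half width: lateral side absorbs the odd column
    med_w = w // 2 if lateral_high else (w + 1) // 2
    col_mid = box.col_lo + med_w
    row_mid = box.row_lo + h // 2  # superior half; inferior absorbs the odd row

    above = mip.pixels_hu[box.row_lo:box.row_hi, box.col_lo:box.col_hi] > threshold_hu
    cm, rm = col_mid - box.col_lo, row_mid - box.row_lo
    low_cols, high_cols = slice(0, cm), slice(cm, w)
    med, lat = (low_cols, high_cols) if lateral_high else (high_cols, low_cols)
    counts = {
        "superomedial": int(np.count_nonzero(above[:rm, med])),
        "superolateral": int(np.count_nonzero(above[:rm, lat])),
        "inferomedial": int(np.count_nonzero(above[rm:, med])),
        "inferolateral": int(np.count_nonzero(above[rm:, lat])),
    }
    total = sum(counts.values())
    if total == 0:
        return "indeterminate"
    ordered = sorted(counts.items(), key=lambda kv: kv[1], reverse=True)
    if ordered[0][1] - ordered[1][1] <= margin * total:
        return "indeterminate"
    return ordered[0][0]
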