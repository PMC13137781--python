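"""Synthetic patella phantoms with known regional mineralization structure.

The phantom is a stylized half-ellipsoid: an ellipsoidal bone body truncated
by a flat posterior articular face, with a cortical shell, homogeneous
trabecular interior, and a one-voxel subchondral plate on the articular face.
The plate carries the mineralization signal: its HU per stripe region (MF,
CR, MLF, LLF, medial to lateral) equals the configured region mean, plus an
optional operated-side shift, plus independent Gaussian HU noise.  Shell and
interior HU sit below every HDA threshold, so supra-threshold projection
pixels are exclusively subchondral-plate pixels and the expected regional
HDA fractions are available in closed form (ground truth for recovery tests).

Left-sided phantoms are exact mirror images of the right-sided construction
along the medial--lateral axis, with noise drawn before mirroring, so the
left-flip convention of the projection stage can be tested for exactness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .region_hda import REGION_LABELS, _round_half_up
from .volume_mip import CtVolume, DensityWindow, MipImage, mirror_ml

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "generate_patella_volume",
    "generate_paired_cohort",
    "generate_mip_fixture",
    "simulate_knee_counts",
    "plate_pixels_per_stripe",
    "truth_records_to_csv",
]

_SIDE_CODE = {"left": 0, "right": 1}
_STATUS_CODE = {"non-operated": 0, "operated": 1}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the observed physiological loading pattern: region mean
    HU ordered MLF > LLF > CR > MF so that high-density area concentrates in
    the lateral facet stripes, nine patients, and a zero operated-side shift
    (the null of no side-to-side difference).
    """

    n_patients: int = 9
    #: subchondral plate mean HU per stripe, ordered (MF, CR, MLF, LLF)
    region_mean_hu: tuple[float, float, float, float] = (700.0, 850.0, 1150.0, 1050.0)
    noise_sd_hu: float = 80.0
    #: HU added to the operated side per stripe; all-zero = the null
    operated_shift_hu: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    volume_shape: tuple[int, int, int] = (48, 36, 64)
    voxel_spacing_mm: tuple[float, float, float] = (0.7, 0.4, 0.4)
    cortical_hu: float = 700.0
    trabecular_hu: float = 400.0
    background_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be nonnegative")
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise ValueError("volume_shape must be 3 integers, all >= 8")
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be 3 positive reals")
        if len(self.region_mean_hu) != 4 or len(self.operated_shift_hu) != 4:
            raise ValueError("region_mean_hu and operated_shift_hu must have 4 entries")


@dataclass(frozen=True)
class TruthRecord:
    """Analytic noise-free ground truth for one patient pair.

    ``true_fraction_*`` maps region label to the expected HDA fraction at the
    truth threshold under the generating model with the noise switched off
    (a plate pixel counts iff its region mean, plus shift on the operated
    side, strictly exceeds the threshold).  ``None`` when no region mean
    exceeds the threshold (undefined fractions).
    """

    patient_id: str
    side_operated: str
    threshold_hu: float
    true_fraction_operated: dict[str, Fraction] | None
    true_fraction_nonoperated: dict[str, Fraction] | None


# ---------------------------------------------------------------------------
# geometry


def _geometry(config: SimulationConfig):
    """Bone support, plate voxel coordinates (canonical order) and stripe
    index per plate voxel, for the right-sided construction."""
    nz, ny, nx = config.volume_shape
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    az, ay, ax = 0.42 * nz, 0.42 * ny, 0.42 * nx
    y_face = int(np.floor(cy + 0.5 * ay))  # flat posterior articular face

    z = np.arange(nz)[:, None, None]
    y = np.arange(ny)[None, :, None]
    x = np.arange(nx)[None, None, :]
    r2 = ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2
    bone = (r2 <= 1.0) & (y <= y_face)
    shell = bone & (r2 >= (1.0 - 0.08) ** 2)

    plate = bone[:, y_face, :]  # (z, x) footprint of the articular face
    pz, px = np.nonzero(plate)  # canonical row-major order

    footprint = bone.any(axis=1)  # (z, x)
    cols = np.flatnonzero(footprint.any(axis=0))
    col_lo, col_hi = int(cols[0]), int(cols[-1]) + 1
    w = col_hi - col_lo
    offsets = np.array([_round_half_up(k * w / 4) for k in range(5)]) + col_lo
    stripe_idx = np.searchsorted(offsets[1:4], px, side="right")
    return bone, shell, y_face, pz, px, stripe_idx


def plate_pixels_per_stripe(config: SimulationConfig) -> np.ndarray:
    """Number of subchondral-plate pixels in each stripe (MF, CR, MLF, LLF)."""
    *_, stripe_idx = _geometry(config)
    return np.bincount(stripe_idx, minlength=4)


def _knee_rng(config: SimulationConfig, patient_index: int, side: str,
              status: str) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=config.seed,
        spawn_key=(patient_index, _SIDE_CODE[side], _STATUS_CODE[status]))
    return np.random.default_rng(ss)


def _plate_values(config: SimulationConfig, patient_index: int, side: str,
                  status: str, stripe_idx: np.ndarray) -> np.ndarray:
    """Noisy plate HU per plate pixel, in canonical (right-construction)
    order; shared by the volume builder and the analytic fast path."""
    means = np.asarray(config.region_mean_hu, dtype=float)
    if status == "operated":
        means = means + np.asarray(config.operated_shift_hu, dtype=float)
    values = means[stripe_idx]
    if config.noise_sd_hu > 0:
        rng = _knee_rng(config, patient_index, side, status)
        values = values + config.noise_sd_hu * rng.standard_normal(len(stripe_idx))
    return values


def generate_patella_volume(config: SimulationConfig, side: str, status: str,
                            patient_index: int) -> CtVolume:
    """Build one phantom knee; deterministic given (seed, patient, side, status).

    The right-sided construction is assembled first (background, trabecular
    interior, cortical shell, noisy subchondral plate) and mirrored along the
    medial--lateral axis for left knees, so a left phantom is the exact
    mirror image of its own right-sided construction.
    """
    if patient_index >= config.n_patients or patient_index < 0:
        raise ValueError("patient_index out of range")
    bone, shell, y_face, pz, px, stripe_idx = _geometry(config)

    vox = np.full(config.volume_shape, config.background_hu, dtype=float)
    vox[bone] = config.trabecular_hu
    vox[shell] = config.cortical_hu
    vox[pz, y_face, px] = _plate_values(config, patient_index, side, status, stripe_idx)

    if side == "left":
        vox = mirror_ml(vox)
    return CtVolume(vox, config.voxel_spacing_mm,
                    f"P{patient_index + 1:02d}", side, status)


def simulate_knee_counts(config: SimulationConfig, patient_index: int, side: str,
                         status: str,
                         thresholds: tuple[float, ...] = (900.0, 1000.0, 1100.0),
                         ) -> dict[float, np.ndarray]:
    """Supra-threshold plate-pixel counts per stripe, without building a volume.

    Draws the identical noise realization as :func:`generate_patella_volume`
    (same per-knee RNG stream, same canonical pixel order) and counts plate
    pixels strictly above each threshold per stripe.  Because shell and
    interior HU lie below every threshold, these counts equal the HDA counts
    the full volume -> MIP -> stripe pipeline measures, pixel for pixel.
    """
    *_, stripe_idx = _geometry(config)
    values = _plate_values(config, patient_index, side, status, stripe_idx)
    out: dict[float, np.ndarray] = {}
    for t in thresholds:
        above = values > t
        out[t] = np.bincount(stripe_idx[above], minlength=4)
    return out


def _truth_fractions(config: SimulationConfig, status: str,
                     threshold_hu: float) -> dict[str, Fraction] | None:
    n_k = plate_pixels_per_stripe(config)
    means = np.asarray(config.region_mean_hu, dtype=float)
    if status == "operated":
        means = means + np.asarray(config.operated_shift_hu, dtype=float)
    counts = np.where(means > threshold_hu, n_k, 0)
    total = int(counts.sum())
    if total == 0:
        return None
    return {lab: Fraction(int(c), total) for lab, c in zip(REGION_LABELS, counts)}


def operated_side_assignment(config: SimulationConfig) -> np.ndarray:
    """Seeded Bernoulli(1/2) operated-side draw per patient."""
    side_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(10**6,)))
    return np.where(side_rng.random(config.n_patients) < 0.5, "left", "right")


def generate_paired_cohort(config: SimulationConfig,
                           truth_threshold_hu: float = 1000.0,
                           ) -> tuple[list[tuple[CtVolume, CtVolume]], list[TruthRecord]]:
    """Generate ``n_patients`` (operated, non-operated) volume pairs.

    The operated side is a seeded Bernoulli(1/2) draw per patient, recorded
    in the :class:`TruthRecord` together with the analytic noise-free HDA
    fractions at ``truth_threshold_hu``.
    """
    operated_sides = operated_side_assignment(config)
    pairs: list[tuple[CtVolume, CtVolume]] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_patients):
        op_side = str(operated_sides[i])
        nop_side = "right" if op_side == "left" else "left"
        op = generate_patella_volume(config, op_side, "operated", i)
        nop = generate_patella_volume(config, nop_side, "non-operated", i)
        pairs.append((op, nop))
        truths.append(TruthRecord(
            patient_id=op.patient_id,
            side_operated=op_side,
            threshold_hu=truth_threshold_hu,
            true_fraction_operated=_truth_fractions(config, "operated", truth_threshold_hu),
            true_fraction_nonoperated=_truth_fractions(config, "non-operated",
                                                       truth_threshold_hu),
        ))
    return pairs, truths


def simulate_cohort_table(config: SimulationConfig,
                          thresholds: tuple[float, ...] = (900.0, 1000.0, 1100.0),
                          ) -> pd.DataFrame:
    """Cohort HDA table straight from the generating model (no volumes built).

    One row per (patient, region, threshold) with operated and non-operated
    fractions, computed from :func:`simulate_knee_counts` under the same
    per-knee noise realizations the volume builder uses.  Suitable for
    Monte-Carlo calibration runs; a pipeline-equivalence test guarantees the
    numbers match the full volume -> MIP -> HDA route.
    """
    operated_sides = operated_side_assignment(config)
    rows = []
    for i in range(config.n_patients):
        op_side = str(operated_sides[i])
        nop_side = "right" if op_side == "left" else "left"
        op_counts = simulate_knee_counts(config, i, op_side, "operated", thresholds)
        nop_counts = simulate_knee_counts(config, i, nop_side, "non-operated",
                                          thresholds)
        for t in thresholds:
            tot_op, tot_nop = op_counts[t].sum(), nop_counts[t].sum()
            for k, region in enumerate(REGION_LABELS):
                rows.append({
                    "patient_id": f"P{i + 1:02d}",
                    "side_operated": op_side,
                    "region": region,
                    "threshold_hu": float(t),
                    "fraction_operated":
                        op_counts[t][k] / tot_op if tot_op else np.nan,
                    "fraction_nonoperated":
                        nop_counts[t][k] / tot_nop if tot_nop else np.nan,
                })
    return pd.DataFrame(rows)


def truth_records_to_csv(truths: list[TruthRecord], path: str | Path) -> pd.DataFrame:
    """Write ground truth as long-format CSV
    (patient_id, side_operated, region, knee, true_fraction)."""
    rows = []
    for t in truths:
        for knee, fracs in (("operated", t.true_fraction_operated),
                            ("non-operated", t.true_fraction_nonoperated)):
            for region in REGION_LABELS:
                rows.append({
                    "patient_id": t.patient_id,
                    "side_operated": t.side_operated,
                    "region": region,
                    "knee": knee,
                    "true_fraction": float(fracs[region]) if fracs else np.nan,
                })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def generate_mip_fixture(region_counts: tuple[int, int, int, int],
                         region_width_px: int, rows: int,
                         threshold_hu: float = 1000.0) -> MipImage:
    """Exact-count 2D fixture: stripe ``k`` contains exactly
    ``region_counts[k]`` pixels strictly above ``threshold_hu``.

    Supra-threshold pixels are placed row-major from each stripe's top-left
    corner; all remaining pixels sit midway between 200 HU and the threshold,
    so the bone bounding box is the full image and the four stripes coincide
    with the fixture's stripes.
    """
    if region_width_px < 1 or rows < 1:
        raise ValueError("region_width_px and rows must be positive")
    capacity = region_width_px * rows
    for k, c in enumerate(region_counts):
        if c < 0 or c > capacity:
            raise ValueError(
                f"region_counts[{k}]={c} exceeds stripe capacity {capacity}")
    filler = (200.0 + threshold_hu) / 2.0
    img = np.full((rows, 4 * region_width_px), filler, dtype=float)
    for k, c in enumerate(region_counts):
        stripe = np.full(capacity, filler)
        stripe[:c] = threshold_hu + 100.0
        img[:, k * region_width_px:(k + 1) * region_width_px] = \
            stripe.reshape(rows, region_width_px)
    return MipImage(img, DensityWindow(), "right", "standardized-right")
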