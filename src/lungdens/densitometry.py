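"""Lung density indices from paired-phase CT volumes.

All indices operate on a 3-D attenuation grid in Hounsfield units (HU)
restricted to a lung mask: mean lung density (MLD) per phase, the
expiratory-inspiratory MLD difference (MLDD), expiratory-to-inspiratory
ratios of volume and MLD (E/I volume, E/I MLD), and threshold attenuation
fractions — low attenuation areas (LAA: % of expiratory lung voxels below
-850/-900/-950 HU, i.e. E850/E900/E950) and high attenuation areas
(HAA: % above -600/-650 HU, i.e. E600/E650).

Sign/threshold conventions used throughout:

* MLDD = expiratory MLD - inspiratory MLD, so a healthy lung that densifies
  on expiration has a positive MLDD.
* Threshold comparisons are strict; a voxel exactly at the threshold counts
  for neither tail.
* Whole-lung values are computed over the union mask (voxel-weighted), with
  per-side values reported alongside.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "Phase",
    "Side",
    "DensityVolume",
    "LungMask",
    "DensitometryResult",
    "EmptyRegionError",
    "AlignmentError",
    "SegmentationError",
    "LAA_THRESHOLDS_HU",
    "HAA_THRESHOLDS_HU",
    "mean_lung_density",
    "lung_volume",
    "mldd",
    "ei_ratio",
    "attenuation_fraction",
    "compute_all_indices",
    "simple_lung_segment",
]

#: Plausibility window for calibrated HU values (12-bit CT range).
HU_PLAUSIBLE = (-1024.0, 3071.0)

#: Expiratory low-attenuation thresholds (E850, E900, E950).
LAA_THRESHOLDS_HU: Tuple[float, ...] = (-850.0, -900.0, -950.0)

#: Expiratory high-attenuation thresholds (E600, E650).
HAA_THRESHOLDS_HU: Tuple[float, ...] = (-600.0, -650.0)


class Phase(str, enum.Enum):
    INSPIRATORY = "inspiratory"
    EXPIRATORY = "expiratory"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    BOTH = "both"


class EmptyRegionError(ValueError):
    """Raised when an index is requested over an empty masked region."""


class AlignmentError(ValueError):
    """Raised when a mask and a volume do not share a grid."""


class SegmentationError(RuntimeError):
    """Raised when threshold segmentation finds no lung candidate."""


@dataclass(frozen=True)
class DensityVolume:
    """A 3-D CT attenuation grid in HU with physical voxel spacing.

    Parameters
    ----------
    values
        3-D float array of attenuation values in HU.
    spacing
        Voxel edge lengths in mm along each array axis. The first array
        axis is the subject left-right axis (label 1 = subject-left).
    phase
        Respiratory phase of the acquisition.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float]
    phase: Phase = Phase.INSPIRATORY

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "phase", Phase(self.phase))
        if values.ndim != 3 or values.size == 0:
            raise ValueError("volume must be a non-empty 3-D grid")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        lo, hi = HU_PLAUSIBLE
        n_bad = int(np.count_nonzero((values < lo) | (values > hi)))
        if n_bad:
            # warn, never clip: phantom noise tails legitimately exceed the window
            warnings.warn(
                f"{n_bad} voxel(s) outside the plausible HU window [{lo:g}, {hi:g}]",
                stacklevel=2,
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class LungMask:
    """Voxel membership grid: 0 = outside, 1 = left lung, 2 = right lung."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or labels.size == 0:
            raise ValueError("mask must be a non-empty 3-D grid")
        if not np.isin(labels, (0, 1, 2)).all():
            raise ValueError("mask labels must be 0 (outside), 1 (left) or 2 (right)")
        object.__setattr__(self, "labels", labels.astype(np.uint8))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def select(self, side: Side | str = Side.BOTH) -> np.ndarray:
        """Boolean selector for the requested side."""
        side = Side(side)
        if side is Side.BOTH:
            return self.labels > 0
        return self.labels == (1 if side is Side.LEFT else 2)

    def voxel_count(self, side: Side | str = Side.BOTH) -> int:
        return int(np.count_nonzero(self.select(side)))


def _require_aligned(volume: DensityVolume, mask: LungMask) -> None:
    if volume.shape != mask.shape:
        raise AlignmentError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )


def _masked_values(
    volume: DensityVolume, mask: LungMask, side: Side | str
) -> np.ndarray:
    _require_aligned(volume, mask)
    sel = mask.select(side)
    if not sel.any():
        raise EmptyRegionError(f"no masked voxels on side '{Side(side).value}'")
    return volume.values[sel]


def mean_lung_density(
    volume: DensityVolume, mask: LungMask, side: Side | str = Side.BOTH
) -> float:
    """Arithmetic mean HU over the masked voxels of one side (or both).

    No weighting or trimming is applied; every masked voxel contributes
    equally regardless of position.
    """
    return float(np.mean(_masked_values(volume, mask, side)))


def lung_volume(
    mask: LungMask,
    spacing: Sequence[float],
    side: Side | str = Side.BOTH,
) -> float:
    """Lung volume in mL: masked voxel count x voxel volume (mm^3 -> mL)."""
    n = mask.voxel_count(side)
    if n == 0:
        raise EmptyRegionError(f"no masked voxels on side '{Side(side).value}'")
    voxel_mm3 = float(np.prod([float(s) for s in spacing]))
    if voxel_mm3 <= 0:
        raise ValueError("voxel spacing must be positive")
    return n * voxel_mm3 / 1000.0


def mldd(ins_mld_hu: float, exp_mld_hu: float) -> float:
    """Mean-lung-density difference: expiratory MLD minus inspiratory MLD.

    With this sign convention a lung that densifies normally on expiration
    (e.g. -788 HU -> -659 HU) yields a positive MLDD (+129 HU), while air
    trapping drives MLDD toward zero.
    """
    if not (np.isfinite(ins_mld_hu) and np.isfinite(exp_mld_hu)):
        raise ValueError("MLD values must be finite")
    return float(exp_mld_hu) - float(ins_mld_hu)


def ei_ratio(ins_value: float, exp_value: float) -> float:
    """Expiratory-to-inspiratory ratio as a percentage: 100 * exp / ins.

    For MLD the ratio is taken on signed HU values (both negative in
    practice), e.g. 100 * (-659) / (-788) = 83.6%.
    """
    if ins_value == 0:
        raise ZeroDivisionError("inspiratory value is zero; E/I ratio undefined")
    return 100.0 * float(exp_value) / float(ins_value)


def attenuation_fraction(
    volume: DensityVolume,
    mask: LungMask,
    threshold_hu: float,
    direction: str = "below",
    side: Side | str = Side.BOTH,
) -> float:
    """Percentage of masked voxels strictly beyond an HU threshold.

    ``direction='below'`` counts voxels with HU < threshold (LAA);
    ``direction='above'`` counts HU > threshold (HAA). Voxels exactly at
    the threshold count for neither direction.
    """
    vals = _masked_values(volume, mask, side)
    if direction == "below":
        n = np.count_nonzero(vals < threshold_hu)
    elif direction == "above":
        n = np.count_nonzero(vals > threshold_hu)
    else:
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    return 100.0 * float(n) / vals.size


def _threshold_key(threshold_hu: float) -> str:
    return f"e{int(round(abs(threshold_hu)))}_pct"


@dataclass
class DensitometryResult:
    """Per-subject lung-density index panel.

    ``laa_pct`` maps each low-attenuation threshold (e.g. -900.0) to the
    percentage of expiratory lung voxels strictly below it; ``haa_pct``
    likewise for voxels strictly above the high-attenuation thresholds.
    ``per_side`` optionally carries the same panel restricted to each lung.
    """

    ins_volume_ml: float
    exp_volume_ml: float
    ins_mld_hu: float
    exp_mld_hu: float
    mldd_hu: float
    ei_volume_pct: float
    ei_mld_pct: float
    laa_pct: Dict[float, float] = field(default_factory=dict)
    haa_pct: Dict[float, float] = field(default_factory=dict)
    per_side: Optional[Dict[str, "DensitometryResult"]] = None

    def to_flat_dict(self, prefix: str = "") -> Dict[str, float]:
        """Flatten to the cohort-table column dictionary (e.g. ``e900_pct``)."""
        out = {
            f"{prefix}ins_volume_ml": self.ins_volume_ml,
            f"{prefix}exp_volume_ml": self.exp_volume_ml,
            f"{prefix}ins_mld_hu": self.ins_mld_hu,
            f"{prefix}exp_mld_hu": self.exp_mld_hu,
            f"{prefix}mldd_hu": self.mldd_hu,
            f"{prefix}ei_volume_pct": self.ei_volume_pct,
            f"{prefix}ei_mld_pct": self.ei_mld_pct,
        }
        for t, v in self.laa_pct.items():
            out[prefix + _threshold_key(t)] = v
        for t, v in self.haa_pct.items():
            out[prefix + _threshold_key(t)] = v
        return out

    def validate(self) -> None:
        """Check internal consistency of the index panel."""
        if not np.isclose(self.mldd_hu, self.exp_mld_hu - self.ins_mld_hu):
            raise ValueError("mldd_hu must equal exp_mld_hu - ins_mld_hu")
        for name, v in [("ei_volume_pct", self.ei_volume_pct)] + [
            (_threshold_key(t), v) for t, v in {**self.laa_pct, **self.haa_pct}.items()
        ]:
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        laa_sorted = sorted(self.laa_pct)  # ascending HU: -950, -900, -850
        for lo, hi in zip(laa_sorted[:-1], laa_sorted[1:]):
            if self.laa_pct[lo] > self.laa_pct[hi] + 1e-12:
                raise ValueError("LAA fractions must be non-decreasing in threshold")


def compute_all_indices(
    ins_volume: DensityVolume,
    ins_mask: LungMask,
    exp_volume: DensityVolume,
    exp_mask: LungMask,
    laa_thresholds: Sequence[float] = LAA_THRESHOLDS_HU,
    haa_thresholds: Sequence[float] = HAA_THRESHOLDS_HU,
    per_side: bool = True,
) -> DensitometryResult:
    """Compute the full LDI panel for one subject's paired-phase scan.

    Threshold fractions are measured on the expiratory phase only: LAA
    thresholds count voxels strictly below (trapped, abnormally lucent
    lung); HAA thresholds count voxels strictly above (normally densified
    lung). Whole-lung values are voxel-weighted over the union mask.
    """
    sides: Sequence[Side] = (Side.BOTH, Side.LEFT, Side.RIGHT) if per_side else (Side.BOTH,)
    results: Dict[str, DensitometryResult] = {}
    for side in sides:
        if side is not Side.BOTH and not (
            ins_mask.select(side).any() and exp_mask.select(side).any()
        ):
            continue  # single-sided mask: omit the empty side from the breakdown
        try:
            ins_mld = mean_lung_density(ins_volume, ins_mask, side)
            exp_mld = mean_lung_density(exp_volume, exp_mask, side)
            ins_v = lung_volume(ins_mask, ins_volume.spacing, side)
            exp_v = lung_volume(exp_mask, exp_volume.spacing, side)
            laa = {
                float(t): attenuation_fraction(exp_volume, exp_mask, t, "below", side)
                for t in laa_thresholds
            }
            haa = {
                float(t): attenuation_fraction(exp_volume, exp_mask, t, "above", side)
                for t in haa_thresholds
            }
        except (EmptyRegionError, AlignmentError) as err:
            raise type(err)(f"side '{side.value}': {err}") from err
        results[side.value] = DensitometryResult(
            ins_volume_ml=ins_v,
            exp_volume_ml=exp_v,
            ins_mld_hu=ins_mld,
            exp_mld_hu=exp_mld,
            mldd_hu=mldd(ins_mld, exp_mld),
            ei_volume_pct=ei_ratio(ins_v, exp_v),
            ei_mld_pct=ei_ratio(ins_mld, exp_mld),
            laa_pct=laa,
            haa_pct=haa,
        )
    whole = results[Side.BOTH.value]
    if per_side:
        whole.per_side = {
            s: results[s] for s in (Side.LEFT.value, Side.RIGHT.value) if s in results
        }
    return whole


def simple_lung_segment(
    volume: DensityVolume,
    air_threshold_hu: float = -400.0,
    min_component_voxels: int = 64,
) -> LungMask:
    """Convenience threshold segmenter for phantom-like volumes.

    Voxels below ``air_threshold_hu`` are air candidates; air connected to
    the grid border (outside-body air) is removed, then the largest one or
    two remaining components are kept and labelled left/right by centroid
    laterality along the first array axis. This is a convenience for
    phantoms and well-behaved volumes, not a clinical segmentation method.
    """
    air = volume.values < air_threshold_hu
    labels, _ = ndimage.label(air)
    border = np.zeros_like(air)
    for ax in range(3):
        sl: list = [slice(None)] * 3
        for idx in (0, -1):
            sl[ax] = idx
            border[tuple(sl)] = True
    border_labels = np.unique(labels[border & air])
    inside = air & ~np.isin(labels, border_labels)
    comp_labels, n_comp = ndimage.label(inside)
    if n_comp == 0:
        raise SegmentationError("no lung candidate below the air threshold")
    sizes = ndimage.sum_labels(inside, comp_labels, index=np.arange(1, n_comp + 1))
    keep = [
        (int(sz), lab)
        for lab, sz in zip(range(1, n_comp + 1), sizes)
        if sz >= min_component_voxels
    ]
    if not keep:
        raise SegmentationError(
            f"no candidate component reaches {min_component_voxels} voxels"
        )
    keep.sort(reverse=True)
    keep = keep[:2]
    out = np.zeros(volume.shape, dtype=np.uint8)
    if len(keep) == 2:
        centroids = ndimage.center_of_mass(inside, comp_labels, [lab for _, lab in keep])
        order = sorted(range(2), key=lambda i: centroids[i][0])
        out[comp_labels == keep[order[0]][1]] = 1  # smaller first-axis index = left
        out[comp_labels == keep[order[1]][1]] = 2
    else:
        lab = keep[0][1]
        cx = ndimage.center_of_mass(inside, comp_labels, lab)[0]
        out[comp_labels == lab] = 1 if cx < volume.shape[0] / 2 else 2
    return LungMask(out)
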