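"""Shared domain types for dual-energy CT iodine-map analysis.

The central objects are the per-phase iodine-density volume (mg iodine per cc
of tissue, one value per voxel), the binary regions of interest drawn on it
(whole-tumor VOI and an aortic blood-pool ROI), and the per-patient record
that ties paired unenhanced / 180 s equilibrium-phase volumes to hematocrit
and histological class.  Everything downstream (feature extraction, phantom
generation, diagnostics) works in terms of these types.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Iodine-decomposition noise floor of the scanner material decomposition,
#: in mg/cc.  Iodine maps can dip slightly negative from image noise; the
#: decomposition clips near this value.
DEFAULT_IODINE_FLOOR = -2.9

#: Canonical ordering of the nine per-case quantitative features.
FEATURE_NAMES = (
    "maximum",
    "minimum",
    "median",
    "average",
    "sd",
    "skewness",
    "kurtosis",
    "iodine_effect",
    "ecv",
)


class IodectError(Exception):
    """Base class for all package errors."""


class ValidationError(IodectError, ValueError):
    """A domain invariant was violated (bad shape, enum, range...)."""


class FormatError(IodectError, ValueError):
    """A file could not be parsed as the expected on-disk format."""


class UndefinedEcvError(IodectError, ArithmeticError):
    """ECV is undefined because the aortic iodine difference is <= 0."""


class Phase(str, enum.Enum):
    """Acquisition phase of an iodine-density volume."""

    UNENHANCED = "unenhanced"
    ENHANCED_180S = "enhanced_180s"


class MaskKind(str, enum.Enum):
    TUMOR_VOI = "tumor_voi"
    AORTA_ROI = "aorta_roi"


class TumorGroup(str, enum.Enum):
    """WHO-derived risk class of a thymic epithelial tumor."""

    LOW_RISK_THYMOMA = "low_risk_thymoma"     # types A, AB, B1
    HIGH_RISK_THYMOMA = "high_risk_thymoma"   # types B2, B3
    THYMIC_CARCINOMA = "thymic_carcinoma"


@dataclass
class IodineVolume:
    """A 3D iodine-density grid (mg/cc) with voxel spacing and phase tag.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Iodine density per voxel, mg/cc.
    spacing : (float, float, float)
        Voxel edge lengths in mm, all strictly positive.
    phase : Phase
        Which acquisition the map comes from.
    floor : float or None
        Declared decomposition floor (mg/cc).  When declared, no voxel may
        lie below it; ``None`` means no floor is asserted.  The floor is
        metadata — reading or constructing a volume never clamps values.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    phase: Phase
    floor: Optional[float] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"iodine volume must be 3D, got ndim={self.voxels.ndim}"
            )
        if min(self.voxels.shape) < 1:
            raise ValidationError("all three dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.phase = Phase(self.phase)
        if self.floor is not None:
            self.floor = float(self.floor)
            lo = float(self.voxels.min())
            if lo < self.floor - 1e-9:
                raise ValidationError(
                    f"voxel value {lo} below declared iodine floor {self.floor}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class RoiMask:
    """Boolean 3D mask, voxel-aligned to its paired volume (no resampling)."""

    voxels: np.ndarray
    kind: MaskKind

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != bool:
            self.voxels = self.voxels.astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError(f"mask must be 3D, got ndim={self.voxels.ndim}")
        self.kind = MaskKind(self.kind)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, vol: IodineVolume) -> None:
        if self.voxels.shape != vol.voxels.shape:
            raise ValidationError(
                f"mask shape {self.voxels.shape} does not match volume shape "
                f"{vol.voxels.shape}; masks must be voxel-aligned"
            )


@dataclass
class CaseRecord:
    """One patient: paired volumes, masks, hematocrit and class label."""

    case_id: str
    group: TumorGroup
    unenhanced: IodineVolume
    enhanced: IodineVolume
    tumor_mask: RoiMask
    aorta_mask: RoiMask
    hematocrit: float
    fibrosis_grade: Optional[int] = None

    def __post_init__(self) -> None:
        self.group = TumorGroup(self.group)
        if self.unenhanced.phase != Phase.UNENHANCED:
            raise ValidationError("unenhanced volume carries the wrong phase tag")
        if self.enhanced.phase != Phase.ENHANCED_180S:
            raise ValidationError("enhanced volume carries the wrong phase tag")
        if self.unenhanced.voxels.shape != self.enhanced.voxels.shape:
            raise ValidationError("paired volumes must share a voxel grid")
        if self.unenhanced.spacing != self.enhanced.spacing:
            raise ValidationError("paired volumes must share spacing")
        self.tumor_mask.check_aligned(self.enhanced)
        self.aorta_mask.check_aligned(self.enhanced)
        if not (0.0 < self.hematocrit < 1.0):
            raise ValidationError(f"hematocrit must lie in (0,1), got {self.hematocrit}")
        if self.fibrosis_grade is not None:
            if int(self.fibrosis_grade) not in (1, 2, 3):
                raise ValidationError(
                    f"fibrosis grade must be 1, 2 or 3, got {self.fibrosis_grade}"
                )
            self.fibrosis_grade = int(self.fibrosis_grade)


@dataclass
class FeatureVector:
    """The nine per-case quantitative features.

    Seven first-order histogram statistics of the enhanced-phase iodine
    density over the tumor VOI (mg/cc, except the dimensionless shape
    moments), plus the iodine effect (mg/cc) and the extracellular volume
    fraction (percent).
    """

    maximum: float
    minimum: float
    median: float
    average: float
    sd: float
    skewness: float
    kurtosis: float
    iodine_effect: float
    ecv: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.median <= self.maximum):
            raise ValidationError(
                "order statistics inconsistent: need minimum <= median <= maximum"
            )
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass(frozen=True)
class TwoByTwoTable:
    """Binarized-score x outcome counts.

    ``a`` positive outcome & score 1, ``b`` negative & score 1,
    ``c`` positive & score 0, ``d`` negative & score 0.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.total < 1:
            raise ValidationError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    @property
    def cross_product_or(self) -> float:
        """ad/bc; inf or nan when a zero cell makes it non-estimable."""
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)
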