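"""Seeded synthetic DECT phantom cohorts.

The generator emulates the study conditions this package analyzes: three
tumor classes (low-risk thymoma, high-risk thymoma, thymic carcinoma) with
class-conditional iodine uptake, an iodine-decomposition floor near
−2.9 mg/cc, necrotic low-iodine subregions that are more frequent in
high-risk tumors, an enhancing aortic blood pool, and a per-case hematocrit.

Model
-----
Each case is a pair of voxel grids (unenhanced, 180 s enhanced) with an
ellipsoidal tumor VOI and a cylindrical aorta ROI:

* Unenhanced iodine is zero-mean Gaussian decomposition noise everywhere —
  the true iodine content before contrast is zero, what the map shows is
  noise.
* Enhanced tumor voxels are Normal(mu_case, sd_intra); mu_case is drawn per
  case from Normal(mean_enhanced_iodine, sd_inter), a two-level model whose
  within-VOI spread and between-case spread are calibrated separately.
* A contiguous ellipsoidal necrotic blob occupying a class-dependent
  fraction of the VOI enhances like water (Normal(0, sd_intra)); necrosis
  is not compensated elsewhere, so more necrosis means a lower VOI mean and
  a lower iodine effect, as in real cystic/necrotic tumors.
* Both phases are clamped at the decomposition floor (default −2.9 mg/cc).
* The aortic enhancement is scaled per case so that the expected ECV equals
  a per-case target drawn from the class ECV distribution given the drawn
  hematocrit.  ECV is therefore calibrated independently of tumor uptake.

Reproducibility: a single cohort seed is expanded into one substream per
case via ``numpy.random.SeedSequence.spawn``, so each case's draws do not
depend on how many cases precede it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .cohort import CohortTable
from .features import extract_cohort
from .types import (
    CaseRecord,
    DEFAULT_IODINE_FLOOR,
    IodineVolume,
    MaskKind,
    Phase,
    RoiMask,
    TumorGroup,
    ValidationError,
)


@dataclass
class ClassIodineParams:
    """Class-conditional generator parameters.

    mean_enhanced_iodine : mg/cc, mean enhanced iodine of viable tumor
        tissue.  Note this is the *viable-tissue* mean; the expected VOI
        mean is (1 − necrosis fraction) × mean_enhanced_iodine.
    sd_inter : mg/cc, between-case spread of the case mean.
    sd_intra : mg/cc, within-tumor voxel spread.
    necrosis_fraction_range : (lo, hi) fraction of VOI voxels in the
        low-iodine necrotic blob, drawn uniformly per case.
    target_ecv_mean, target_ecv_sd : percent, class ECV distribution.
    fibrosis_probs : P(grade 1), P(grade 2), P(grade 3).
    """

    mean_enhanced_iodine: float
    sd_inter: float
    sd_intra: float
    necrosis_fraction_range: tuple[float, float]
    target_ecv_mean: float
    target_ecv_sd: float
    fibrosis_probs: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sd_inter < 0 or self.sd_intra < 0:
            raise ValidationError("class sds must be >= 0")
        lo, hi = self.necrosis_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValidationError(
                f"necrosis fractions must satisfy 0 <= lo <= hi < 1, got ({lo}, {hi})"
            )
        if abs(sum(self.fibrosis_probs) - 1.0) > 1e-9 or min(self.fibrosis_probs) < 0:
            raise ValidationError("fibrosis_probs must be a probability vector")


@dataclass
class AortaParams:
    radius_mm: float = 8.0
    mean_enhanced_iodine: float = 5.0  # used only when ECV calibration is off
    voxel_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValidationError("aorta radius must be positive")
        if self.voxel_sd < 0:
            raise ValidationError("aorta voxel sd must be >= 0")


def _default_class_params() -> dict[TumorGroup, ClassIodineParams]:
    # Viable-tissue means are the class iodine-effect targets divided by
    # (1 - mean necrosis fraction), so the expected VOI mean lands on
    # 1.31 / 1.20 / 1.61 mg/cc; within-VOI sd_intra matches the per-class
    # voxel SD (~0.8-1.0 mg/cc) and sd_inter the between-case spread of the
    # iodine effect.  Fibrosis grade distributions reproduce per-class
    # pathological score means of about 1.45 / 1.56 / 2.25.
    return {
        TumorGroup.LOW_RISK_THYMOMA: ClassIodineParams(
            mean_enhanced_iodine=1.31 / 0.975,
            sd_inter=0.51,
            sd_intra=0.80,
            necrosis_fraction_range=(0.0, 0.05),
            target_ecv_mean=20.49,
            target_ecv_sd=7.22,
            fibrosis_probs=(0.60, 0.35, 0.05),
        ),
        TumorGroup.HIGH_RISK_THYMOMA: ClassIodineParams(
            mean_enhanced_iodine=1.20 / 0.85,
            sd_inter=0.36,
            sd_intra=0.86,
            necrosis_fraction_range=(0.05, 0.25),
            target_ecv_mean=18.65,
            target_ecv_sd=5.97,
            fibrosis_probs=(0.50, 0.44, 0.06),
        ),
        TumorGroup.THYMIC_CARCINOMA: ClassIodineParams(
            mean_enhanced_iodine=1.61 / 0.915,
            sd_inter=0.26,
            sd_intra=0.97,
            necrosis_fraction_range=(0.02, 0.15),
            target_ecv_mean=25.58,
            target_ecv_sd=4.67,
            fibrosis_probs=(0.0, 0.75, 0.25),
        ),
    }


def _default_cases_per_class() -> dict[TumorGroup, int]:
    return {
        TumorGroup.LOW_RISK_THYMOMA: 20,
        TumorGroup.HIGH_RISK_THYMOMA: 16,
        TumorGroup.THYMIC_CARCINOMA: 6,
    }


@dataclass
class PhantomConfig:
    """Full phantom-cohort configuration (see module docstring)."""

    grid_shape: tuple[int, int, int] = (56, 56, 36)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.25)  # mm
    tumor_radius_range: tuple[float, float] = (8.0, 14.0)  # mm, per-axis
    aorta: AortaParams = field(default_factory=AortaParams)
    unenhanced_noise_sd: float = 0.5  # mg/cc
    iodine_floor: float = DEFAULT_IODINE_FLOOR
    hematocrit_mean: float = 0.42
    hematocrit_sd: float = 0.05
    hematocrit_bounds: tuple[float, float] = (0.25, 0.55)
    class_params: dict[TumorGroup, ClassIodineParams] = field(
        default_factory=_default_class_params
    )
    cases_per_class: dict[TumorGroup, int] = field(
        default_factory=_default_cases_per_class
    )
    calibrate_ecv: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.hematocrit_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("hematocrit bounds must satisfy 0 < lo < hi < 1")
        if not (lo <= self.hematocrit_mean <= hi):
            raise ValidationError("hematocrit mean must lie within its bounds")
        if self.hematocrit_sd < 0:
            raise ValidationError("hematocrit sd must be >= 0")
        if self.unenhanced_noise_sd < 0:
            raise ValidationError("unenhanced noise sd must be >= 0")
        r_lo, r_hi = self.tumor_radius_range
        if not (0 < r_lo <= r_hi):
            raise ValidationError("tumor radius range must be positive and ordered")
        half_extent = [
            n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing)
        ]
        if r_hi > min(half_extent):
            raise ValidationError(
                f"tumor radius {r_hi} mm does not fit grid half-extent {half_extent}"
            )
        for g, n in self.cases_per_class.items():
            if n < 1:
                raise ValidationError(f"cases_per_class[{TumorGroup(g).value}] must be >= 1")

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "grid_shape": list(self.grid_shape),
            "spacing": list(self.spacing),
            "tumor_radius_range": list(self.tumor_radius_range),
            "aorta": dataclasses.asdict(self.aorta),
            "unenhanced_noise_sd": self.unenhanced_noise_sd,
            "iodine_floor": self.iodine_floor,
            "hematocrit_mean": self.hematocrit_mean,
            "hematocrit_sd": self.hematocrit_sd,
            "hematocrit_bounds": list(self.hematocrit_bounds),
            "class_params": {
                TumorGroup(g).value: {
                    **dataclasses.asdict(p),
                    "necrosis_fraction_range": list(p.necrosis_fraction_range),
                    "fibrosis_probs": list(p.fibrosis_probs),
                }
                for g, p in self.class_params.items()
            },
            "cases_per_class": {
                TumorGroup(g).value: int(n) for g, n in self.cases_per_class.items()
            },
            "calibrate_ecv": self.calibrate_ecv,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "aorta" in d:
            d["aorta"] = AortaParams(**d["aorta"])
        if "class_params" in d:
            d["class_params"] = {
                TumorGroup(g): ClassIodineParams(
                    **{
                        **p,
                        "necrosis_fraction_range": tuple(p["necrosis_fraction_range"]),
                        "fibrosis_probs": tuple(p.get("fibrosis_probs", (1, 0, 0))),
                    }
                )
                for g, p in d["class_params"].items()
            }
        if "cases_per_class" in d:
            d["cases_per_class"] = {
                TumorGroup(g): int(n) for g, n in d["cases_per_class"].items()
            }
        for key in ("grid_shape", "spacing", "tumor_radius_range", "hematocrit_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhantomConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def sample_hematocrit(config: PhantomConfig, rng: np.random.Generator) -> float:
    """Truncated-normal hematocrit draw within the configured bounds."""
    lo, hi = config.hematocrit_bounds
    if lo >= hi:
        raise ValidationError("degenerate hematocrit bounds")
    if config.hematocrit_sd == 0.0:
        return float(config.hematocrit_mean)
    for _ in range(10_000):  # rejection sampling; bounds are ~2.6 sd wide
        x = rng.normal(config.hematocrit_mean, config.hematocrit_sd)
        if lo <= x <= hi:
            return float(x)
    raise ValidationError("hematocrit rejection sampling failed; bounds too tight")


def _truncated_normal_min(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    if sd == 0.0:
        return max(float(mean), lo)
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x >= lo:
            return float(x)
    return lo


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    radii_mm: np.ndarray,
) -> np.ndarray:
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, radii_mm))
    return q <= 1.0


def _cylinder_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_xy_mm: tuple[float, float],
    radius_mm: float,
) -> np.ndarray:
    x = (np.arange(shape[0]) + 0.5) * spacing[0]
    y = (np.arange(shape[1]) + 0.5) * spacing[1]
    d2 = (x[:, None] - center_xy_mm[0]) ** 2 + (y[None, :] - center_xy_mm[1]) ** 2
    return np.broadcast_to((d2 <= radius_mm**2)[:, :, None], shape).copy()


# ---------------------------------------------------------------------------
# Case / cohort generation
# ---------------------------------------------------------------------------

def generate_case(
    config: PhantomConfig,
    group: TumorGroup,
    rng: np.random.Generator,
    case_id: str = "case",
) -> CaseRecord:
    """One synthetic case: paired volumes, masks, hematocrit, fibrosis grade."""
    group = TumorGroup(group)
    params = config.class_params[group]
    shape, spacing = config.grid_shape, config.spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])

    # Tumor: ellipsoid in the grid's far corner half; aorta cylinder near the
    # near corner.  Geometry keeps the two structures disjoint by construction.
    r_lo, r_hi = config.tumor_radius_range
    radii = rng.uniform(r_lo, r_hi, size=3)
    center = extent * 0.62 + rng.uniform(-1.5, 1.5, size=3)
    center[2] = extent[2] / 2.0 + rng.uniform(-1.5, 1.5)
    if np.any(center - radii < 0) or np.any(center + radii > extent):
        center = np.clip(center, radii, extent - radii)
    tumor = _ellipsoid_mask(shape, spacing, center, radii)
    if not tumor.any():
        raise ValidationError("tumor mask empty after rasterization")

    aorta_center = (config.aorta.radius_mm + 2.0, config.aorta.radius_mm + 2.0)
    aorta = _cylinder_mask(shape, spacing, aorta_center, config.aorta.radius_mm)
    aorta &= ~tumor
    if not aorta.any():
        raise ValidationError("aorta mask empty after rasterization")

    # Necrotic blob: sub-ellipsoid with volume fraction f of the VOI,
    # offset uniformly while staying inside the tumor.
    f_lo, f_hi = params.necrosis_fraction_range
    necrosis_fraction = rng.uniform(f_lo, f_hi)
    necrosis = np.zeros(shape, dtype=bool)
    if necrosis_fraction > 0.0:
        scale = necrosis_fraction ** (1.0 / 3.0)
        max_offset = radii * (1.0 - scale)
        offset = rng.uniform(-1.0, 1.0, size=3) * max_offset
        necrosis = _ellipsoid_mask(shape, spacing, center + offset, radii * scale)
        necrosis &= tumor

    hematocrit = sample_hematocrit(config, rng)
    mu_case = _truncated_normal_min(rng, params.mean_enhanced_iodine, params.sd_inter, 0.2)

    noise_sd = config.unenhanced_noise_sd
    unenh = rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else np.zeros(shape)
    enh = rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else np.zeros(shape)
    viable = tumor & ~necrosis
    enh[viable] = rng.normal(mu_case, params.sd_intra, size=int(viable.sum()))
    if necrosis.any():
        enh[necrosis] = rng.normal(0.0, params.sd_intra, size=int(necrosis.sum()))

    # Aortic enhancement: scaled so the expected ECV equals a per-case target
    # drawn from the class ECV distribution, given the drawn hematocrit.
    delta_tumor = float(enh[tumor].mean() - unenh[tumor].mean())
    if config.calibrate_ecv:
        ecv_target = _truncated_normal_min(
            rng, params.target_ecv_mean, params.target_ecv_sd, 5.0
        )
        delta_aorta = 100.0 * (1.0 - hematocrit) * max(delta_tumor, 0.05) / ecv_target
    else:
        delta_aorta = config.aorta.mean_enhanced_iodine
    aorta_unenh_mean = float(unenh[aorta].mean())
    if config.aorta.voxel_sd > 0:
        enh[aorta] = rng.normal(
            delta_aorta + aorta_unenh_mean, config.aorta.voxel_sd, size=int(aorta.sum())
        )
    else:
        enh[aorta] = delta_aorta + aorta_unenh_mean

    floor = config.iodine_floor
    np.clip(unenh, floor, None, out=unenh)
    np.clip(enh, floor, None, out=enh)

    fibrosis = int(rng.choice([1, 2, 3], p=params.fibrosis_probs))
    return CaseRecord(
        case_id=case_id,
        group=group,
        unenhanced=IodineVolume(unenh, spacing, Phase.UNENHANCED, floor=floor),
        enhanced=IodineVolume(enh, spacing, Phase.ENHANCED_180S, floor=floor),
        tumor_mask=RoiMask(tumor, MaskKind.TUMOR_VOI),
        aorta_mask=RoiMask(aorta, MaskKind.AORTA_ROI),
        hematocrit=hematocrit,
        fibrosis_grade=fibrosis,
    )


def generate_cohort(config: PhantomConfig) -> tuple[list[CaseRecord], CohortTable]:
    """Full cohort: per-class case counts from the config, features extracted.

    Deterministic under a fixed config+seed; each case consumes an
    independent child stream of the cohort seed.
    """
    order = [
        TumorGroup.LOW_RISK_THYMOMA,
        TumorGroup.HIGH_RISK_THYMOMA,
        TumorGroup.THYMIC_CARCINOMA,
    ]
    total = sum(config.cases_per_class[g] for g in order)
    streams = np.random.SeedSequence(config.seed).spawn(total)
    cases: list[CaseRecord] = []
    i = 0
    for group in order:
        for k in range(config.cases_per_class[group]):
            rng = np.random.default_rng(streams[i])
            case_id = f"{group.value}_{k:03d}"
            cases.append(generate_case(config, group, rng, case_id=case_id))
            i += 1
    return cases, extract_cohort(cases)
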