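"""Volume, mask and case-directory I/O.

Volumes and masks are stored as NIfTI-1 (``.nii`` / ``.nii.gz``) with a JSON
sidecar next to each file.  The sidecar carries acquisition metadata that
does not belong in the voxel grid — phase, declared iodine floor — and the
voxel spacing at full float precision (NIfTI header zooms are float32 and
would truncate spacings such as 0.674 mm).  The sidecar spacing wins on read.

A case directory bundles the four grids of one patient plus ``case.json``
with the scalar record (id, group, hematocrit, fibrosis grade).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .types import (
    CaseRecord,
    FormatError,
    IodineVolume,
    MaskKind,
    Phase,
    RoiMask,
    TumorGroup,
    ValidationError,
)

_VOLUME_FILES = {"unenhanced": Phase.UNENHANCED, "enhanced": Phase.ENHANCED_180S}
_MASK_FILES = {"tumor_mask": MaskKind.TUMOR_VOI, "aorta_mask": MaskKind.AORTA_ROI}


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name
    if name.endswith(".nii.gz"):
        stem = name[: -len(".nii.gz")]
    elif name.endswith(".nii"):
        stem = name[: -len(".nii")]
    else:
        raise FormatError(f"expected a .nii or .nii.gz file, got {path}")
    return path.with_name(stem + ".json")


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(vol: IodineVolume, path: str | Path) -> None:
    """Write volume + sidecar; voxels are stored as float64 (lossless)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.voxels.astype(np.float64), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    meta = {
        "phase": vol.phase.value,
        "spacing_mm": list(vol.spacing),
        "iodine_floor_mg_cc": vol.floor,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2), encoding="utf-8")


def read_volume(path: str | Path, phase: Optional[Phase] = None) -> IodineVolume:
    """Read a 3D iodine volume; phase comes from the sidecar or `phase`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"not a readable NIfTI volume: {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got ndim={data.ndim} in {path}")

    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text(encoding="utf-8"))

    if "spacing_mm" in meta:
        spacing = tuple(float(s) for s in meta["spacing_mm"])
    else:
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise FormatError(f"non-positive voxel spacing {spacing} in {path}")

    if phase is None:
        if "phase" not in meta:
            raise FormatError(
                f"phase not given and no sidecar metadata found for {path}"
            )
        phase = Phase(meta["phase"])
    floor = meta.get("iodine_floor_mg_cc")
    return IodineVolume(voxels=data, spacing=spacing, phase=phase, floor=floor)


def write_mask(mask: RoiMask, spacing: tuple[float, float, float], path: str | Path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))
    meta = {"kind": mask.kind.value, "spacing_mm": list(spacing)}
    sidecar_path(path).write_text(json.dumps(meta, indent=2), encoding="utf-8")


def read_mask(path: str | Path, kind: Optional[MaskKind] = None) -> RoiMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D mask, got ndim={data.ndim} in {path}")
    if kind is None:
        sc = sidecar_path(path)
        if not sc.exists():
            raise FormatError(f"mask kind not given and no sidecar for {path}")
        kind = MaskKind(json.loads(sc.read_text(encoding="utf-8"))["kind"])
    return RoiMask(voxels=data > 0, kind=kind)


# ---------------------------------------------------------------------------
# Case directories
# ---------------------------------------------------------------------------

def write_case(case: CaseRecord, case_dir: str | Path) -> None:
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    write_volume(case.unenhanced, case_dir / "unenhanced.nii.gz")
    write_volume(case.enhanced, case_dir / "enhanced.nii.gz")
    write_mask(case.tumor_mask, case.enhanced.spacing, case_dir / "tumor_mask.nii.gz")
    write_mask(case.aorta_mask, case.enhanced.spacing, case_dir / "aorta_mask.nii.gz")
    record = {
        "case_id": case.case_id,
        "group": case.group.value,
        "hematocrit": case.hematocrit,
        "fibrosis_grade": case.fibrosis_grade,
    }
    (case_dir / "case.json").write_text(json.dumps(record, indent=2), encoding="utf-8")


def read_case(case_dir: str | Path) -> CaseRecord:
    case_dir = Path(case_dir)
    record_path = case_dir / "case.json"
    if not record_path.exists():
        raise FormatError(f"{case_dir} is not a case directory (no case.json)")
    record = json.loads(record_path.read_text(encoding="utf-8"))
    vols = {
        name: read_volume(case_dir / f"{name}.nii.gz", phase)
        for name, phase in _VOLUME_FILES.items()
    }
    masks = {
        name: read_mask(case_dir / f"{name}.nii.gz", kind)
        for name, kind in _MASK_FILES.items()
    }
    return CaseRecord(
        case_id=record["case_id"],
        group=TumorGroup(record["group"]),
        unenhanced=vols["unenhanced"],
        enhanced=vols["enhanced"],
        tumor_mask=masks["tumor_mask"],
        aorta_mask=masks["aorta_mask"],
        hematocrit=float(record["hematocrit"]),
        fibrosis_grade=record.get("fibrosis_grade"),
    )
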