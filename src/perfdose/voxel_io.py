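"""Voxel volumes: containers, file formats, label-to-HU conversion, resampling.

The in-memory currency of the pipeline is :class:`VoxelVolume`: a 3-D array
indexed ``[x, y, z]`` with x = lateral (LAT), y = anterior-posterior (AP) and
z = longitudinal (increasing toward the head), plus physical spacing and
origin in mm.  Voxel centres sit at ``origin + (index + 0.5) * spacing``.

Supported on-disk formats: NIfTI (.nii/.nii.gz), MetaImage (.mhd/.raw),
DICOM series directories (read-only) and a pinned raw+JSON dialect for
integer label phantoms (16-bit little-endian values, JSON sidecar with dims,
spacing and label map).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelVolume",
    "DEFAULT_HU_MAP",
    "BASE_TISSUE_OF",
    "read_volume",
    "write_volume",
    "labels_to_hu",
    "resample_nearest",
]

HU_MIN = -1024
HU_MAX = 65535  # upper bound of the iron conversion bin

#: HU assigned to the six base tissues when converting a labelled phantom.
DEFAULT_HU_MAP = {
    "air": -1000,
    "lung": -700,
    "adipose": -100,
    "soft_tissue": 30,
    "blood": 200,
    "bone": 1000,
}

#: Organ/tissue names mapped onto the six base tissues of the HU map.
#: Cortical bone, spongiosa and medullary cavity are all treated as bone.
BASE_TISSUE_OF = {
    "cortical_bone": "bone",
    "spongiosa": "bone",
    "medullary_cavity": "bone",
    "bones": "bone",
    "blood_pool": "blood",
    "lungs": "lung",
    "breasts": "adipose",
    "breast": "adipose",
    "skin": "soft_tissue",
    "muscle": "soft_tissue",
    "table": "soft_tissue",
}


class VolumeFormatError(ValueError):
    """Raised for unreadable or inconsistent volume files."""


@dataclass
class VoxelVolume:
    """3-D voxel grid with physical geometry and a value-role tag.

    Parameters
    ----------
    values:
        Array of shape (nx, ny, nz); HU (int), labels (int) or dose (float,
        mGy) depending on ``role``.
    spacing:
        mm per voxel along (x, y, z); all positive.
    origin:
        mm position of the corner of voxel (0, 0, 0).
    role:
        One of ``"hu"``, ``"label"``, ``"dose"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "hu"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("volume must be a 3-D array with >=1 voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive floats (mm)")
        self.origin = tuple(float(o) for o in self.origin)
        if self.role not in ("hu", "label", "dose"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "hu":
            vmin, vmax = self.values.min(), self.values.max()
            if vmin < HU_MIN or vmax > HU_MAX:
                raise ValueError(
                    f"HU values outside [{HU_MIN}, {HU_MAX}]: range [{vmin}, {vmax}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self, **changes) -> "VoxelVolume":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        return out


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".mhd"):
        return "metaimage"
    if name.endswith(".raw"):
        return "rawjson"
    if path.is_dir():
        return "dicom"
    raise VolumeFormatError(f"cannot infer volume format from {path}")


def read_volume(path, fmt: str | None = None, role: str = "hu") -> VoxelVolume:
    """Read a volume from disk, normalising axes to (x=LAT, y=AP, z=long)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "nifti":
        return _read_nifti(path, role)
    if fmt == "metaimage":
        return _read_metaimage(path, role)
    if fmt == "dicom":
        return _read_dicom_series(path)
    if fmt == "rawjson":
        return _read_rawjson(path)
    raise VolumeFormatError(f"unknown format {fmt!r}")


def write_volume(volume: VoxelVolume, path, fmt: str | None = None) -> Path:
    """Write a volume; lossless for integer roles, float32 for dose."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "nifti":
        _write_nifti(volume, path)
    elif fmt == "metaimage":
        _write_metaimage(volume, path)
    elif fmt == "rawjson":
        _write_rawjson(volume, path)
    elif fmt == "dicom":
        raise VolumeFormatError("DICOM writing is not supported")
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")
    return path


def _dtype_for(volume: VoxelVolume):
    if volume.role == "dose":
        return np.float32
    # HU may exceed int16 (iron bin reaches 64535)
    if volume.role == "hu" and volume.values.max() > 32767:
        return np.int32
    return np.int32 if volume.role == "label" and volume.values.max() > 32767 else np.int16


def _read_nifti(path: Path, role: str) -> VoxelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3-D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if np.issubdtype(data.dtype, np.floating) and role != "dose":
        data = np.rint(data).astype(np.int32)
    return VoxelVolume(data, tuple(float(z) for z in zooms), origin, role=role)


def _write_nifti(volume: VoxelVolume, path: Path) -> None:
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values.astype(_dtype_for(volume)), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def _read_metaimage(path: Path, role: str) -> VoxelVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.transpose(arr, (2, 1, 0))
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(float(o) for o in img.GetOrigin())
    if np.issubdtype(data.dtype, np.floating) and role != "dose":
        data = np.rint(data).astype(np.int32)
    return VoxelVolume(data, spacing, origin, role=role)


def _write_metaimage(volume: VoxelVolume, path: Path) -> None:
    import SimpleITK as sitk

    arr = np.ascontiguousarray(
        np.transpose(volume.values.astype(_dtype_for(volume)), (2, 1, 0))
    )
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    sitk.WriteImage(img, str(path))


def _read_dicom_series(path: Path) -> VoxelVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise VolumeFormatError(f"{path}: no .dcm files in directory")
    slices = [pydicom.dcmread(str(f)) for f in files]
    try:
        slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    except AttributeError as exc:
        raise VolumeFormatError(f"{path}: missing ImagePositionPatient") from exc
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.ptp(dz) > 0.01:
            raise VolumeFormatError(
                f"{path}: inconsistent DICOM slice spacing (spread {np.ptp(dz):.4f} mm)"
            )
        slice_spacing = float(dz.mean())
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0))
    first = slices[0]
    try:
        py, px = (float(v) for v in first.PixelSpacing)
    except AttributeError as exc:
        raise VolumeFormatError(f"{path}: missing PixelSpacing") from exc
    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # pixel_array rows are y (AP), columns x (LAT)
    data = np.stack([np.rint(p).astype(np.int32).T for p in planes], axis=2)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return VoxelVolume(data, (px, py, slice_spacing), origin, role="hu")


def _read_rawjson(path: Path) -> VoxelVolume:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise VolumeFormatError(f"{path}: missing JSON sidecar {sidecar.name}")
    header = json.loads(sidecar.read_text())
    for key in ("dims", "spacing"):
        if key not in header:
            raise VolumeFormatError(f"{path}: sidecar missing field {key!r}")
    dims = tuple(int(d) for d in header["dims"])
    raw = np.fromfile(path, dtype="<u2")
    if raw.size != int(np.prod(dims)):
        raise VolumeFormatError(
            f"{path}: {raw.size} voxels in file but dims {dims} imply {int(np.prod(dims))}"
        )
    data = raw.reshape(dims[::-1]).transpose(2, 1, 0).astype(np.int32)
    vol = VoxelVolume(
        data,
        tuple(float(s) for s in header["spacing"]),
        tuple(float(o) for o in header.get("origin", (0, 0, 0))),
        role="label",
    )
    if "label_map" in header:
        vol.meta["label_map"] = {int(k): v for k, v in header["label_map"].items()}
    return vol


def _write_rawjson(volume: VoxelVolume, path: Path) -> None:
    if volume.role == "dose":
        raise VolumeFormatError("raw+JSON phantom format stores integer labels only")
    if volume.values.min() < 0 or volume.values.max() > 0xFFFF:
        raise VolumeFormatError("raw+JSON stores unsigned 16-bit values")
    arr = volume.values.astype("<u2").transpose(2, 1, 0)
    arr.tofile(path)
    header = {
        "dims": list(volume.shape),
        "spacing": list(volume.spacing),
        "origin": list(volume.origin),
    }
    if "label_map" in volume.meta:
        header["label_map"] = {str(k): v for k, v in volume.meta["label_map"].items()}
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


# ---------------------------------------------------------------------------
# label -> HU and resampling
# ---------------------------------------------------------------------------

def labels_to_hu(
    labels: VoxelVolume,
    tissue_map: dict[int, str],
    hu_map: dict[str, int] | None = None,
    variant: str = "plain",
) -> VoxelVolume:
    """Convert a labelled phantom to phantom-based HU values.

    ``variant="contrast"`` raises blood to 500 HU to emulate iodinated
    contrast; every bone compartment (cortical bone, spongiosa, medullary
    cavity) maps to the single bone HU.
    """
    if variant not in ("plain", "contrast"):
        raise ValueError(f"unknown variant {variant!r}")
    hu_map = dict(DEFAULT_HU_MAP if hu_map is None else hu_map)
    if variant == "contrast":
        hu_map["blood"] = 500
    present = np.unique(labels.values)
    unmapped = [int(l) for l in present if int(l) not in tissue_map]
    if unmapped:
        raise KeyError(f"labels without tissue assignment: {unmapped}")

    lut_size = int(present.max()) + 1
    lut = np.zeros(lut_size, dtype=np.int32)
    for label in present:
        tissue = tissue_map[int(label)]
        base = tissue if tissue in hu_map else BASE_TISSUE_OF.get(tissue)
        if base is None or base not in hu_map:
            raise KeyError(f"tissue {tissue!r} (label {int(label)}) has no HU mapping")
        lut[int(label)] = hu_map[base]
    out = lut[labels.values]
    return VoxelVolume(out, labels.spacing, labels.origin, role="hu")


def resample_nearest(volume: VoxelVolume, target_spacing) -> VoxelVolume:
    """Nearest-neighbour resampling onto ``target_spacing``.

    Each target voxel centre maps to the nearest source voxel centre; exact
    ties break toward the lower index.  The physical extent is preserved to
    within one target voxel and label volumes never acquire new values.
    """
    target_spacing = tuple(float(s) for s in np.broadcast_to(target_spacing, (3,)))
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    if np.allclose(target_spacing, volume.spacing):
        return volume.copy()
    idx = []
    for ax in range(3):
        n_src = volume.shape[ax]
        extent = n_src * volume.spacing[ax]
        n_tgt = max(1, int(round(extent / target_spacing[ax])))
        centers = (np.arange(n_tgt) + 0.5) * target_spacing[ax]
        u = centers / volume.spacing[ax] - 0.5
        j = np.ceil(u - 0.5).astype(np.intp)  # ties toward lower index
        idx.append(np.clip(j, 0, n_src - 1))
    out = volume.values[np.ix_(*idx)]
    return VoxelVolume(out, target_spacing, volume.origin, role=volume.role, meta=dict(volume.meta))
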