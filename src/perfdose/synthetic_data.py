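"""Synthetic patient CT volumes and miniature reference phantoms.

The dosimetry pipeline needs two kinds of input that cannot be shipped with
the package: contrast-enhanced thorax CT volumes and a labelled whole-body
reference voxel phantom.  This module generates miniature stand-ins for both
with exact, analytic ground truth: every organ is a quadric (ellipsoid or
cylinder) voxelised by centre-of-voxel inclusion, so segmentations are known
exactly at any resolution.

The patient-like volume emulates a thorax CTA acquisition: lungs, heart with
an iodine-enhanced blood pool (configurable HU), breasts, spine and ribs, a
partially visible patient support table below the body, Gaussian HU noise and
an optional lateral field-of-view truncation that removes peripheral adipose
tissue.  The reference phantom is a head-to-thigh labelled volume carrying
every tissue the effective-dose computation needs; organs far outside a
thorax scan (brain, bladder, gonads, ...) are small token regions placed in
anatomical order along the body axis so that scatter-dose falloff with
distance from the scan range is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .voxel_io import VoxelVolume, DEFAULT_HU_MAP

__all__ = [
    "SyntheticPhantomSpec",
    "OrganShape",
    "make_patient_volume",
    "make_reference_phantom",
    "make_table_arc",
]

HU_CLIP = (-1024, 3071)


class OrganCollisionError(ValueError):
    """Two organ shapes claim the same voxels."""


@dataclass
class OrganShape:
    """Analytic organ: ellipsoid or z-aligned cylinder.

    ``center`` and ``size`` are in mm; for ellipsoids ``size`` holds the three
    semi-axes, for cylinders ``(radius, radius, half_length)``.  ``center`` is
    relative to the torso centre in-plane and to the grid bottom along z.
    ``carve_into`` names organs this shape is allowed to replace (e.g. the
    blood pool sits inside the heart).
    """

    kind: str  # "ellipsoid" | "cylinder"
    center: tuple[float, float, float]
    size: tuple[float, float, float]
    tissue: str  # base tissue for HU assignment
    carve_into: tuple[str, ...] = ()


@dataclass
class SyntheticPhantomSpec:
    """Parameters of a synthetic thorax case or reference phantom."""

    shape: tuple[int, int, int] = (96, 96, 32)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    torso_semiaxes: tuple[float, float] = (80.0, 60.0)  # (LAT, AP) mm
    adipose_shell_fraction: float = 0.18  # of the elliptical radius
    enhancement_hu: int = 500
    blood_gradient: bool = False
    table_radius_mm: float = 78.0
    table_thickness_mm: float = 6.0
    table_extent_rad: float = 1.2
    table_hu: int = 100
    truncation_fraction: float = 0.0
    noise_sd: float = 5.0
    seed: int = 0
    organs: dict[str, OrganShape] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 200 <= self.enhancement_hu <= 771:
            raise ValueError("enhancement HU must lie in [200, 771]")
        if not 0.0 <= self.truncation_fraction <= 1.0:
            raise ValueError("truncation fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticPhantomSpec":
        raw = yaml.safe_load(Path(path).read_text())
        organs = {
            name: OrganShape(
                kind=o["kind"],
                center=tuple(o["center"]),
                size=tuple(o["size"]),
                tissue=o["tissue"],
                carve_into=tuple(o.get("carve_into", ())),
            )
            for name, o in raw.pop("organs", {}).items()
        }
        for key in ("shape", "spacing", "torso_semiaxes"):
            raw[key] = tuple(raw[key])
        return cls(organs=organs, **raw)

    @classmethod
    def reference_default(cls, seed: int = 0) -> "SyntheticPhantomSpec":
        return cls(
            shape=(120, 100, 110),
            spacing=(1.775, 1.775, 4.84),
            noise_sd=0.0,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grids(spec: SyntheticPhantomSpec):
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    x = (np.arange(nx) + 0.5) * sx - nx * sx / 2.0
    y = (np.arange(ny) + 0.5) * sy - ny * sy / 2.0
    z = (np.arange(nz) + 0.5) * sz
    return np.meshgrid(x, y, z, indexing="ij", sparse=True)


def _shape_mask(shape: OrganShape, X, Y, Z) -> np.ndarray:
    cx, cy, cz = shape.center
    a, b, c = shape.size
    if shape.kind == "ellipsoid":
        return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
    if shape.kind == "cylinder":
        inplane = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
        return inplane & (np.abs(Z - cz) <= c)
    raise ValueError(f"unknown organ kind {shape.kind!r}")


def _torso_rho(spec: SyntheticPhantomSpec, X, Y) -> np.ndarray:
    a, b = spec.torso_semiaxes
    return np.sqrt((X / a) ** 2 + (Y / b) ** 2)


def _thorax_organs(spec: SyntheticPhantomSpec, z_lo: float, z_hi: float) -> dict[str, OrganShape]:
    a, b = spec.torso_semiaxes
    zc = 0.5 * (z_lo + z_hi)
    hz = 0.5 * (z_hi - z_lo)
    organs = {
        "lung_left": OrganShape("ellipsoid", (-0.54 * a, 0.12 * b, zc), (0.24 * a, 0.45 * b, 0.85 * hz), "lung"),
        "lung_right": OrganShape("ellipsoid", (0.54 * a, 0.12 * b, zc), (0.24 * a, 0.45 * b, 0.85 * hz), "lung"),
        "heart": OrganShape("ellipsoid", (-0.06 * a, -0.32 * b, zc), (0.22 * a, 0.26 * b, 0.60 * hz), "soft_tissue"),
        "blood_pool": OrganShape(
            "ellipsoid", (-0.06 * a, -0.32 * b, zc), (0.13 * a, 0.15 * b, 0.40 * hz), "blood",
            carve_into=("heart",),
        ),
        "breast_left": OrganShape("ellipsoid", (-0.40 * a, -0.66 * b, zc), (0.20 * a, 0.18 * b, 0.45 * hz), "adipose"),
        "breast_right": OrganShape("ellipsoid", (0.40 * a, -0.66 * b, zc), (0.20 * a, 0.18 * b, 0.45 * hz), "adipose"),
        "spine": OrganShape("cylinder", (0.0, 0.70 * b, zc), (0.13 * a, 0.13 * a, hz), "bone"),
        "spongiosa": OrganShape("cylinder", (0.0, 0.70 * b, zc), (0.07 * a, 0.07 * a, hz), "bone",
                                carve_into=("spine",)),
        "rib_left": OrganShape("cylinder", (-0.88 * a, 0.0, zc), (0.05 * a, 0.05 * a, 0.9 * hz), "bone"),
        "rib_right": OrganShape("cylinder", (0.88 * a, 0.0, zc), (0.05 * a, 0.05 * a, 0.9 * hz), "bone"),
        "oesophagus": OrganShape("cylinder", (0.10 * a, 0.42 * b, zc), (0.045 * a, 0.045 * a, hz), "soft_tissue"),
    }
    return organs


def _token(name: str, x_frac: float, z_mm: float, spec: SyntheticPhantomSpec,
           tissue: str = "soft_tissue", r_mm: float = 9.0) -> OrganShape:
    a, b = spec.torso_semiaxes
    return OrganShape("ellipsoid", (x_frac * a, 0.10 * b, z_mm), (r_mm, r_mm, r_mm), tissue)


def default_patient_organs(spec: SyntheticPhantomSpec) -> dict[str, OrganShape]:
    nz_mm = spec.shape[2] * spec.spacing[2]
    return _thorax_organs(spec, 0.0, nz_mm)


def default_reference_organs(spec: SyntheticPhantomSpec) -> dict[str, OrganShape]:
    """Head-to-thigh organ layout with token organs in anatomical z-order."""
    L = spec.shape[2] * spec.spacing[2]
    th_lo, th_hi = 0.55 * L, 0.82 * L
    organs = _thorax_organs(spec, th_lo, th_hi)
    a, b = spec.torso_semiaxes
    # thorax extras
    organs["thymus"] = _token("thymus", -0.05, 0.795 * L, spec, r_mm=7.0)
    organs["lymphatic_nodes"] = _token("lymphatic_nodes", -0.70, 0.52 * L, spec, r_mm=6.0)
    # neck / head
    organs["thyroid"] = _token("thyroid", 0.0, 0.845 * L, spec, r_mm=6.0)
    organs["extrathoracic"] = _token("extrathoracic", 0.0, 0.865 * L, spec, r_mm=6.0)
    organs["oral_mucosa"] = _token("oral_mucosa", 0.0, 0.885 * L, spec, r_mm=6.0)
    organs["salivary_glands"] = _token("salivary_glands", 0.18, 0.90 * L, spec, r_mm=6.0)
    organs["brain"] = _token("brain", 0.0, 0.95 * L, spec, r_mm=12.0)
    # abdomen
    organs["liver"] = OrganShape("ellipsoid", (0.30 * a, -0.05 * b, 0.50 * L), (0.33 * a, 0.33 * b, 0.07 * L), "soft_tissue")
    organs["stomach"] = _token("stomach", -0.50, 0.50 * L, spec, r_mm=10.0)
    organs["spleen"] = OrganShape("ellipsoid", (-0.55 * a, 0.45 * b, 0.47 * L), (10.0, 10.0, 12.0), "soft_tissue")
    organs["gall_bladder"] = _token("gall_bladder", 0.25, 0.415 * L, spec, r_mm=5.0)
    organs["pancreas"] = _token("pancreas", -0.30, 0.445 * L, spec, r_mm=7.0)
    organs["adrenals"] = _token("adrenals", -0.12, 0.415 * L, spec, r_mm=5.0)
    organs["kidney_left"] = OrganShape("ellipsoid", (-0.40 * a, 0.45 * b, 0.42 * L), (9.0, 9.0, 14.0), "soft_tissue")
    organs["kidney_right"] = OrganShape("ellipsoid", (0.40 * a, 0.45 * b, 0.42 * L), (9.0, 9.0, 14.0), "soft_tissue")
    organs["small_intestine"] = OrganShape("ellipsoid", (0.0, -0.15 * b, 0.375 * L), (0.30 * a, 0.28 * b, 0.035 * L), "soft_tissue")
    organs["colon"] = OrganShape("ellipsoid", (0.0, 0.05 * b, 0.315 * L), (0.33 * a, 0.25 * b, 0.02 * L), "soft_tissue")
    # pelvis
    organs["urinary_bladder"] = _token("urinary_bladder", 0.0, 0.24 * L, spec, r_mm=8.0)
    organs["uterus"] = _token("uterus", 0.0, 0.27 * L, spec, r_mm=7.0)
    organs["gonads"] = _token("gonads", 0.25, 0.215 * L, spec, r_mm=5.0)
    # thighs: femur with medullary cavity
    organs["femur_left"] = OrganShape("cylinder", (-0.35 * a, 0.0, 0.09 * L), (0.08 * a, 0.08 * a, 0.09 * L), "bone")
    organs["femur_right"] = OrganShape("cylinder", (0.35 * a, 0.0, 0.09 * L), (0.08 * a, 0.08 * a, 0.09 * L), "bone")
    organs["medullary_cavity"] = OrganShape(
        "cylinder", (-0.35 * a, 0.0, 0.09 * L), (0.04 * a, 0.04 * a, 0.09 * L), "bone",
        carve_into=("femur_left",),
    )
    return organs


#: organ label name -> base tissue used for HU conversion
_ORGAN_TISSUE = {
    "lung_left": "lung", "lung_right": "lung",
    "blood_pool": "blood",
    "spine": "bone", "rib_left": "bone", "rib_right": "bone",
    "spongiosa": "bone", "femur_left": "bone", "femur_right": "bone",
    "medullary_cavity": "bone",
    "breast_left": "adipose", "breast_right": "adipose",
}


def _paint(spec: SyntheticPhantomSpec, organs: dict[str, OrganShape]):
    """Rasterise body + organs; returns (labels int16, name->id, id->tissue)."""
    X, Y, Z = _grids(spec)
    rho = _torso_rho(spec, X, Y)
    body = np.broadcast_to(rho <= 1.0, spec.shape)
    shell = body & np.broadcast_to(rho > 1.0 - spec.adipose_shell_fraction, spec.shape)

    labels = np.zeros(spec.shape, dtype=np.int16)
    name_to_id = {"air": 0, "adipose_shell": 1, "muscle": 2}
    tissue_of = {0: "air", 1: "adipose", 2: "soft_tissue"}
    labels[body] = 2
    labels[shell] = 1
    body_ids = (0, 1, 2)

    next_id = 3
    id_of_name = {}
    for name, shape in organs.items():
        mask = _shape_mask(shape, X, Y, Z) & body
        if not mask.any():
            raise ValueError(f"grid too small: organ {name!r} has no voxels inside the torso")
        current = labels[mask]
        allowed = set(body_ids) | {id_of_name[c] for c in shape.carve_into if c in id_of_name}
        clash = set(np.unique(current)) - allowed
        if clash:
            other = [n for n, i in id_of_name.items() if i in clash]
            raise OrganCollisionError(f"organ {name!r} overlaps {other}")
        labels[mask] = next_id
        id_of_name[name] = next_id
        name_to_id[name] = next_id
        tissue_of[next_id] = shape.tissue
        next_id += 1
    return labels, name_to_id, tissue_of


def make_table_arc(spec: SyntheticPhantomSpec) -> VoxelVolume:
    """Boolean mask of a circular-arc patient-support table below the body.

    The arc is a shell of the circle centred on the torso axis with radius
    ``table_radius_mm`` and thickness ``table_thickness_mm``, spanning
    ``table_extent_rad`` symmetric about the downward (anterior, -y)
    direction.  Raises if the shell would intersect the torso.
    """
    X, Y, Z = _grids(spec)
    r_out = spec.table_radius_mm
    r_in = r_out - spec.table_thickness_mm
    if spec.table_extent_rad <= 0:
        return VoxelVolume(np.zeros(spec.shape, dtype=bool), spec.spacing, role="label")
    r = np.sqrt(X**2 + Y**2)
    # angle measured from the -y (table-side) direction
    ang = np.abs(np.arctan2(X, -Y))
    mask = (r >= r_in) & (r <= r_out) & (ang <= spec.table_extent_rad / 2.0)
    mask = np.broadcast_to(mask, np.broadcast_shapes(mask.shape, Z.shape)).copy()
    if (mask & (_torso_rho(spec, X, Y) <= 1.0)).any():
        raise ValueError("table arc intersects the torso; increase table_radius_mm")
    return VoxelVolume(mask, spec.spacing, role="label")


def make_patient_volume(spec: SyntheticPhantomSpec):
    """Generate a patient-like thorax HU volume and its ground-truth labels.

    Returns ``(hu_volume, truth)``; ``truth.meta["label_map"]`` maps label ids
    to organ names and ``truth.meta["tissue_map"]`` to base tissues.  The
    blood pool receives ``spec.enhancement_hu`` (uniform, or a linear lateral
    ramp from 200 HU up to the enhancement level when ``blood_gradient``);
    Gaussian noise of ``spec.noise_sd`` HU is added and clipped to the CT
    number range [-1024, 3071].
    """
    organs = spec.organs or default_patient_organs(spec)
    labels, name_to_id, tissue_of = _paint(spec, organs)
    rng = np.random.default_rng(spec.seed)

    hu = np.empty(spec.shape, dtype=np.float64)
    for label_id, tissue in tissue_of.items():
        hu[labels == label_id] = DEFAULT_HU_MAP[tissue]

    if "blood_pool" in name_to_id:
        pool = labels == name_to_id["blood_pool"]
        if spec.blood_gradient:
            X, _, _ = _grids(spec)
            xs = np.broadcast_to(X, spec.shape)[pool]
            span = xs.max() - xs.min()
            frac = (xs - xs.min()) / span if span > 0 else np.ones_like(xs)
            hu[pool] = 200.0 + frac * (spec.enhancement_hu - 200.0)
        else:
            hu[pool] = spec.enhancement_hu

    table = make_table_arc(spec).values
    hu[table] = spec.table_hu
    labels = labels.copy()
    table_id = labels.max() + 1
    labels[table] = table_id
    name_to_id["table"] = int(table_id)
    tissue_of[int(table_id)] = "soft_tissue"

    if spec.truncation_fraction > 0:
        X, Y, _ = _grids(spec)
        rho = _torso_rho(spec, X, Y)
        a, b = spec.torso_semiaxes
        lateral = np.abs(X) / a > np.abs(Y) / b
        cut = (rho > 1.0 - spec.adipose_shell_fraction * spec.truncation_fraction) & lateral
        cut = np.broadcast_to(cut, spec.shape) & (labels == name_to_id["adipose_shell"])
        hu[cut] = DEFAULT_HU_MAP["air"]
        labels[cut] = 0

    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    hu = np.clip(np.rint(hu), *HU_CLIP).astype(np.int16)

    truth = VoxelVolume(labels, spec.spacing, role="label",
                        meta={"label_map": {v: k for k, v in name_to_id.items()},
                              "tissue_map": dict(tissue_of)})
    return VoxelVolume(hu, spec.spacing, role="hu"), truth


def make_reference_phantom(spec: SyntheticPhantomSpec | None = None):
    """Generate a miniature head-to-thigh labelled reference phantom.

    Returns ``(labels, tissue_map)``; the tissue map sends every label to one
    of the base tissues (air, lung, adipose, soft tissue, blood, bone), while
    ``labels.meta["label_map"]`` keeps the organ identity of each label.  The
    default spacing follows the reference adult-female voxel phantom
    (1.775 mm in-plane, 4.84 mm slices).  Deterministic given the spec.
    """
    spec = spec or SyntheticPhantomSpec.reference_default()
    organs = spec.organs or default_reference_organs(spec)
    labels, name_to_id, tissue_of = _paint(spec, organs)
    # skin: the outermost voxel layer of the body contour
    from scipy import ndimage

    body = labels > 0
    skin = body & ~ndimage.binary_erosion(body)
    skin_id = int(labels.max()) + 1
    labels = labels.copy()
    labels[skin & np.isin(labels, [1, 2])] = skin_id
    name_to_id["skin"] = skin_id
    tissue_of[skin_id] = "soft_tissue"
    vol = VoxelVolume(labels, spec.spacing, role="label",
                      meta={"label_map": {v: k for k, v in name_to_id.items()},
                            "tissue_map": dict(tissue_of)})
    return vol, dict(tissue_of)
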