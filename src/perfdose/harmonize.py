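"""Patient-phantom harmonisation: the preprocessing chain before simulation.

A thorax CT volume covers only part of the body; for organ doses outside the
scan range the patient data are merged with a whole-body reference phantom.
The chain, applied in order:

1. remove the patient support table from the CT volume;
2. resample patient and phantom to a common grid (default 0.98 mm in-plane,
   3 mm slices, nearest-neighbour);
3. identify corresponding junction slices (config input; a helper suggests
   candidates but never auto-commits);
4. rescale the phantom in-plane so the body cross-sectional areas agree at
   the lower junction;
5. splice patient slices into the phantom between the junctions;
6. re-insert the table;
7. append missing peripheral adipose as a circle segment per slice.

All resampling/rescaling is nearest-neighbour, so label volumes stay valid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .voxel_io import VoxelVolume, resample_nearest

__all__ = [
    "MergeConfig",
    "remove_table",
    "add_table",
    "body_area",
    "junction_scale_factor",
    "rescale_phantom_inplane",
    "merge_patient_phantom",
    "add_adipose_segment",
    "effective_diameter",
    "suggest_junctions",
]

log = logging.getLogger("perfdose.harmonize")

AIR_HU = -1000
ADIPOSE_HU = -100
BODY_THRESHOLD_HU = -300  # lungs stay inside the closed body contour
TABLE_HU_DEFAULT = 100


@dataclass
class MergeConfig:
    """Junctions and options for the patient-phantom merge.

    Junction slice indices are inclusive; the patient block
    ``[patient_lower, patient_upper]`` replaces the phantom block
    ``[phantom_lower, phantom_upper]``.
    """

    patient_lower: int
    patient_upper: int
    phantom_lower: int
    phantom_upper: int
    body_threshold_hu: int = BODY_THRESHOLD_HU
    table_hu: int = TABLE_HU_DEFAULT
    scale_bounds: tuple[float, float] = (0.5, 2.0)

    def validate(self, patient_nz: int, phantom_nz: int) -> None:
        if not (0 <= self.patient_lower <= self.patient_upper < patient_nz):
            raise ValueError("patient junction indices outside the patient volume")
        if not (0 <= self.phantom_lower <= self.phantom_upper < phantom_nz):
            raise ValueError("phantom junction indices outside the phantom volume")


# ---------------------------------------------------------------------------
# table handling
# ---------------------------------------------------------------------------

def _body_mask(values: np.ndarray, threshold: int) -> np.ndarray:
    return values >= threshold


def remove_table(hu_volume: VoxelVolume, table_mask: np.ndarray,
                 body_threshold: int = BODY_THRESHOLD_HU) -> VoxelVolume:
    """Set table voxels to air; idempotent; errors if the mask touches the body."""
    table_mask = np.asarray(table_mask, dtype=bool)
    if table_mask.shape != hu_volume.shape:
        raise ValueError("table mask shape differs from volume shape")
    body = _body_mask(hu_volume.values, body_threshold) & ~table_mask
    # the mask may not claim voxels connected to the body contour
    dil = ndimage.binary_dilation(table_mask)
    if (dil & body).sum() > 0 and (table_mask & body).any():
        raise ValueError("table mask overlaps the body contour")
    out = hu_volume.values.copy()
    out[table_mask] = AIR_HU
    return hu_volume.copy(values=out)


def add_table(hu_volume: VoxelVolume, table_mask: np.ndarray,
              table_hu: int = TABLE_HU_DEFAULT,
              body_threshold: int = BODY_THRESHOLD_HU) -> VoxelVolume:
    """Insert the table at ``table_hu`` (default 100 HU); idempotent."""
    table_mask = np.asarray(table_mask, dtype=bool)
    if table_mask.shape != hu_volume.shape:
        raise ValueError("table mask shape differs from volume shape")
    body = _body_mask(hu_volume.values, body_threshold)
    out = hu_volume.values.copy()
    out[table_mask & ~body] = table_hu
    return hu_volume.copy(values=out)


# ---------------------------------------------------------------------------
# areas, junctions, scaling
# ---------------------------------------------------------------------------

def body_area(hu_slice: np.ndarray, spacing_xy: tuple[float, float],
              threshold: int = BODY_THRESHOLD_HU) -> float:
    """Area (mm^2) of the largest connected body component in an axial slice."""
    mask = np.asarray(hu_slice) >= threshold
    if not mask.any():
        raise ValueError("slice contains no body voxels above the threshold")
    lab, n = ndimage.label(mask)
    counts = np.bincount(lab.ravel())[1:]
    largest = counts.max()
    return float(largest) * spacing_xy[0] * spacing_xy[1]


def junction_scale_factor(patient_slice: np.ndarray, phantom_slice: np.ndarray,
                          spacing_xy: tuple[float, float],
                          threshold: int = BODY_THRESHOLD_HU) -> float:
    """In-plane factor f = sqrt(A_patient / A_phantom) equalising body areas."""
    a_p = body_area(patient_slice, spacing_xy, threshold)
    a_ph = body_area(phantom_slice, spacing_xy, threshold)
    if a_ph <= 0:
        raise ValueError("phantom slice has zero body area")
    return math.sqrt(a_p / a_ph)


def suggest_junctions(patient: VoxelVolume, phantom: VoxelVolume,
                      threshold: int = BODY_THRESHOLD_HU) -> dict:
    """Suggest phantom junction slices by body-area-profile matching.

    Returns candidates only -- junctions remain a config input.
    """
    def profile(vol):
        areas = []
        for k in range(vol.shape[2]):
            try:
                areas.append(body_area(vol.values[:, :, k], vol.spacing[:2], threshold))
            except ValueError:
                areas.append(0.0)
        return np.array(areas)

    ap, aph = profile(patient), profile(phantom)
    n = len(ap)
    best, best_err = 0, np.inf
    for start in range(0, max(1, len(aph) - n + 1)):
        seg = aph[start:start + n]
        if len(seg) < n:
            break
        err = float(np.mean((seg / seg.mean() - ap / ap.mean()) ** 2)) if seg.mean() > 0 else np.inf
        if err < best_err:
            best, best_err = start, err
    return {"phantom_lower": best, "phantom_upper": best + n - 1,
            "patient_lower": 0, "patient_upper": n - 1, "mismatch": best_err}


def rescale_phantom_inplane(volume: VoxelVolume, factor: float,
                            threshold: int = BODY_THRESHOLD_HU,
                            bounds: tuple[float, float] = (0.5, 2.0)) -> VoxelVolume:
    """Magnify in-plane by ``factor`` about the body centroid (nearest-neighbour).

    The grid is unchanged; label/HU values are preserved as a set.  Raises if
    the factor is outside ``bounds`` or the rescaled body leaves the grid.
    """
    if not bounds[0] <= factor <= bounds[1]:
        raise ValueError(f"scale factor {factor:.3f} outside bounds {bounds}")
    if factor == 1.0:
        return volume.copy()
    vals = volume.values
    if volume.role == "hu":
        body = vals >= threshold
    else:
        body = vals > 0
    if not body.any():
        raise ValueError("volume has no body voxels to centre the rescale on")
    xs, ys, _ = np.nonzero(body)
    cx, cy = xs.mean(), ys.mean()

    nx, ny = volume.shape[:2]
    ix = np.arange(nx)[:, None]
    iy = np.arange(ny)[None, :]
    sx = np.rint(cx + (ix - cx) / factor).astype(np.intp)
    sy = np.rint(cy + (iy - cy) / factor).astype(np.intp)
    if factor > 1.0:
        # check the magnified body stays inside the grid
        half_x = (xs.max() - cx) * factor, (cx - xs.min()) * factor
        half_y = (ys.max() - cy) * factor, (cy - ys.min()) * factor
        if cx + half_x[0] > nx - 1 or cx - half_x[1] < 0 or \
           cy + half_y[0] > ny - 1 or cy - half_y[1] < 0:
            raise ValueError("rescaled body exceeds the grid; pad the volume first")
    valid = np.broadcast_to((sx >= 0) & (sx < nx), (nx, ny)) & \
        np.broadcast_to((sy >= 0) & (sy < ny), (nx, ny))
    SX = np.broadcast_to(np.clip(sx, 0, nx - 1), (nx, ny))
    SY = np.broadcast_to(np.clip(sy, 0, ny - 1), (nx, ny))
    out = vals[SX, SY, :].copy()
    fill = AIR_HU if volume.role == "hu" else 0
    out[~valid, :] = fill
    return volume.copy(values=out)


def merge_patient_phantom(patient: VoxelVolume, phantom: VoxelVolume,
                          cfg: MergeConfig):
    """Splice the patient block into the phantom between the junctions.

    The phantom is first rescaled in-plane with the factor measured at the
    lower junction; the merged volume keeps the phantom's head and leg ends
    with the patient slices substituted in between.  Returns
    ``(merged, provenance)`` where provenance is 1 for patient voxels and 2
    for phantom voxels.  Patient voxels are never altered.
    """
    if patient.shape[:2] != phantom.shape[:2]:
        raise ValueError("patient and phantom must share the in-plane grid; resample first")
    if not np.allclose(patient.spacing, phantom.spacing):
        raise ValueError("patient and phantom must share voxel spacing; resample first")
    cfg.validate(patient.shape[2], phantom.shape[2])

    f = junction_scale_factor(
        patient.values[:, :, cfg.patient_lower],
        phantom.values[:, :, cfg.phantom_lower],
        patient.spacing[:2], cfg.body_threshold_hu,
    )
    scaled = rescale_phantom_inplane(phantom, f, cfg.body_threshold_hu, cfg.scale_bounds)
    upper_f = junction_scale_factor(
        patient.values[:, :, cfg.patient_upper],
        scaled.values[:, :, cfg.phantom_upper],
        patient.spacing[:2], cfg.body_threshold_hu,
    )
    log.info("merge: lower-junction scale %.4f, residual upper-junction factor %.4f", f, upper_f)

    head = scaled.values[:, :, cfg.phantom_upper + 1:]
    legs = scaled.values[:, :, :cfg.phantom_lower]
    block = patient.values[:, :, cfg.patient_lower:cfg.patient_upper + 1]
    merged = np.concatenate([legs, block, head], axis=2)
    prov = np.concatenate(
        [np.full_like(legs, 2), np.full_like(block, 1), np.full_like(head, 2)], axis=2
    ).astype(np.int16)
    out = VoxelVolume(merged, patient.spacing, patient.origin, role=patient.role,
                      meta={"scale_factor": f, "patient_z": (legs.shape[2], legs.shape[2] + block.shape[2] - 1)})
    return out, VoxelVolume(prov, patient.spacing, patient.origin, role="label")


# ---------------------------------------------------------------------------
# adipose augmentation and effective diameter
# ---------------------------------------------------------------------------

def add_adipose_segment(hu_volume: VoxelVolume, chord_fraction: float = 0.6,
                        max_thickness_mm: float = 0.0,
                        threshold: int = BODY_THRESHOLD_HU) -> VoxelVolume:
    """Append truncated peripheral adipose as a circle segment per slice.

    The segment has a chord of ``chord_fraction`` times the body's lateral
    extent lying on the anterior body edge and a sagitta (maximum thickness)
    of ``max_thickness_mm``; only air voxels anterior of the body are filled
    with adipose (-100 HU).  Zero thickness is the identity.
    """
    if max_thickness_mm <= 0:
        return hu_volume.copy()
    sx, sy = hu_volume.spacing[:2]
    vals = hu_volume.values.copy()
    for k in range(vals.shape[2]):
        sl = vals[:, :, k]
        body = sl >= threshold
        if not body.any():
            continue
        xs, ys = np.nonzero(body)
        y_front = ys.min()  # anterior = low y
        x_lo, x_hi = xs.min(), xs.max()
        lat_mm = (x_hi - x_lo + 1) * sx
        c = chord_fraction * lat_mm
        h = max_thickness_mm
        radius = (c * c / 4.0 + h * h) / (2.0 * h)
        x_c = 0.5 * (x_lo + x_hi) * sx
        y_chord = y_front * sy  # top edge of the anterior body row
        y0 = y_chord - h + radius
        h_vox = int(np.ceil(h / sy))
        if y_front - h_vox < 0:
            raise ValueError("adipose segment exceeds the grid margin; pad anteriorly")
        ix = (np.arange(sl.shape[0]) + 0.5) * sx
        iy = (np.arange(sl.shape[1]) + 0.5) * sy
        XX, YY = np.meshgrid(ix, iy, indexing="ij")
        seg = ((XX - x_c) ** 2 + (YY - y0) ** 2 <= radius**2) & (YY < y_chord)
        sl[seg & (sl <= AIR_HU + 50)] = ADIPOSE_HU
    return hu_volume.copy(values=vals)


def circle_segment_area(chord: float, sagitta: float) -> float:
    """Analytic area r^2 (theta - sin theta) / 2 of a circle segment."""
    r = (chord * chord / 4.0 + sagitta * sagitta) / (2.0 * sagitta)
    theta = 2.0 * math.asin(min(1.0, chord / (2.0 * r)))
    return r * r * (theta - math.sin(theta)) / 2.0


def effective_diameter(hu_volume: VoxelVolume,
                       threshold: int = BODY_THRESHOLD_HU) -> float:
    """Maximum slice-wise sqrt(LAT * AP) of the thresholded body (mm).

    LAT and AP are the bounding-box extents of the body contour in each
    axial slice; the slice-wise maximum over the volume is returned.
    """
    sx, sy = hu_volume.spacing[:2]
    best = 0.0
    found = False
    for k in range(hu_volume.shape[2]):
        mask = hu_volume.values[:, :, k] >= threshold
        if not mask.any():
            continue
        found = True
        # measure the largest connected component (the body, not e.g. the table)
        lab, n = ndimage.label(mask)
        if n > 1:
            counts = np.bincount(lab.ravel())
            counts[0] = 0
            mask = lab == counts.argmax()
        xs, ys = np.nonzero(mask)
        lat = (xs.max() - xs.min() + 1) * sx
        ap = (ys.max() - ys.min() + 1) * sy
        best = max(best, math.sqrt(lat * ap))
    if not found:
        raise ValueError("no body voxels above the threshold in any slice")
    return best
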