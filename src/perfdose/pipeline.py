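"""End-to-end per-case and cohort orchestration on synthetic data.

``run_case`` executes the full chain for one synthetic case: generate the
patient-like thorax volume and the miniature reference phantom, harmonise
them (table removal, common-grid resampling, junction scaling, merge, table
re-insertion, optional adipose augmentation), build the case-specific
HU-to-material table, run the two-tube Monte Carlo simulation, combine and
scale the dose maps for shuttle mode, and reduce the result to an organ-dose
report with an ICRP-103 effective dose.  ``run_cohort`` aggregates a list of
case reports, including the effective-diameter protocol split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ct_source, dose_report, harmonize, materials, mc_transport, synthetic_data
from .voxel_io import VoxelVolume, labels_to_hu, resample_nearest, write_volume

__all__ = ["CaseConfig", "run_case", "run_cohort", "diameter_groups"]

log = logging.getLogger("perfdose.pipeline")

PROTOCOLS = {
    "flash80": ct_source.ScanProtocol.flash80,
    "flash100": ct_source.ScanProtocol.flash100,
}


@dataclass
class CaseConfig:
    """Configuration of one synthetic end-to-end case."""

    case_id: str = "case"
    protocol: str = "flash80"
    patient_spec: synthetic_data.SyntheticPhantomSpec = field(
        default_factory=synthetic_data.SyntheticPhantomSpec)
    phantom_spec: synthetic_data.SyntheticPhantomSpec | None = None
    grid_spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    adipose_thickness_mm: float = 0.0
    transport: mc_transport.TransportConfig = field(
        default_factory=mc_transport.TransportConfig)
    output_dir: str | None = None

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")


def _rescale_labels(labels: VoxelVolume, factor: float) -> VoxelVolume:
    if factor == 1.0:
        return labels.copy()
    return harmonize.rescale_phantom_inplane(labels, factor)


def _organ_masks(patient_truth: VoxelVolume, phantom_labels: VoxelVolume,
                 block: tuple[int, int], legs_len: int, merged_shape) -> dict[str, np.ndarray]:
    """Merged organ masks: patient truth inside the block, phantom outside."""
    masks: dict[str, np.ndarray] = {}
    p_map = patient_truth.meta["label_map"]
    ph_map = phantom_labels.meta["label_map"]
    lo, hi = block

    def add(name, mask):
        if name in ("air", "adipose_shell", "table"):
            return
        full = masks.setdefault(name, np.zeros(merged_shape, dtype=bool))
        full |= mask

    for label_id, name in p_map.items():
        sub = np.zeros(merged_shape, dtype=bool)
        sub[:, :, lo:hi + 1] = patient_truth.values == label_id
        add(name, sub)
    outside = np.ones(merged_shape[2], dtype=bool)
    outside[lo:hi + 1] = False
    ph_vals = phantom_labels.values
    for label_id, name in ph_map.items():
        sub = np.zeros(merged_shape, dtype=bool)
        sub[:, :, outside] = ph_vals[:, :, outside] == label_id
        add(name, sub)
    return masks


#: synthetic organ labels folded into the reported organ set
_REPORT_GROUPS = {
    "lungs": ("lung_left", "lung_right"),
    "breasts": ("breast_left", "breast_right"),
    "kidneys": ("kidney_left", "kidney_right"),
    "bones": ("spine", "rib_left", "rib_right", "femur_left", "femur_right",
              "spongiosa", "medullary_cavity"),
    "heart": ("heart", "blood_pool"),
}


def report_organ_masks(raw: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Fold left/right and bone-compartment masks into report organs."""
    out: dict[str, np.ndarray] = {}
    used = set()
    for organ, parts in _REPORT_GROUPS.items():
        parts = [p for p in parts if p in raw]
        if parts:
            out[organ] = np.any([raw[p] for p in parts], axis=0)
            used.update(parts)
    for name, mask in raw.items():
        if name not in used and name not in out:
            out[name] = mask
    return out


def run_case(cfg: CaseConfig, phantom_report: dose_report.DoseReport | None = None):
    """Run one synthetic case end-to-end; returns (DoseReport, artifacts dict)."""
    protocol = PROTOCOLS[cfg.protocol]()
    # 0. synthetic inputs
    patient_hu, patient_truth = synthetic_data.make_patient_volume(cfg.patient_spec)
    phantom_spec = cfg.phantom_spec or synthetic_data.SyntheticPhantomSpec.reference_default(
        seed=cfg.patient_spec.seed)
    phantom_labels, tissue_map = synthetic_data.make_reference_phantom(phantom_spec)
    phantom_hu = labels_to_hu(phantom_labels, tissue_map, variant="plain")
    phantom_hu.meta.update(phantom_labels.meta)

    # 1. table removal
    table_id = {v: k for k, v in patient_truth.meta["label_map"].items()}["table"]
    table_mask = patient_truth.values == table_id
    patient_hu = harmonize.remove_table(patient_hu, table_mask)

    # 2. common grid
    patient_hu = resample_nearest(patient_hu, cfg.grid_spacing)
    patient_truth_rs = resample_nearest(patient_truth, cfg.grid_spacing)
    phantom_hu = resample_nearest(phantom_hu, cfg.grid_spacing)
    phantom_labels_rs = resample_nearest(phantom_labels, cfg.grid_spacing)

    if patient_hu.shape[:2] != phantom_hu.shape[:2]:
        target_xy = (max(patient_hu.shape[0], phantom_hu.shape[0]),
                     max(patient_hu.shape[1], phantom_hu.shape[1]))
        patient_hu, patient_truth_rs = _pad_inplane(patient_hu, patient_truth_rs, target_xy)
        phantom_hu, phantom_labels_rs = _pad_inplane(phantom_hu, phantom_labels_rs, target_xy)

    # 3. junctions: the patient thorax block replaces the phantom thorax
    nz_pat = patient_hu.shape[2]
    nz_ph = phantom_hu.shape[2]
    th_center = int(round(0.685 * nz_ph))  # centre of the phantom thorax band
    ph_lower = max(0, th_center - nz_pat // 2)
    ph_upper = min(nz_ph - 1, ph_lower + nz_pat - 1)
    cfg_merge = harmonize.MergeConfig(
        patient_lower=0, patient_upper=nz_pat - 1,
        phantom_lower=ph_lower, phantom_upper=ph_upper,
    )

    # 4-5. scale + merge
    merged, provenance = harmonize.merge_patient_phantom(patient_hu, phantom_hu, cfg_merge)
    factor = merged.meta["scale_factor"]
    legs_len, block_hi = merged.meta["patient_z"]

    # 6. re-insert the table over the patient block
    table_rs = patient_truth_rs.values == table_id
    table_full = np.zeros(merged.shape, dtype=bool)
    table_full[:, :, legs_len:block_hi + 1] = table_rs
    merged = harmonize.add_table(merged, table_full, cfg.patient_spec.table_hu)

    # 7. adipose augmentation (explicit opt-in)
    if cfg.adipose_thickness_mm > 0:
        merged = harmonize.add_adipose_segment(merged, max_thickness_mm=cfg.adipose_thickness_mm)

    # organ masks on the merged grid
    scaled_ph_labels = _rescale_labels(phantom_labels_rs, factor)
    scaled_ph_labels.meta = phantom_labels_rs.meta
    ph_spliced = _splice_phantom_labels(scaled_ph_labels, cfg_merge, merged.shape)
    raw_masks = _organ_masks(patient_truth_rs, ph_spliced, (legs_len, block_hi),
                             legs_len, merged.shape)
    masks = report_organ_masks(raw_masks)

    # material table from the blood HU sample
    blood_mask = raw_masks.get("blood_pool", np.zeros(merged.shape, bool))
    blood_sample = merged.values[blood_mask]
    blood_max = materials.blood_hu_max(blood_sample) if blood_sample.size else 499
    blood_max = max(blood_max, 249)
    table = materials.build_material_table(blood_max, protocol.kv)
    log.info("case %s: scale %.3f, blood max %d HU, %d material bins",
             cfg.case_id, factor, blood_max, len(table.bins))

    # simulation: isocenter at the centre of the patient block
    iso = (merged.shape[0] * merged.spacing[0] / 2.0,
           merged.shape[1] * merged.spacing[1] / 2.0,
           (legs_len + (block_hi - legs_len + 1) / 2.0) * merged.spacing[2])
    spectrum = ct_source.packaged_spectrum(protocol.kv)
    doses = []
    for i, tube in enumerate(protocol.tubes):
        tcfg = mc_transport.TransportConfig(
            n_photons=cfg.transport.n_photons,
            max_interactions=cfg.transport.max_interactions,
            cutoff_kev=cfg.transport.cutoff_kev,
            seed=cfg.transport.seed + i,
            rayleigh=cfg.transport.rayleigh,
            batch_size=cfg.transport.batch_size,
        )
        doses.append(mc_transport.simulate_tube(
            merged, table, protocol, tube, tcfg, spectrum=spectrum, iso_mm=iso))
    total = mc_transport.combine_and_scale(doses[0], doses[1] if len(doses) > 1 else None,
                                           protocol)

    # organ doses
    organ_doses = {}
    for organ, mask in masks.items():
        if mask.any():
            organ_doses[organ] = dose_report.organ_mean_dose(total, mask)

    # red bone marrow: MEAC method in the patient block, spongiosa outside
    comps = materials.load_compositions()
    meac_ratio = materials.mean_meac_ratio(spectrum, comps["red_marrow"], comps["whole_bone"])
    bone_mask = masks.get("bones", np.zeros(merged.shape, bool))
    in_block = np.zeros(merged.shape, dtype=bool)
    in_block[:, :, legs_len:block_hi + 1] = True
    bone_patient = bone_mask & in_block
    spong_mask = raw_masks.get("spongiosa", np.zeros(merged.shape, bool)) & ~in_block
    spong_fraction = _spongiosa_fraction(ph_spliced)
    d_bone = float(total.values[bone_patient].mean()) if bone_patient.any() else 0.0
    d_spong = float(total.values[spong_mask].mean()) if spong_mask.any() else 0.0
    organ_doses["rbm"] = dose_report.rbm_dose(
        d_bone, int(bone_patient.sum()), d_spong, int(spong_mask.sum()),
        meac_ratio, spong_fraction)

    if "lymphatic_nodes" not in organ_doses and phantom_report is not None:
        organ_doses["lymphatic_nodes"] = dose_report.lymph_fallback(phantom_report)

    weights = dose_report.load_icrp103_female_weights()
    e_msv = dose_report.effective_dose(organ_doses, weights)
    diameter = harmonize.effective_diameter(merged)

    report = dose_report.DoseReport(
        case_id=cfg.case_id, kv=protocol.kv, doses=organ_doses,
        effective_dose_msv=e_msv, effective_diameter_mm=diameter,
        meta={"scale_factor": factor, "blood_max_hu": int(blood_max),
              "meac_ratio": meac_ratio, "n_photons": cfg.transport.n_photons,
              "seed": cfg.transport.seed,
              "escaped_fraction": doses[0].meta["escaped_fraction"]},
    )
    artifacts = {"merged": merged, "provenance": provenance, "dose": total,
                 "masks": masks, "material_table": table}
    if cfg.output_dir:
        _write_artifacts(cfg, report, artifacts)
    return report, artifacts


def _pad_inplane(hu: VoxelVolume, truth: VoxelVolume, target_xy):
    """Centre-pad the patient grid to the phantom's in-plane shape."""
    nx, ny = target_xy
    out_hu = np.full((nx, ny, hu.shape[2]), -1000, dtype=hu.values.dtype)
    out_tr = np.zeros((nx, ny, hu.shape[2]), dtype=truth.values.dtype)
    ox = (nx - hu.shape[0]) // 2
    oy = (ny - hu.shape[1]) // 2
    if ox < 0 or oy < 0:
        raise ValueError("patient grid larger than phantom grid in-plane")
    out_hu[ox:ox + hu.shape[0], oy:oy + hu.shape[1], :] = hu.values
    out_tr[ox:ox + hu.shape[0], oy:oy + hu.shape[1], :] = truth.values
    return (VoxelVolume(out_hu, hu.spacing, role="hu"),
            VoxelVolume(out_tr, hu.spacing, role="label", meta=truth.meta))


def _splice_phantom_labels(scaled_labels: VoxelVolume, cfg_merge: harmonize.MergeConfig,
                           merged_shape) -> VoxelVolume:
    vals = scaled_labels.values
    legs = vals[:, :, :cfg_merge.phantom_lower]
    head = vals[:, :, cfg_merge.phantom_upper + 1:]
    block_len = merged_shape[2] - legs.shape[2] - head.shape[2]
    block = np.zeros((vals.shape[0], vals.shape[1], block_len), dtype=vals.dtype)
    out = np.concatenate([legs, block, head], axis=2)
    return VoxelVolume(out, scaled_labels.spacing, role="label", meta=scaled_labels.meta)


def _spongiosa_fraction(phantom_labels: VoxelVolume) -> float:
    """Phantom spongiosa / total-bone voxel-count ratio (rbm correction)."""
    ids = {v: k for k, v in phantom_labels.meta["label_map"].items()}
    bone_names = [n for n in ("spine", "rib_left", "rib_right", "femur_left",
                              "femur_right", "spongiosa", "medullary_cavity") if n in ids]
    n_bone = int(np.isin(phantom_labels.values, [ids[n] for n in bone_names]).sum())
    n_spong = int((phantom_labels.values == ids.get("spongiosa", -1)).sum())
    return n_spong / n_bone if n_bone else 1.0


def _write_artifacts(cfg: CaseConfig, report, artifacts) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(artifacts["merged"], out / f"{cfg.case_id}_merged.nii.gz")
    write_volume(artifacts["dose"].dose, out / f"{cfg.case_id}_dose.nii.gz")
    artifacts["material_table"].to_tsv(out / f"{cfg.case_id}_materials.tsv")
    report.to_json(out / f"{cfg.case_id}_report.json")
    manifest = {"case_id": cfg.case_id, "protocol": cfg.protocol,
                "seed": cfg.transport.seed, "n_photons": cfg.transport.n_photons}
    (out / f"{cfg.case_id}_manifest.json").write_text(json.dumps(manifest, indent=1))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def diameter_groups(reports, threshold_mm: float = 320.0,
                    labels: tuple[str, str] = ("le_threshold", "gt_threshold")):
    """Group cases by maximum effective diameter (default split at 32 cm)."""
    groups = {}
    for r in reports:
        if r.effective_diameter_mm is None:
            raise ValueError(f"case {r.case_id} has no effective diameter")
        groups[r.case_id] = labels[0] if r.effective_diameter_mm <= threshold_mm else labels[1]
    return groups


def run_cohort(reports, groups: dict[str, str] | None = None):
    """Cohort summary over per-case reports; see ``dose_report.cohort_statistics``."""
    if not reports:
        raise ValueError("empty cohort")
    if groups is not None:
        labels = set(groups.values())
        for lab in labels:
            if not any(groups[r.case_id] == lab for r in reports):
                raise ValueError(f"group {lab!r} has no cases")
    return dose_report.cohort_statistics(reports, groups)
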