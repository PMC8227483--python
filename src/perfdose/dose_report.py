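"""Organ segmentation, organ doses, effective dose and cohort statistics.

Organ doses are means of the absorbed-dose grid over organ masks obtained by
combining a rough region of interest with an HU window (the phantom part of
a merged volume reuses its own labels).  Red bone marrow cannot be segmented
from CT data; its dose is estimated with the mass energy-absorption
coefficient (MEAC) ratio method,

    D_rbm = (mu_en/rho)_rbm / (mu_en/rho)_bone * D_bone,

applied to the patient-region bone dose, combined with the phantom-region
spongiosa dose in a voxel-count-weighted mean (with a spongiosa-fraction
correction on the patient bone count).  Effective dose is the ICRP-103
weighted sum E = sum_i w_i D_i with the female remainder list and the
remainder dose as the arithmetic mean of the remainder organs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mc_transport import DoseGrid
from .voxel_io import VoxelVolume

__all__ = [
    "SegmentationMap",
    "TissueWeights",
    "DoseReport",
    "load_icrp103_female_weights",
    "segment_hu",
    "organ_mean_dose",
    "rbm_dose",
    "effective_dose",
    "lymph_fallback",
    "cohort_statistics",
    "group_contrast",
    "load_reference_cohort",
    "load_reference_diameters",
]


@dataclass
class SegmentationMap:
    """Organ name -> boolean mask, with per-organ provenance."""

    masks: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)  # patient|phantom|fallback

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("segmentation masks have mismatching shapes")


@dataclass
class TissueWeights:
    """ICRP-style tissue weighting factors with a remainder list."""

    weights: dict[str, float]
    remainder: list[str]
    remainder_weight: float

    def __post_init__(self):
        total = sum(self.weights.values()) + self.remainder_weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tissue weights sum to {total}, not 1")


@dataclass
class DoseReport:
    """Per-case organ doses (mGy) and effective dose (mSv)."""

    case_id: str
    kv: int
    doses: dict[str, float]
    effective_dose_msv: float | None = None
    effective_diameter_mm: float | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "DoseReport":
        return cls(**json.loads(Path(path).read_text()))


def load_icrp103_female_weights() -> TissueWeights:
    raw = yaml.safe_load(
        resources.files("perfdose.data").joinpath("icrp103_female_weights.yaml").read_text()
    )
    return TissueWeights({k: float(v) for k, v in raw["weights"].items()},
                         list(raw["remainder"]), float(raw["remainder_weight"]))


# ---------------------------------------------------------------------------
# segmentation and organ doses
# ---------------------------------------------------------------------------

def segment_hu(hu_volume: VoxelVolume, roi_mask: np.ndarray,
               hu_lo: int, hu_hi: int) -> np.ndarray:
    """Mask of voxels inside ``roi_mask`` whose HU lies in [hu_lo, hu_hi]."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty region of interest")
    mask = roi_mask & (hu_volume.values >= hu_lo) & (hu_volume.values <= hu_hi)
    if not mask.any():
        warnings.warn("HU-window segmentation produced an empty mask", stacklevel=2)
    return mask


def organ_mean_dose(dose: DoseGrid, mask: np.ndarray) -> float:
    """Arithmetic mean dose (mGy) over the organ mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty organ mask; use a phantom fallback")
    return float(dose.values[mask].mean())


def rbm_dose(bone_dose_patient: float, n_bone_patient: int,
             spongiosa_dose_phantom: float, n_spongiosa_phantom: int,
             meac_ratio: float, spongiosa_fraction: float = 1.0) -> float:
    """Red-bone-marrow dose from patient bone and phantom spongiosa regions.

    The patient contribution is the MEAC-converted bone dose with an
    effective voxel count ``n_bone_patient * spongiosa_fraction``; the
    combined estimate is the count-weighted mean with the phantom spongiosa
    term.
    """
    if meac_ratio <= 0:
        raise ValueError("MEAC ratio must be positive")
    if n_bone_patient < 0 or n_spongiosa_phantom < 0:
        raise ValueError("voxel counts must be >= 0")
    n_eff = n_bone_patient * spongiosa_fraction
    denom = n_eff + n_spongiosa_phantom
    if denom <= 0:
        raise ValueError("no bone or spongiosa voxels to average over")
    return (n_eff * meac_ratio * bone_dose_patient
            + n_spongiosa_phantom * spongiosa_dose_phantom) / denom


def effective_dose(doses: dict[str, float], weights: TissueWeights) -> float:
    """ICRP effective dose E = sum_i w_i D_i in mSv (photons: 1 mGy = 1 mSv)."""
    missing = [o for o in weights.weights if o not in doses]
    missing += [o for o in weights.remainder if o not in doses]
    if missing:
        raise KeyError(f"missing organ doses: {sorted(set(missing))}")
    e = sum(w * doses[o] for o, w in weights.weights.items())
    remainder_mean = float(np.mean([doses[o] for o in weights.remainder]))
    return e + weights.remainder_weight * remainder_mean


def lymph_fallback(phantom_report: DoseReport) -> float:
    """Lymphatic-node dose taken from the phantom-only run at the same kV."""
    if phantom_report is None:
        raise ValueError("no phantom run available for the lymphatic-node fallback")
    try:
        return phantom_report.doses["lymphatic_nodes"]
    except KeyError as exc:
        raise ValueError("phantom report lacks a lymphatic-node dose") from exc


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def cohort_statistics(reports: list[DoseReport],
                      groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-group mean and sample SD of every organ dose and the effective dose.

    ``groups`` maps case id -> group label (default: one group ``"all"``).
    Returns a tidy frame with columns (group, quantity, mean, sd, n); the SD
    is the n-1 sample standard deviation, blank (NaN) for singleton groups.
    """
    if not reports:
        raise ValueError("no reports to summarise")
    groups = groups or {r.case_id: "all" for r in reports}
    unknown = [r.case_id for r in reports if r.case_id not in groups]
    if unknown:
        raise KeyError(f"cases without group labels: {unknown}")
    rows = []
    by_group: dict[str, list[DoseReport]] = {}
    for r in reports:
        by_group.setdefault(groups[r.case_id], []).append(r)
    for g, rs in by_group.items():
        organs = sorted({o for r in rs for o in r.doses})
        for organ in organs:
            vals = np.array([r.doses[organ] for r in rs if organ in r.doses])
            rows.append((g, organ, vals.mean(),
                         vals.std(ddof=1) if len(vals) > 1 else np.nan, len(vals)))
        evals = np.array([r.effective_dose_msv for r in rs
                          if r.effective_dose_msv is not None])
        if evals.size:
            rows.append((g, "effective_dose", evals.mean(),
                         evals.std(ddof=1) if len(evals) > 1 else np.nan, len(evals)))
    return pd.DataFrame(rows, columns=["group", "quantity", "mean", "sd", "n"])


def group_contrast(summary: pd.DataFrame, group_a: str, group_b: str,
                   quantity: str = "effective_dose") -> float:
    """Percentage difference of group means: 100 * (A - B) / B."""
    def pick(g):
        sel = summary[(summary["group"] == g) & (summary["quantity"] == quantity)]
        if sel.empty:
            raise KeyError(f"group {g!r} / quantity {quantity!r} not in summary")
        return float(sel["mean"].iloc[0])

    a, b = pick(group_a), pick(group_b)
    return 100.0 * (a - b) / b


# ---------------------------------------------------------------------------
# packaged reference cohort (transcribed published per-case doses)
# ---------------------------------------------------------------------------

def load_reference_cohort(kv: int) -> list[DoseReport]:
    """The packaged 20-case reference cohort (plus the phantom row) at 80/100 kV."""
    name = f"reference_cohort_{kv}kv.tsv"
    text = resources.files("perfdose.data").joinpath(name).read_text()
    import io

    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    diam = load_reference_diameters()
    reports = []
    for _, row in df.iterrows():
        case = str(row["case"])
        doses = {c: float(row[c]) for c in df.columns if c not in ("case", "effective_dose")}
        reports.append(DoseReport(
            case_id=case, kv=kv, doses=doses,
            effective_dose_msv=float(row["effective_dose"]),
            effective_diameter_mm=diam.get(case),
        ))
    return reports


def load_reference_diameters() -> dict[str, float]:
    text = resources.files("perfdose.data").joinpath(
        "reference_cohort_diameters.tsv").read_text()
    out = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("case"):
            continue
        case, d = line.split("\t")
        out[case] = float(d)
    return out
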