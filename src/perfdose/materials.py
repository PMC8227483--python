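"""Materials: HU binning, blood-iodine mixtures, photon coefficients.

The HU scale of a contrast-enhanced thorax CT is mapped onto an ordered
table of material bins.  The base bins (air, lung, adipose, muscle, bone,
iron) are fixed; between 200 HU and the case-specific maximum blood HU the
table carries 50-HU-wide blood-iodine bins whose iodine content follows the
linear contrast-enhancement relation

    c [mg iodine / ml] = (HU_mid - 40) / k,

with the blood baseline at 40 HU and k = 41.12 HU/(mg/ml) at 80 kV or
31.74 HU/(mg/ml) at 100 kV.  A mixture with c mg iodine per ml is treated as
c mg iodine per 1000 mg of mixture, i.e. an iodine mass percentage of c/10.

Elemental mass-attenuation and mass energy-absorption coefficients are
vendored package data (see ``data/provenance.md``); material coefficients
follow mass-fraction additivity with log-log interpolation in energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

__all__ = [
    "MaterialComposition",
    "MaterialTable",
    "MeacTables",
    "load_compositions",
    "load_meac_tables",
    "blood_hu_max",
    "iodine_mass_fraction",
    "mixture_composition",
    "build_material_table",
    "attenuation",
    "mean_meac_ratio",
    "klein_nishina",
]

HU_FLOOR = -1024
HU_CEIL = 64535
BLOOD_BASELINE_HU = 40.0
ENHANCEMENT_COEF = {80: 41.12, 100: 31.74}  # HU per (mg iodine / ml)
BLOOD_BIN_WIDTH = 50
#: a trailing remainder shorter than this merges into the previous blood bin
_REMAINDER_MIN = 20

ME_KEV = 510.99895
R_E_CM = 2.8179403e-13
N_A = 6.02214076e23


@dataclass(frozen=True)
class MaterialComposition:
    """Named elemental mixture: mass fractions summing to 1, density g/cm^3."""

    name: str
    fractions: dict[str, float]
    density: float

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, not 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError(f"{self.name}: negative mass fraction")
        if self.density <= 0:
            raise ValueError(f"{self.name}: non-positive density")


@dataclass
class MaterialBin:
    lo: int
    hi: int
    composition: MaterialComposition


@dataclass
class MaterialTable:
    """Ordered, contiguous HU bins covering [-1024, 64535]."""

    bins: list[MaterialBin]
    kv: int = 80

    def __post_init__(self):
        if self.bins[0].lo != HU_FLOOR or self.bins[-1].hi != HU_CEIL:
            raise ValueError("material table must cover [-1024, 64535]")
        for a, b in zip(self.bins, self.bins[1:]):
            if b.lo != a.hi + 1:
                raise ValueError(
                    f"bins not contiguous: {a.composition.name} ends {a.hi}, "
                    f"{b.composition.name} starts {b.lo}"
                )

    def index_of_hu(self, hu: np.ndarray) -> np.ndarray:
        los = np.array([b.lo for b in self.bins])
        hu = np.asarray(hu)
        if hu.min() < HU_FLOOR or hu.max() > HU_CEIL:
            bad = hu[(hu < HU_FLOOR) | (hu > HU_CEIL)]
            raise ValueError(f"HU value {int(bad.flat[0])} outside the material table")
        return np.searchsorted(los, hu, side="right") - 1

    @property
    def compositions(self) -> list[MaterialComposition]:
        return [b.composition for b in self.bins]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("material\thu_lo\thu_hi\tdensity_g_cm3\tfractions\n")
            for b in self.bins:
                fr = ";".join(f"{el}:{v:.6f}" for el, v in b.composition.fractions.items())
                fh.write(f"{b.composition.name}\t{b.lo}\t{b.hi}\t{b.composition.density}\t{fr}\n")


@dataclass
class MeacTables:
    """Per-element energy grids (keV) with mu/rho and mu_en/rho (cm^2/g)."""

    energies: dict[str, np.ndarray]
    mu: dict[str, np.ndarray]
    mu_en: dict[str, np.ndarray]
    z: dict[str, int] = field(default_factory=dict)
    a: dict[str, float] = field(default_factory=dict)

    def emin(self) -> float:
        return max(e[0] for e in self.energies.values())

    def emax(self) -> float:
        return min(e[-1] for e in self.energies.values())


# ---------------------------------------------------------------------------
# package data
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("perfdose.data").joinpath(name).read_text()


@lru_cache(maxsize=1)
def load_compositions() -> dict[str, MaterialComposition]:
    raw = yaml.safe_load(_data_text("compositions.yaml"))
    out = {}
    for name, entry in raw.items():
        fr = {el: float(v) for el, v in entry["fractions"].items()}
        total = sum(fr.values())
        fr = {el: v / total for el, v in fr.items()}  # absorb rounding in the YAML
        out[name] = MaterialComposition(name, fr, float(entry["density"]))
    return out


@lru_cache(maxsize=1)
def load_meac_tables() -> MeacTables:
    energies, mu, mu_en, zz, aa = {}, {}, {}, {}, {}
    rows: dict[str, list] = {}
    for line in _data_text("element_coefficients.tsv").splitlines():
        if not line or line.startswith("#") or line.startswith("element"):
            continue
        el, z, a, e, m, men = line.split("\t")
        rows.setdefault(el, []).append((float(e), float(m), float(men)))
        zz[el], aa[el] = int(z), float(a)
    for el, rr in rows.items():
        rr.sort()
        arr = np.array(rr)
        energies[el] = arr[:, 0]
        mu[el] = arr[:, 1]
        mu_en[el] = arr[:, 2]
    return MeacTables(energies, mu, mu_en, zz, aa)


# ---------------------------------------------------------------------------
# blood HU statistics and iodine mixtures
# ---------------------------------------------------------------------------

def blood_hu_max(blood_hu_values) -> int:
    """Case-specific maximum blood-iodine HU from the blood-voxel HU sample.

    Rules: (1) if more than 10% of blood voxels exceed 501 HU, use the value
    containing 90% of the blood voxels (the 90th percentile); (2) else if the
    maximum is below 501 HU, use the maximum; (3) otherwise use 499 HU.
    """
    values = np.asarray(blood_hu_values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty blood HU sample")
    frac_above = np.mean(values > 501)
    if frac_above > 0.10:
        return int(round(float(np.percentile(values, 90))))
    if values.max() < 501:
        return int(round(float(values.max())))
    return 499


def iodine_mass_fraction(bin_lo: float, bin_hi: float, kv: int) -> tuple[float, float]:
    """(blood %, iodine %) of the mixture assigned to an HU bin.

    The iodine concentration follows the bin-midpoint enhancement over the
    40 HU blood baseline; c mg/ml is read as c mg per 1000 mg mixture.
    """
    if kv not in ENHANCEMENT_COEF:
        raise ValueError(f"kv must be 80 or 100, got {kv}")
    if not bin_hi >= bin_lo >= BLOOD_BASELINE_HU:
        raise ValueError("bin must satisfy hi >= lo >= 40 HU")
    c = ((bin_lo + bin_hi) / 2.0 - BLOOD_BASELINE_HU) / ENHANCEMENT_COEF[kv]
    iodine_pct = c / 10.0
    return 100.0 - iodine_pct, iodine_pct


def mixture_composition(blood: MaterialComposition, iodine_pct: float,
                        name: str | None = None) -> MaterialComposition:
    """Blood-iodine mixture by mass: iodine_pct% iodine, rest blood.

    The mixture inherits the blood density; the mass-fraction convention is
    independent of that choice.
    """
    if not 0.0 <= iodine_pct <= 100.0:
        raise ValueError("iodine percentage must lie in [0, 100]")
    p = iodine_pct / 100.0
    fr = {el: (1.0 - p) * v for el, v in blood.fractions.items()}
    if p > 0.0:
        fr["I"] = fr.get("I", 0.0) + p
    return MaterialComposition(name or f"blood_iodine_{iodine_pct:.3f}pct",
                               fr, blood.density)


def build_material_table(blood_max: int, kv: int,
                         compositions: dict[str, MaterialComposition] | None = None
                         ) -> MaterialTable:
    """HU-to-material conversion table for one case.

    Base bins: air -1024..-900, lung -899..-300, adipose -299..-50, muscle
    -49..199, bone blood_max+1..1999, iron 2000..64535.  Between 200 HU and
    ``blood_max`` lie 50-HU blood-iodine bins; a trailing remainder shorter
    than 20 HU extends the previous bin instead of forming its own
    (reproducing the printed per-case bin layouts, e.g. 450..510 for a
    maximum of 510 but a separate 750..771 bin for a maximum of 771).
    """
    if blood_max < 249:
        raise ValueError("blood_max must be at least 249 HU")
    if blood_max >= 2000:
        raise ValueError("blood_max must stay below the 2000 HU iron bin")
    comps = compositions or load_compositions()
    blood = comps["blood"]

    bins = [
        MaterialBin(HU_FLOOR, -900, comps["air"]),
        MaterialBin(-899, -300, comps["lung"]),
        MaterialBin(-299, -50, comps["adipose"]),
        MaterialBin(-49, 199, comps["muscle"]),
    ]
    edges = []
    lo = 200
    while lo + BLOOD_BIN_WIDTH - 1 <= blood_max:
        edges.append([lo, lo + BLOOD_BIN_WIDTH - 1])
        lo += BLOOD_BIN_WIDTH
    if not edges:
        edges.append([200, blood_max])
    elif edges[-1][1] < blood_max:
        if blood_max - (edges[-1][1] + 1) + 1 >= _REMAINDER_MIN:
            edges.append([edges[-1][1] + 1, blood_max])
        else:
            edges[-1][1] = blood_max
    for i, (b_lo, b_hi) in enumerate(edges, start=1):
        _, iodine_pct = iodine_mass_fraction(b_lo, b_hi, kv)
        comp = mixture_composition(blood, iodine_pct, name=f"blood_iodine_{i}")
        bins.append(MaterialBin(b_lo, b_hi, comp))
    bins.append(MaterialBin(blood_max + 1, 1999, comps["whole_bone"]))
    bins.append(MaterialBin(2000, HU_CEIL, comps["iron"]))
    return MaterialTable(bins, kv)


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------

def _loglog_interp(e: float | np.ndarray, eg: np.ndarray, vg: np.ndarray) -> np.ndarray:
    return np.exp(np.interp(np.log(e), np.log(eg), np.log(vg)))


def attenuation(comp: MaterialComposition, energy_kev, tables: MeacTables | None = None):
    """(mu/rho, mu_en/rho) of a composition in cm^2/g at ``energy_kev``.

    Mass-fraction additivity over the elements, each log-log interpolated
    onto the requested energy.  Energies must lie within [1, 150] keV.
    """
    tables = tables or load_meac_tables()
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < tables.emin()) or np.any(e > tables.emax()):
        raise ValueError(f"energy outside the tabulated range "
                         f"[{tables.emin()}, {tables.emax()}] keV")
    mu = np.zeros_like(e, dtype=float)
    mu_en = np.zeros_like(e, dtype=float)
    for el, w in comp.fractions.items():
        if w == 0.0:
            continue
        mu += w * _loglog_interp(e, tables.energies[el], tables.mu[el])
        mu_en += w * _loglog_interp(e, tables.energies[el], tables.mu_en[el])
    if np.isscalar(energy_kev):
        return float(mu), float(mu_en)
    return mu, mu_en


def _spline_mu_en(comp: MaterialComposition, e_grid: np.ndarray,
                  tables: MeacTables) -> np.ndarray:
    """mu_en/rho on a 1 keV grid via cubic-spline interpolation in log-log."""
    out = np.zeros_like(e_grid, dtype=float)
    for el, w in comp.fractions.items():
        if w == 0.0:
            continue
        cs = CubicSpline(np.log(tables.energies[el]), np.log(tables.mu_en[el]))
        out += w * np.exp(cs(np.log(e_grid)))
    return out


def mean_meac_ratio(spectrum, comp_a: MaterialComposition, comp_b: MaterialComposition,
                    tables: MeacTables | None = None) -> float:
    """Ratio of spectrum-weighted mean mass energy-absorption coefficients.

    Each material's mean MEAC is sum_E sum_m (mu_en/rho)(m, E) R_m R_E with
    coefficients cubic-spline interpolated at 1 keV steps; R_E is the
    normalised spectral weight, so the ratio is invariant to rescaling the
    spectrum.  Raises if the spectrum extends outside the coefficient tables.
    """
    tables = tables or load_meac_tables()
    e = np.asarray(spectrum.energies, dtype=float)
    w = np.asarray(spectrum.fluence, dtype=float)
    pos = w > 0
    e, w = e[pos], w[pos]
    if e.size == 0:
        raise ValueError("spectrum has no positive bins")
    if e.min() < tables.emin() or e.max() > tables.emax():
        raise ValueError("spectrum support outside the coefficient tables")
    w = w / w.sum()
    num = float(np.sum(w * _spline_mu_en(comp_a, e, tables)))
    den = float(np.sum(w * _spline_mu_en(comp_b, e, tables)))
    return num / den


# ---------------------------------------------------------------------------
# analytic scatter pieces shared with the transport kernel
# ---------------------------------------------------------------------------

_COS_GRID = np.linspace(-1.0, 1.0, 4001)


def klein_nishina(e_kev: float) -> tuple[float, float]:
    """Free-electron Klein-Nishina total and energy-transfer cross sections (cm^2)."""
    k = e_kev / ME_KEV
    mu = _COS_GRID
    kappa = 1.0 / (1.0 + k * (1.0 - mu))
    dsdmu = math.pi * R_E_CM**2 * kappa**2 * (kappa + 1.0 / kappa - (1.0 - mu**2))
    total = float(np.trapezoid(dsdmu, mu))
    transfer = float(np.trapezoid(dsdmu * (1.0 - kappa), mu))
    return total, transfer


def electrons_per_gram(comp: MaterialComposition, tables: MeacTables | None = None) -> float:
    tables = tables or load_meac_tables()
    return sum(w * tables.z[el] / tables.a[el] * N_A
               for el, w in comp.fractions.items() if w > 0)


def interaction_partition(comp: MaterialComposition, e_grid: np.ndarray,
                          tables: MeacTables | None = None):
    """Split mu/rho into (photoelectric+coherent residual, incoherent) parts.

    The incoherent part is the free-electron Klein-Nishina coefficient; the
    residual (total minus incoherent, floored at 0) is treated as absorption
    in transport.  Returns ``(mu_total, mu_absorb, mu_incoherent)`` in
    cm^2/g on ``e_grid``.
    """
    tables = tables or load_meac_tables()
    mu_tot, _ = attenuation(comp, e_grid, tables)
    ne = electrons_per_gram(comp, tables)
    incoh = np.array([ne * klein_nishina(float(e))[0] for e in e_grid])
    incoh = np.minimum(incoh, mu_tot * (1.0 - 1e-9))
    absorb = np.clip(mu_tot - incoh, 0.0, None)
    return mu_tot, absorb, incoh
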