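"""CT source model: spectra, bowtie filtration, geometry, calibration.

Models a dual-tube fan-beam scanner in helical shuttle mode.  Photons start
from a point focus on a circle of radius ``focus_iso_mm`` around the
isocenter; the gantry angle runs continuously over ``rotations`` full turns
while the focus advances ``table_increment_mm`` per turn along z.  Fan angle
is uniform within each tube's half fan angle; the cone (z) opening covers
the beam collimation at the isocenter.  Photon energies follow the tube
spectrum hardened by the fan-angle-dependent Al-equivalent bowtie thickness.

Absolute dose comes from a measured free-in-air kerma at the isocenter: the
closed-form kerma per simulated photon ties the simulated energy-deposition
grid to mGy for the protocol's mAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .materials import load_compositions, load_meac_tables, attenuation

__all__ = [
    "Spectrum",
    "BowtieProfile",
    "ScanProtocol",
    "load_spectrum",
    "packaged_spectrum",
    "load_bowtie",
    "packaged_bowtie",
    "bowtie_filtered_spectrum",
    "sample_emission",
    "air_kerma_per_photon",
    "calibration_factor",
]

RHO_AL = 2.699  # g/cm^3
KEV_TO_J = 1.602176634e-16


@dataclass
class Spectrum:
    """Relative photon fluence per 1 keV energy bin."""

    energies: np.ndarray  # keV, 1 keV spacing
    fluence: np.ndarray  # relative, >= 0
    kv: int = 0

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.fluence = np.asarray(self.fluence, dtype=float)
        if self.energies.shape != self.fluence.shape:
            raise ValueError("energy and fluence arrays differ in length")
        if np.any(self.fluence < 0):
            raise ValueError("negative fluence")
        if not np.any(self.fluence > 0):
            raise ValueError("spectrum has no positive bins")
        if self.kv and self.energies[self.fluence > 0].max() > self.kv + 0.5:
            raise ValueError(f"spectrum contains energies above {self.kv} kV")

    @property
    def weights(self) -> np.ndarray:
        """Normalised spectral weights R_E."""
        return self.fluence / self.fluence.sum()

    def mean_energy(self) -> float:
        return float(np.sum(self.weights * self.energies))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# energy_keV relative_fluence\n")
            for e, f in zip(self.energies, self.fluence):
                fh.write(f"{e:.1f} {f:.8e}\n")


@dataclass
class BowtieProfile:
    """Al-equivalent thickness (mm) vs. signed fan angle (rad)."""

    angles: np.ndarray
    thickness_mm: np.ndarray
    tube: str = "A"

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.thickness_mm = np.asarray(self.thickness_mm, dtype=float)
        if np.any(self.thickness_mm < 0):
            raise ValueError("bowtie thickness must be >= 0")
        if not np.all(np.diff(self.angles) > 0):
            raise ValueError("bowtie angles must be strictly increasing")

    def thickness(self, fan_angle) -> np.ndarray:
        a = np.asarray(fan_angle, dtype=float)
        if np.any(a < self.angles[0] - 1e-12) or np.any(a > self.angles[-1] + 1e-12):
            raise ValueError(
                f"fan angle outside bowtie domain [{self.angles[0]:.4f}, {self.angles[-1]:.4f}] rad"
            )
        return np.interp(a, self.angles, self.thickness_mm)


@dataclass
class ScanProtocol:
    """Scan geometry and output constants of the shuttle-mode protocol."""

    kv: int = 80
    mas: float = 370.0
    tubes: tuple[str, ...] = ("A", "B")
    half_fan: dict = field(default_factory=lambda: {"A": 0.7955 / 2, "B": 0.5441 / 2})
    focus_iso_mm: float = 595.0
    collimation_mm: float = 38.4
    table_increment_mm: float = 34.56
    rotations: int = 2
    projections_per_rotation: int = 36
    arc_fraction: float = 95.0 / 360.0
    time_points: int = 15
    air_kerma_per_100mas: float = 5.66  # mGy at the isocenter
    discrete_projections: bool = False

    def __post_init__(self):
        if not 0 < self.arc_fraction <= 1:
            raise ValueError("arc fraction must lie in (0, 1]")
        for name in ("mas", "focus_iso_mm", "collimation_mm", "table_increment_mm",
                     "air_kerma_per_100mas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pitch(self) -> float:
        return self.table_increment_mm / self.collimation_mm

    @classmethod
    def flash80(cls) -> "ScanProtocol":
        return cls(kv=80, mas=370.0, air_kerma_per_100mas=5.66)

    @classmethod
    def flash100(cls) -> "ScanProtocol":
        return cls(kv=100, mas=300.0, air_kerma_per_100mas=10.35)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_two_column(text: str) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()[:2]
        rows.append((float(a), float(b)))
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1]


def load_spectrum(path, kv: int | None = None) -> Spectrum:
    """Load a two-column (keV, relative fluence) file, rebinned to 1 keV."""
    e, f = _read_two_column(Path(path).read_text())
    if np.any(f < 0):
        raise ValueError(f"{path}: negative fluence")
    kv = kv or int(round(e[f > 0].max()))
    grid = np.arange(1.0, kv + 1.0)
    binned = np.zeros_like(grid)
    idx = np.clip(np.rint(e - 1.0).astype(int), 0, len(grid) - 1)
    np.add.at(binned, idx, f)
    return Spectrum(grid, binned, kv)


def packaged_spectrum(kv: int) -> Spectrum:
    """The packaged synthetic tungsten spectrum for 80 or 100 kV."""
    text = resources.files("perfdose.data").joinpath(
        f"spectrum_{kv}kv_synthetic.txt").read_text()
    e, f = _read_two_column(text)
    return Spectrum(e, f, kv)


def load_bowtie(path, tube: str = "A") -> BowtieProfile:
    a, t = _read_two_column(Path(path).read_text())
    return BowtieProfile(a, t, tube)


def packaged_bowtie(tube: str) -> BowtieProfile:
    """Packaged synthetic Al-equivalent bowtie (80 kV shape, both voltages)."""
    text = resources.files("perfdose.data").joinpath(
        f"bowtie_tube{tube}_80kv_synthetic.txt").read_text()
    a, t = _read_two_column(text)
    return BowtieProfile(a, t, tube)


# ---------------------------------------------------------------------------
# filtration and emission
# ---------------------------------------------------------------------------

def _al_mu(e_kev: np.ndarray) -> np.ndarray:
    comps = load_compositions()
    mu, _ = attenuation(comps["aluminium"], e_kev, load_meac_tables())
    return np.asarray(mu)


def bowtie_filtered_spectrum(spectrum: Spectrum, bowtie: BowtieProfile,
                             fan_angle: float) -> Spectrum:
    """Spectrum hardened by the bowtie thickness at ``fan_angle``."""
    t_mm = float(bowtie.thickness(fan_angle))
    if t_mm == 0.0:
        return Spectrum(spectrum.energies.copy(), spectrum.fluence.copy(), spectrum.kv)
    trans = np.exp(-_al_mu(spectrum.energies) * RHO_AL * t_mm / 10.0)
    return Spectrum(spectrum.energies.copy(), spectrum.fluence * trans, spectrum.kv)


def sample_emission(spectrum: Spectrum, bowtie: BowtieProfile,
                    protocol: ScanProtocol, tube: str, rng: np.random.Generator,
                    n: int, iso_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
                    n_fan_strata: int = 32):
    """Sample ``n`` emission photons for one tube.

    Returns ``(energies keV, origins (n,3) mm, directions (n,3), weights)``.
    Gantry angle is continuous-uniform over ``rotations`` turns (start-angle
    averaging); the focus z advances linearly (helical); fan angle is uniform
    within the tube's half fan angle and the cone angle covers the beam
    collimation at the isocenter.  Energies are drawn from the
    bowtie-filtered spectrum of the photon's fan-angle stratum.
    """
    half = protocol.half_fan[tube]
    R = protocol.focus_iso_mm
    total_angle = 2.0 * np.pi * protocol.rotations

    if protocol.discrete_projections:
        n_proj = protocol.projections_per_rotation * protocol.rotations
        phi = (rng.integers(0, n_proj, n) + 0.5) / n_proj * total_angle
    else:
        phi = rng.uniform(0.0, total_angle, n)
    # focus z: one shuttle pass advances one table increment over the whole
    # simulated angular range, so the imaged length is increment + collimation
    # (~73 mm for the default protocol)
    travel = protocol.table_increment_mm
    z_f = iso_mm[2] - travel / 2.0 + phi / total_angle * travel

    alpha = rng.uniform(-half, half, n)
    dz = rng.uniform(-protocol.collimation_mm / 2.0, protocol.collimation_mm / 2.0, n)

    # focus position on the source circle
    fx = iso_mm[0] + R * np.sin(phi)
    fy = iso_mm[1] - R * np.cos(phi)
    origins = np.stack([fx, fy, z_f], axis=1)

    # direction: toward the isocenter, rotated in-plane by the fan angle,
    # tilted by the cone angle covering the collimation at the isocenter
    beta = phi + np.pi + alpha  # in-plane direction angle (from +y toward +x)
    dx = np.sin(beta)
    dy = -np.cos(beta)
    tan_gamma = dz / R
    norm = np.sqrt(1.0 + tan_gamma**2)
    directions = np.stack([dx / norm, dy / norm, tan_gamma / norm], axis=1)

    # stratified energies from the filtered spectrum
    edges = np.linspace(-half, half, n_fan_strata + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    strata = np.clip(np.searchsorted(edges, alpha) - 1, 0, n_fan_strata - 1)
    energies = np.empty(n)
    for s, c in enumerate(centers):
        sel = strata == s
        if not sel.any():
            continue
        filt = bowtie_filtered_spectrum(spectrum, bowtie, float(c))
        cdf = np.cumsum(filt.weights)
        u = rng.uniform(0.0, 1.0, int(sel.sum()))
        energies[sel] = filt.energies[np.searchsorted(cdf, u)]
    return energies, origins, directions, np.ones(n)


def air_kerma_per_photon(spectrum: Spectrum, bowtie: BowtieProfile,
                         protocol: ScanProtocol, tube: str = "A") -> float:
    """Closed-form free-in-air kerma at the isocenter per simulated photon (mGy).

    The emission sampler spreads photons uniformly over fan angle (2*half)
    and collimation height (c at the isocenter), so the photon fluence at
    the isocenter per history is 1 / (2 * half * c * R); the kerma follows
    from the centre-ray filtered spectrum as sum_E R'_E E (mu_en/rho)_air.
    Scatter and air attenuation are neglected.
    """
    half = protocol.half_fan[tube]
    c_cm = protocol.collimation_mm / 10.0
    r_cm = protocol.focus_iso_mm / 10.0
    fluence = 1.0 / (2.0 * half * c_cm * r_cm)  # photons / cm^2 / history

    center = bowtie_filtered_spectrum(spectrum, bowtie, 0.0)
    comps = load_compositions()
    _, mu_en_air = attenuation(comps["air"], center.energies, load_meac_tables())
    # Gy = J/kg; coefficients cm^2/g -> *1000 g/kg
    kerma_gy = float(np.sum(center.weights * center.energies * KEV_TO_J
                            * mu_en_air * 1000.0) * fluence)
    return kerma_gy * 1000.0  # mGy


def calibration_factor(k_sim_per_photon: float, protocol: ScanProtocol,
                       n_photons: int) -> float:
    """Scale from raw simulated dose (sum over histories) to absolute mGy.

    ``scale = (k_meas_per_100mAs * mAs / 100) / (k_sim_per_photon * N)``:
    applying it to the energy-deposition grid of ``N`` histories yields the
    absolute dose of one helical rotation pair at the protocol's exposure.
    """
    if k_sim_per_photon <= 0 or n_photons <= 0:
        raise ValueError("kerma per photon and photon count must be positive")
    target = protocol.air_kerma_per_100mas * protocol.mas / 100.0
    return target / (k_sim_per_photon * n_photons)
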