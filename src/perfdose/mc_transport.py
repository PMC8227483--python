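"""Voxel Monte Carlo photon transport with Woodcock (delta) tracking.

Histories start from the CT source model and are tracked through the voxel
grid against a per-energy majorant attenuation coefficient; fictitious
interactions avoid per-voxel boundary crossings.  Real interactions are
photoelectric absorption (local deposit of the full remaining energy),
incoherent scatter with free-electron Klein-Nishina sampling (local deposit
of the electron energy; kerma approximation, no electron transport) and
optional coherent scatter (Thomson-shaped deflection, no deposit).
Histories end below the energy cutoff (local deposit), at the interaction
cap (local deposit of the remaining energy, conserving energy) or on exit.

A slower, independent analog ray-trace sampler (`simulate_raytrace`) tracks
photons voxel-by-voxel with explicit boundary crossings; it shares no path
logic with the Woodcock kernel and serves as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import ct_source
from .materials import (
    MaterialTable,
    load_meac_tables,
    attenuation,
    electrons_per_gram,
    klein_nishina,
)
from .voxel_io import VoxelVolume

__all__ = [
    "TransportConfig",
    "DoseGrid",
    "TransportTables",
    "build_transport_tables",
    "simulate_tube",
    "simulate_raytrace",
    "transport_photon",
    "sample_compton",
    "combine_and_scale",
]

ME_KEV = 510.99895
KEV_TO_J = 1.602176634e-16
E_GRID = np.arange(1.0, 151.0)  # 1 keV transport bins


@dataclass
class TransportConfig:
    """Photon-transport settings."""

    n_photons: int = 100_000
    max_interactions: int = 10
    cutoff_kev: float = 10.0
    seed: int = 0
    rayleigh: bool = True
    batch_size: int = 200_000
    uncertainty: bool = False

    def __post_init__(self):
        if self.n_photons < 1:
            raise ValueError("photon count must be >= 1")
        if self.cutoff_kev < 1.0:
            raise ValueError("energy cutoff must be >= 1 keV")


@dataclass
class DoseGrid:
    """Absorbed dose per voxel (mGy), aligned with the input HU volume."""

    dose: VoxelVolume
    uncertainty: np.ndarray | None = None  # relative SD per voxel
    meta: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.dose.values


@dataclass
class TransportTables:
    """Per-material cross-section tables on the 1 keV transport grid."""

    mu_lin: np.ndarray  # (n_mat, n_E) linear attenuation 1/mm
    p_pe: np.ndarray  # photoelectric fraction of mu
    p_pe_coh: np.ndarray  # photoelectric + coherent cumulative fraction
    mu_majorant: np.ndarray  # (n_E,) max over materials, 1/mm
    density: np.ndarray  # g/cm^3 per material


def _screening_b(tables) -> float:
    # the screening constant is recorded in the vendored table header
    from importlib import resources

    for line in resources.files("perfdose.data").joinpath(
            "element_coefficients.tsv").read_text().splitlines():
        if line.startswith("# screening constant"):
            return float(line.split("=")[1].split()[0])
    return 4.5754


def _coherent_mu(comp, e_grid: np.ndarray, tables) -> np.ndarray:
    """Screened-form-factor coherent coefficient (cm^2/g) of a composition."""
    b = _screening_b(tables)
    sigma_t = 8.0 / 3.0 * math.pi * (2.8179403e-13) ** 2
    hbarc = 1.9732698
    cosg = np.linspace(-1.0, 1.0, 801)
    out = np.zeros_like(e_grid)
    for el, w in comp.fractions.items():
        if w == 0.0:
            continue
        z = tables.z[el]
        per_atom = 6.02214076e23 / tables.a[el]
        q0 = b * z ** (1.0 / 3.0)
        for i, e in enumerate(e_grid):
            q = 2.0 * (e / hbarc) * np.sqrt((1.0 - cosg) / 2.0)
            ff = z / (1.0 + (q / q0) ** 2) ** 2
            dsdmu = 3.0 / 8.0 * sigma_t * (1.0 + cosg**2) / 2.0 * ff**2
            out[i] += w * per_atom * np.trapezoid(dsdmu, cosg)
    return out


def build_transport_tables(material_table: MaterialTable,
                           rayleigh: bool = True,
                           present: np.ndarray | None = None) -> TransportTables:
    """Precompute per-material linear attenuation and branching fractions.

    ``present`` restricts the Woodcock majorant to the material indices that
    actually occur in the volume (tighter majorant, fewer fictitious
    interactions); all materials keep their cross sections.
    """
    meac = load_meac_tables()
    comps = material_table.compositions
    n_mat, n_e = len(comps), len(E_GRID)
    mu_lin = np.zeros((n_mat, n_e))
    p_pe = np.zeros((n_mat, n_e))
    p_pe_coh = np.zeros((n_mat, n_e))
    density = np.array([c.density for c in comps])
    kn_tot = np.array([klein_nishina(float(e))[0] for e in E_GRID])
    for m, comp in enumerate(comps):
        mu_tot, _ = attenuation(comp, E_GRID, meac)
        incoh = electrons_per_gram(comp, meac) * kn_tot
        incoh = np.minimum(incoh, mu_tot * (1.0 - 1e-9))
        coh = np.minimum(_coherent_mu(comp, E_GRID, meac), mu_tot - incoh)
        pe = np.clip(mu_tot - incoh - coh, 0.0, None)
        if not rayleigh:
            mu_tot = mu_tot - coh  # transport without coherent scatter
            coh = np.zeros_like(coh)
        mu_lin[m] = mu_tot * comp.density / 10.0  # cm^2/g * g/cm^3 -> 1/cm -> /10 = 1/mm
        with np.errstate(invalid="ignore", divide="ignore"):
            tot = pe + coh + incoh
            p_pe[m] = np.where(tot > 0, pe / tot, 1.0)
            p_pe_coh[m] = np.where(tot > 0, (pe + coh) / tot, 1.0)
    rows = mu_lin if present is None else mu_lin[np.asarray(present, dtype=int)]
    return TransportTables(mu_lin, p_pe, p_pe_coh, rows.max(axis=0), density)


# ---------------------------------------------------------------------------
# physics sampling (shared by kernel and reference samplers)
# ---------------------------------------------------------------------------

def sample_compton(energy_kev: float, rng: np.random.Generator) -> tuple[float, float]:
    """Sample a Klein-Nishina scatter: returns (scattered energy keV, polar angle rad).

    Rejection sampling of cos(theta) against the KN differential cross
    section; the scattered energy follows the Compton relation at the
    sampled angle.
    """
    k = energy_kev / ME_KEV
    while True:
        c = rng.uniform(-1.0, 1.0)
        kappa = 1.0 / (1.0 + k * (1.0 - c))
        f = kappa * kappa * (kappa + 1.0 / kappa - (1.0 - c * c))
        if rng.uniform(0.0, 2.0) <= f:
            return energy_kev * kappa, math.acos(c)


def _rotate(u: np.ndarray, cos_t: float, phi: float) -> np.ndarray:
    st = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp, sp = math.cos(phi), math.sin(phi)
    ux, uy, uz = u
    if abs(uz) > 0.99999:
        sign = 1.0 if uz > 0 else -1.0
        return np.array([st * cp, st * sp, cos_t * sign])
    den = math.sqrt(1.0 - uz * uz)
    return np.array([
        ux * cos_t + st * (ux * uz * cp - uy * sp) / den,
        uy * cos_t + st * (uy * uz * cp + ux * sp) / den,
        uz * cos_t - st * cp * den,
    ])


def transport_photon(photon, grids, config: TransportConfig,
                     rng: np.random.Generator):
    """Track a single photon (reference implementation); returns deposits.

    ``photon`` is ``(energy_kev, origin_mm, direction)``; ``grids`` is
    ``(mat_index_volume, TransportTables, spacing_mm)``.  Returns a list of
    ``((ix, iy, iz), deposited_kev)``; deposited plus escaped energy equals
    the initial energy exactly.
    """
    e0, pos, u = float(photon[0]), np.array(photon[1], float), np.array(photon[2], float)
    mat, tab, spacing = grids
    spacing = np.asarray(spacing, float)
    box = np.array(mat.shape) * spacing
    deposits = []

    # advance to the grid bounding box
    with np.errstate(divide="ignore"):
        t1 = (0.0 - pos) / u
        t2 = (box - pos) / u
    tmin = np.minimum(t1, t2).max()
    tmax = np.maximum(t1, t2).min()
    if tmax <= max(tmin, 0.0):
        return deposits  # geometric miss
    if tmin > 0:
        pos = pos + u * (tmin + 1e-9)

    e = e0
    n_int = 0
    while True:
        ei = min(max(int(round(e)) - 1, 0), len(E_GRID) - 1)
        mu_maj = tab.mu_majorant[ei]
        s = -math.log(rng.uniform(1e-12, 1.0)) / mu_maj
        pos = pos + u * s
        idx = np.floor(pos / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= mat.shape):
            break  # escaped
        m = mat[idx[0], idx[1], idx[2]]
        if rng.uniform(0.0, 1.0) > tab.mu_lin[m, ei] / mu_maj:
            continue  # fictitious interaction
        n_int += 1
        r = rng.uniform(0.0, 1.0)
        vox = (int(idx[0]), int(idx[1]), int(idx[2]))
        if r < tab.p_pe[m, ei]:
            deposits.append((vox, e))
            e = 0.0
            break
        if r < tab.p_pe_coh[m, ei]:
            # coherent: Thomson-shaped deflection, no energy loss
            while True:
                c = rng.uniform(-1.0, 1.0)
                if rng.uniform(0.0, 1.0) <= (1.0 + c * c) / 2.0:
                    break
            u = _rotate(u, c, rng.uniform(0.0, 2.0 * math.pi))
        else:
            e_new, theta = sample_compton(e, rng)
            deposits.append((vox, e - e_new))
            e = e_new
            u = _rotate(u, math.cos(theta), rng.uniform(0.0, 2.0 * math.pi))
            if e < config.cutoff_kev:
                deposits.append((vox, e))
                e = 0.0
                break
        if n_int >= config.max_interactions:
            if e > 0.0:
                deposits.append((vox, e))
                e = 0.0
            break
    return deposits


# ---------------------------------------------------------------------------
# Woodcock kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_batch(energies, origins, directions, mat, sx, sy, sz,
               mu_lin, p_pe, p_pe_coh, mu_maj, edep,
               max_inter, cutoff, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    nx, ny, nz = mat.shape
    bx, by, bz = nx * sx, ny * sy, nz * sz
    escaped = 0.0
    n_e = mu_maj.shape[0]
    for i in range(energies.shape[0]):
        e = energies[i]
        px, py, pz = origins[i, 0], origins[i, 1], origins[i, 2]
        ux, uy, uz = directions[i, 0], directions[i, 1], directions[i, 2]
        # ray-box entry
        tmin = -1.0e30
        tmax = 1.0e30
        for ax in range(3):
            if ax == 0:
                p, u, b = px, ux, bx
            elif ax == 1:
                p, u, b = py, uy, by
            else:
                p, u, b = pz, uz, bz
            if abs(u) < 1e-12:
                if p < 0.0 or p > b:
                    tmin = 1.0e31
                    break
            else:
                t1 = (0.0 - p) / u
                t2 = (b - p) / u
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
        if tmax <= tmin or tmin > 1.0e30:
            escaped += e
            continue
        if tmin > 0.0:
            px += ux * (tmin + 1e-9)
            py += uy * (tmin + 1e-9)
            pz += uz * (tmin + 1e-9)
        n_int = 0
        alive = True
        while alive:
            ei = int(e + 0.5) - 1
            if ei < 0:
                ei = 0
            elif ei >= n_e:
                ei = n_e - 1
            mm = mu_maj[ei]
            s = -math.log(np.random.random() + 1e-300) / mm
            px += ux * s
            py += uy * s
            pz += uz * s
            ix = int(px / sx)
            iy = int(py / sy)
            iz = int(pz / sz)
            if px < 0.0 or py < 0.0 or pz < 0.0 or ix >= nx or iy >= ny or iz >= nz:
                escaped += e
                break
            m = mat[ix, iy, iz]
            if np.random.random() > mu_lin[m, ei] / mm:
                continue
            n_int += 1
            r = np.random.random()
            if r < p_pe[m, ei]:
                edep[ix, iy, iz] += e
                e = 0.0
                break
            elif r < p_pe_coh[m, ei]:
                # Thomson-shaped coherent deflection
                while True:
                    c = 2.0 * np.random.random() - 1.0
                    if np.random.random() <= (1.0 + c * c) / 2.0:
                        break
            else:
                k = e / ME_KEV
                while True:
                    c = 2.0 * np.random.random() - 1.0
                    kap = 1.0 / (1.0 + k * (1.0 - c))
                    f = kap * kap * (kap + 1.0 / kap - (1.0 - c * c))
                    if 2.0 * np.random.random() <= f:
                        break
                e_new = e * kap
                edep[ix, iy, iz] += e - e_new
                e = e_new
            # rotate direction by polar angle acos(c), uniform azimuth
            phi = 2.0 * math.pi * np.random.random()
            st = math.sqrt(max(0.0, 1.0 - c * c))
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                sign = 1.0 if uz > 0.0 else -1.0
                ux, uy, uz = st * cp, st * sp, c * sign
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = ux * c + st * (ux * uz * cp - uy * sp) / den
                nuy = uy * c + st * (uy * uz * cp + ux * sp) / den
                nuz = uz * c - st * cp * den
                ux, uy, uz = nux, nuy, nuz
            if e > 0.0 and e < cutoff:
                edep[ix, iy, iz] += e
                e = 0.0
                break
            if n_int >= max_inter:
                if e > 0.0:
                    edep[ix, iy, iz] += e
                    e = 0.0
                break
        if e > 0.0 and not alive:
            pass
    return escaped


def simulate_tube(hu_volume: VoxelVolume, material_table: MaterialTable,
                  protocol: ct_source.ScanProtocol, tube: str,
                  config: TransportConfig,
                  spectrum: ct_source.Spectrum | None = None,
                  bowtie: ct_source.BowtieProfile | None = None,
                  iso_mm: tuple[float, float, float] | None = None,
                  calibrate: bool = True) -> DoseGrid:
    """Simulate one tube's contribution to the absorbed-dose grid (mGy).

    Photons are emitted by the CT source model and tracked with the Woodcock
    kernel; the per-voxel energy deposition is converted to dose with the
    nominal material density and, when ``calibrate``, scaled to absolute mGy
    via the measured free-in-air kerma at the isocenter.
    """
    spectrum = spectrum or ct_source.packaged_spectrum(protocol.kv)
    bowtie = bowtie or ct_source.packaged_bowtie(tube)
    mat = np.ascontiguousarray(material_table.index_of_hu(hu_volume.values).astype(np.int16))
    tab = build_transport_tables(material_table, rayleigh=config.rayleigh,
                                 present=np.unique(mat))
    shape = hu_volume.shape
    if iso_mm is None:
        iso_mm = tuple(s * sp / 2.0 for s, sp in zip(shape, hu_volume.spacing))

    rng = np.random.default_rng(config.seed)
    n_batches = max(1, -(-config.n_photons // config.batch_size))
    edep_batches = []
    escaped = 0.0
    emitted = 0.0
    remaining = config.n_photons
    for bi in range(n_batches):
        n = min(config.batch_size, remaining)
        remaining -= n
        e, o, d, _ = ct_source.sample_emission(spectrum, bowtie, protocol, tube,
                                               rng, n, iso_mm)
        emitted += e.sum()
        edep = np.zeros(shape, dtype=np.float64)
        kernel_seed = int((config.seed * 1_000_003 + bi * 7919 + 1) % 2_147_483_647)
        escaped += _run_batch(e, np.ascontiguousarray(o), np.ascontiguousarray(d),
                              mat, *hu_volume.spacing,
                              tab.mu_lin, tab.p_pe, tab.p_pe_coh, tab.mu_majorant,
                              edep, config.max_interactions, config.cutoff_kev,
                              kernel_seed)
        edep_batches.append(edep)
    edep_total = np.sum(edep_batches, axis=0)

    # energy (keV) -> dose (mGy) via voxel mass
    voxel_cm3 = hu_volume.voxel_volume_mm3() / 1000.0
    mass_kg = tab.density[mat] * voxel_cm3 * 1e-3
    raw_dose = edep_total * KEV_TO_J / mass_kg * 1000.0  # mGy (uncalibrated)

    scale = 1.0
    if calibrate:
        k_sim = ct_source.air_kerma_per_photon(spectrum, bowtie, protocol, tube)
        scale = ct_source.calibration_factor(k_sim, protocol, config.n_photons)
        raw_dose = raw_dose * scale  # scale already carries the 1/N factor

    uncertainty = None
    if config.uncertainty and len(edep_batches) > 1:
        stack = np.stack(edep_batches)
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1) / math.sqrt(len(edep_batches))
        with np.errstate(invalid="ignore", divide="ignore"):
            uncertainty = np.where(mean > 0, sd / mean, 0.0)

    meta = {
        "tube": tube,
        "kv": protocol.kv,
        "n_photons": config.n_photons,
        "seed": config.seed,
        "escaped_fraction": escaped / emitted if emitted else 0.0,
        "calibration_scale": scale,
        "iso_mm": iso_mm,
    }
    vol = VoxelVolume(raw_dose, hu_volume.spacing, hu_volume.origin, role="dose")
    return DoseGrid(vol, uncertainty, meta)


# ---------------------------------------------------------------------------
# independent analog ray-trace sampler (cross-check)
# ---------------------------------------------------------------------------

def simulate_raytrace(energies, origins, directions, mat: np.ndarray,
                      tables: TransportTables, spacing, config: TransportConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Analog voxel-by-voxel transport (no Woodcock); returns the keV grid.

    Tracks every photon to the next voxel boundary or interaction point with
    explicit exponential sampling inside each voxel.  Vectorised over
    photons; independent of the delta-tracking kernel.
    """
    spacing = np.asarray(spacing, float)
    shape = np.array(mat.shape)
    box = shape * spacing
    edep = np.zeros(mat.shape, dtype=np.float64)

    pos = np.array(origins, dtype=float).copy()
    u = np.array(directions, dtype=float).copy()
    e = np.array(energies, dtype=float).copy()
    n_int = np.zeros(len(e), dtype=int)

    # advance to the box
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (0.0 - pos) / u
        t2 = (box - pos) / u
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = tmax > np.maximum(tmin, 0.0)
    pos[hit] += u[hit] * (np.maximum(tmin[hit], 0.0) + 1e-9)[:, None]
    alive = hit.copy()

    def deposit(idx3, amounts):
        np.add.at(edep, (idx3[:, 0], idx3[:, 1], idx3[:, 2]), amounts)

    while alive.any():
        ai = np.nonzero(alive)[0]
        p, d, ee = pos[ai], u[ai], e[ai]
        idx = np.floor(p / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        if not inside.all():
            alive[ai[~inside]] = False
            ai = ai[inside]
            if ai.size == 0:
                continue
            p, d, ee, idx = p[inside], d[inside], ee[inside], idx[inside]
        ei = np.clip(np.rint(ee).astype(int) - 1, 0, len(E_GRID) - 1)
        m = mat[idx[:, 0], idx[:, 1], idx[:, 2]]
        mu = tables.mu_lin[m, ei]
        # distance to next boundary
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(d > 0,
                            ((idx + 1) * spacing - p) / d,
                            np.where(d < 0, (idx * spacing - p) / d, np.inf))
        t_b = step.min(axis=1)
        s = -np.log(rng.uniform(1e-12, 1.0, len(ai))) / np.maximum(mu, 1e-12)
        interact = (s < t_b) & (mu > 0)

        # move the non-interacting photons across the boundary
        cross = ~interact
        pos[ai[cross]] = p[cross] + d[cross] * (t_b[cross] + 1e-9)[:, None]

        if interact.any():
            ii = ai[interact]
            pint = p[interact] + d[interact] * s[interact][:, None]
            pos[ii] = pint
            vox = idx[interact]
            mi = m[interact]
            eii = ei[interact]
            r = rng.uniform(0.0, 1.0, len(ii))
            n_int[ii] += 1

            pe = r < tables.p_pe[mi, eii]
            coh = (~pe) & (r < tables.p_pe_coh[mi, eii])
            com = ~(pe | coh)

            if pe.any():
                deposit(vox[pe], e[ii[pe]])
                e[ii[pe]] = 0.0
                alive[ii[pe]] = False
            for j in np.nonzero(coh)[0]:
                while True:
                    c = rng.uniform(-1.0, 1.0)
                    if rng.uniform(0.0, 1.0) <= (1.0 + c * c) / 2.0:
                        break
                u[ii[j]] = _rotate(u[ii[j]], c, rng.uniform(0.0, 2.0 * math.pi))
            if com.any():
                for j in np.nonzero(com)[0]:
                    gid = ii[j]
                    e_new, theta = sample_compton(e[gid], rng)
                    deposit(vox[j:j + 1], np.array([e[gid] - e_new]))
                    e[gid] = e_new
                    u[gid] = _rotate(u[gid], math.cos(theta), rng.uniform(0.0, 2.0 * math.pi))
                    if e[gid] < config.cutoff_kev:
                        deposit(vox[j:j + 1], np.array([e[gid]]))
                        e[gid] = 0.0
                        alive[gid] = False
            capped = (n_int[ii] >= config.max_interactions) & alive[ii]
            if capped.any():
                deposit(vox[capped], e[ii[capped]])
                e[ii[capped]] = 0.0
                alive[ii[capped]] = False
    return edep


def combine_and_scale(dose_a: DoseGrid, dose_b: DoseGrid | None,
                      protocol: ct_source.ScanProtocol) -> DoseGrid:
    """Total shuttle-mode dose: (D_A + D_B) * arc_fraction * time_points.

    The partial-rotation arc (default 95/360) and the number of
    time-attenuation-curve points (default 15) scale the per-rotation-pair
    dose to the full dynamic examination.
    """
    total = dose_a.values.copy()
    if dose_b is not None:
        if dose_b.values.shape != total.shape:
            raise ValueError("dose grids have mismatching shapes")
        total = total + dose_b.values
    total *= protocol.arc_fraction * protocol.time_points
    meta = dict(dose_a.meta)
    meta.update({"arc_fraction": protocol.arc_fraction,
                 "time_points": protocol.time_points,
                 "tubes_combined": [dose_a.meta.get("tube")] +
                 ([dose_b.meta.get("tube")] if dose_b else [])})
    vol = dose_a.dose.copy(values=total)
    return DoseGrid(vol, None, meta)
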