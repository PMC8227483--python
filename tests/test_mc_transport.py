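"""Photon transport: sampling physics, conservation, tracking cross-checks."""

import math

import numpy as np
import pytest
from scipy import stats

from perfdose import ct_source as cs
from perfdose import materials as mat
from perfdose import mc_transport as mc
from perfdose.voxel_io import VoxelVolume

ME_KEV = 510.99895


def kn_pdf(cos_t, e_kev):
    k = e_kev / ME_KEV
    kappa = 1.0 / (1.0 + k * (1.0 - cos_t))
    return kappa**2 * (kappa + 1.0 / kappa - (1.0 - cos_t**2))


def kn_mean_scattered_energy(e_kev):
    c = np.linspace(-1.0, 1.0, 200_001)
    pdf = kn_pdf(c, e_kev)
    kappa = 1.0 / (1.0 + e_kev / ME_KEV * (1.0 - c))
    return float(np.trapezoid(pdf * e_kev * kappa, c) / np.trapezoid(pdf, c))


@pytest.fixture(scope="module")
def water_table():
    return mat.build_material_table(499, 80)


@pytest.fixture(scope="module")
def water_tables(water_table):
    return mc.build_transport_tables(water_table)


class TestComptonSampler:
    def test_mean_scattered_energy_matches_numeric_integral(self, rng):
        e0 = 100.0
        samples = np.array([mc.sample_compton(e0, rng)[0] for _ in range(200_000)])
        expected = kn_mean_scattered_energy(e0)
        se = samples.std() / math.sqrt(len(samples))
        assert abs(samples.mean() - expected) < max(3 * se, 0.005 * expected)

    def test_cos_theta_distribution_chi_square(self, rng):
        e0 = 80.0
        cos_t = np.array([math.cos(mc.sample_compton(e0, rng)[1])
                          for _ in range(100_000)])
        edges = np.linspace(-1, 1, 21)
        hist, _ = np.histogram(cos_t, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        pdf = kn_pdf(centers, e0)
        expected = pdf / pdf.sum() * len(cos_t)
        p = stats.chisquare(hist, expected * hist.sum() / expected.sum()).pvalue
        assert p > 0.01

    def test_low_energy_limit_is_symmetric_thomson(self, rng):
        cos_t = np.array([math.cos(mc.sample_compton(1.0, rng)[1])
                          for _ in range(100_000)])
        forward = (cos_t > 0).sum()
        backward = (cos_t < 0).sum()
        se = math.sqrt(len(cos_t)) / 2
        assert abs(forward - backward) < 3 * 2 * se

    def test_energy_consistent_with_compton_relation(self, rng):
        e0 = 60.0
        for _ in range(200):
            e1, theta = mc.sample_compton(e0, rng)
            expected = e0 / (1.0 + e0 / ME_KEV * (1.0 - math.cos(theta)))
            assert e1 == pytest.approx(expected, rel=1e-12)


class TestSinglePhoton:
    def _grids(self, water_tables):
        matvol = np.zeros((10, 10, 10), dtype=np.int16)
        matvol[:] = 3  # muscle bin
        return matvol, water_tables, (5.0, 5.0, 5.0)

    def test_geometric_miss_deposits_nothing(self, water_tables, rng):
        grids = self._grids(water_tables)
        deposits = mc.transport_photon(
            (60.0, (-100.0, -100.0, -100.0), (0.0, 0.0, -1.0)),
            grids, mc.TransportConfig(), rng)
        assert deposits == []

    def test_energy_bookkeeping_exact(self, water_tables, rng):
        grids = self._grids(water_tables)
        cfg = mc.TransportConfig()
        for i in range(300):
            e0 = 15.0 + (i % 50)
            deposits = mc.transport_photon(
                (e0, (-10.0, 25.0, 25.0), (1.0, 0.0, 0.0)), grids, cfg, rng)
            total = sum(d for _, d in deposits)
            assert total <= e0 + 1e-9
            # terminated histories must have deposited everything
            if deposits and deposits[-1][1] == pytest.approx(e0 - sum(
                    d for _, d in deposits[:-1])):
                pass  # absorbed; exact conservation by construction

    def test_forced_photoelectric_single_full_deposit(self, water_tables, rng):
        matvol, tab, spacing = self._grids(water_tables)
        forced = mc.TransportTables(tab.mu_lin, np.ones_like(tab.p_pe),
                                    np.ones_like(tab.p_pe_coh), tab.mu_majorant,
                                    tab.density)
        deposits = mc.transport_photon(
            (60.0, (-10.0, 25.0, 25.0), (1.0, 0.0, 0.0)),
            (matvol, forced, spacing), mc.TransportConfig(), rng)
        assert len(deposits) == 1
        assert deposits[0][1] == pytest.approx(60.0)


def _pencil_beam(n, e_kev, x0=-5.0):
    energies = np.full(n, e_kev)
    origins = np.tile([x0, 10.0, 10.0], (n, 1)).astype(float)
    directions = np.tile([1.0, 0.0, 0.0], (n, 1)).astype(float)
    return energies, origins, directions


class TestKernel:
    def test_beer_lambert_attenuation_of_primaries(self, water_table):
        """First-interaction depth follows exp(-mu x) for a monoenergetic beam."""
        # water-equivalent muscle column, 60 keV pencil beam along x
        hu = VoxelVolume(np.full((200, 4, 4), 30, np.int16), (1.0, 5.0, 5.0), role="hu")
        tab = mc.build_transport_tables(water_table)
        matvol = water_table.index_of_hu(hu.values).astype(np.int16)
        # absorb at first interaction so deposits mark primary interaction sites
        forced = mc.TransportTables(tab.mu_lin, np.ones_like(tab.p_pe),
                                    np.ones_like(tab.p_pe_coh), tab.mu_majorant,
                                    tab.density)
        n = 200_000
        e, o, d = _pencil_beam(n, 60.0)
        o[:, 1] = 10.0
        o[:, 2] = 10.0
        edep = np.zeros(hu.shape)
        escaped = mc._run_batch(e, o, d, matvol, 1.0, 5.0, 5.0,
                                forced.mu_lin, forced.p_pe, forced.p_pe_coh,
                                forced.mu_majorant, edep, 10, 10.0, 1234)
        counts = edep.sum(axis=(1, 2)) / 60.0
        m = water_table.index_of_hu(np.array([30]))[0]
        mu = tab.mu_lin[m, 59]  # 1/mm
        depths = np.arange(200) + 0.5
        expected = n * mu * np.exp(-mu * depths)
        sel = expected > 500
        z = (counts[sel] - expected[sel]) / np.sqrt(expected[sel])
        assert np.abs(z).mean() < 1.5
        assert np.abs(z).max() < 5.0

    def test_inverse_square_in_air(self, water_table):
        """Interaction density around a point source in air falls as 1/r^2."""
        hu = VoxelVolume(np.full((61, 61, 61), -1000, np.int16), (2.0, 2.0, 2.0),
                         role="hu")
        matvol = water_table.index_of_hu(hu.values).astype(np.int16)
        tab = mc.build_transport_tables(water_table, present=np.unique(matvol))
        centers = (np.indices(hu.shape).reshape(3, -1).T + 0.5) * 2.0
        r = np.linalg.norm(centers - 61.0, axis=1)
        shells = [(10, 20), (20, 30), (30, 40), (40, 50)]
        n = 300_000
        per_seed = []
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            u = rng.normal(size=(n, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            origins = np.tile([61.0, 61.0, 61.0], (n, 1))
            energies = np.full(n, 60.0)
            edep = np.zeros(hu.shape)
            mc._run_batch(energies, origins, u, matvol, 2.0, 2.0, 2.0,
                          tab.mu_lin, tab.p_pe, tab.p_pe_coh, tab.mu_majorant,
                          edep, 10, 10.0, 77 + seed)
            dep = edep.ravel()
            vals = []
            for lo, hi in shells:
                sel = (r >= lo) & (r < hi)
                vals.append(dep[sel].sum() / sel.sum() * ((lo + hi) / 2) ** 2)
            per_seed.append(vals)
        per_seed = np.array(per_seed)
        mean = per_seed.mean(axis=0)
        se = per_seed.std(axis=0, ddof=1) / math.sqrt(len(per_seed))
        target = mean.mean()
        z = (mean - target) / se
        assert np.all(np.abs(z) < 3.5)

    def test_woodcock_vs_raytrace_two_material_slab(self, water_table):
        """Independent analog tracker agrees with delta tracking in mean dose."""
        hu = np.full((40, 20, 20), 30, np.int16)
        hu[20:, :, :] = 1000  # bone half
        vol = VoxelVolume(hu, (2.0, 5.0, 5.0), role="hu")
        tab = mc.build_transport_tables(water_table)
        matvol = water_table.index_of_hu(vol.values).astype(np.int16)
        cfg = mc.TransportConfig(n_photons=1, seed=0)
        n = 60_000
        totals = []
        for seed in range(5):
            e, o, d = _pencil_beam(n, 60.0)
            o[:, 1] = 50.0
            o[:, 2] = 50.0
            edep = np.zeros(vol.shape)
            mc._run_batch(e, o, d, matvol, 2.0, 5.0, 5.0,
                          tab.mu_lin, tab.p_pe, tab.p_pe_coh, tab.mu_majorant,
                          edep, 10, 10.0, 1000 + seed)
            totals.append(edep.sum())
        wood_mean = np.mean(totals)
        wood_se = np.std(totals, ddof=1)
        rng = np.random.default_rng(42)
        e, o, d = _pencil_beam(20_000, 60.0)
        o[:, 1] = 50.0
        o[:, 2] = 50.0
        edep_rt = mc.simulate_raytrace(e, o, d, matvol, tab, (2.0, 5.0, 5.0), cfg, rng)
        rt_mean = edep_rt.sum() * n / 20_000
        assert abs(rt_mean - wood_mean) < 3 * max(wood_se * math.sqrt(1 + n / 20_000),
                                                  0.01 * wood_mean)

    def test_reproducibility_same_seed(self, water_table):
        hu = VoxelVolume(np.full((20, 20, 20), 30, np.int16), (5.0, 5.0, 5.0), role="hu")
        cfg = mc.TransportConfig(n_photons=20_000, seed=9)
        protocol = cs.ScanProtocol.flash80()
        a = mc.simulate_tube(hu, water_table, protocol, "A", cfg)
        b = mc.simulate_tube(hu, water_table, protocol, "A", cfg)
        assert np.array_equal(a.values, b.values)

    def test_global_energy_conservation(self, water_table):
        hu = VoxelVolume(np.full((20, 20, 20), 30, np.int16), (5.0, 5.0, 5.0), role="hu")
        tab = mc.build_transport_tables(water_table)
        matvol = water_table.index_of_hu(hu.values).astype(np.int16)
        n = 50_000
        e, o, d = _pencil_beam(n, 60.0, x0=-5.0)
        o[:, 1] = 50.0
        o[:, 2] = 50.0
        edep = np.zeros(hu.shape)
        escaped = mc._run_batch(e, o, d, matvol, 5.0, 5.0, 5.0,
                                tab.mu_lin, tab.p_pe, tab.p_pe_coh,
                                tab.mu_majorant, edep, 10, 10.0, 3)
        assert edep.sum() + escaped == pytest.approx(e.sum(), rel=1e-9)

    def test_uncertainty_scales_with_photon_count(self, water_table):
        hu = VoxelVolume(np.full((10, 10, 10), 30, np.int16), (10.0, 10.0, 10.0),
                         role="hu")
        protocol = cs.ScanProtocol.flash80()
        rels = []
        for n in (20_000, 80_000):
            cfg = mc.TransportConfig(n_photons=n, seed=4, batch_size=n // 10,
                                     uncertainty=True)
            grid = mc.simulate_tube(hu, water_table, protocol, "A", cfg)
            sel = grid.values > grid.values.max() * 0.2
            rels.append(np.median(grid.uncertainty[sel]))
        ratio = rels[0] / rels[1]  # expect ~sqrt(4) = 2
        assert 1.3 < ratio < 3.1


class TestCombineAndScale:
    def _grid(self, value):
        vol = VoxelVolume(np.full((4, 4, 4), value, float), (1, 1, 1), role="dose")
        return mc.DoseGrid(vol, meta={"tube": "A"})

    def test_shuttle_factors_arithmetic(self):
        protocol = cs.ScanProtocol.flash80()
        out = mc.combine_and_scale(self._grid(1.0), self._grid(1.0), protocol)
        assert out.values[0, 0, 0] == pytest.approx(2 * (95 / 360) * 15)
        assert out.values[0, 0, 0] == pytest.approx(7.9167, abs=1e-4)

    def test_identity_with_unit_factors(self):
        protocol = cs.ScanProtocol(arc_fraction=1.0, time_points=1)
        out = mc.combine_and_scale(self._grid(3.0), None, protocol)
        assert np.allclose(out.values, 3.0)

    def test_linearity_in_tube_a(self):
        protocol = cs.ScanProtocol.flash80()
        base = mc.combine_and_scale(self._grid(1.0), self._grid(1.0), protocol)
        double = mc.combine_and_scale(self._grid(2.0), self._grid(1.0), protocol)
        a_contrib = double.values - base.values
        assert np.allclose(a_contrib, (95 / 360) * 15 * 1.0)

    def test_shape_mismatch_errors(self):
        protocol = cs.ScanProtocol.flash80()
        other = mc.DoseGrid(VoxelVolume(np.zeros((2, 2, 2)), (1, 1, 1), role="dose"))
        with pytest.raises(ValueError, match="shape"):
            mc.combine_and_scale(self._grid(1.0), other, protocol)
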