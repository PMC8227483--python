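"""HU-to-material conversion, iodine mixtures and photon coefficients."""

import numpy as np
import pytest

from perfdose import materials as mat
from perfdose.ct_source import Spectrum

# printed iodine mass percentages of the twelve blood-iodine mixtures
PRINTED_IODINE = {
    80: [0.442, 0.570, 0.692, 0.813, 0.935, 1.057, 1.178, 1.300, 1.421,
         1.543, 1.664, 1.752],
    100: [0.581, 0.739, 0.896, 1.054, 1.211, 1.369, 1.526, 1.684, 1.842,
          2.060, 2.157, 2.396],
}
# entries where the printed value deviates from the midpoint formula
ANOMALIES = {(80, 1), (100, 10), (100, 12)}
BIN_EDGES = [(200, 249), (250, 299), (300, 349), (350, 399), (400, 449),
             (450, 499), (500, 549), (550, 599), (600, 649), (650, 699),
             (700, 749), (750, 771)]


class TestBloodHuMax:
    def test_max_rule_when_below_501(self):
        assert mat.blood_hu_max([300] * 50) == 300

    def test_fallback_499_when_few_high_values(self):
        values = [400] * 95 + [520] * 5
        assert mat.blood_hu_max(values) == 499

    def test_percentile_rule_against_sorting_oracle(self, rng):
        values = rng.uniform(200, 800, 1000)
        expected = int(round(float(np.sort(values)[int(0.9 * (len(values) - 1))])))
        got = mat.blood_hu_max(values)
        assert abs(got - expected) <= 1  # percentile interpolation at the boundary

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mat.blood_hu_max([])


class TestIodineMassFraction:
    @pytest.mark.parametrize("kv,mixture", [
        (kv, i) for kv in (80, 100) for i in range(1, 13)
        if (kv, i) not in ANOMALIES
    ])
    def test_reproduces_printed_percentages(self, kv, mixture):
        # agreement to the printed precision (one unit in the last printed digit)
        lo, hi = BIN_EDGES[mixture - 1]
        blood_pct, iodine_pct = mat.iodine_mass_fraction(lo, hi, kv)
        printed = PRINTED_IODINE[kv][mixture - 1]
        assert abs(iodine_pct - printed) < 1e-3
        assert abs(blood_pct - (100 - printed)) < 1e-3

    @pytest.mark.parametrize("kv,mixture,formula_value", [
        (80, 1, 0.449), (100, 10, 1.999), (100, 12, 2.270)])
    def test_documented_anomalies_follow_the_formula(self, kv, mixture, formula_value):
        lo, hi = BIN_EDGES[mixture - 1]
        _, iodine_pct = mat.iodine_mass_fraction(lo, hi, kv)
        assert round(iodine_pct, 3) == pytest.approx(formula_value, abs=5e-4)
        assert round(iodine_pct, 3) != PRINTED_IODINE[kv][mixture - 1]

    def test_zero_enhancement_midpoint(self):
        _, iodine = mat.iodine_mass_fraction(40, 40, 80)
        assert iodine == 0.0

    def test_invalid_kv_errors(self):
        with pytest.raises(ValueError, match="kv"):
            mat.iodine_mass_fraction(200, 249, 120)

    def test_monotone_in_midpoint_and_kv(self):
        pct80 = [mat.iodine_mass_fraction(lo, hi, 80)[1] for lo, hi in BIN_EDGES]
        pct100 = [mat.iodine_mass_fraction(lo, hi, 100)[1] for lo, hi in BIN_EDGES]
        assert np.all(np.diff(pct80) > 0)
        assert np.all(np.diff(pct100) > 0)
        assert np.all(np.array(pct100) > np.array(pct80))


class TestMixtureComposition:
    def test_zero_iodine_is_blood(self):
        blood = mat.load_compositions()["blood"]
        out = mat.mixture_composition(blood, 0.0)
        assert out.fractions == pytest.approx(blood.fractions)

    def test_full_iodine(self):
        blood = mat.load_compositions()["blood"]
        out = mat.mixture_composition(blood, 100.0)
        assert out.fractions["I"] == pytest.approx(1.0)

    def test_mixture_six_fractions(self):
        blood = mat.load_compositions()["blood"]
        out = mat.mixture_composition(blood, 1.057)
        assert out.fractions["I"] == pytest.approx(0.01057)
        for el, v in blood.fractions.items():
            assert out.fractions[el] == pytest.approx(0.98943 * v)
        assert sum(out.fractions.values()) == pytest.approx(1.0)


class TestMaterialTable:
    def test_blood_max_499_layout(self):
        table = mat.build_material_table(499, 80)
        names = [b.composition.name for b in table.bins]
        assert names.count("whole_bone") == 1
        blood_bins = [b for b in table.bins if b.composition.name.startswith("blood_iodine")]
        assert len(blood_bins) == 6
        bone = next(b for b in table.bins if b.composition.name == "whole_bone")
        assert (bone.lo, bone.hi) == (500, 1999)

    def test_blood_max_771_has_twelve_bins(self):
        table = mat.build_material_table(771, 80)
        blood_bins = [b for b in table.bins if b.composition.name.startswith("blood_iodine")]
        assert len(blood_bins) == 12
        assert (blood_bins[-1].lo, blood_bins[-1].hi) == (750, 771)
        bone = next(b for b in table.bins if b.composition.name == "whole_bone")
        assert bone.lo == 772

    def test_blood_max_510_extends_last_bin(self):
        table = mat.build_material_table(510, 80)
        blood_bins = [b for b in table.bins if b.composition.name.startswith("blood_iodine")]
        assert (blood_bins[-1].lo, blood_bins[-1].hi) == (450, 510)
        bone = next(b for b in table.bins if b.composition.name == "whole_bone")
        assert bone.lo == 511

    def test_bins_partition_full_hu_range(self):
        for blood_max in (499, 510, 755, 771):
            table = mat.build_material_table(blood_max, 100)
            assert table.bins[0].lo == -1024
            assert table.bins[-1].hi == 64535
            for a, b in zip(table.bins, table.bins[1:]):
                assert b.lo == a.hi + 1

    def test_blood_max_2000_errors(self):
        with pytest.raises(ValueError, match="2000"):
            mat.build_material_table(2000, 80)

    def test_hu_lookup_roundtrip(self):
        table = mat.build_material_table(499, 80)
        hus = np.array([-1024, -1000, -899, -300, -100, 30, 200, 499, 500, 1999,
                        2000, 64535])
        idx = table.index_of_hu(hus)
        for h, i in zip(hus, idx):
            assert table.bins[i].lo <= h <= table.bins[i].hi

    def test_out_of_range_hu_errors(self):
        table = mat.build_material_table(499, 80)
        with pytest.raises(ValueError, match="outside"):
            table.index_of_hu(np.array([-2000]))


class TestAttenuation:
    def test_single_element_at_tabulated_energy_exact(self):
        tab = mat.load_meac_tables()
        comp = mat.MaterialComposition("oxygen", {"O": 1.0}, 1.0)
        i = np.searchsorted(tab.energies["O"], 60.0)
        mu, mu_en = mat.attenuation(comp, 60.0, tab)
        assert mu == pytest.approx(tab.mu["O"][i])
        assert mu_en == pytest.approx(tab.mu_en["O"][i])

    def test_fifty_fifty_mix_is_mean(self):
        tab = mat.load_meac_tables()
        comp = mat.MaterialComposition("mix", {"C": 0.5, "O": 0.5}, 1.0)
        mu, _ = mat.attenuation(comp, 50.0, tab)
        mu_c, _ = mat.attenuation(mat.MaterialComposition("c", {"C": 1.0}, 1.0), 50.0, tab)
        mu_o, _ = mat.attenuation(mat.MaterialComposition("o", {"O": 1.0}, 1.0), 50.0, tab)
        assert mu == pytest.approx(0.5 * (mu_c + mu_o))

    def test_water_against_independent_interpolation(self):
        tab = mat.load_meac_tables()
        water = mat.load_compositions()["water"]
        # independent oracle: plain log-log interpolation per element
        expected = 0.0
        for el, w in water.fractions.items():
            lg = np.interp(np.log(60.0), np.log(tab.energies[el]), np.log(tab.mu[el]))
            expected += w * np.exp(lg)
        mu, _ = mat.attenuation(water, 60.0, tab)
        assert mu == pytest.approx(expected, rel=0.005)

    def test_energy_outside_range_errors(self):
        water = mat.load_compositions()["water"]
        with pytest.raises(ValueError, match="energy"):
            mat.attenuation(water, 500.0)


class TestMeanMeacRatio:
    def test_monoenergetic_equals_pointwise_ratio(self):
        comps = mat.load_compositions()
        tab = mat.load_meac_tables()
        f = np.zeros(100)
        f[59] = 1.0  # 60 keV line
        spec = Spectrum(np.arange(1.0, 101.0), f, 100)
        got = mat.mean_meac_ratio(spec, comps["red_marrow"], comps["whole_bone"], tab)
        a = mat._spline_mu_en(comps["red_marrow"], np.array([60.0]), tab)[0]
        b = mat._spline_mu_en(comps["whole_bone"], np.array([60.0]), tab)[0]
        assert got == pytest.approx(a / b)

    def test_two_line_spectrum_hand_computed(self):
        comps = mat.load_compositions()
        tab = mat.load_meac_tables()
        f = np.zeros(100)
        f[39] = 0.5
        f[59] = 0.5
        spec = Spectrum(np.arange(1.0, 101.0), f, 100)
        a40 = mat._spline_mu_en(comps["water"], np.array([40.0]), tab)[0]
        a60 = mat._spline_mu_en(comps["water"], np.array([60.0]), tab)[0]
        b40 = mat._spline_mu_en(comps["cortical_bone"], np.array([40.0]), tab)[0]
        b60 = mat._spline_mu_en(comps["cortical_bone"], np.array([60.0]), tab)[0]
        expected = (0.5 * a40 + 0.5 * a60) / (0.5 * b40 + 0.5 * b60)
        got = mat.mean_meac_ratio(spec, comps["water"], comps["cortical_bone"], tab)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_spectrum_rescaling(self):
        comps = mat.load_compositions()
        e = np.arange(1.0, 81.0)
        f = np.clip(80.0 - e, 0, None) / e
        f[:14] = 0.0
        a = mat.mean_meac_ratio(Spectrum(e, f, 80), comps["red_marrow"], comps["whole_bone"])
        b = mat.mean_meac_ratio(Spectrum(e, 10 * f, 80), comps["red_marrow"], comps["whole_bone"])
        assert a == pytest.approx(b, rel=1e-12)

    def test_spectrum_outside_tables_errors(self):
        comps = mat.load_compositions()
        f = np.zeros(300)
        f[250] = 1.0
        spec = Spectrum(np.arange(1.0, 301.0), f, 300)
        with pytest.raises(ValueError, match="outside"):
            mat.mean_meac_ratio(spec, comps["water"], comps["whole_bone"])


class TestVendoredTables:
    def test_water_mu_en_close_to_reference_values(self):
        """Composite water mu_en/rho agrees with standard reference data."""
        water = mat.load_compositions()["water"]
        for e, ref in [(30, 0.1557), (50, 0.04223), (60, 0.0319), (100, 0.02546)]:
            _, mu_en = mat.attenuation(water, float(e))
            assert mu_en == pytest.approx(ref, rel=0.04)

    def test_iodine_k_edge_jump(self):
        tab = mat.load_meac_tables()
        comp = mat.MaterialComposition("iodine", {"I": 1.0}, 4.93)
        below, _ = mat.attenuation(comp, 33.0, tab)
        above, _ = mat.attenuation(comp, 34.0, tab)
        assert above / below > 4.0

    def test_coefficients_positive_and_cover_range(self):
        tab = mat.load_meac_tables()
        assert tab.emin() <= 1.0
        assert tab.emax() >= 150.0
        for el in tab.mu:
            assert np.all(tab.mu[el] > 0)
            assert np.all(tab.mu_en[el] > 0)
            assert np.all(tab.mu[el] >= tab.mu_en[el])
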