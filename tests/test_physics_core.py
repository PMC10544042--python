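"""Elemental data, mixture rule, Jackson-Hawkes basis and ground truths."""

import json
from importlib import resources

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dectspr import physics_core as pc


def _raw_elements():
    with resources.files("dectspr.data").joinpath("elements_synthetic.json").open() as fh:
        return json.load(fh)


class TestMassAttenuation:
    def test_single_element_at_grid_point_is_tabulated_value(self):
        raw = _raw_elements()
        grid = raw["energy_grid_keV"]
        rec = raw["elements"]["O"]
        expected = rec["photoelectric"][2] + rec["coherent"][2] + rec["incoherent"][2]
        mat = pc.Material("oxygen", 1.0, {"O": 1.0})
        assert pc.mass_attenuation(mat, grid[2]) == pytest.approx(expected, rel=1e-9)

    def test_fifty_fifty_mixture_is_arithmetic_mean(self):
        mat = pc.Material("CO", 1.0, {"C": 0.5, "O": 0.5})
        mu_c = pc.mass_attenuation(pc.Material("c", 1.0, {"C": 1.0}), 80.0)
        mu_o = pc.mass_attenuation(pc.Material("o", 1.0, {"O": 1.0}), 80.0)
        assert pc.mass_attenuation(mat, 80.0) == pytest.approx(0.5 * (mu_c + mu_o))

    def test_water_matches_hand_summed_elemental_values(self):
        # independent oracle: sum the packaged JSON directly at a grid energy
        raw = _raw_elements()
        i60 = raw["energy_grid_keV"].index(60.0)
        total = 0.0
        for sym, w in (("H", 0.111894), ("O", 0.888106)):
            rec = raw["elements"][sym]
            total += w * (
                rec["photoelectric"][i60] + rec["coherent"][i60] + rec["incoherent"][i60]
            )
        assert pc.mass_attenuation(pc.water(), 60.0) == pytest.approx(total, rel=1e-9)

    def test_energy_outside_grid_raises(self):
        with pytest.raises(pc.OutOfDomainError):
            pc.mass_attenuation(pc.water(), 200.0)

    def test_unknown_element_raises_composition_error(self):
        with pytest.raises(pc.CompositionError):
            pc.Material("bad", 1.0, {"Xx": 1.0})

    @given(w=st.floats(0.05, 0.95))
    @settings(max_examples=20, deadline=None)
    def test_mixture_rule_linear_in_mass_fractions(self, w):
        mat = pc.Material("mix", 1.0, {"C": w, "Ca": 1.0 - w})
        mu_c = pc.mass_attenuation(pc.Material("c", 1.0, {"C": 1.0}), 70.0)
        mu_ca = pc.mass_attenuation(pc.Material("ca", 1.0, {"Ca": 1.0}), 70.0)
        assert pc.mass_attenuation(mat, 70.0) == pytest.approx(
            w * mu_c + (1 - w) * mu_ca, rel=1e-12
        )


class TestRelativeAttenuation:
    def test_water_is_one_at_every_energy(self):
        for e in (40.0, 74.0, 140.0):
            assert pc.linear_attenuation_rel_water(pc.water(), e) == pytest.approx(1.0)

    def test_near_vacuum_density_goes_to_zero(self):
        thin = pc.Material("thin", 1e-9, {"N": 1.0})
        assert pc.linear_attenuation_rel_water(thin, 60.0) == pytest.approx(0.0, abs=1e-8)

    def test_cortical_bone_exceeds_water_and_matches_hand_computation(self, tissues):
        bone = tissues["cortical_bone"]
        val = pc.linear_attenuation_rel_water(bone, 60.0)
        w = pc.water()
        by_hand = (bone.density * pc.mass_attenuation(bone, 60.0)) / (
            w.density * pc.mass_attenuation(w, 60.0)
        )
        assert val > 1.5
        assert val == pytest.approx(by_hand, rel=1e-12)


class TestJHBasis:
    def test_exact_decomposition_at_all_table_nodes(self, basis):
        for sym in ("C", "O", "P", "Ca", "Fe", "I"):
            el = pc.element(sym)
            conv = el.A / (el.Z * pc.N_AVOGADRO)
            for e in el.energy_grid:
                expected = el.mass_attenuation(float(e)) * conv
                got = basis.per_electron(float(el.Z), float(e))
                assert got == pytest.approx(expected, rel=1e-10)

    def test_F_decreases_with_energy_at_fixed_z(self, basis):
        energies = np.arange(40.0, 141.0, 10.0)
        for z in (6.0, 7.4, 13.0, 20.0):
            f = np.array([basis.F(z, e) for e in energies])
            assert np.all(np.diff(f) < 0)

    def test_G_varies_weakly_across_soft_tissue_z_at_100keV(self, basis):
        g = np.array([basis.G(float(z), 100.0) for z in range(6, 21)])
        assert (g.max() - g.min()) / g.min() < 0.20

    def test_out_of_domain_z_raises(self, basis):
        with pytest.raises(pc.OutOfDomainError):
            basis.F(60.0, 70.0)


class TestGroundTruths:
    def test_true_red_water_and_doubled_density(self):
        assert pc.true_red(pc.water()) == pytest.approx(1.0)
        heavy = pc.Material("heavy_water", 2.0, dict(pc.water().mass_fractions))
        assert pc.true_red(heavy) == pytest.approx(2.0)

    def test_true_red_muscle_matches_hand_computation(self, tissues):
        m = tissues["skeletal_muscle_2"]
        z_over_a = sum(
            w * pc.element(s).Z / pc.element(s).A for s, w in m.mass_fractions.items()
        )
        water_z_over_a = 0.111894 * 1 / 1.008 + 0.888106 * 8 / 15.999
        assert pc.true_red(m) == pytest.approx(
            m.density * z_over_a / water_z_over_a, rel=1e-9
        )

    def test_true_lnI_single_element_and_equal_fraction_mean(self):
        carbon = pc.Material("c", 2.0, {"C": 1.0})
        assert pc.true_lnI(carbon) == pytest.approx(np.log(pc.element("C").I_eV))
        # equal electron fractions: solve mass fractions for lambda = 0.5 each
        zc = pc.element("C").Z / pc.element("C").A
        zo = pc.element("O").Z / pc.element("O").A
        wc = (1 / zc) / (1 / zc + 1 / zo)
        mat = pc.Material("co", 1.0, {"C": wc, "O": 1 - wc})
        expect = 0.5 * (np.log(pc.element("C").I_eV) + np.log(pc.element("O").I_eV))
        assert pc.true_lnI(mat) == pytest.approx(expect, rel=1e-6)

    def test_water_I_value_is_the_reference_78_73_eV(self):
        ln_i = pc.true_lnI(pc.water())
        assert np.log(70) < ln_i < np.log(80)
        assert np.exp(ln_i) == pytest.approx(78.73, abs=0.01)


class TestBethe:
    def test_water_I_gives_identity(self):
        assert pc.spr_bethe(1.0, 78.73) == pytest.approx(1.0, abs=1e-12)
        assert pc.spr_bethe(1.05, 78.73) == pytest.approx(1.05, abs=1e-12)

    def test_known_value_for_75_eV_at_100MeV(self):
        # independent evaluation of the ratio with beta^2 from 100 MeV protons
        assert pc.spr_bethe(1.0, 75.0) == pytest.approx(1.00623, abs=1e-4)

    def test_strictly_decreasing_in_I(self):
        i_values = np.linspace(60.0, 120.0, 13)
        spr = np.array([pc.spr_bethe(1.0, i) for i in i_values])
        assert np.all(np.diff(spr) < 0)

    def test_huge_I_value_raises_domain_error(self):
        with pytest.raises(ValueError):
            pc.spr_bethe(1.0, 1e9)

    @given(red=st.floats(0.01, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_bracket_cancellation_for_any_red(self, red):
        assert pc.spr_bethe(red, 78.73) == pytest.approx(red, rel=1e-12)

    def test_beta_squared_from_relativistic_kinematics(self):
        b2 = pc.BETHE_DEFAULT.beta_sq
        gamma = 1.0 + 100.0 / 938.272
        assert b2 == pytest.approx(1.0 - 1.0 / gamma**2)


class TestYang:
    @pytest.mark.parametrize(
        "zeff, expected",
        [(7.0, 4.247), (13.0, 4.567), (8.5, 4.2025)],  # boundary on upper branch
    )
    def test_piecewise_values(self, zeff, expected):
        assert pc.yang_lnI(zeff) == pytest.approx(expected, abs=1e-12)

    def test_branch_discontinuity_is_preserved(self):
        below = pc.yang_lnI(8.5 - 1e-9)
        at = pc.yang_lnI(8.5)
        assert abs(below - at) > 0.2


class TestHUConversion:
    @pytest.mark.parametrize("hu, expected", [(0.0, 1.0), (-1000.0, 0.0), (800.0, 1.8)])
    def test_linear_map(self, hu, expected):
        assert pc.hu_to_rel_atten(hu) == pytest.approx(expected)

    def test_below_air_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert pc.hu_to_rel_atten(-1500.0) == 0.0

    def test_round_trip(self):
        assert pc.rel_atten_to_hu(pc.hu_to_rel_atten(123.4)) == pytest.approx(123.4)


class TestPackagedLibraries:
    def test_73_reference_tissues(self, tissues):
        assert len(tissues) == 73

    def test_nine_inserts_with_valid_compositions(self, inserts):
        assert len(inserts) == 9
        for mat in inserts.values():
            assert abs(sum(mat.mass_fractions.values()) - 1.0) < 1e-6

    def test_composition_sum_enforced(self):
        with pytest.raises(pc.CompositionError):
            pc.Material("bad", 1.0, {"H": 0.5, "O": 0.4})
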