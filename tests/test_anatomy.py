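"""Derived-trait computations: hydraulic diameter, radii, areas, g_max."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heartwoodkit import anatomy
from heartwoodkit.anatomy import (
    GmaxConstants,
    disc_traits,
    gmax,
    hw_proportion_profile,
    hydraulic_diameter,
    quadratic_mean_radius,
)


class TestHydraulicDiameter:
    @pytest.mark.parametrize(
        "vessels, expected",
        [
            # single circular vessel: D_H equals its diameter exactly
            ([(100.0, 100.0)], 100.0),
            # two circles d=50,100: ((50^4 + 100^4)/2)^(1/4)
            ([(50.0, 50.0), (100.0, 100.0)], ((50**4 + 100**4) / 2) ** 0.25),
            # single ellipse 120x80: (2*120^3*80^3/(120^2+80^2))^(1/4)
            ([(120.0, 80.0)], (2 * 120**3 * 80**3 / (120**2 + 80**2)) ** 0.25),
        ],
    )
    def test_reference_values(self, vessels, expected):
        assert hydraulic_diameter(vessels) == pytest.approx(expected, rel=1e-12)

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            hydraulic_diameter([])
        with pytest.raises(ValueError):
            hydraulic_diameter([(50.0, -1.0)])

    @given(
        d=st.lists(st.floats(1.0, 500.0), min_size=1, max_size=40),
    )
    @settings(deadline=None, derandomize=True)
    def test_circular_limit_is_fourth_power_mean(self, d):
        """For circular lumina D_H reduces to (mean d^4)^(1/4)."""
        d = np.asarray(d)
        got = hydraulic_diameter(np.column_stack([d, d]))
        assert got == pytest.approx(float(np.mean(d**4) ** 0.25), rel=1e-12)

    @given(
        pairs=st.lists(
            st.tuples(st.floats(1.0, 300.0), st.floats(0.1, 1.0)),
            min_size=2,
            max_size=30,
        ),
        seed=st.integers(0, 10_000),
    )
    @settings(deadline=None, derandomize=True)
    def test_bounds_and_permutation_invariance(self, pairs, seed):
        """D_H^4 lies between the extreme per-vessel elliptical terms and
        does not depend on vessel order."""
        vessels = np.array([(a, a * frac) for a, frac in pairs])
        a, b = vessels[:, 0], vessels[:, 1]
        term = 2 * a**3 * b**3 / (a**2 + b**2)
        dh = hydraulic_diameter(vessels)
        assert term.min() * (1 - 1e-9) <= dh**4 <= term.max() * (1 + 1e-9)
        perm = np.random.default_rng(seed).permutation(len(vessels))
        assert hydraulic_diameter(vessels[perm]) == pytest.approx(dh, rel=1e-12)


class TestQuadraticMeanRadius:
    def test_constant_and_mixed_radii(self):
        assert quadratic_mean_radius([10.0] * 8) == pytest.approx(10.0)
        assert quadratic_mean_radius([6.0] * 4 + [8.0] * 4) == pytest.approx(
            np.sqrt(50.0), rel=1e-12
        )
        assert quadratic_mean_radius([0.0] * 8) == 0.0

    def test_wrong_count_or_negative_rejected(self):
        with pytest.raises(ValueError):
            quadratic_mean_radius([1.0] * 7)
        with pytest.raises(ValueError):
            quadratic_mean_radius([1.0] * 7 + [-1.0])

    @given(
        radii=st.lists(st.floats(0.0, 100.0), min_size=8, max_size=8),
    )
    @settings(deadline=None, derandomize=True)
    def test_dominates_arithmetic_mean(self, radii):
        assert quadratic_mean_radius(radii) >= np.mean(radii) - 1e-12


class TestDiscTraits:
    def test_area_partition_from_radii(self):
        t = disc_traits([20.0] * 8, [10.0] * 8, cambial_age=40)
        assert t.SW_R == pytest.approx(10.0)
        assert t.CSa == pytest.approx(400 * np.pi)
        assert t.HWa == pytest.approx(100 * np.pi)
        assert t.SWa == pytest.approx(300 * np.pi)
        assert t.hw_proportion == pytest.approx(0.25)
        assert t.GR == pytest.approx(1.0)  # diameter 40 cm at 40 years

    def test_vessel_fraction_and_tcva(self):
        # a single circular vessel with area 0.01 mm^2 (d ~ 112.838 um)
        d = 2 * np.sqrt(0.01 / np.pi) * 1000
        t = disc_traits(
            [np.sqrt(200 / np.pi)] * 8,
            [0.0] * 8,
            cambial_age=20,
            vessels=[(d, d)],
            vessel_density=15.0,
        )
        assert t.A_V == pytest.approx(0.01, rel=1e-9)
        assert t.F_V == pytest.approx(15.0, rel=1e-9)
        assert t.TCVA == pytest.approx(0.01 * 15.0 * t.SWa, rel=1e-9)
        assert t.TCVA <= t.SWa

    def test_inconsistent_units_rejected(self):
        # vessel lumina of 0.115 mm^2 at 17 mm^-2 would fill >100% of
        # the sapwood: flagged, not silently reported
        d = 2 * np.sqrt(0.115 / np.pi) * 1000
        with pytest.raises(ValueError, match="lumen fraction"):
            disc_traits(
                [10.0] * 8, [0.0] * 8, 20, vessels=[(d, d)], vessel_density=17.3
            )

    def test_heartwood_exceeding_stem_rejected(self):
        with pytest.raises(ValueError):
            disc_traits([5.0] * 8, [6.0] * 8, 10)

    def test_measured_area_passthrough_checks_closure(self):
        t = disc_traits([10.0] * 8, [5.0] * 8, 20, measured_csa=315.0)
        assert t.SWa + t.HWa == pytest.approx(t.CSa)
        with pytest.raises(ValueError, match="inconsistent"):
            disc_traits([10.0] * 8, [5.0] * 8, 20, measured_csa=150.0)

    @given(
        s=st.floats(1.0, 50.0),
        frac=st.floats(0.0, 0.99),
        age=st.integers(2, 200),
    )
    @settings(deadline=None, derandomize=True)
    def test_area_closure_property(self, s, frac, age):
        t = disc_traits([s] * 8, [s * frac] * 8, age)
        assert t.SWa + t.HWa == pytest.approx(t.CSa, rel=1e-9)
        assert 0 <= t.hw_proportion < 1


class TestGmax:
    def test_linear_in_density(self):
        g1 = gmax(300.0, 100.0)
        g2 = gmax(600.0, 100.0)
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_hand_computed_value(self):
        """Independent arithmetic in SI units for the default constants."""
        ds = 300.0 * 1e6  # m^-2
        a_max = 0.12 * 100.0 * 1e-12  # m^2
        pd_m = np.sqrt(a_max / np.pi)
        expected = (
            (2.49e-5 / 0.0245)
            * ds
            * a_max
            / (pd_m + (np.pi / 2) * np.sqrt(a_max / np.pi))
        )
        assert gmax(300.0, 100.0) == pytest.approx(expected, rel=1e-12)

    def test_fixed_pore_depth_rule(self):
        c = GmaxConstants(pore_depth_rule="fixed", pore_depth_um=2.0)
        assert gmax(300.0, 100.0, c) > 0

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            GmaxConstants(pore_area_fraction=0.0)
        with pytest.raises(ValueError):
            GmaxConstants(water_vapour_diffusivity=-1.0)
        with pytest.raises(ValueError):
            gmax(-5.0, 100.0)


class TestHwProportionProfile:
    def test_monotone_and_flat_profiles(self):
        L = np.array([10.0, 8.0, 6.0, 4.0, 2.0])
        prof, sign = hw_proportion_profile(L, 0.05 * L)
        assert sign == 1
        assert list(prof["distance_from_top"]) == sorted(L, reverse=True)
        _, sign0 = hw_proportion_profile(L, np.full(5, 0.3))
        assert sign0 == 0

    def test_too_few_discs_rejected(self):
        with pytest.raises(ValueError):
            hw_proportion_profile([5.0], [0.2])

    def test_generated_sun_tree_decreases_toward_top(self, derived):
        trunk = derived[derived["disc_type"] == "trunk"]
        tree = trunk[trunk["cohort"] == "sun_exposed"]
        tid = tree.groupby("tree_id").size().idxmax()
        one = tree[tree["tree_id"] == tid]
        prof, sign = hw_proportion_profile(
            one["distance_from_top"], one["hw_proportion"]
        )
        assert sign == 1
        assert prof["hw_proportion"].iloc[0] > prof["hw_proportion"].iloc[-1]


def test_derive_discs_schema_and_missing_vessels(study, derived):
    dataset, _ = study
    assert len(derived) == len(dataset["discs"])
    branches = derived[derived["disc_type"] == "branch"]
    # branches carry no vessel sample: TCVA missing, not zero
    assert branches["TCVA"].isna().all()
    assert branches["total_leaf_area_m2"].notna().all()
    trunk = derived[derived["disc_type"] == "trunk"]
    assert trunk["TCVA"].notna().all()
    np.testing.assert_allclose(
        derived["SWa"] + derived["HWa"], derived["CSa"], rtol=1e-9
    )
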