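"""Vessel anatomy: diameters, classes, Hagen-Poiseuille shares, KS, wood."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lianahydro import anatomy


def brute_force_hp(diameters, edges):
    """Independent fourth-power class shares by explicit double loop."""
    r4 = [(d / 2.0) ** 4 for d in diameters]
    total = sum(r4)
    shares = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        s = sum(
            w for d, w in zip(diameters, r4)
            if lo <= d < hi or (last and d == hi)
        )
        shares.append(s / total)
    return np.array(shares)


def brute_force_ks_d(freq, cond):
    """Max CDF gap over all class boundaries, by explicit loop."""
    best = 0.0
    cf = cc = 0.0
    for f, c in zip(freq, cond):
        cf += f
        cc += c
        best = max(best, abs(cf - cc))
    return best


class TestVesselDiameter:
    @pytest.mark.parametrize(
        "la,sa,expected", [(20, 20, 20), (30, 20, 25), (30.5, 20.5, 25.5)]
    )
    def test_axis_average(self, la, sa, expected):
        assert anatomy.vessel_diameter(la, sa) == pytest.approx(expected)

    def test_swapped_axes_rejected(self):
        with pytest.raises(anatomy.AnatomyDomainError, match="index 1"):
            anatomy.vessel_diameter([30.0, 20.0], [20.0, 30.0])


class TestSummaries:
    @staticmethod
    def _vessels(branch_specs):
        rows, areas = [], []
        for bid, (diams, area) in branch_specs.items():
            areas.append(dict(branch_id=bid, counted_area_mm2=area))
            for k, d in enumerate(diams):
                rows.append(dict(vessel_id=f"{bid}-{k}", branch_id=bid, site="A",
                                 species="x", long_axis_um=d, short_axis_um=d))
        return pd.DataFrame(rows), pd.DataFrame(areas)

    def test_branch_mean_and_density(self):
        vessels, areas = self._vessels({"b1": ([20.0, 30.0], 0.5)})
        with pytest.warns(UserWarning, match="vessels"):
            branch, species = anatomy.summarize_vessels(vessels, areas)
        assert branch.loc[0, "mean_diameter_um"] == pytest.approx(25.0)
        assert branch.loc[0, "vessel_density_per_mm2"] == pytest.approx(4.0)

    def test_species_mean_is_unweighted_over_branches(self):
        vessels, areas = self._vessels(
            {"b1": ([20.0] * 3, 1.0), "b2": ([40.0] * 9, 1.0)}
        )
        with pytest.warns(UserWarning):
            _, species = anatomy.summarize_vessels(vessels, areas)
        assert species.loc[0, "mean_diameter_um"] == pytest.approx(30.0)

    def test_missing_area_rejected(self):
        vessels, areas = self._vessels({"b1": ([20.0], 1.0)})
        with pytest.raises(anatomy.AnatomyDomainError, match="b1"):
            anatomy.summarize_vessels(vessels, areas.iloc[:0])


class TestBinning:
    def test_hand_counts(self):
        t = anatomy.bin_vessels([5, 15, 15, 25])
        assert t.counts.tolist() == [1, 2, 1]
        assert t.relative_frequency.sum() == pytest.approx(1.0)

    def test_left_closed_boundary(self):
        t = anatomy.bin_vessels([10.0])
        assert t.counts.tolist() == [0, 1]

    def test_empty_rejected(self):
        with pytest.raises(anatomy.AnatomyDomainError):
            anatomy.bin_vessels([])


class TestHpContribution:
    def test_two_vessel_fourth_powers(self):
        t = anatomy.bin_vessels([20.0, 40.0])
        assert t.relative_conductivity[np.nonzero(t.counts)[0]].tolist() == pytest.approx(
            [1 / 17, 16 / 17]
        )

    def test_identical_vessels_proportional_to_counts(self):
        t = anatomy.bin_vessels([25.0] * 7)
        assert t.relative_conductivity.tolist() == pytest.approx(
            t.relative_frequency.tolist()
        )

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.lognormal(np.log(40), 0.5, size=rng.integers(1, 200))
        t = anatomy.bin_vessels(d)
        expected = brute_force_hp(d.tolist(), t.bin_edges.tolist())
        np.testing.assert_allclose(t.relative_conductivity, expected, rtol=1e-12)
        assert t.relative_conductivity.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unit_invariance(self):
        d = np.array([12.0, 47.0, 83.0, 112.0])
        um = anatomy.bin_vessels(d, width=10.0)
        mm = anatomy.bin_vessels(d / 1000.0, width=10.0 / 1000.0)
        np.testing.assert_allclose(
            um.relative_conductivity, mm.relative_conductivity, rtol=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    def test_conductivity_cdf_dominated_by_frequency_cdf(self, seed):
        # r^4 weights are increasing in diameter, so conductivity mass sits
        # in the larger classes: its CDF never exceeds the frequency CDF
        rng = np.random.default_rng(seed)
        d = rng.lognormal(np.log(50), 0.4, size=100)
        t = anatomy.bin_vessels(d)
        assert np.all(
            np.cumsum(t.relative_conductivity) <= np.cumsum(t.relative_frequency) + 1e-12
        )


class TestWideVesselShare:
    def test_no_wide_vessels(self):
        assert anatomy.wide_vessel_share([50.0] * 5) == (0.0, 0.0)

    def test_count_and_conductivity_shares(self):
        count, cond = anatomy.wide_vessel_share([20.0, 120.0])
        assert count == pytest.approx(0.5)
        assert cond == pytest.approx(1296 / 1297)

    def test_threshold_below_minimum(self):
        assert anatomy.wide_vessel_share([50.0, 60.0], threshold_um=10) == (1.0, 1.0)

    def test_threshold_is_strict(self):
        count, _ = anatomy.wide_vessel_share([100.0, 120.0])
        assert count == pytest.approx(0.5)


class TestKsCompare:
    def test_single_class_degenerate(self):
        t = anatomy.bin_vessels([5.0, 6.0, 7.0])
        assert anatomy.ks_compare(t) == (0.0, 1.0)

    def test_disjoint_mass_gives_unit_statistic(self):
        t = anatomy.DiameterClassTable(
            bin_edges=np.array([0.0, 10.0, 20.0]),
            counts=np.array([5, 0]),
            relative_frequency=np.array([1.0, 0.0]),
            relative_conductivity=np.array([0.0, 1.0]),
            diameters=np.full(5, 5.0),
        )
        d, p = anatomy.ks_compare(t, n_vessels=5)
        assert d == 1.0
        assert p < 0.05

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_gap(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.lognormal(np.log(45), 0.5, size=200)
        t = anatomy.bin_vessels(d)
        stat, _ = anatomy.ks_compare(t)
        assert stat == pytest.approx(
            brute_force_ks_d(t.relative_frequency, t.relative_conductivity), abs=1e-12
        )

    def test_permutation_p_detects_size_weight_association(self):
        rng = np.random.default_rng(5)
        d = rng.lognormal(np.log(60), 0.6, size=300)
        t = anatomy.bin_vessels(d)
        stat, p = anatomy.ks_compare(t, method="permutation", n_permutations=199, seed=1)
        assert stat > 0.2
        assert p <= 0.01


class TestWoodDensity:
    @pytest.mark.parametrize(
        "mass,vol,expected", [(0.5, 1.25, 0.4), (2.0, 2.0, 1.0), (0.94, 2.0, 0.47)]
    )
    def test_mass_over_volume(self, mass, vol, expected):
        assert anatomy.wood_density(mass, vol) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(anatomy.AnatomyDomainError):
            anatomy.wood_density(0.5, 0.0)
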