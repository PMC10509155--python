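"""ANCOVA, Tukey, PCA and correlation behaviour on trait tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lianahydro import reference, trait_stats


@pytest.fixture(scope="module")
def design_units():
    units = [(s, sp) for s in reference.SITES for sp in reference.SPECIES_BY_SITE[s]]
    table = pd.DataFrame(units, columns=["site", "species"])
    table["tmin_mean_C"] = table["site"].map(
        reference.CLIMATE.set_index("site")["tmin_mean_C"]
    )
    return table


class TestBuildTraitTable:
    def test_reference_design_has_16_units(self, ref_traits):
        assert len(ref_traits.trait_table) == 16
        assert not ref_traits.trait_table.duplicated(["site", "species"]).any()
        assert set(ref_traits.trait_table["tmin_mean_C"]) == {4.8, 3.3, 2.7}

    def test_zero_noise_recovers_generator_targets(self, noiseless_bundle):
        import lianahydro as lh

        tr = lh.report.run_traits(noiseless_bundle)
        merged = tr.trait_table.merge(
            noiseless_bundle.targets, on=["site", "species"], suffixes=("", "_target")
        )
        for trait in ("Ks_max", "PLC", "root_pressure", "AGR", "wood_density",
                      "vessel_density"):
            np.testing.assert_allclose(
                merged[trait], merged[f"{trait}_target"], rtol=1e-9,
                err_msg=trait,
            )


class TestAncova:
    def test_constant_trait_yields_null_result(self, design_units):
        table = design_units.assign(y=1.0)
        res = trait_stats.ancova(table, "y")
        assert res.terms.loc["site", "F"] == 0.0
        assert res.terms.loc["site", "p"] == 1.0

    def test_aliased_covariate_dropped_with_reference_df(self, design_units):
        rng = np.random.default_rng(1)
        table = design_units.assign(y=rng.standard_normal(16))
        res = trait_stats.ancova(table, "y")
        assert res.collinearity_flag
        assert res.terms.loc["site", "df_num"] == 2.0
        assert res.terms.loc["site", "df_den"] == 13.0
        assert "covariate" not in res.terms.index

    def test_non_aliased_covariate_is_tested(self, design_units):
        rng = np.random.default_rng(2)
        table = design_units.assign(
            tmin_mean_C=design_units["tmin_mean_C"] + rng.normal(0, 0.3, 16),
            y=rng.standard_normal(16),
        )
        res = trait_stats.ancova(table, "y")
        assert not res.collinearity_flag
        assert "covariate" in res.terms.index
        assert res.terms.loc["site", "df_den"] == 12.0

    def test_single_site_rejected(self, design_units):
        table = design_units[design_units["site"] == "Aysen"].assign(y=[1, 2, 3, 4.0])
        with pytest.raises(ValueError, match="sites"):
            trait_stats.ancova(table, "y")

    def test_row_order_invariance(self, design_units):
        rng = np.random.default_rng(3)
        table = design_units.assign(y=rng.standard_normal(16))
        shuffled = table.sample(frac=1, random_state=5)
        a = trait_stats.ancova(table, "y").terms.loc["site", "F"]
        b = trait_stats.ancova(shuffled, "y").terms.loc["site", "F"]
        assert a == pytest.approx(b, rel=1e-10)


class TestTukey:
    def test_identical_groups_not_significant(self):
        table = pd.DataFrame(
            dict(site=["A"] * 4 + ["B"] * 4, y=[1.0, 2.0, 3.0, 4.0] * 2)
        )
        res = trait_stats.tukey_hsd(table, "y")
        assert res.contrasts.loc[0, "p_adj"] > 0.9

    def test_separated_group_detected(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            dict(
                site=np.repeat(["A", "B", "C"], 6),
                y=np.concatenate(
                    [rng.normal(0, 1, 6), rng.normal(0, 1, 6), rng.normal(10, 1, 6)]
                ),
            )
        )
        res = trait_stats.tukey_hsd(table, "y").contrasts.set_index(["group1", "group2"])
        assert res.loc[("A", "C"), "p_adj"] < 1e-4
        assert res.loc[("B", "C"), "p_adj"] < 1e-4

    def test_adjusted_p_matches_studentized_range_oracle(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            dict(site=np.repeat(["A", "B", "C"], 5), y=rng.normal(0, 1, 15))
        )
        table.loc[table["site"] == "B", "y"] += 1.5
        res = trait_stats.tukey_hsd(table, "y").contrasts
        g = table.groupby("site")["y"]
        mse = float(
            ((table["y"] - table["site"].map(g.mean())) ** 2).sum() / (15 - 3)
        )
        for _, row in res.iterrows():
            q = abs(row["estimate"]) / np.sqrt(mse / 5)
            expected = sps.studentized_range.sf(q, 3, 12)
            assert row["p_adj"] == pytest.approx(expected, abs=1e-6)

    def test_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            dict(site=np.repeat(["A", "B", "C"], 5), y=rng.normal(0, 1, 15))
        )
        res = trait_stats.tukey_hsd(table, "y").contrasts
        assert (res["p_adj"] >= res["p_unadj"] - 1e-12).all()


class TestPca:
    def test_perfectly_correlated_pair_loads_on_one_axis(self, design_units):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(16)
        table = design_units.assign(t1=x, t2=2 * x + 1)
        res = trait_stats.pca_traits(table, ["t1", "t2"])
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_loadings_match_eigendecomposition_oracle(self, design_units):
        rng = np.random.default_rng(6)
        traits = [f"t{i}" for i in range(8)]
        table = design_units.assign(
            **{t: rng.standard_normal(16) for t in traits}
        )
        res = trait_stats.pca_traits(table, traits)
        corr = np.corrcoef(table[traits].to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(
            np.abs(res.loadings), np.abs(evecs), atol=1e-8
        )
        np.testing.assert_allclose(
            res.percent_variance, 100 * evals / evals.sum(), atol=1e-8
        )

    def test_reconstruction_orthogonality_and_normalisation(self, design_units):
        rng = np.random.default_rng(8)
        traits = [f"t{i}" for i in range(5)]
        table = design_units.assign(**{t: rng.standard_normal(16) for t in traits})
        res = trait_stats.pca_traits(table, traits)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        x = table[traits].to_numpy()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        np.testing.assert_allclose(res.scores @ res.loadings.T, z, atol=1e-8)
        gram = res.scores.T @ res.scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)

    def test_constant_trait_rejected(self, design_units):
        table = design_units.assign(t1=np.arange(16.0), t2=1.0)
        with pytest.raises(ValueError, match="t2"):
            trait_stats.pca_traits(table, ["t1", "t2"])

    def test_deterministic_sign_convention(self, design_units):
        rng = np.random.default_rng(10)
        traits = [f"t{i}" for i in range(4)]
        table = design_units.assign(**{t: rng.standard_normal(16) for t in traits})
        res = trait_stats.pca_traits(table, traits)
        for j in range(res.loadings.shape[1]):
            assert res.loadings[np.argmax(np.abs(res.loadings[:, j])), j] > 0


class TestScoreRegressions:
    def _pca(self, table, traits):
        return trait_stats.pca_traits(table, traits)

    def test_constant_growth_gives_zero_r2(self, design_units):
        rng = np.random.default_rng(11)
        table = design_units.assign(
            AGR=5.0, t1=rng.standard_normal(16), t2=rng.standard_normal(16)
        )
        res = trait_stats.regress_scores_vs_agr(
            self._pca(table, ["t1", "t2"]), table, components=(0,)
        )
        assert all(r.r_squared == 0.0 for r in res)

    def test_growth_equal_to_score_gives_unit_r2(self, design_units):
        rng = np.random.default_rng(12)
        table = design_units.assign(
            t1=rng.standard_normal(16), t2=rng.standard_normal(16)
        )
        pca = self._pca(table, ["t1", "t2"])
        table = table.assign(AGR=pca.scores[:, 0])
        res = trait_stats.regress_scores_vs_agr(pca, table, components=(0,))
        assert all(r.r_squared == pytest.approx(1.0) for r in res)

    def test_small_site_flagged(self):
        table = pd.DataFrame(
            dict(
                site=["A"] * 4 + ["B"] * 2,
                species=list("abcdef"),
                t1=[1.0, 2, 3, 4, 5, 6],
                t2=[2.0, 1, 4, 3, 6, 5],
                AGR=[1.0, 2, 3, 4, 5, 6],
            )
        )
        res = trait_stats.regress_scores_vs_agr(self._pca(table, ["t1", "t2"]), table,
                                                components=(0,))
        flags = {r.site: r.insufficient_n for r in res}
        assert flags == {"A": False, "B": True}


class TestSiteMeanCorrelation:
    def test_perfect_negative_correlation(self, design_units):
        table = design_units.assign(AGR=design_units["tmin_mean_C"],
                                    PLC=-design_units["tmin_mean_C"])
        r, r2, p, n = trait_stats.site_mean_correlation(table, "AGR", "PLC")
        assert r == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)
        assert n == 3

    def test_zero_variance_rejected(self, design_units):
        table = design_units.assign(AGR=1.0, PLC=design_units["tmin_mean_C"])
        with pytest.raises(ValueError, match="variance"):
            trait_stats.site_mean_correlation(table, "AGR", "PLC")
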