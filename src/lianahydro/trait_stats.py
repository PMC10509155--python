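"""Trait-table statistics: ANCOVA, Tukey HSD, PCA trade-off axes, correlations.

The analysis unit is the species-site mean (one row per species per site;
16 rows in the reference design of 7+5+4 species over three sites), with
the site's mean minimum temperature attached as the continuous covariate.
Because the covariate takes a single value per site it is perfectly
collinear (aliased) with the site factor; when that happens the aliased
covariate is dropped, the site test proceeds on the remaining degrees of
freedom, and the result is flagged.

The efficiency-safety trade-off is summarised by a principal component
analysis on the correlation matrix of the (standardised) traits; per-site
ordinary least squares regressions of apical growth rate on the component
scores then ask whether growth tracks the trade-off axes within each site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

TRAIT_COLUMNS = (
    "AGR",
    "PLC",
    "Ks_max",
    "vessel_diameter",
    "vessel_density",
    "wood_density",
    "root_pressure",
    "hc",
)


def build_trait_table(
    stem_summary: pd.DataFrame,
    vessel_summary: pd.DataFrame,
    wood: pd.DataFrame,
    pr_estimates: pd.DataFrame,
    growth: pd.DataFrame,
    climate: pd.DataFrame,
) -> pd.DataFrame:
    """One row per species-site with trait means and the site covariate.

    Inputs are the per-record outputs of the hydraulics and anatomy
    modules plus the raw growth table (``individual_id, site, species,
    growth_cm, months_elapsed``) and the site climate table.  A trait with
    no records for a unit is left as NaN (explicit missing marker).
    """
    key = ["site", "species"]
    parts = []

    agr = growth.assign(AGR=growth["growth_cm"] / growth["months_elapsed"])
    parts.append(agr.groupby(key)["AGR"].mean())

    parts.append(stem_summary.groupby(key)[["Ks_max", "PLC"]].mean())

    vs = vessel_summary.rename(
        columns={
            "mean_diameter_um": "vessel_diameter",
            "vessel_density_per_mm2": "vessel_density",
        }
    )
    parts.append(vs.set_index(key)[["vessel_diameter", "vessel_density"]])

    wd = wood.rename(columns={"wood_density_g_cm3": "wood_density"})
    parts.append(wd.groupby(key)["wood_density"].mean())

    pr = pr_estimates.rename(columns={"PR": "root_pressure"})
    parts.append(pr.groupby(key)[["root_pressure", "hc"]].mean())

    table = pd.concat(parts, axis=1).reset_index()
    if table.duplicated(key).any():
        raise ValueError("duplicated species-site unit in trait table")
    tmin = climate.set_index("site")["tmin_mean_C"]
    table["tmin_mean_C"] = table["site"].map(tmin)
    return table


@dataclass
class AncovaResult:
    trait: str
    terms: pd.DataFrame          # index: term; columns F, df_num, df_den, p
    levene_stat: float
    levene_p: float
    collinearity_flag: bool
    model: object = field(repr=False, default=None)


def _covariate_aliased(table: pd.DataFrame, covariate: str) -> bool:
    # aliased iff the covariate is constant within every site level
    return bool((table.groupby("site")[covariate].nunique() <= 1).all())


def ancova(
    table: pd.DataFrame, trait: str, covariate: str = "tmin_mean_C"
) -> AncovaResult:
    """Type-II ANCOVA of a trait on site with a temperature covariate.

    With one covariate value per site (the reference design) the model is
    rank-deficient; the aliased covariate is dropped, the site F-test runs
    on the remaining degrees of freedom (df 2, 13 in the 16-unit design)
    and ``collinearity_flag`` is set.  Levene's test (median-centred) on
    the trait by site checks variance homogeneity.
    """
    data = table[["site", covariate, trait]].dropna().copy()
    sites = data["site"].unique()
    if len(sites) < 2:
        raise ValueError("ANCOVA needs at least 2 sites")
    if (data.groupby("site")[trait].count() < 2).any():
        raise ValueError("ANCOVA needs >= 2 units per site")

    aliased = _covariate_aliased(data, covariate)
    data = data.rename(columns={trait: "_y", covariate: "_x"})
    if data["_y"].nunique() == 1:
        # degenerate: no variation at all -> nothing to test
        n_par = len(sites) if aliased else len(sites) + 1
        terms = {"site": {"F": 0.0, "df_num": float(len(sites) - 1),
                          "df_den": float(len(data) - n_par), "p": 1.0}}
        if not aliased:
            terms["covariate"] = {"F": 0.0, "df_num": 1.0,
                                  "df_den": float(len(data) - n_par), "p": 1.0}
        return AncovaResult(trait, pd.DataFrame(terms).T, 0.0, 1.0, aliased, None)
    if aliased:
        fit = smf.ols("_y ~ C(site)", data=data).fit()
    else:
        fit = smf.ols("_y ~ _x + C(site)", data=data).fit()
    aov = sm.stats.anova_lm(fit, typ=2)

    rows = {}
    df_den = float(aov.loc["Residual", "df"])
    for term, label in (("C(site)", "site"), ("_x", "covariate")):
        if term in aov.index:
            rows[label] = {
                "F": float(aov.loc[term, "F"]),
                "df_num": float(aov.loc[term, "df"]),
                "df_den": df_den,
                "p": float(min(max(aov.loc[term, "PR(>F)"], np.finfo(float).eps), 1.0)),
            }
    groups = [g["_y"].to_numpy() for _, g in data.groupby("site")]
    lev_stat, lev_p = stats.levene(*groups, center="median")
    return AncovaResult(
        trait=trait,
        terms=pd.DataFrame(rows).T,
        levene_stat=float(lev_stat),
        levene_p=float(lev_p),
        collinearity_flag=aliased,
        model=fit,
    )


@dataclass
class TukeyResult:
    trait: str
    contrasts: pd.DataFrame  # group1, group2, estimate, p_adj, p_unadj


def tukey_hsd(table: pd.DataFrame, trait: str) -> TukeyResult:
    """All pairwise site contrasts with studentized-range adjusted p-values.

    ``p_unadj`` is the unadjusted two-sided t probability from the pooled
    within-site mean square, for diagnostic comparison (Tukey-adjusted p is
    never smaller).
    """
    data = table[["site", trait]].dropna()
    sites = sorted(data["site"].unique())
    if len(sites) < 2:
        return TukeyResult(trait, pd.DataFrame(
            columns=["group1", "group2", "estimate", "p_adj", "p_unadj"]))
    res = pairwise_tukeyhsd(data[trait].to_numpy(), data["site"].to_numpy())
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]]
    )
    out = pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "estimate": res.meandiffs,
            "p_adj": res.pvalues,
        }
    )
    # unadjusted pairwise t on the pooled error
    g = data.groupby("site")[trait]
    means, ns = g.mean(), g.count()
    sse = float(((data[trait] - data["site"].map(means)) ** 2).sum())
    df_err = len(data) - len(sites)
    mse = sse / df_err
    p_un = []
    for _, row in out.iterrows():
        se = np.sqrt(mse * (1 / ns[row["group1"]] + 1 / ns[row["group2"]]))
        t = abs(row["estimate"]) / se
        p_un.append(2 * stats.t.sf(t, df_err))
    out["p_unadj"] = p_un
    return TukeyResult(trait, out)


@dataclass
class PcaResult:
    traits: list
    units: pd.DataFrame          # site, species keys for each score row
    loadings: np.ndarray         # traits x components
    scores: np.ndarray           # units x components
    percent_variance: np.ndarray


def pca_traits(table: pd.DataFrame, traits=None) -> PcaResult:
    """Correlation-matrix PCA of the trait table.

    Columns are centred and scaled to unit variance (ddof=1); components
    come from the SVD of the standardised matrix.  Sign convention: within
    each component the largest-magnitude loading is made positive, so the
    decomposition is deterministic.  Units with any missing trait are
    excluded with a warning.
    """
    import warnings as _warnings

    if traits is None:
        traits = [t for t in TRAIT_COLUMNS if t in table.columns]
    traits = list(traits)
    if len(traits) < 2:
        raise ValueError("PCA needs >= 2 traits")
    sub = table[["site", "species"] + traits]
    complete = sub.dropna()
    if len(complete) < len(sub):
        _warnings.warn(
            f"excluding {len(sub) - len(complete)} unit(s) with missing traits",
            stacklevel=2,
        )
    if len(complete) < 3:
        raise ValueError("PCA needs >= 3 complete units")
    x = complete[traits].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = traits[int(np.argmin(sd))]
        raise ValueError(f"trait {bad!r} is constant; cannot standardise")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2 / (len(z) - 1)
    loadings = vt.T
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = z @ loadings
    pct = 100.0 * eigvals / eigvals.sum()
    return PcaResult(
        traits=traits,
        units=complete[["site", "species"]].reset_index(drop=True),
        loadings=loadings,
        scores=scores,
        percent_variance=pct,
    )


@dataclass
class RegressionResult:
    site: str
    component: int
    slope: float
    r_squared: float
    p: float
    n: int
    insufficient_n: bool


def regress_scores_vs_agr(
    pca: PcaResult, table: pd.DataFrame, components=(0, 1)
) -> list[RegressionResult]:
    """Per-site OLS of apical growth rate on PCA scores.

    Sites with fewer than 3 complete units are reported with the
    ``insufficient_n`` flag instead of being dropped.
    """
    joined = pca.units.copy()
    for c in components:
        joined[f"score_{c}"] = pca.scores[:, c]
    joined = joined.merge(table[["site", "species", "AGR"]], on=["site", "species"])
    results = []
    for site, grp in joined.groupby("site", sort=True):
        for c in components:
            n = len(grp)
            if n < 3:
                results.append(RegressionResult(site, c, np.nan, np.nan, np.nan, n, True))
                continue
            if np.allclose(grp["AGR"].var(ddof=1), 0) or np.allclose(
                grp[f"score_{c}"].var(ddof=1), 0
            ):
                results.append(RegressionResult(site, c, 0.0, 0.0, 1.0, n, False))
                continue
            lr = stats.linregress(grp[f"score_{c}"], grp["AGR"])
            results.append(
                RegressionResult(
                    site, c, float(lr.slope), float(lr.rvalue**2), float(lr.pvalue),
                    n, False,
                )
            )
    return results


def site_mean_correlation(table: pd.DataFrame, x_trait: str, y_trait: str):
    """Pearson correlation of site means of two traits.

    Returns ``(r, r_squared, p, n_sites)`` with a two-sided p from the t
    distribution on n-2 df.  Errors on zero variance in either trait.
    """
    means = table.groupby("site")[[x_trait, y_trait]].mean().dropna()
    n = len(means)
    if n < 3:
        raise ValueError("site-mean correlation needs >= 3 sites")
    x, y = means[x_trait].to_numpy(), means[y_trait].to_numpy()
    if np.allclose(x.var(), 0) or np.allclose(y.var(), 0):
        raise ValueError("zero variance in a trait across sites")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r**2), float(p), n
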