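"""Pipeline orchestration and the derived-results report.

``run_traits`` turns a raw bundle into the species-site trait table plus
diameter-class tables; ``run_stats`` runs the full statistics battery;
``fold_change_panel`` computes the derived fold changes a site-mean trait
table implies (conductivity ratios with and without embolism adjustment,
growth and vessel-diameter ratios, embolism-reversal heights).

Rounding conventions live here and only here: fold changes and heights to
1 decimal where printed with 1 decimal, nearest integer where printed as
integers; all underlying values are kept at full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anatomy, hydraulics, phylostats, reference, trait_stats


@dataclass
class TraitResults:
    stem_table: pd.DataFrame
    trait_table: pd.DataFrame
    site_summary: pd.DataFrame
    class_tables: dict            # (site, species) -> DiameterClassTable
    warnings: hydraulics.HydraulicWarnings


def run_traits(bundle, pc_kpa: float = 0.0) -> TraitResults:
    """Raw records -> per-stem hydraulics, species-site trait table,
    site summary and per-unit diameter-class tables."""
    collect = hydraulics.HydraulicWarnings()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stem_table = hydraulics.stem_hydraulics(bundle.stems, collect=collect)
        if bundle.vessels is not None and bundle.areas is not None:
            _, species_vessels = anatomy.summarize_vessels(bundle.vessels, bundle.areas)
        else:
            species_vessels = pd.DataFrame(
                columns=["site", "species", "mean_diameter_um", "vessel_density_per_mm2"]
            )
        wood = (
            anatomy.wood_density_table(bundle.wood)
            if bundle.wood is not None
            else pd.DataFrame(columns=["site", "species", "wood_density_g_cm3"])
        )
        if bundle.manometer is not None:
            pr = hydraulics.root_pressure_estimates(bundle.manometer, pc_kpa, collect=collect)
        else:
            pr = pd.DataFrame(columns=["site", "species", "PR", "hc"])
        growth = (
            bundle.growth
            if bundle.growth is not None
            else pd.DataFrame(columns=["site", "species", "growth_cm", "months_elapsed"])
        )
        trait_table = trait_stats.build_trait_table(
            stem_table, species_vessels, wood, pr, growth, bundle.climate
        )

    class_tables = {}
    if bundle.vessels is not None:
        v = bundle.vessels.assign(
            diameter_um=anatomy.vessel_diameter(
                bundle.vessels["long_axis_um"].to_numpy(),
                bundle.vessels["short_axis_um"].to_numpy(),
            )
        )
        for (site, sp), grp in v.groupby(["site", "species"]):
            class_tables[(site, sp)] = anatomy.bin_vessels(grp["diameter_um"].to_numpy())

    trait_cols = [c for c in trait_stats.TRAIT_COLUMNS if c in trait_table.columns]
    site_summary = hydraulics.group_summary(trait_table, trait_cols, by="site")
    return TraitResults(stem_table, trait_table, site_summary, class_tables, collect)


# ---------------------------------------------------------------------------
# Derived fold changes


def fold_change_panel(site_means: pd.DataFrame, north: str = "Nahuelbuta",
                      mid: str = "Puyehue", south: str = "Aysen") -> dict:
    """Derived ratios from a site-mean trait table (index: site).

    Returns full-precision values; see ``round_panel`` for the reporting
    conventions.  ``*_field`` conductivities are PLC-adjusted:
    Ks_max * (1 - PLC/100).
    """
    ks = site_means["Ks_max"]
    plc = site_means["PLC"]
    ks_field = {
        s: float(hydraulics.adjusted_conductivity(ks[s], plc[s]))
        for s in (north, mid, south)
    }
    panel = {
        "ks_max_ratio_north_south": hydraulics.fold_change(ks[north], ks[south]),
        "joint_reduction_north_south": hydraulics.fold_change(ks[north], ks_field[south]),
        "adjusted_ratio_north_mid": hydraulics.fold_change(ks_field[north], ks_field[mid]),
        "adjusted_ratio_north_south": hydraulics.fold_change(ks_field[north], ks_field[south]),
        "agr_ratio_north_south": hydraulics.fold_change(
            site_means["AGR"][north], site_means["AGR"][south]
        ),
        "vessel_diameter_ratio_north_south": hydraulics.fold_change(
            site_means["vessel_diameter"][north], site_means["vessel_diameter"][south]
        ),
    }
    if "root_pressure" in site_means:
        for s in (north, mid, south):
            panel[f"reversal_height_m_{s}"] = hydraulics.embolism_reversal_height(
                site_means["root_pressure"][s]
            )
    return panel


#: Reporting precision: number of decimals per panel entry (None = integer).
PANEL_ROUNDING = {
    "ks_max_ratio_north_south": 1,
    "joint_reduction_north_south": None,
    "adjusted_ratio_north_mid": 1,
    "adjusted_ratio_north_south": None,
    "agr_ratio_north_south": None,
    "vessel_diameter_ratio_north_south": None,
    "reversal_height_m_Nahuelbuta": None,
    "reversal_height_m_Puyehue": 1,
    "reversal_height_m_Aysen": 1,
}


def round_panel(panel: dict) -> dict:
    """Apply the report rounding conventions to a fold-change panel."""
    out = {}
    for key, value in panel.items():
        nd = PANEL_ROUNDING.get(key, 1)
        out[key] = int(round(value)) if nd is None else round(value, nd)
    return out


def reference_panel() -> tuple[dict, dict]:
    """Fold-change panel computed from the published site means.

    Returns ``(full_precision, rounded)``.
    """
    panel = fold_change_panel(reference.TRAIT_MEANS)
    return panel, round_panel(panel)


# ---------------------------------------------------------------------------
# Statistics battery


@dataclass
class StatsResults:
    ancova: dict                  # trait -> AncovaResult
    tukey: dict                   # trait -> TukeyResult
    pca: trait_stats.PcaResult | None
    regressions: list
    agr_plc_correlation: tuple | None
    ks_tests: pd.DataFrame
    dic: pd.DataFrame | None = None


def run_stats(traits: TraitResults, newick: str | None = None,
              mcmc_profile: dict | None = None, seed: int | None = None,
              run_dic: bool = True) -> StatsResults:
    """ANCOVA + Tukey per trait, PCA with per-site growth regressions,
    site-mean growth-PLC correlation, per-unit KS tests, and (optionally)
    the phylogenetic DIC comparison per trait."""
    table = traits.trait_table
    trait_cols = [c for c in trait_stats.TRAIT_COLUMNS if c in table.columns]

    anc, tuk = {}, {}
    enough_sites = table["site"].nunique() >= 2
    for trait in trait_cols:
        if not enough_sites or table[trait].dropna().empty:
            continue
        try:
            anc[trait] = trait_stats.ancova(table, trait)
            tuk[trait] = trait_stats.tukey_hsd(table, trait)
        except ValueError:
            continue

    pca = regs = corr = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca = trait_stats.pca_traits(table, [t for t in trait_cols if t != "hc"])
            regs = trait_stats.regress_scores_vs_agr(pca, table)
    except ValueError:
        regs = []
    try:
        corr = trait_stats.site_mean_correlation(table, "AGR", "PLC")
    except ValueError:
        corr = None

    ks_rows = []
    for (site, sp), tbl in traits.class_tables.items():
        d, p = anatomy.ks_compare(tbl)
        ks_rows.append(dict(site=site, species=sp, D=d, p=p,
                            n_vessels=int(tbl.diameters.size)))
    ks_tests = pd.DataFrame(ks_rows)

    dic_frame = None
    if run_dic and newick is not None and enough_sites:
        tree = phylostats.read_newick(newick)
        cov = phylostats.phylo_covariance(tree)
        profile = mcmc_profile or phylostats.CI_PROFILE
        rows = []
        sites = sorted(table["site"].unique())
        x = np.column_stack(
            [np.ones(len(table))]
            + [(table["site"] == s).to_numpy(float) for s in sites[1:]]
        )
        for i, trait in enumerate(trait_cols):
            y = table[trait].to_numpy(float)
            if np.isnan(y).any():
                continue
            settings = phylostats.McmcSettings(
                **profile, seed=None if seed is None else seed + i
            )
            fit_with = phylostats.fit_mixed_model(
                y, x, species=list(table["species"]), cov=cov, settings=settings
            )
            fit_wo = phylostats.fit_mixed_model(y, x, settings=settings)
            cmp = phylostats.compare_models(fit_with, fit_wo)
            rows.append(dict(trait=trait, DIC_with=cmp.dic_with_phylo,
                             DIC_without=cmp.dic_without, delta=cmp.delta,
                             signal=cmp.signal))
        dic_frame = pd.DataFrame(rows)

    return StatsResults(anc, tuk, pca, regs, corr, ks_tests, dic_frame)
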