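"""Xylem vessel anatomy and wood density.

Vessel diameter is the mean of the longest and shortest lumen axes measured
on a transverse section.  Vessels are grouped in 10-µm diameter classes and
each class's relative contribution to total hydraulic conductivity follows
the Hagen-Poiseuille law: conductivity scales with the fourth power of the
lumen radius, so a class contributes the sum of r^4 over its vessels
divided by the sum of r^4 over all vessels.  The contrast between the
frequency distribution (where the vessels are) and the conductivity
distribution (where the water goes) quantifies the efficiency-safety
trade-off: a small share of wide vessels can carry most of the flow while
being the most vulnerable to freeze-thaw embolism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import distributions

#: Branches summarised from fewer vessels than this get a low-count warning.
MIN_VESSELS_PER_BRANCH = 100

CLASS_WIDTH_UM = 10.0


class AnatomyDomainError(ValueError):
    pass


def vessel_diameter(long_axis, short_axis):
    """Lumen diameter (µm) as the mean of the longest and shortest axes."""
    la = np.asarray(long_axis, float)
    sa = np.asarray(short_axis, float)
    if np.any(sa <= 0):
        raise AnatomyDomainError("short_axis must be > 0")
    if np.any(la < sa):
        bad = np.nonzero(np.atleast_1d(la < sa))[0]
        raise AnatomyDomainError(f"long_axis < short_axis at record index {bad[0]}")
    d = (la + sa) / 2.0
    return float(d) if np.isscalar(long_axis) and np.isscalar(short_axis) else d


def summarize_vessels(vessels: pd.DataFrame, areas: pd.DataFrame):
    """Branch- and species-level vessel summaries.

    The branch mean diameter averages its vessels; the species(-site) mean
    is the *unweighted* mean of its branch means, so branches with more
    measured vessels do not dominate.  Vessel density is vessel count per
    counted section area (vessels mm^-2).

    Parameters
    ----------
    vessels : DataFrame
        Columns ``vessel_id, branch_id, site, species, long_axis_um,
        short_axis_um``.
    areas : DataFrame
        Columns ``branch_id, counted_area_mm2``.

    Returns
    -------
    (branch_summary, species_summary) : tuple of DataFrame
    """
    v = vessels.copy()
    v["diameter_um"] = vessel_diameter(
        v["long_axis_um"].to_numpy(), v["short_axis_um"].to_numpy()
    )
    area_map = areas.set_index("branch_id")["counted_area_mm2"]
    missing = set(v["branch_id"]) - set(area_map.index)
    if missing:
        raise AnatomyDomainError(f"no counted area for branch(es): {sorted(missing)[:5]}")
    if np.any(area_map.to_numpy() <= 0):
        raise AnatomyDomainError("counted_area_mm2 must be > 0")

    branch = (
        v.groupby(["site", "species", "branch_id"])["diameter_um"]
        .agg(mean_diameter_um="mean", n_vessels="count")
        .reset_index()
    )
    branch["counted_area_mm2"] = branch["branch_id"].map(area_map)
    branch["vessel_density_per_mm2"] = branch["n_vessels"] / branch["counted_area_mm2"]
    low = branch["n_vessels"] < MIN_VESSELS_PER_BRANCH
    branch["low_count"] = low
    if low.any():
        warnings.warn(
            f"{int(low.sum())} branch(es) summarised from < "
            f"{MIN_VESSELS_PER_BRANCH} vessels",
            stacklevel=2,
        )

    species = (
        branch.groupby(["site", "species"])
        .agg(
            mean_diameter_um=("mean_diameter_um", "mean"),
            vessel_density_per_mm2=("vessel_density_per_mm2", "mean"),
            n_branches=("branch_id", "count"),
            n_vessels=("n_vessels", "sum"),
        )
        .reset_index()
    )
    return branch, species


@dataclass
class DiameterClassTable:
    """10-µm diameter classes with frequency and conductivity shares.

    ``bin_edges`` has length ``n_classes + 1``; class k is
    [edges[k], edges[k+1]) with the top class closed on the maximum
    observed diameter.  ``relative_frequency`` and
    ``relative_conductivity`` each sum to 1.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    relative_frequency: np.ndarray
    relative_conductivity: np.ndarray
    diameters: np.ndarray  # individual vessel diameters, µm

    @property
    def n_classes(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_low_um": self.bin_edges[:-1],
                "class_high_um": self.bin_edges[1:],
                "count": self.counts,
                "relative_frequency": self.relative_frequency,
                "relative_conductivity": self.relative_conductivity,
            }
        )


def bin_vessels(diameters, width: float = CLASS_WIDTH_UM) -> DiameterClassTable:
    """Group vessel diameters into left-closed classes [0,w), [w,2w), ...

    The top class is extended to include the maximum diameter (a vessel at
    exactly an upper edge belongs to the next class, so edges are extended
    one class beyond the maximum when it falls on an edge).
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise AnatomyDomainError("cannot bin an empty set of vessels")
    if np.any(d <= 0):
        raise AnatomyDomainError("diameters must be > 0")
    n_classes = int(np.floor(d.max() / width)) + 1
    edges = np.arange(n_classes + 1, dtype=float) * width
    counts = np.histogram(d, bins=edges)[0]
    rel = counts / counts.sum()
    table = DiameterClassTable(
        bin_edges=edges,
        counts=counts,
        relative_frequency=rel,
        relative_conductivity=np.empty(n_classes),
        diameters=d,
    )
    table.relative_conductivity = hp_contribution(table)
    return table


def hp_contribution(table: DiameterClassTable) -> np.ndarray:
    """Hagen-Poiseuille relative conductivity contribution per class.

    For class c this is sum_{v in c} r_v^4 / sum_{all v} r_v^4 with
    r = diameter/2, using the *individual* vessel radii (not class
    midpoints).  Invariant to the unit of diameter.
    """
    r4 = (table.diameters / 2.0) ** 4
    total = r4.sum()
    cls = np.clip(
        np.digitize(table.diameters, table.bin_edges) - 1, 0, table.n_classes - 1
    )
    contrib = np.bincount(cls, weights=r4, minlength=table.n_classes) / total
    return contrib


def wide_vessel_share(diameters, threshold_um: float = 100.0):
    """Fractions of vessel count and of total r^4 above a diameter threshold.

    Strict inequality: a vessel at exactly the threshold counts as narrow.
    Returns ``(count_share, conductivity_share)``, both in [0, 1].
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise AnatomyDomainError("empty vessel set")
    wide = d > threshold_um
    r4 = (d / 2.0) ** 4
    return float(wide.mean()), float(r4[wide].sum() / r4.sum())


def ks_compare(table: DiameterClassTable, n_vessels: int | None = None,
               method: str = "asymptotic", n_permutations: int = 999,
               seed: int | None = None):
    """Kolmogorov-Smirnov comparison of frequency vs conductivity distributions.

    D is the maximum absolute gap between the two class-wise cumulative
    distributions, evaluated at the class boundaries.  The asymptotic
    p-value uses the two-sample Kolmogorov distribution with both effective
    sample sizes equal to the vessel count.  ``method='permutation'``
    shuffles the per-vessel r^4 weights against the diameters (the null of
    no association between vessel size and conductivity share) and reports
    the fraction of permuted D at least as large as the observed one.

    Returns ``(D, p)``.
    """
    if n_vessels is None:
        n_vessels = int(table.diameters.size)
    freq_cdf = np.cumsum(table.relative_frequency)
    cond_cdf = np.cumsum(table.relative_conductivity)
    d_stat = float(np.max(np.abs(freq_cdf - cond_cdf))) if table.n_classes > 1 else 0.0
    if table.n_classes <= 1:
        return 0.0, 1.0
    if method == "asymptotic":
        en = np.sqrt(n_vessels * n_vessels / (2.0 * n_vessels))
        p = float(np.clip(distributions.kstwobign.sf(en * d_stat), 0.0, 1.0))
        return d_stat, p
    if method == "permutation":
        rng = np.random.default_rng(seed)
        r4 = (table.diameters / 2.0) ** 4
        cls = np.clip(
            np.digitize(table.diameters, table.bin_edges) - 1, 0, table.n_classes - 1
        )
        exceed = 0
        for _ in range(n_permutations):
            w = rng.permutation(r4)
            cond = np.bincount(cls, weights=w, minlength=table.n_classes) / w.sum()
            d_perm = np.max(np.abs(freq_cdf - np.cumsum(cond)))
            if d_perm >= d_stat - 1e-15:
                exceed += 1
        return d_stat, (exceed + 1) / (n_permutations + 1)
    raise ValueError(f"unknown method: {method!r}")


def wood_density(dry_mass_g, volume_cm3):
    """Wood density (g cm^-3): oven-dry mass over fresh volume."""
    m = np.asarray(dry_mass_g, float)
    v = np.asarray(volume_cm3, float)
    if np.any(v <= 0):
        raise AnatomyDomainError("volume_cm3 must be > 0")
    if np.any(m <= 0):
        raise AnatomyDomainError("dry_mass_g must be > 0")
    wd = m / v
    return float(wd) if np.isscalar(dry_mass_g) and np.isscalar(volume_cm3) else wd


def wood_density_table(wood: pd.DataFrame) -> pd.DataFrame:
    """Per-sample wood density from a mass/volume table."""
    required = {"sample_id", "site", "species", "dry_mass_g", "volume_cm3"}
    missing = required - set(wood.columns)
    if missing:
        raise ValueError(f"wood table missing columns: {sorted(missing)}")
    out = wood[["sample_id", "site", "species"]].copy()
    out["wood_density_g_cm3"] = wood_density(
        wood["dry_mass_g"].to_numpy(), wood["volume_cm3"].to_numpy()
    )
    return out
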