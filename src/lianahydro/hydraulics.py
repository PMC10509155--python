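"""Stem hydraulics: specific conductivity, embolism (PLC), root pressure.

Specific hydraulic conductivity of a stem segment,

    Ks = F * L / (dP * Ax)        [kg s^-1 m^-1 MPa^-1]

normalises the mass flow ``F`` (kg s^-1) driven by the pressure difference
``dP`` (MPa) by segment length ``L`` (m) and xylem cross-sectional area
``Ax`` (m^2), making segments of different sizes comparable.  Percent loss
of conductivity,

    PLC = 100 * (Ks_max - Ks_field) / Ks_max,

contrasts the native winter (field) conductivity with the maximum measured
after flushing emboli out of the segment, and is the standard proxy for
freeze-thaw embolism.  Root pressure is estimated from the compression of
the air bubble in a closed manometer via the ideal gas law,

    PR = 100 * (Latm / Lpd - 1)   [kPa],

where ``Lpd`` is the bubble length under root pressure at pre-dawn and
``Latm`` its length at atmospheric pressure.  A root pressure ``PR`` can
dissolve emboli up to the height

    hc = (PR - Pc) / 10           [m]

above the reference point at pressure ``Pc`` (kPa; default 0, i.e. gauge
pressure at the stem base).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class HydraulicsDomainError(ValueError):
    """A physically inadmissible input (non-positive length, area, ...)."""


def _check_positive(name: str, value) -> None:
    if np.any(~np.isfinite(np.asarray(value, dtype=float))) or np.any(
        np.asarray(value, dtype=float) <= 0
    ):
        raise HydraulicsDomainError(f"{name} must be finite and > 0")


def specific_conductivity(flow, length, pressure_drop, xylem_area):
    """Specific hydraulic conductivity Ks = F*L/(dP*Ax).

    Parameters
    ----------
    flow : float or array
        Mass flow F through the segment, kg s^-1 (>= 0).
    length : float or array
        Segment length L, m (> 0).
    pressure_drop : float or array
        Pressure difference dP across the segment, MPa (> 0).
    xylem_area : float or array
        Xylem cross-sectional area Ax, m^2 (> 0).

    Returns
    -------
    float or ndarray
        Ks in kg s^-1 m^-1 MPa^-1.
    """
    _check_positive("length", length)
    _check_positive("pressure_drop", pressure_drop)
    _check_positive("xylem_area", xylem_area)
    f = np.asarray(flow, dtype=float)
    if np.any(f < 0):
        raise HydraulicsDomainError("flow must be >= 0")
    ks = f * np.asarray(length, float) / (
        np.asarray(pressure_drop, float) * np.asarray(xylem_area, float)
    )
    return float(ks) if np.isscalar(flow) else ks


def percent_loss_conductivity(ks_field, ks_max, *, clamp: bool = True):
    """Percent loss of conductivity, 100*(Ks_max - Ks_field)/Ks_max.

    Measurement noise can make the flushed (maximum) reading fall below the
    field reading; physically flushing can only increase conductivity, so
    negative PLC is clamped to 0 and a warning issued (``clamp=False``
    returns the raw value).
    """
    _check_positive("ks_max", ks_max)
    kf = np.asarray(ks_field, dtype=float)
    if np.any(kf < 0):
        raise HydraulicsDomainError("ks_field must be >= 0")
    plc = 100.0 * (np.asarray(ks_max, float) - kf) / np.asarray(ks_max, float)
    if clamp and np.any(np.asarray(plc) < 0):
        warnings.warn(
            "field conductivity exceeded flushed maximum; PLC clamped to 0",
            stacklevel=2,
        )
        plc = np.maximum(plc, 0.0)
    return float(plc) if np.isscalar(ks_field) and np.isscalar(ks_max) else plc


def root_pressure(bubble_atm, bubble_predawn):
    """Root pressure PR = 100*(Latm/Lpd - 1) in kPa from bubble lengths (m).

    A pre-dawn bubble longer than the atmospheric one implies negative
    pressure; the value is returned but flagged with a warning, since it
    usually indicates a leaking manometer fitting.
    """
    _check_positive("bubble_atm", bubble_atm)
    _check_positive("bubble_predawn", bubble_predawn)
    pr = 100.0 * (np.asarray(bubble_atm, float) / np.asarray(bubble_predawn, float) - 1.0)
    if np.any(np.asarray(pr) < 0):
        warnings.warn("negative root pressure (Lpd > Latm)", stacklevel=2)
    return float(pr) if np.isscalar(bubble_atm) and np.isscalar(bubble_predawn) else pr


def embolism_reversal_height(pr_kpa, pc_kpa=0.0):
    """Maximum embolism-reversal height hc = (PR - Pc)/10, in metres.

    ``pc_kpa`` is the pressure at the reference height (default 0: gauge
    pressure at the stem base).  10 kPa of positive pressure supports
    roughly 1 m of water column.
    """
    hc = (np.asarray(pr_kpa, float) - np.asarray(pc_kpa, float)) / 10.0
    return float(hc) if np.isscalar(pr_kpa) and np.isscalar(pc_kpa) else hc


# ---------------------------------------------------------------------------
# Record-level pipeline


@dataclass
class HydraulicWarnings:
    """Structured warnings collected while deriving per-stem records."""

    clamped_plc_stems: list = field(default_factory=list)
    negative_pr_plants: list = field(default_factory=list)


def stem_hydraulics(stems: pd.DataFrame, collect=None) -> pd.DataFrame:
    """Per-stem Ks_field, Ks_max and PLC from paired flow measurements.

    ``stems`` is long-format with columns ``stem_id, site, species, state,
    flow_kg_per_s, length_m, dP_MPa, xylem_area_m2`` where ``state`` is
    ``field`` or ``flushed``; each stem must have exactly one row per state.
    """
    required = {"stem_id", "site", "species", "state", "flow_kg_per_s",
                "length_m", "dP_MPa", "xylem_area_m2"}
    missing = required - set(stems.columns)
    if missing:
        raise ValueError(f"stems table missing columns: {sorted(missing)}")
    bad_state = set(stems["state"]) - {"field", "flushed"}
    if bad_state:
        raise ValueError(f"unknown measurement state(s): {sorted(bad_state)}")

    ks = stems.assign(
        Ks=specific_conductivity(
            stems["flow_kg_per_s"].to_numpy(),
            stems["length_m"].to_numpy(),
            stems["dP_MPa"].to_numpy(),
            stems["xylem_area_m2"].to_numpy(),
        )
    )
    wide = ks.pivot_table(
        index=["stem_id", "site", "species"], columns="state", values="Ks"
    ).reset_index()
    if "field" not in wide or "flushed" not in wide or wide[["field", "flushed"]].isna().any().any():
        raise ValueError("each stem needs exactly one 'field' and one 'flushed' measurement")
    wide = wide.rename(columns={"field": "Ks_field", "flushed": "Ks_max"})

    raw = percent_loss_conductivity(
        wide["Ks_field"].to_numpy(), wide["Ks_max"].to_numpy(), clamp=False
    )
    clamped = raw < 0
    if clamped.any():
        stems_clamped = wide.loc[clamped, "stem_id"].tolist()
        if collect is not None:
            collect.clamped_plc_stems.extend(stems_clamped)
        warnings.warn(
            f"PLC clamped to 0 for {int(clamped.sum())} stem(s)", stacklevel=2
        )
    wide["PLC"] = np.maximum(raw, 0.0)
    return wide[["stem_id", "site", "species", "Ks_field", "Ks_max", "PLC"]]


def root_pressure_estimates(
    manometer: pd.DataFrame, pc_kpa: float = 0.0, collect=None
) -> pd.DataFrame:
    """Per-plant root pressure (kPa) and embolism-reversal height (m)."""
    required = {"plant_id", "site", "species", "L_atm_m", "L_pd_m"}
    missing = required - set(manometer.columns)
    if missing:
        raise ValueError(f"manometer table missing columns: {sorted(missing)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pr = root_pressure(manometer["L_atm_m"].to_numpy(), manometer["L_pd_m"].to_numpy())
    neg = pr < 0
    if neg.any():
        plants = manometer.loc[neg, "plant_id"].tolist()
        if collect is not None:
            collect.negative_pr_plants.extend(plants)
        warnings.warn(f"negative root pressure for {int(neg.sum())} plant(s)", stacklevel=2)
    out = manometer[["plant_id", "site", "species"]].copy()
    out["PR"] = pr
    out["hc"] = embolism_reversal_height(pr, pc_kpa)
    out["Pc"] = pc_kpa
    return out


# ---------------------------------------------------------------------------
# Group summaries and fold changes


def group_summary(df: pd.DataFrame, values, by) -> pd.DataFrame:
    """Mean, standard error and n per group for the given value columns.

    Single-observation groups get ``NaN`` standard error (undefined) rather
    than being dropped; an all-empty group requested upstream surfaces as a
    missing row in joins, never silently.
    """
    if isinstance(values, str):
        values = [values]
    g = df.groupby(by, sort=True)
    out = {}
    for v in values:
        agg = g[v].agg(["mean", "sem", "count"])
        agg.columns = [f"{v}_mean", f"{v}_se", f"{v}_n"]
        out[v] = agg
    return pd.concat(out.values(), axis=1).reset_index()


def adjusted_conductivity(ks_max, plc):
    """Field-equivalent conductivity Ks_max*(1 - PLC/100)."""
    return np.asarray(ks_max, float) * (1.0 - np.asarray(plc, float) / 100.0)


def fold_change(numerator: float, denominator: float) -> float:
    """Ratio of two group means, computed at full precision."""
    if denominator == 0:
        raise HydraulicsDomainError("fold change denominator is zero")
    return float(numerator) / float(denominator)
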