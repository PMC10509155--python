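"""CSV and Newick readers/writers with schema validation.

All tables are UTF-8, comma-delimited, dot-decimal CSV with a required
header row.  Schema violations are reported with the offending column or
row so field data sheets can be fixed quickly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMAS = {
    "growth": ["individual_id", "site", "species", "growth_cm", "months_elapsed"],
    "stems": ["stem_id", "site", "species", "state", "flow_kg_per_s",
              "length_m", "dP_MPa", "xylem_area_m2"],
    "vessels": ["vessel_id", "branch_id", "site", "species",
                "long_axis_um", "short_axis_um"],
    "areas": ["branch_id", "counted_area_mm2"],
    "wood": ["sample_id", "site", "species", "dry_mass_g", "volume_cm3"],
    "manometer": ["plant_id", "site", "species", "L_atm_m", "L_pd_m"],
    "climate": ["site", "annual_precip_mm", "seasonality_months", "tmax_mean_C",
                "tmin_mean_C", "tmin_abs_C", "frost_events", "frost_hours"],
}

_STRING_COLUMNS = {
    "individual_id", "stem_id", "vessel_id", "branch_id", "sample_id",
    "plant_id", "site", "species", "state",
}


class SchemaError(ValueError):
    pass


def read_table(path, kind: str) -> pd.DataFrame:
    """Read one of the known CSV kinds, validating the header."""
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    expected = SCHEMAS[kind]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    frame = frame[expected]
    numeric = [c for c in expected if c not in _STRING_COLUMNS]
    for col in numeric:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path.name}: column {col!r} is not numeric") from exc
        bad = frame.index[frame[col].isna()]
        if len(bad):
            raise SchemaError(
                f"{path.name}: column {col!r} has missing value at row {bad[0] + 2}"
            )
    return frame


def write_table(frame: pd.DataFrame, path, kind: str) -> None:
    """Write a known CSV kind (column order normalised to the schema)."""
    expected = SCHEMAS[kind]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"cannot write {kind}: missing column(s) {missing}")
    frame[expected].to_csv(path, index=False)


def read_bundle(directory, require_all: bool = False):
    """Read a bundle directory written by ``write_bundle``.

    Missing optional tables are left as None (the pipeline continues with
    the corresponding trait marked missing); the stems table and climate
    table are always required.
    """
    from .synthetic_data import SyntheticBundle  # local import avoids cycle

    directory = Path(directory)
    tables = {}
    for name in SyntheticBundle.TABLES:
        path = directory / f"{name}.csv"
        if path.exists():
            tables[name] = read_table(path, name)
        elif require_all or name in ("stems", "climate"):
            raise FileNotFoundError(path)
        else:
            tables[name] = None
    nwk_path = directory / "phylogeny.nwk"
    newick = nwk_path.read_text().strip() if nwk_path.exists() else None
    return SyntheticBundle(
        growth=tables["growth"],
        stems=tables["stems"],
        vessels=tables["vessels"],
        areas=tables["areas"],
        manometer=tables["manometer"],
        wood=tables["wood"],
        climate=tables["climate"],
        newick=newick,
        targets=None,
        config=None,
    )
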