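"""Readers and writers for the pipeline's on-disk formats.

All tabular inputs are TSV with fixed, documented column names; trees
are Newick with branch lengths.  Malformed rows are collected into an
error report and never silently dropped.

Drying inputs (two tables):

* mass series (long): ``leaf_id  taxon  time_s  mass_g``
* leaf metadata: ``leaf_id  taxon  mass_saturated_g  mass_dry_g
  mass_wax_g  area_saturated_m2  [lt_mm]  [air_temperature_c]
  [relative_humidity]  [pressure_kpa]``

Titration input (long): ``taxon  individual  group  phase  time_of_day
fresh_mass_g  extract_ml  aliquot_ml  naoh_mM  rep1_ul  rep2_ul  rep3_ul``
(replicate columns may be empty).
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from camtraits.drying import DryingCurveRecord, Environment
from camtraits.titration import TitrationSample

MASS_SERIES_COLUMNS = ["leaf_id", "taxon", "time_s", "mass_g"]
LEAF_META_COLUMNS = [
    "leaf_id", "taxon", "mass_saturated_g", "mass_dry_g", "mass_wax_g",
    "area_saturated_m2",
]
TITRATION_COLUMNS = [
    "taxon", "individual", "group", "phase", "time_of_day", "fresh_mass_g",
    "extract_ml", "aliquot_ml", "naoh_mM", "rep1_ul", "rep2_ul", "rep3_ul",
]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what}: missing columns {missing}; found {list(df.columns)}"
        )


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths; tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels in tree: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_drying_tables(
    mass_series_path: str | Path,
    leaf_meta_path: str | Path,
    default_environment: Environment | None = None,
) -> tuple[list[DryingCurveRecord], list[dict]]:
    """Assemble drying-curve records from the mass-series and metadata tables.

    Returns ``(records, rejections)`` where each rejection names the leaf
    and the reason it could not be assembled.
    """
    env_default = default_environment or Environment()
    series = pd.read_csv(mass_series_path, sep="\t")
    meta = pd.read_csv(leaf_meta_path, sep="\t")
    _require_columns(series, MASS_SERIES_COLUMNS, "mass series table")
    _require_columns(meta, LEAF_META_COLUMNS, "leaf metadata table")
    records: list[DryingCurveRecord] = []
    rejections: list[dict] = []
    meta = meta.set_index("leaf_id", drop=False)
    for leaf_id, grp in series.groupby("leaf_id", sort=True):
        try:
            m = meta.loc[leaf_id]
            if isinstance(m, pd.DataFrame):
                raise ValueError("duplicate metadata rows")
            env = Environment(
                air_temperature=float(m.get("air_temperature_c", env_default.air_temperature)),
                relative_humidity=float(m.get("relative_humidity", env_default.relative_humidity)),
                pressure=float(m.get("pressure_kpa", env_default.pressure)),
            )
            grp = grp.sort_values("time_s")
            lt = m.get("lt_mm", np.nan)
            records.append(
                DryingCurveRecord(
                    leaf_id=str(leaf_id),
                    taxon=str(m["taxon"]),
                    times=grp["time_s"].to_numpy(dtype=float),
                    masses=grp["mass_g"].to_numpy(dtype=float),
                    mass_saturated=float(m["mass_saturated_g"]),
                    mass_dry=float(m["mass_dry_g"]),
                    mass_wax=float(m["mass_wax_g"]),
                    area_saturated=float(m["area_saturated_m2"]),
                    environment=env,
                    leaf_thickness_mm=None if pd.isna(lt) else float(lt),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            rejections.append({"leaf_id": str(leaf_id), "reason": str(exc)})
    return records, rejections


def write_drying_tables(
    records: list[DryingCurveRecord],
    mass_series_path: str | Path,
    leaf_meta_path: str | Path,
) -> None:
    series_rows, meta_rows = [], []
    for r in records:
        for t, m in zip(r.times, r.masses):
            series_rows.append(
                {"leaf_id": r.leaf_id, "taxon": r.taxon, "time_s": t, "mass_g": m}
            )
        meta_rows.append(
            {
                "leaf_id": r.leaf_id,
                "taxon": r.taxon,
                "mass_saturated_g": r.mass_saturated,
                "mass_dry_g": r.mass_dry,
                "mass_wax_g": r.mass_wax,
                "area_saturated_m2": r.area_saturated,
                "lt_mm": r.leaf_thickness_mm,
                "air_temperature_c": r.environment.air_temperature,
                "relative_humidity": r.environment.relative_humidity,
                "pressure_kpa": r.environment.pressure,
            }
        )
    pd.DataFrame(series_rows).to_csv(mass_series_path, sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(leaf_meta_path, sep="\t", index=False)


def read_titration_table(
    path: str | Path,
) -> tuple[list[TitrationSample], list[dict]]:
    """Parse the long-format titration table into typed samples.

    Returns ``(samples, rejections)``; a row with an invalid group,
    phase, non-positive mass etc. becomes a rejection with the offending
    row index and reason.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, TITRATION_COLUMNS, "titration table")
    samples: list[TitrationSample] = []
    rejections: list[dict] = []
    rep_cols = ["rep1_ul", "rep2_ul", "rep3_ul"]
    for idx, row in df.iterrows():
        try:
            vols = tuple(
                float(row[c]) for c in rep_cols if pd.notna(row[c])
            )
            if not vols:
                raise ValueError("no technical replicate volumes")
            samples.append(
                TitrationSample(
                    taxon=str(row["taxon"]),
                    individual_id=str(row["individual"]),
                    group=str(row["group"]),
                    phase=str(row["phase"]),
                    time_of_day=str(row["time_of_day"]),
                    fresh_mass=float(row["fresh_mass_g"]),
                    naoh_volumes_ul=vols,
                    extract_volume_ml=float(row["extract_ml"]),
                    aliquot_volume_ml=float(row["aliquot_ml"]),
                    naoh_molarity=float(row["naoh_mM"]) * 1e-3,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            rejections.append({"row": int(idx), "reason": str(exc)})
    return samples, rejections


def write_titration_table(samples: list[TitrationSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        row = {
            "taxon": s.taxon,
            "individual": s.individual_id,
            "group": s.group,
            "phase": s.phase,
            "time_of_day": s.time_of_day,
            "fresh_mass_g": s.fresh_mass,
            "extract_ml": s.extract_volume_ml,
            "aliquot_ml": s.aliquot_volume_ml,
            "naoh_mM": s.naoh_molarity * 1e3,
        }
        for i, c in enumerate(["rep1_ul", "rep2_ul", "rep3_ul"]):
            row[c] = s.naoh_volumes_ul[i] if i < len(s.naoh_volumes_ul) else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_climate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "taxon" not in df.columns:
        raise ValueError("climate table must have a 'taxon' column")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
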