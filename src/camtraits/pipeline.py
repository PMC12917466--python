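"""Full-analysis orchestration: ingest → traits → statistics → phylogenetics.

The pipeline reproduces the study's analysis chain on any conforming
inputs: leaf-drying curves become per-leaf g_min and succulence values,
titration records become ΔH⁺ tables, treatment effects and cross-species
regressions are computed, and the phylogenetic analyses (Pagel's λ,
PGLS against climate covariates, ancestral states) are run on species
means.  Every stage accounts for its inputs: records used plus records
excluded (with reasons) always reconcile with records read.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from camtraits import __version__
from camtraits.design import GROUPS, PHASES
from camtraits.drying import (
    DryingCurveRecord,
    Environment,
    ShrinkageModel,
    fit_shrinkage_model,
    gmin,
    rwd_series,
    succulence,
)
from camtraits.errors import CamTraitsError, ConfigError
from camtraits.io import (
    read_climate_table,
    read_drying_tables,
    read_newick,
    read_titration_table,
    write_tsv,
)
from camtraits.phylo import ancestral_states, fit_lambda, pgls, prune_and_lump
from camtraits.titration import build_delta_h_table
from camtraits.treatment_stats import build_effect_matrix, ols_regression


@dataclass
class AnalysisConfig:
    """Declarative configuration of one full analysis run."""

    mass_series: str
    leaf_meta: str
    titration: str
    tree: str
    out_dir: str
    climate: str | None = None
    shrinkage_curves: str | None = None  # TSV: taxon, rwd, area_m2
    shrinkage_reference: dict[str, str] = field(default_factory=dict)
    lump_map: dict[str, str] = field(default_factory=dict)
    rwd_max: float = 0.7
    min_sse_reduction: float = 0.25
    tlp_rwd_fixed: float | None = None
    air_temperature_c: float = 25.0
    relative_humidity: float = 0.50
    pressure_kpa: float = 101.325
    pgls_structure: str = "lambda"
    lambda_cap: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("mass_series", "leaf_meta", "titration", "tree"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        for name in ("climate", "shrinkage_curves"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        if not 0 < self.rwd_max <= 1:
            raise ConfigError("rwd_max must lie in (0, 1]")
        if not 0 <= self.min_sse_reduction < 1:
            raise ConfigError("min_sse_reduction must lie in [0, 1)")
        if self.pgls_structure not in ("lambda", "bm", "identity"):
            raise ConfigError("pgls_structure must be lambda|bm|identity")

    def environment(self) -> Environment:
        return Environment(
            air_temperature=self.air_temperature_c,
            relative_humidity=self.relative_humidity,
            pressure=self.pressure_kpa,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    version: str = __version__

    def reconcile(self) -> None:
        """Assert inputs = used + excluded at every stage that counts records."""
        for name, counts in self.stages.items():
            if {"n_in", "n_used", "n_excluded"} <= set(counts):
                if counts["n_in"] != counts["n_used"] + counts["n_excluded"]:
                    raise CamTraitsError(
                        f"stage {name}: counts do not reconcile: {counts}"
                    )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _shrinkage_models(config: AnalysisConfig) -> dict[str, ShrinkageModel]:
    """Fit per-taxon shrinkage models and resolve the reference-taxon map."""
    models: dict[str, ShrinkageModel] = {}
    if config.shrinkage_curves is not None:
        curves = pd.read_csv(config.shrinkage_curves, sep="\t")
        for taxon, grp in curves.groupby("taxon"):
            models[str(taxon)] = fit_shrinkage_model(
                grp["area_m2"].to_numpy(float),
                grp["rwd"].to_numpy(float),
                reference_taxon=str(taxon),
            )
    for taxon, ref in config.shrinkage_reference.items():
        if ref not in models:
            raise ConfigError(
                f"shrinkage reference {ref!r} for {taxon!r} has no fitted curve"
            )
        models[taxon] = models[ref]
    return models


def _leaf_traits(
    records: list[DryingCurveRecord],
    models: dict[str, ShrinkageModel],
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Per-leaf trait table, conductance diagnostics and exclusions."""
    rows, diag_rows, exclusions = [], [], []
    for rec in records:
        shrink = models.get(rec.taxon, ShrinkageModel.none(rec.taxon))
        try:
            g = gmin(
                rec, shrink,
                rwd_max=config.rwd_max,
                min_sse_reduction=config.min_sse_reduction,
                tlp_rwd_fixed=config.tlp_rwd_fixed,
            )
            s = succulence(rec)
        except CamTraitsError as exc:
            exclusions.append({"leaf_id": rec.leaf_id, "reason": str(exc)})
            continue
        rows.append(
            {
                "taxon": rec.taxon,
                "leaf_id": rec.leaf_id,
                "gmin_mmol": g.gmin_molar,
                "gmin_ms": g.gmin_velocity,
                "DS": s.DS,
                "SWC": s.SWC,
                "LT": s.LT,
                "tlp_rwd": g.tlp_rwd,
                "n_window_points": g.n_points_in_window,
            }
        )
        rwd = rwd_series(rec)
        for i, (t, r) in enumerate(zip(rec.times, rwd)):
            diag_rows.append(
                {"leaf_id": rec.leaf_id, "taxon": rec.taxon, "time_s": t, "rwd": r}
            )
    return pd.DataFrame(rows), pd.DataFrame(diag_rows), exclusions


def _condition_regressions(
    dh_summary: pd.DataFrame, species_traits: pd.DataFrame
) -> pd.DataFrame:
    """Cross-species OLS of mean ΔH⁺ against log g_min, DS and LT per condition."""
    rows = []
    for (group, phase), sub in dh_summary.groupby(["group", "phase"]):
        merged = sub.merge(species_traits, on="taxon", how="inner")
        for predictor, transform in (("gmin_mmol", "log"), ("DS", "none"), ("LT", "none")):
            data = merged[["mean", predictor]].dropna()
            if transform == "log":
                data = data[data[predictor] > 0]
            if len(data) < 3:
                continue
            try:
                fit = ols_regression(
                    data[predictor].to_numpy(float),
                    data["mean"].to_numpy(float),
                    x_transform=transform,
                )
            except (ValueError, CamTraitsError):
                continue
            rows.append(
                {
                    "group": group,
                    "phase": phase,
                    "predictor": predictor,
                    "x_transform": transform,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "slope_p": fit.slope_p,
                    "r": fit.r,
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)


def run_full_analysis(config: AnalysisConfig) -> RunReport:
    """Execute the full analysis chain and write all output tables.

    Stages: drying curves → titration → treatment statistics →
    phylogenetic analyses.  Deterministic given the configuration.
    Returns the :class:`RunReport`; also written to ``run_report.json``
    in the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())

    # -- stage 1: drying curves -> leaf traits
    records, drying_rejects = read_drying_tables(
        config.mass_series, config.leaf_meta, config.environment()
    )
    models = _shrinkage_models(config)
    leaf_traits, diagnostics, drying_excl = _leaf_traits(records, models, config)
    if leaf_traits.empty:
        raise CamTraitsError("drying stage: no usable leaves")
    write_tsv(leaf_traits, out / "leaf_traits.tsv")
    write_tsv(diagnostics, out / "drying_diagnostics.tsv")
    report.stages["drying"] = {
        "n_in": len(records) + len(drying_rejects),
        "n_used": int(len(leaf_traits)),
        "n_excluded": len(drying_rejects) + len(drying_excl),
        "exclusions": drying_rejects + drying_excl,
    }

    species_traits = (
        leaf_traits.groupby("taxon")[["gmin_mmol", "gmin_ms", "DS", "SWC", "LT"]]
        .mean()
        .reset_index()
    )
    write_tsv(species_traits, out / "species_traits.tsv")

    # -- stage 2: titration -> delta-H tables
    samples, titr_rejects = read_titration_table(config.titration)
    dh_long, dh_summary, unpaired = build_delta_h_table(samples)
    if dh_long.empty:
        raise CamTraitsError("titration stage: no evening/morning pairs")
    write_tsv(dh_long, out / "delta_h_long.tsv")
    write_tsv(dh_summary, out / "delta_h_summary.tsv")
    report.stages["titration"] = {
        "n_in": len(samples) + len(titr_rejects),
        "n_used": int(2 * len(dh_long)),
        "n_excluded": len(titr_rejects) + len(unpaired),
        "n_pairs": int(len(dh_long)),
        "exclusions": titr_rejects + unpaired,
    }

    # -- stage 3: treatment statistics
    effects = build_effect_matrix(dh_long)
    write_tsv(effects, out / "effect_matrix.tsv")
    regressions = _condition_regressions(dh_summary, species_traits)
    write_tsv(regressions, out / "regressions.tsv")
    report.stages["stats"] = {
        "n_comparisons": int(len(effects)),
        "n_regressions": int(len(regressions)),
    }

    # -- stage 4: phylogenetic comparative analyses
    tree = read_newick(config.tree)
    lambda_rows = []
    trait_frames: dict[str, pd.DataFrame] = {
        "gmin_mmol": leaf_traits.rename(columns={"gmin_mmol": "value"})[
            ["taxon", "value"]
        ],
        "DS": leaf_traits.rename(columns={"DS": "value"})[["taxon", "value"]],
        "LT": leaf_traits.rename(columns={"LT": "value"})[["taxon", "value"]],
    }
    for group in GROUPS:
        for phase in PHASES:
            sub = dh_long[(dh_long["group"] == group) & (dh_long["phase"] == phase)]
            if sub.empty:
                continue
            trait_frames[f"delta_h:{group}:{phase}"] = sub.rename(
                columns={"delta_h_umol_g": "value"}
            )[["taxon", "value"]]
    anc_table = None
    for name, frame in trait_frames.items():
        frame = frame.dropna()
        if frame["taxon"].nunique() < 4:
            continue
        pruned, means = prune_and_lump(tree, frame, config.lump_map)
        values = means["mean"].to_numpy(float)
        if np.var(values) == 0:
            continue
        fit = fit_lambda(values, pruned, lambda_cap=config.lambda_cap)
        lambda_rows.append(
            {
                "variable": name,
                "lambda": fit.lam,
                "loglik": fit.loglik,
                "lrt": fit.lrt,
                "p": fit.pvalue,
                "n": fit.n,
            }
        )
        if name == "delta_h:cold-switch:treatment":
            anc = ancestral_states(values, pruned)
            anc_table = anc.table
    write_tsv(pd.DataFrame(lambda_rows), out / "lambda_signal.tsv")
    if anc_table is not None:
        write_tsv(anc_table, out / "ancestral_states_delta_h_heat.tsv")

    pgls_rows = []
    if config.climate is not None:
        climate = read_climate_table(config.climate)
        heat = trait_frames.get("delta_h:cold-switch:treatment")
        if heat is not None:
            pruned, means = prune_and_lump(tree, heat.dropna(), config.lump_map)
            merged = means.merge(climate, on="taxon", how="inner")
            bio_cols = [c for c in climate.columns if c != "taxon"]
            if len(merged) == len(means):
                for bio in bio_cols:
                    fit = pgls(
                        means["mean"].to_numpy(float),
                        merged[bio].to_numpy(float),
                        pruned,
                        structure=config.pgls_structure,
                        names=(bio,),
                        lambda_cap=config.lambda_cap,
                    )
                    pgls_rows.append(
                        {
                            "response": "delta_h:cold-switch:treatment",
                            "predictor": bio,
                            "slope": float(fit.coef[1]),
                            "slope_p": float(fit.p[1]),
                            "lambda_used": fit.lambda_used,
                            "structure": fit.structure,
                            "n": fit.n,
                        }
                    )
    write_tsv(pd.DataFrame(pgls_rows), out / "pgls_climate.tsv")
    report.stages["phylo"] = {
        "n_lambda_fits": len(lambda_rows),
        "n_pgls_fits": len(pgls_rows),
    }

    report.outputs = sorted(p.name for p in out.iterdir() if p.is_file())
    report.reconcile()
    report.to_json(out / "run_report.json")
    report.outputs = sorted(
        p.name for p in out.iterdir() if p.is_file()
    )
    return report
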