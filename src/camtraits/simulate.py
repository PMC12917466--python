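"""Synthetic data with the statistical structure the analysis assumes.

Every input the pipeline consumes can be generated here: pure-birth
trees, continuous traits evolved under λ-transformed Brownian motion,
two-phase (stomatal + cuticular) leaf-drying curves, a full factorial
climate-chamber titration design with group-specific nocturnal
acidification effects, and species-level climate covariates with a
configurable phylogenetic correlation to a trait.  All generators are
reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from camtraits.design import GROUPS, PHASES
from camtraits.drying import (
    DryingCurveRecord,
    Environment,
    M_WATER,
    ShrinkageModel,
    mole_fraction_vpd,
)
from camtraits.phylo import bm_covariance, lambda_transform
from camtraits.titration import TitrationSample

__all__ = [
    "DryingSimConfig",
    "StudyDesignConfig",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_drying_curve",
    "simulate_titration_dataset",
    "simulate_climate_covariates",
    "simulate_study",
    "StudySim",
]


# ---------------------------------------------------------------------------
# trees and traits

def simulate_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with exponential waiting times, unit depth.

    Tips are labelled ``t1 … tn`` in leaf order; the tree is ultrametric
    with root-to-tip depth exactly 1 after rescaling.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    birth: dict[int, float] = {}
    t = 0.0
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = root.new_child()
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = t - birth[id(node)]
        for _ in range(2):
            child = node.new_child()
            birth[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    for i, node in enumerate(active):
        node.edge.length = t - birth[id(node)]
    root.edge.length = 0.0
    # scale to unit depth
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length /= t
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(label=f"t{i + 1}")
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    lam: float = 1.0,
    root: float = 0.0,
    seed: int = 0,
    se: float | np.ndarray | None = None,
    size: int | None = None,
) -> tuple[list[str], np.ndarray]:
    """Draw tip values from N(root·1, σ²·C(λ)) via Cholesky factorisation.

    ``se`` optionally adds independent observation noise per tip.
    Returns ``(labels, values)`` in the tree's leaf order; with ``size``
    set, ``values`` has shape ``(size, n_tips)`` (independent replicate
    draws sharing one covariance factorisation).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("λ must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels, C = bm_covariance(tree)
    V = sigma2 * lambda_transform(C, lam)
    n = len(labels)
    n_rep = 1 if size is None else int(size)
    if sigma2 == 0:
        x = np.full((n_rep, n), float(root))
    else:
        jitter = 1e-12 * np.max(np.diag(V))
        L = np.linalg.cholesky(V + jitter * np.eye(n))
        x = root + rng.standard_normal((n_rep, n)) @ L.T
    if se is not None:
        x = x + rng.normal(0.0, np.broadcast_to(np.asarray(se, float), (n,)), (n_rep, n))
    return labels, x[0] if size is None else x


# ---------------------------------------------------------------------------
# drying curves

@dataclass(frozen=True)
class DryingSimConfig:
    """Forward model of a detached-leaf drying curve.

    Total conductance is g_c + g_s0·exp(−t/τ): a constant cuticular term
    plus a stomatal term closing with time constant τ.  Water loss
    follows dW/dt = −g(t)·Δw·A(RWD)·M_w with the double-projected area
    shrinking linearly in RWD.  ``mass_noise_sd`` is multiplicative on
    each per-interval water-loss increment (endpoint-reading noise),
    which keeps the recorded masses monotone.
    """

    g_c: float = 1.0  # cuticular conductance, mmol m⁻² s⁻¹
    g_s0: float = 5.0  # initial stomatal conductance, mmol m⁻² s⁻¹
    tau_s: float = 300.0  # stomatal closure time constant, s
    water_saturated: float = 1.0  # g
    mass_dry: float = 0.20  # g
    mass_wax: float = 0.05  # g
    area_saturated: float = 2.0e-3  # m², single projected
    shrinkage_slope: float = 0.2  # fractional area loss per unit RWD
    sampling_times: tuple[float, ...] | None = None  # s; None → auto
    mass_noise_sd: float = 0.0  # fractional SD per water-loss increment
    environment: Environment = field(default_factory=Environment)
    seed: int = 0
    leaf_id: str = "leaf1"
    taxon: str = "taxon1"

    def __post_init__(self) -> None:
        if self.g_c <= 0:
            raise ValueError("g_c must be positive")
        if self.g_s0 < 0:
            raise ValueError("g_s0 must be non-negative")
        if self.tau_s <= 0:
            raise ValueError("τ must be positive")


def _auto_sampling_times(config: DryingSimConfig, dw: float) -> np.ndarray:
    """Sampling schedule resolving both the stomatal transient and the plateau."""
    area = 2.0 * config.area_saturated
    rate_c = config.g_c * 1e-3 * dw * area * M_WATER  # g s⁻¹ cuticular phase
    if rate_c <= 0:
        return np.linspace(0.0, 36.0 * config.tau_s, 40)
    duration = 0.85 * config.water_saturated / rate_c + 6.0 * config.tau_s
    early = config.tau_s * np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0])
    late = np.linspace(10.0 * config.tau_s, duration, 32)
    times = np.concatenate([[0.0], early, late])
    return np.unique(times)


def simulate_drying_curve(config: DryingSimConfig) -> DryingCurveRecord:
    """Integrate the drying ODE and emit a weighing record.

    Explicit Euler with sub-stepping between weighings; refuses schedules
    so coarse that a single integration step would lose more than 5% of
    the saturated water (the trajectory would be unreliable).
    """
    dw = mole_fraction_vpd(config.environment)
    times = (
        np.asarray(config.sampling_times, dtype=float)
        if config.sampling_times is not None
        else _auto_sampling_times(config, dw)
    )
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("sampling times must be strictly increasing, ≥ 2 points")
    rng = np.random.default_rng(config.seed)
    w_sat = config.water_saturated
    area2 = 2.0 * config.area_saturated
    w = w_sat
    water = [w_sat]
    n_substeps = 8
    for t0, t1 in zip(times[:-1], times[1:]):
        w_start = w
        dt = (t1 - t0) / n_substeps
        for k in range(n_substeps):
            t = t0 + k * dt
            rwd = max(1.0 - w / w_sat, 0.0)
            area = area2 * max(1.0 - config.shrinkage_slope * rwd, 0.0)
            g_mol = (config.g_c + config.g_s0 * np.exp(-t / config.tau_s)) * 1e-3
            dwdt = -g_mol * dw * area * M_WATER
            step_loss = -dwdt * dt
            if step_loss > 0.05 * w_sat:
                raise ValueError(
                    "integration step would lose > 5% of saturated water; "
                    "use a finer sampling schedule or shorter intervals"
                )
            w = max(w + dwdt * dt, 0.0)
        loss = w_start - w
        if config.mass_noise_sd > 0:
            loss *= max(1.0 + rng.normal(0.0, config.mass_noise_sd), 0.0)
        water.append(max(w_start - loss, 0.0))
        w = water[-1]
    masses = np.asarray(water) + config.mass_dry + config.mass_wax
    return DryingCurveRecord(
        leaf_id=config.leaf_id,
        taxon=config.taxon,
        times=times,
        masses=masses,
        mass_saturated=float(masses[0]),
        mass_dry=config.mass_dry,
        mass_wax=config.mass_wax,
        area_saturated=config.area_saturated,
        environment=config.environment,
    )


# ---------------------------------------------------------------------------
# titration design

#: Group × phase multipliers on the per-taxon baseline nocturnal
#: acidification.  Acclimatisation is the common baseline; drought and
#: heat treatments upregulate CAM (stronger for the heat switch), the
#: warm→cold switch depresses it; reversal relaxes partway back.
DEFAULT_EFFECTS: dict[tuple[str, str], float] = {
    **{(g, "acclimatisation"): 1.0 for g in GROUPS},
    ("cold-control", "treatment"): 1.0,
    ("cold-control", "reversal"): 1.0,
    ("warm-control", "treatment"): 1.0,
    ("warm-control", "reversal"): 1.0,
    ("cold-dry", "treatment"): 2.5,
    ("cold-dry", "reversal"): 1.3,
    ("cold-switch", "treatment"): 3.0,
    ("cold-switch", "reversal"): 1.2,
    ("warm-dry", "treatment"): 2.0,
    ("warm-dry", "reversal"): 1.5,
    ("warm-switch", "treatment"): 0.6,
    ("warm-switch", "reversal"): 1.0,
}


@dataclass(frozen=True)
class StudyDesignConfig:
    """Factorial climate-chamber design for the synthetic titration study.

    ``taxa`` and ``baseline_delta_h`` are aligned; the last
    ``n_singleton_taxa`` taxa contribute a single plant each, assigned to
    the cold–switch group only (the one group every taxon undergoes).
    Remaining taxa contribute ``replicates_per_group`` plants per group.
    """

    taxa: tuple[str, ...]
    baseline_delta_h: tuple[float, ...]  # μmol g⁻¹ per taxon
    replicates_per_group: int = 6
    n_singleton_taxa: int = 0
    effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    evening_content: float = 40.0  # μmol g⁻¹ baseline free acid at dusk
    content_noise_sd: float = 8.0  # μmol g⁻¹ biological noise per harvest
    volume_noise_sd_ul: float = 5.0  # μl endpoint noise per technical replicate
    n_technical_replicates: int = 3
    fresh_mass_g: float = 0.050
    extract_volume_ml: float = 3.5
    aliquot_volume_ml: float = 1.0
    naoh_molarity: float = 0.010
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.baseline_delta_h):
            raise ValueError("taxa and baseline_delta_h must align")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be ≥ 1")
        if not 0 <= self.n_singleton_taxa <= len(self.taxa):
            raise ValueError("n_singleton_taxa out of range")
        if any(m <= -1.0 for m in self.effects.values()):
            raise ValueError("effect multipliers must exceed −1")


def _content_to_volumes(
    content: float,
    config: StudyDesignConfig,
    rng: np.random.Generator,
) -> tuple[float, ...]:
    """Invert the titration stoichiometry: content → replicate NaOH volumes (μl)."""
    acid_umol = max(content, 0.0) * config.fresh_mass_g
    aliquot_umol = acid_umol * config.aliquot_volume_ml / config.extract_volume_ml
    v_ul = aliquot_umol / config.naoh_molarity
    vols = np.full(config.n_technical_replicates, v_ul)
    if config.volume_noise_sd_ul > 0:
        vols = vols + rng.normal(0.0, config.volume_noise_sd_ul, vols.size)
    return tuple(np.clip(vols, 0.0, None))


def simulate_titration_dataset(design: StudyDesignConfig) -> list[TitrationSample]:
    """Generate the full evening/morning titration sample list for a design.

    Per plant and phase: the evening free-acid content is the baseline
    plus biological noise; the morning content adds the taxon's baseline
    ΔH⁺ scaled by the group × phase effect multiplier, plus noise.
    Contents are back-converted to NaOH volumes through the same
    stoichiometry the analysis inverts.
    """
    rng = np.random.default_rng(design.seed)
    n_regular = len(design.taxa) - design.n_singleton_taxa
    samples: list[TitrationSample] = []
    for ti, taxon in enumerate(design.taxa):
        singleton = ti >= n_regular
        groups = ("cold-switch",) if singleton else GROUPS
        n_rep = 1 if singleton else design.replicates_per_group
        for group in groups:
            for rep in range(n_rep):
                individual = f"{taxon}_{group}_{rep + 1}"
                for phase in PHASES:
                    evening = design.evening_content + rng.normal(
                        0.0, design.content_noise_sd
                    )
                    dh_true = design.baseline_delta_h[ti] * design.effects[
                        (group, phase)
                    ]
                    morning = evening + dh_true + rng.normal(
                        0.0, design.content_noise_sd
                    )
                    for tod, content in (("evening", evening), ("morning", morning)):
                        samples.append(
                            TitrationSample(
                                taxon=taxon,
                                individual_id=individual,
                                group=group,
                                phase=phase,
                                time_of_day=tod,
                                fresh_mass=design.fresh_mass_g,
                                naoh_volumes_ul=_content_to_volumes(
                                    content, design, rng
                                ),
                                extract_volume_ml=design.extract_volume_ml,
                                aliquot_volume_ml=design.aliquot_volume_ml,
                                naoh_molarity=design.naoh_molarity,
                            )
                        )
    return samples


# ---------------------------------------------------------------------------
# climate covariates

def simulate_climate_covariates(
    tree: dendropy.Tree,
    trait: np.ndarray,
    target_correlation: float = 0.7,
    seed: int = 0,
    n_covariates: int = 3,
) -> pd.DataFrame:
    """Species-level BIO-style covariates with a set correlation to a trait.

    The first column (``BIO1``) is a·trait + phylogenetic (BM) noise,
    standardised so the expected correlation with the trait equals
    ``target_correlation``; the remaining columns are independent BM
    draws (expected correlation 0).
    """
    if not -1.0 <= target_correlation <= 1.0:
        raise ValueError("|target_correlation| must be ≤ 1")
    labels, _ = bm_covariance(tree)
    trait = np.asarray(trait, dtype=float)
    if trait.size != len(labels):
        raise ValueError("trait length does not match number of tips")
    rng = np.random.default_rng(seed)
    sd = trait.std()
    x_std = (trait - trait.mean()) / (sd if sd > 0 else 1.0)
    cols = {"taxon": labels}
    r = target_correlation
    for k in range(n_covariates):
        _, noise = simulate_bm_traits(
            tree, sigma2=1.0, lam=1.0, root=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        nsd = noise.std()
        noise_std = (noise - noise.mean()) / (nsd if nsd > 0 else 1.0)
        if k == 0:
            z = r * x_std + np.sqrt(max(1.0 - r**2, 0.0)) * noise_std
        else:
            z = noise_std
        cols[f"BIO{k + 1}"] = z
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# full study

@dataclass
class StudySim:
    """In-memory bundle of one synthetic study: inputs plus true parameters."""

    tree: dendropy.Tree
    taxa: list[str]
    drying_records: list[DryingCurveRecord]
    shrinkage_models: dict[str, ShrinkageModel]
    titration_samples: list[TitrationSample]
    climate: pd.DataFrame
    manifest: dict


def simulate_study(
    n_taxa: int = 36,
    n_singleton_taxa: int = 9,
    replicates_per_group: int = 6,
    leaves_per_taxon: int = 3,
    seed: int = 0,
    gmin_delta_h_slope: float = -18.0,
    drying_noise_sd: float = 0.01,
    lambda_gmin: float = 0.5,
    effects: dict[tuple[str, str], float] | None = None,
) -> StudySim:
    """Generate every input of a full study with known ground truth.

    Species-level log g_min evolves under λ-transformed BM on a fresh
    pure-birth tree, spanning the observed range of the genus
    (≈ 0.07–5 mmol m⁻² s⁻¹).  Baseline nocturnal acidification is
    coupled to it as ΔH⁺ = 60 + slope·ln(g_min) + noise (negative slope:
    stronger CAM behind tighter cuticles).  Each taxon receives drying
    curves at its true cuticular conductance and a titration design
    with group × phase effect multipliers.  The manifest records every
    true parameter for recovery tests.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, seed=int(rng.integers(2**31 - 1)))
    taxa, ln_g = simulate_bm_traits(
        tree, sigma2=1.0, lam=lambda_gmin, root=0.0,
        seed=int(rng.integers(2**31 - 1)),
    )
    sd = ln_g.std()
    ln_g = (ln_g - ln_g.mean()) / (sd if sd > 0 else 1.0) * 0.9 + np.log(0.5)
    gmin_true = np.exp(ln_g)  # mmol m⁻² s⁻¹
    baseline_dh = np.clip(
        60.0 + gmin_delta_h_slope * ln_g + rng.normal(0.0, 8.0, n_taxa), 5.0, 220.0
    )
    # succulence: strongly conserved (λ ≈ 0.8), spanning a few hundred to
    # a couple of thousand g m⁻²; leaf thickness tracks DS
    _, z_ds = simulate_bm_traits(
        tree, sigma2=1.0, lam=0.8, root=0.0, seed=int(rng.integers(2**31 - 1))
    )
    zsd = z_ds.std()
    ds_true = np.exp((z_ds - z_ds.mean()) / (zsd if zsd > 0 else 1.0) * 0.45 + np.log(800.0))
    lt_true = ds_true / 285.0 * np.exp(rng.normal(0.0, 0.1, n_taxa))

    shrink = {t: ShrinkageModel(reference_taxon=t, slope=0.2) for t in taxa}
    records: list[DryingCurveRecord] = []
    for ti, taxon in enumerate(taxa):
        for leaf in range(leaves_per_taxon):
            area = float(rng.uniform(1.5e-3, 2.5e-3))
            water = float(ds_true[ti]) * 2.0 * area * float(
                np.exp(rng.normal(0.0, 0.05))
            )
            cfg = DryingSimConfig(
                g_c=float(gmin_true[ti]),
                g_s0=5.0,
                water_saturated=water,
                mass_dry=0.2 * water,
                area_saturated=area,
                shrinkage_slope=0.2,
                mass_noise_sd=drying_noise_sd,
                seed=int(rng.integers(2**31 - 1)),
                leaf_id=f"{taxon}_L{leaf + 1}",
                taxon=taxon,
            )
            rec = simulate_drying_curve(cfg)
            rec.leaf_thickness_mm = float(
                lt_true[ti] * np.exp(rng.normal(0.0, 0.05))
            )
            records.append(rec)

    design = StudyDesignConfig(
        taxa=tuple(taxa),
        baseline_delta_h=tuple(float(v) for v in baseline_dh),
        replicates_per_group=replicates_per_group,
        n_singleton_taxa=n_singleton_taxa,
        effects=dict(effects) if effects is not None else dict(DEFAULT_EFFECTS),
        seed=int(rng.integers(2**31 - 1)),
    )
    titration = simulate_titration_dataset(design)
    climate = simulate_climate_covariates(
        tree, baseline_dh, target_correlation=0.7,
        seed=int(rng.integers(2**31 - 1)),
    )
    manifest = {
        "seed": seed,
        "n_taxa": n_taxa,
        "taxa": list(taxa),
        "gmin_true_mmol": [float(v) for v in gmin_true],
        "ds_true_g_m2": [float(v) for v in ds_true],
        "lt_true_mm": [float(v) for v in lt_true],
        "baseline_delta_h": [float(v) for v in baseline_dh],
        "gmin_delta_h_slope": gmin_delta_h_slope,
        "lambda_gmin": lambda_gmin,
        "effects": {f"{g}|{p}": m for (g, p), m in design.effects.items()},
        "replicates_per_group": replicates_per_group,
        "n_singleton_taxa": n_singleton_taxa,
        "leaves_per_taxon": leaves_per_taxon,
        "climate_target_correlation": 0.7,
    }
    return StudySim(
        tree=tree,
        taxa=list(taxa),
        drying_records=records,
        shrinkage_models=shrink,
        titration_samples=titration,
        climate=climate,
        manifest=manifest,
    )


def write_study(sim: StudySim, out_dir) -> dict[str, str]:
    """Write a synthetic study to disk in the exact formats the pipeline reads.

    Emits the Newick tree, the two drying tables, a shrinkage-curve
    table (area vs RWD points for five reference taxa, mirroring a
    design where only some species have measured shrinkage curves, with
    the remaining taxa mapped onto them), the titration table, the
    climate covariate table, a manifest JSON of true parameter values,
    and a ready-to-run analysis config YAML.  Returns the path map.
    """
    import json
    from pathlib import Path

    import yaml

    from camtraits.io import (
        write_drying_tables,
        write_newick,
        write_titration_table,
        write_tsv,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": str(out / "tree.nwk"),
        "mass_series": str(out / "drying_mass_series.tsv"),
        "leaf_meta": str(out / "drying_leaf_meta.tsv"),
        "shrinkage_curves": str(out / "shrinkage_curves.tsv"),
        "titration": str(out / "titration.tsv"),
        "climate": str(out / "climate.tsv"),
        "manifest": str(out / "manifest.json"),
        "config": str(out / "analysis_config.yaml"),
    }
    write_newick(sim.tree, paths["tree"])
    write_drying_tables(sim.drying_records, paths["mass_series"], paths["leaf_meta"])
    write_titration_table(sim.titration_samples, paths["titration"])
    write_tsv(sim.climate, paths["climate"])

    reference_taxa = sim.taxa[: min(5, len(sim.taxa))]
    rwd_pts = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
    rows = []
    for taxon in reference_taxa:
        slope = sim.shrinkage_models[taxon].slope
        for r in rwd_pts:
            rows.append(
                {"taxon": taxon, "rwd": r, "area_m2": 2e-3 * (1.0 - slope * r)}
            )
    write_tsv(pd.DataFrame(rows), paths["shrinkage_curves"])
    reference_map = {
        t: reference_taxa[i % len(reference_taxa)]
        for i, t in enumerate(sim.taxa)
        if t not in reference_taxa
    }

    with open(paths["manifest"], "w") as fh:
        json.dump(sim.manifest, fh, indent=2, sort_keys=True)
    config = {
        "mass_series": paths["mass_series"],
        "leaf_meta": paths["leaf_meta"],
        "titration": paths["titration"],
        "tree": paths["tree"],
        "climate": paths["climate"],
        "shrinkage_curves": paths["shrinkage_curves"],
        "shrinkage_reference": reference_map,
        "out_dir": str(out / "results"),
        "seed": int(sim.manifest["seed"]),
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return paths
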