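"""Titratable leaf acidity and nocturnal acidification (ΔH⁺).

Leaf samples (~50 mg fresh weight) are extracted in ethanol; aliquots of
the extract are titrated with NaOH to neutrality.  Free-acid content per
gram fresh weight follows from the stoichiometry

    content = V_NaOH · C_NaOH · (extract / aliquot) / fresh_mass,

averaged over technical replicates.  Nocturnal acidification for one
plant in one experimental phase is the signed difference

    ΔH⁺ = content(morning) − content(evening)   [μmol g⁻¹ FW],

negative values indicating net overnight de-acidification.  Pairing and
summary construction follow the factorial climate-chamber design
(:mod:`camtraits.design`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from camtraits.design import validate_group, validate_phase
from camtraits.errors import DuplicateSampleError

#: Fresh-mass window (g) of the sampling protocol (50 ± 20 mg); samples
#: outside it are analysed but flagged.
FRESH_MASS_RANGE = (0.030, 0.070)


@dataclass
class TitrationSample:
    """One leaf harvest's titration measurements with design coordinates."""

    taxon: str
    individual_id: str
    group: str  # one of design.GROUPS
    phase: str  # one of design.PHASES
    time_of_day: str  # "evening" | "morning"
    fresh_mass: float  # g
    naoh_volumes_ul: tuple[float, ...]  # technical replicates, μl
    extract_volume_ml: float = 3.5
    aliquot_volume_ml: float = 1.0
    naoh_molarity: float = 0.010  # mol l⁻¹
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_group(self.group)
        validate_phase(self.phase)
        if self.time_of_day not in ("evening", "morning"):
            raise ValueError(f"time_of_day must be evening|morning, got {self.time_of_day!r}")
        if self.fresh_mass <= 0:
            raise ValueError("fresh_mass must be positive")
        if self.aliquot_volume_ml > self.extract_volume_ml:
            raise ValueError("aliquot_volume cannot exceed extract_volume")
        if any(v < 0 for v in self.naoh_volumes_ul):
            raise ValueError("NaOH volumes must be non-negative")
        if not FRESH_MASS_RANGE[0] <= self.fresh_mass <= FRESH_MASS_RANGE[1]:
            self.flags.append("fresh_mass_out_of_protocol_window")


def free_acid_content(sample: TitrationSample) -> float:
    """Free acid per gram fresh weight (μmol g⁻¹), mean over technical replicates.

    Per replicate: acid in the aliquot is V_NaOH·C_NaOH (μmol when V is
    in μl and C in mol l⁻¹ ≡ μmol μl⁻¹·10⁻³ — the arithmetic below keeps
    explicit unit factors), scaled to the whole extract and normalised by
    fresh mass.  Replicates are averaged at the content level.
    """
    if not sample.naoh_volumes_ul:
        raise ValueError("sample has no technical replicates")
    v_ul = np.asarray(sample.naoh_volumes_ul, dtype=float)
    acid_umol = v_ul * 1e-6 * sample.naoh_molarity * 1e6  # l × mol/l → mol → μmol
    whole_extract = acid_umol * sample.extract_volume_ml / sample.aliquot_volume_ml
    return float(np.mean(whole_extract / sample.fresh_mass))


def delta_h(evening_content: float, morning_content: float) -> float:
    """Signed nocturnal acidification: morning − evening (μmol g⁻¹ FW)."""
    return morning_content - evening_content


def build_delta_h_table(
    samples: list[TitrationSample],
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Pair evening/morning samples and assemble the ΔH⁺ tables.

    Returns ``(long, summary, exclusions)``:

    * ``long`` — one row per (taxon, individual, group, phase) pair with
      evening/morning contents and ΔH⁺;
    * ``summary`` — per (taxon, group, phase): mean, SD, SE and n of ΔH⁺;
    * ``exclusions`` — unpaired samples with the reason, never silently
      dropped.

    Duplicate design coordinates raise :class:`DuplicateSampleError`.
    """
    by_key: dict[tuple, dict[str, TitrationSample]] = {}
    for s in samples:
        key = (s.taxon, s.individual_id, s.group, s.phase)
        slot = by_key.setdefault(key, {})
        if s.time_of_day in slot:
            raise DuplicateSampleError(
                f"duplicate sample for {key} at {s.time_of_day}"
            )
        slot[s.time_of_day] = s

    rows: list[dict] = []
    exclusions: list[dict] = []
    for key in sorted(by_key):
        taxon, individual, group, phase = key
        pair = by_key[key]
        if "evening" in pair and "morning" in pair:
            ev = free_acid_content(pair["evening"])
            mo = free_acid_content(pair["morning"])
            rows.append(
                {
                    "taxon": taxon,
                    "individual_id": individual,
                    "group": group,
                    "phase": phase,
                    "evening_umol_g": ev,
                    "morning_umol_g": mo,
                    "delta_h_umol_g": delta_h(ev, mo),
                }
            )
        else:
            missing = "morning" if "evening" in pair else "evening"
            exclusions.append(
                {
                    "taxon": taxon,
                    "individual_id": individual,
                    "group": group,
                    "phase": phase,
                    "reason": f"missing {missing} sample",
                }
            )

    long = pd.DataFrame(
        rows,
        columns=[
            "taxon", "individual_id", "group", "phase",
            "evening_umol_g", "morning_umol_g", "delta_h_umol_g",
        ],
    )
    if long.empty:
        summary = pd.DataFrame(
            columns=["taxon", "group", "phase", "mean", "sd", "se", "n"]
        )
    else:
        grouped = long.groupby(["taxon", "group", "phase"])["delta_h_umol_g"]
        summary = grouped.agg(mean="mean", sd="std", n="count").reset_index()
        summary["se"] = summary["sd"] / np.sqrt(summary["n"])
        summary = summary[["taxon", "group", "phase", "mean", "sd", "se", "n"]]
    return long, summary, exclusions
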