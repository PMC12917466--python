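"""Leaf-drying curves: conductance series, minimum conductance and succulence.

A detached, rehydrated leaf with a wax-sealed petiole loses water first
through closing stomata and then, beyond the turgor loss point (TLP),
through the cuticle alone.  Weighing the leaf repeatedly yields a mass
series that this module converts into a conductance series

    g(t) = E(t) / Δw,   E = (−dm/dt) / (M_w · A),

with E the transpiration rate per double-projected, shrinkage-corrected
leaf area and Δw the leaf-to-air water-vapour mole-fraction gradient.
Minimum conductance g_min is the mean conductance over the window between
the TLP and lethal dehydration (relative water deficit ≈ 0.7).

Units are fixed package-wide: seconds, grams, m², kPa, °C in storage;
mmol m⁻² s⁻¹ is the canonical conductance reporting unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from camtraits.errors import (
    DegenerateRecordError,
    EmptyWindowError,
    InsufficientDataError,
    NoDrivingForceError,
    NoPlateauError,
    UnknownUnitError,
)

#: Universal gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314
#: Molar mass of water, g mol⁻¹.
M_WATER = 18.015

_MASS_TOLERANCE = 1e-4  # g; balance noise allowed against monotone mass loss


@dataclass(frozen=True)
class Environment:
    """Drying-bench air conditions used to form the transpiration driving force."""

    air_temperature: float = 25.0  # °C
    relative_humidity: float = 0.50  # fraction
    pressure: float = 101.325  # kPa

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise ValueError("relative_humidity must lie in [0, 1]")
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")


@dataclass
class DryingCurveRecord:
    """One detached leaf's timed mass series plus leaf masses and area.

    Masses include the paraffin wax seal except ``mass_dry`` (oven-dry
    leaf only).  ``area_saturated`` is the single projected area at full
    hydration; transpiring area is twice that (both surfaces bear
    stomata), shrinkage-corrected downstream.
    """

    leaf_id: str
    taxon: str
    times: np.ndarray  # s since start, strictly increasing
    masses: np.ndarray  # g, leaf + wax
    mass_saturated: float  # g, leaf + wax at full hydration
    mass_dry: float  # g, oven-dry leaf (no wax)
    mass_wax: float  # g, paraffin seal
    area_saturated: float  # m², single projected
    environment: Environment = field(default_factory=Environment)
    leaf_thickness_mm: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.shape != self.masses.shape:
            raise ValueError("times and masses must have equal length")
        if self.times.size < 2:
            raise DegenerateRecordError(f"{self.leaf_id}: need at least 2 weighings")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.leaf_id}: times must be strictly increasing")
        if np.any(np.diff(self.masses) > _MASS_TOLERANCE):
            raise ValueError(f"{self.leaf_id}: masses increase beyond tolerance")
        if self.mass_dry + self.mass_wax >= self.mass_saturated:
            raise DegenerateRecordError(
                f"{self.leaf_id}: dry + wax mass exceeds saturated mass"
            )
        if self.area_saturated <= 0:
            raise ValueError(f"{self.leaf_id}: area_saturated must be positive")

    @property
    def water_saturated(self) -> float:
        """Saturated leaf water mass (g): m_sat − m_wax − m_dry."""
        return self.mass_saturated - self.mass_wax - self.mass_dry


@dataclass(frozen=True)
class ShrinkageModel:
    """Fractional projected-area loss as a linear function of RWD through the origin."""

    reference_taxon: str
    slope: float  # fractional area loss per unit RWD
    rwd_range: tuple[float, float] = (0.0, 1.0)

    def predict(self, rwd) -> np.ndarray:
        """Fractional area loss at the given RWD, clamped to [0, 1]."""
        loss = self.slope * np.asarray(rwd, dtype=float)
        return np.clip(loss, 0.0, 1.0)

    @classmethod
    def none(cls, reference_taxon: str = "none") -> "ShrinkageModel":
        """Zero-loss model for taxa whose leaves do not shrink measurably."""
        return cls(reference_taxon=reference_taxon, slope=0.0)


@dataclass
class ConductanceSeries:
    """Per-interval transpiration and conductance assigned to interval midpoints."""

    leaf_id: str
    taxon: str
    rwd: np.ndarray  # fraction at interval midpoint
    transpiration: np.ndarray  # E, mol m⁻² s⁻¹
    conductance: np.ndarray  # g, mol m⁻² s⁻¹
    corrected_area: np.ndarray  # m², double projected, shrinkage corrected
    time_mid: np.ndarray  # s
    environment: Environment


@dataclass(frozen=True)
class GminResult:
    gmin_molar: float  # mmol m⁻² s⁻¹
    gmin_velocity: float  # m s⁻¹
    window_start_index: int
    window_end_index: int  # exclusive
    n_points_in_window: int
    tlp_rwd: float


@dataclass(frozen=True)
class SucculenceResult:
    DS: float  # g m⁻², saturated water per double-projected area
    SWC: float | None  # g g⁻¹, saturated water per dry mass
    LT: float | None  # mm, caliper pass-through


def rwd_series(record: DryingCurveRecord) -> np.ndarray:
    """Relative water deficit at each weighing: 1 − W_t / W_sat.

    Leaf water at time t is W_t = m_t − m_wax − m_dry; the wax seal and
    the dry matter are subtracted from every weighing, including the
    saturated one.  Values are clipped to [0, 1].
    """
    w_sat = record.water_saturated
    if w_sat <= 0:
        raise DegenerateRecordError(f"{record.leaf_id}: non-positive saturated water")
    w_t = record.masses - record.mass_wax - record.mass_dry
    return np.clip(1.0 - w_t / w_sat, 0.0, 1.0)


def saturation_vapour_pressure(temperature_c: float) -> float:
    """Saturation vapour pressure over liquid water (kPa), Buck (1981).

    e_sat(T) = 0.61121 · exp[(18.678 − T/234.5) · T / (257.14 + T)],
    T in °C.  Valid for the bench range −20…60 °C.
    """
    t = float(temperature_c)
    if not -20.0 <= t <= 60.0:
        raise ValueError(f"temperature {t} °C outside supported range [-20, 60]")
    return 0.61121 * np.exp((18.678 - t / 234.5) * t / (257.14 + t))


def mole_fraction_vpd(env: Environment) -> float:
    """Leaf-to-air water-vapour mole-fraction difference Δw (dimensionless).

    Assumes leaf temperature equals air temperature and saturated
    intercellular air:  Δw = e_sat(T) · (1 − RH) / P.
    """
    return (
        saturation_vapour_pressure(env.air_temperature)
        * (1.0 - env.relative_humidity)
        / env.pressure
    )


def fit_shrinkage_model(
    areas: np.ndarray,
    rwd: np.ndarray,
    reference_taxon: str,
) -> ShrinkageModel:
    """Fit fractional area loss vs RWD, linear through the origin.

    ``areas`` are projected areas measured alongside the RWD values; the
    area paired with the smallest RWD anchors the zero-loss reference.
    Requires ≥ 4 pairs including one near full hydration (RWD < 0.05).
    """
    areas = np.asarray(areas, dtype=float)
    rwd = np.asarray(rwd, dtype=float)
    if areas.size != rwd.size or areas.size < 4:
        raise InsufficientDataError("need ≥ 4 paired (area, RWD) measurements")
    if rwd.min() > 0.05:
        raise InsufficientDataError("need one measurement near full hydration (RWD < 0.05)")
    a0 = areas[np.argmin(rwd)]
    if a0 <= 0:
        raise InsufficientDataError("reference area must be positive")
    loss = 1.0 - areas / a0
    denom = float(np.sum(rwd**2))
    slope = float(np.sum(rwd * loss) / denom) if denom > 0 else 0.0
    slope = max(slope, 0.0)
    return ShrinkageModel(
        reference_taxon=reference_taxon,
        slope=slope,
        rwd_range=(float(rwd.min()), float(rwd.max())),
    )


def conductance_series(
    record: DryingCurveRecord,
    shrinkage: ShrinkageModel | None = None,
    smooth: bool = False,
) -> ConductanceSeries:
    """First-difference transpiration and conductance per weighing interval.

    For each interval, E = (Δmass/Δt) / (M_w · A_corr) with A_corr the
    double projected area reduced by the predicted fractional area loss
    at the interval-midpoint RWD; g = E / Δw.  Values are assigned to the
    interval midpoint.  ``smooth`` applies a width-3 moving median to g.
    """
    if shrinkage is None:
        shrinkage = ShrinkageModel.none(record.taxon)
    dw = mole_fraction_vpd(record.environment)
    if dw <= 0:
        raise NoDrivingForceError(
            f"{record.leaf_id}: Δw = {dw:.3g}; air is saturated, record unusable"
        )
    rwd = rwd_series(record)
    dm = -np.diff(record.masses)  # g lost per interval, ≥ 0 within noise
    dt = np.diff(record.times)
    rwd_mid = 0.5 * (rwd[:-1] + rwd[1:])
    area_corr = 2.0 * record.area_saturated * (1.0 - shrinkage.predict(rwd_mid))
    e = np.clip(dm, 0.0, None) / dt / (M_WATER * area_corr)
    g = e / dw
    if smooth and g.size >= 3:
        from scipy.ndimage import median_filter

        g = median_filter(g, size=3, mode="nearest")
    return ConductanceSeries(
        leaf_id=record.leaf_id,
        taxon=record.taxon,
        rwd=rwd_mid,
        transpiration=e,
        conductance=g,
        corrected_area=area_corr,
        time_mid=0.5 * (record.times[:-1] + record.times[1:]),
        environment=record.environment,
    )


def _line_sse(x: np.ndarray, y: np.ndarray) -> float:
    basis = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(basis, y, rcond=None)
    return float(np.sum((y - basis @ beta) ** 2))


def _split_sse(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """SSE of two independent line fits split before index ``k``."""
    return _line_sse(x[:k], y[:k]) + _line_sse(x[k:], y[k:])


def detect_gmin_window(
    series: ConductanceSeries,
    rwd_max: float = 0.7,
    min_sse_reduction: float = 0.25,
    tlp_rwd_fixed: float | None = None,
) -> tuple[int, int, float]:
    """Locate the g_min averaging window on a conductance series.

    The turgor loss point is the changepoint of a two-segment linear
    least-squares fit of g against RWD (each segment its own line, split
    at an observed point; the reported TLP is the midpoint between the
    last stomatal-phase and first cuticular-phase RWD).  The window is
    all points with tlp_rwd < RWD < ``rwd_max``.  The split must reduce
    SSE by at least ``min_sse_reduction`` relative to a single line,
    otherwise the plateau is declared unidentifiable.  Supplying
    ``tlp_rwd_fixed`` bypasses detection with a fixed RWD threshold.

    Returns ``(start_index, end_index, tlp_rwd)`` with ``end_index``
    exclusive, indices into the series arrays.
    """
    x = series.rwd
    y = series.conductance
    usable = x < rwd_max
    if int(usable.sum()) < 6:
        raise InsufficientDataError(
            f"{series.leaf_id}: need ≥ 6 points with RWD < {rwd_max}"
        )
    if tlp_rwd_fixed is None:
        xs, ys = x[usable], y[usable]
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
        sse1 = _line_sse(xs, ys)
        if sse1 <= 0:
            raise NoPlateauError(f"{series.leaf_id}: breakpoint not identifiable")
        # split points with ≥ 2 observations on each side
        splits = np.arange(2, xs.size - 1)
        sse2 = np.array([_split_sse(xs, ys, k) for k in splits])
        best = int(np.argmin(sse2))
        if sse2[best] > (1.0 - min_sse_reduction) * sse1:
            raise NoPlateauError(
                f"{series.leaf_id}: two-segment fit reduces SSE by "
                f"{100 * (1 - sse2[best] / sse1):.1f}% < "
                f"{100 * min_sse_reduction:.0f}%"
            )
        k = int(splits[best])
        tlp = float(0.5 * (xs[k - 1] + xs[k]))
    else:
        tlp = float(tlp_rwd_fixed)
    in_window = (x > tlp) & (x < rwd_max)
    if not np.any(in_window):
        raise EmptyWindowError(
            f"{series.leaf_id}: no points with RWD in ({tlp:.2f}, {rwd_max})"
        )
    idx = np.flatnonzero(in_window)
    return int(idx[0]), int(idx[-1]) + 1, tlp


def convert_conductance(
    value: float,
    from_unit: str,
    to_unit: str,
    temperature_c: float = 25.0,
    pressure_kpa: float = 101.325,
) -> float:
    """Convert between velocity and molar-flux conductance units.

    Supported units: ``"m s-1"``, ``"mol m-2 s-1"``, ``"mmol m-2 s-1"``.
    A velocity converts to a molar flux by the molar density of air,
    P/(R·T):  g_molar = g_velocity · P / (R · T_K).
    """
    units = {"m s-1", "mol m-2 s-1", "mmol m-2 s-1"}
    if from_unit not in units or to_unit not in units:
        raise UnknownUnitError(f"units must be in {sorted(units)}")
    molar_density = pressure_kpa * 1e3 / (R_GAS * (temperature_c + 273.15))  # mol m⁻³
    # normalise to mol m⁻² s⁻¹
    if from_unit == "m s-1":
        molar = value * molar_density
    elif from_unit == "mmol m-2 s-1":
        molar = value * 1e-3
    else:
        molar = value
    if to_unit == "m s-1":
        return molar / molar_density
    if to_unit == "mmol m-2 s-1":
        return molar * 1e3
    return molar


def gmin(
    record: DryingCurveRecord,
    shrinkage: ShrinkageModel | None = None,
    rwd_max: float = 0.7,
    min_sse_reduction: float = 0.25,
    tlp_rwd_fixed: float | None = None,
    smooth: bool = False,
) -> GminResult:
    """Minimum conductance of one leaf: mean g beyond the turgor loss point.

    Reported in mmol m⁻² s⁻¹ and, via the record's bench environment, as
    an equivalent velocity in m s⁻¹.
    """
    series = conductance_series(record, shrinkage, smooth=smooth)
    start, end, tlp = detect_gmin_window(
        series, rwd_max=rwd_max, min_sse_reduction=min_sse_reduction,
        tlp_rwd_fixed=tlp_rwd_fixed,
    )
    g_mean_molar = float(np.mean(series.conductance[start:end]))  # mol m⁻² s⁻¹
    g_mmol = g_mean_molar * 1e3
    g_ms = convert_conductance(
        g_mean_molar,
        "mol m-2 s-1",
        "m s-1",
        temperature_c=record.environment.air_temperature,
        pressure_kpa=record.environment.pressure,
    )
    return GminResult(
        gmin_molar=g_mmol,
        gmin_velocity=g_ms,
        window_start_index=start,
        window_end_index=end,
        n_points_in_window=end - start,
        tlp_rwd=tlp,
    )


def succulence(
    record: DryingCurveRecord,
    leaf_thickness_mm: float | None = None,
) -> SucculenceResult:
    """Degree of succulence and saturated water content of one leaf.

    DS (g m⁻²) is saturated leaf water per double-projected area; SWC
    (g g⁻¹) is saturated leaf water per dry mass; LT is passed through
    from the caliper measurement when available.
    """
    water = record.water_saturated
    ds = water / (2.0 * record.area_saturated)
    swc = water / record.mass_dry if record.mass_dry > 0 else None
    lt = leaf_thickness_mm if leaf_thickness_mm is not None else record.leaf_thickness_mm
    return SucculenceResult(DS=ds, SWC=swc, LT=lt)
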