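"""Arithmetic derived-trait formulas.

Unit conversions and ratio metrics used throughout the phenotyping workflow:
stomatal/papillae densities from counts in a microscope region, detached-leaf
water-loss percentages, the dry-down field-capacity midpoint rule, per-plant
yield metrics (filled-grain %, harvest index, thousand-grain weight) and
milling quality percentages (brown/milled/head rice yields).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, IntegrityError


# --------------------------------------------------------------------------
# densities

def density_per_mm2(
    count: int,
    region_width_um: float = 600.0,
    region_height_um: float = 450.0,
) -> float:
    """Convert a count in a width x height (um) microscope region to per-mm2.

    The default region is 600 um x 450 um = 0.27 mm2, the standard field used
    for abaxial stomatal counts at 200x magnification.
    """
    if region_width_um <= 0 or region_height_um <= 0:
        raise ConfigError("region dimensions must be positive")
    if count < 0:
        raise ConfigError("count must be non-negative")
    area_mm2 = region_width_um * region_height_um * 1e-6
    return count / area_mm2


def percent_change(reference: float, value: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ConfigError("reference must be nonzero for a percent change")
    return 100.0 * (value - reference) / abs(reference)


# --------------------------------------------------------------------------
# detached-leaf water loss

@dataclass
class WaterLossSeries:
    """Weighed detached-leaf time course.

    ``pct_retained(t) = 100 * weight(t) / weight(0)`` and ``pct_lost`` is its
    complement.  The field protocol phrases the retained fraction as
    "percentage water loss"; both quantities are carried under unambiguous
    names so neither convention is silently assumed.  ``monotone`` reports
    whether retention never increases (false indicates balance noise).
    """

    times: np.ndarray
    weights: np.ndarray
    pct_retained: np.ndarray
    pct_lost: np.ndarray
    monotone: bool


def water_loss_series(times: list[float], weights: list[float]) -> WaterLossSeries:
    """Build a :class:`WaterLossSeries` from raw times (min) and weights (g)."""
    t = np.asarray(times, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape or t.ndim != 1 or t.size == 0:
        raise ConfigError("times and weights must be equal-length 1-D sequences")
    if t[0] != 0:
        raise ConfigError("times must start at 0 (initial weighing)")
    if np.any(np.diff(t) <= 0):
        raise ConfigError("times must be strictly ascending")
    if np.any(w <= 0):
        raise ConfigError("weights must be positive")
    pct_retained = 100.0 * w / w[0]
    return WaterLossSeries(
        times=t,
        weights=w,
        pct_retained=pct_retained,
        pct_lost=100.0 - pct_retained,
        monotone=bool(np.all(np.diff(pct_retained) <= 0)),
    )


# --------------------------------------------------------------------------
# yield and milling

@dataclass(frozen=True)
class YieldRecord:
    """Per-plant harvest bookkeeping at physiological maturity."""

    panicle_count: int
    filled_grains: int
    total_spikelets: int
    grain_dry_weight: float
    shoot_dry_biomass: float
    tgw_sample_mass: float
    tgw_sample_count: int = 1000

    def __post_init__(self) -> None:
        if self.panicle_count < 0 or self.filled_grains < 0:
            raise IntegrityError("counts must be non-negative")
        if self.filled_grains > self.total_spikelets:
            raise IntegrityError("filled_grains cannot exceed total_spikelets")
        if self.shoot_dry_biomass <= 0:
            raise IntegrityError("shoot_dry_biomass must be positive")
        if self.tgw_sample_count <= 0:
            raise IntegrityError("tgw_sample_count must be positive")


def yield_metrics(record: YieldRecord) -> dict[str, float]:
    """Filled-grain %, harvest index and thousand-grain weight.

    filled_pct = 100 * filled / total spikelets;
    harvest_index = filled-grain dry weight / above-ground shoot dry biomass;
    tgw = 1000 * sample mass / sample count (identity when 1000 grains are
    weighed, the standard protocol).
    """
    if record.total_spikelets <= 0:
        raise ConfigError("total_spikelets must be positive")
    return {
        "filled_pct": 100.0 * record.filled_grains / record.total_spikelets,
        "harvest_index": record.grain_dry_weight / record.shoot_dry_biomass,
        "tgw": 1000.0 * record.tgw_sample_mass / record.tgw_sample_count,
    }


@dataclass(frozen=True)
class MillingRecord:
    """Mass bookkeeping through dehusking and polishing of one paddy sample."""

    paddy_mass: float
    brown_mass: float
    milled_mass: float
    head_mass: float  # intact kernels >= 75% of full grain length

    def __post_init__(self) -> None:
        if self.paddy_mass <= 0:
            raise IntegrityError("paddy_mass must be positive")
        if not 0 <= self.head_mass <= self.milled_mass <= self.brown_mass <= self.paddy_mass:
            raise IntegrityError(
                "mass ordering violated: need head <= milled <= brown <= paddy"
            )


def milling_metrics(record: MillingRecord) -> dict[str, float]:
    """Brown (BRY), milled (MRY) and head (HRR) rice yields, all as
    percentages of the initial paddy mass.

    HRR is expressed against paddy mass, not milled mass; both conventions
    exist in the milling literature, so the denominator is stated here.
    """
    return {
        "bry": 100.0 * record.brown_mass / record.paddy_mass,
        "mry": 100.0 * record.milled_mass / record.paddy_mass,
        "hrr": 100.0 * record.head_mass / record.paddy_mass,
    }


# --------------------------------------------------------------------------
# soil dry-down field-capacity rule

@dataclass
class DryDownCurve:
    """Daily soil moisture (%) during an unwatered dry-down, with the day
    index at which early wilting symptoms (leaf folding/rolling) appeared."""

    days: np.ndarray
    moisture: np.ndarray
    wilting_index: int

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.moisture = np.asarray(self.moisture, dtype=float)
        if self.days.shape != self.moisture.shape or self.days.ndim != 1:
            raise ConfigError("days and moisture must be equal-length 1-D sequences")
        if np.any(np.diff(self.days) <= 0):
            raise ConfigError("days must be strictly ascending")
        if np.any((self.moisture < 0) | (self.moisture > 100)):
            raise ConfigError("moisture values must lie in [0, 100]")
        if not 0 <= self.wilting_index < self.days.size:
            raise ConfigError("wilting_index out of range")


def drydown_fc_target(curve: DryDownCurve) -> dict[str, float]:
    """Limited-water target moisture: midpoint between the saturated start
    of the dry-down and the observed wilting point.

    Returns the target moisture content (%) and that target as a percentage
    of the initial (field-capacity) moisture.
    """
    if curve.wilting_index == 0:
        raise ConfigError("wilting_index must be after the start of the dry-down")
    target = (curve.moisture[0] + curve.moisture[curve.wilting_index]) / 2.0
    return {
        "target_mc": float(target),
        "pct_of_initial_fc": float(100.0 * target / curve.moisture[0]),
    }
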