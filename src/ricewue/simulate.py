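"""Synthetic genotype x treatment trait data with planted statistical structure.

The generator emulates a two-trial glasshouse screen of 21 rice genotypes
(2 indica, 19 japonica-type) under ponded-water (PW) and limited-water (LW)
treatments with 8 replicate plants per genotype x treatment x trial.  Each
trait value is drawn as

    value = baseline + genotype offset + trial shift + treatment shift + noise

where the treatment shift applies to LW plants only and equals
``d * residual_sd`` for a planted Cohen's d, so the planted and estimated
effect sizes are directly commensurable.  Genotypes belong to one of two
planted strategy classes: *stable* genotypes receive a small planted |d|
and *plastic* genotypes a large one, mimicking constitutive tolerance versus
adaptive plasticity.

Leaf carbon-isotope composition (delta13C, the intrinsic-WUE proxy) is not
drawn independently: per plant it is a linear combination of the
standardized values of a known informative trait subset plus noise, giving
downstream regression/VIP stages a recoverable ground truth.

Two auxiliary generators produce ATR-FTIR-like spectra (Gaussian peaks on a
linear baseline) and detached-leaf water-loss series (exponential decline
with multiplicative noise).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .derived import WaterLossSeries, water_loss_series
from .errors import ConfigError
from .registry import TraitRegistry, default_registry
from .spectra import Spectrum
from .table import TraitTable

STABLE = "stable"
PLASTIC = "plastic"

#: Default per-trait (baseline, residual sd) in trait units.  Baselines sit in
#: the range reported for well-watered temperate rice (gs ~420 mmol m-2 s-1,
#: SD ~440 mm-2, PhiPSII ~0.65, ...); residual sds give coefficients of
#: variation of roughly 5-25%.
DEFAULT_TRAIT_PARAMS: dict[str, tuple[float, float]] = {
    "gs": (420.0, 60.0),
    "SD": (440.0, 30.0),
    "CEW": (10.0, 1.5),
    "PhiPSII": (0.65, 0.05),
    "FvFm": (0.80, 0.03),
    "PhiNPQ": (0.15, 0.04),
    "NPQt": (1.5, 0.3),
    "RCh": (42.0, 4.0),
    "LT": (28.0, 1.0),
}

#: Planted delta13C coefficients on standardized informative traits (permil
#: per sd).  Signs follow each trait's expected LW response so that delta13C
#: becomes less negative under LW, as observed for C3 leaves with improved
#: intrinsic WUE; magnitudes give R^2 ~ 0.7 at the default noise sd.
DEFAULT_DELTA13C_COEFFICIENTS: dict[str, float] = {
    "gs": -0.8,
    "CEW": 0.6,
    "SD": -0.5,
    "PhiPSII": -0.4,
}

DEFAULT_DELTA13C_INTERCEPT = -29.5
DEFAULT_DELTA13C_NOISE_SD = 0.78


@dataclass(frozen=True)
class TraitEffect:
    """Planted Cohen's d (LW - PW, in residual-sd units) per strategy class."""

    d_stable: float
    d_plastic: float


def default_class_assignment(n_genotypes: int = 21) -> dict[str, str]:
    """Alternate plastic/stable across genotypes, starting with plastic.

    For the default 21 genotypes this yields 10 stable / 11 plastic, an
    approximately even split of the two strategy groups.
    """
    return {
        _genotype_name(i, n_genotypes): (PLASTIC if i % 2 == 0 else STABLE)
        for i in range(n_genotypes)
    }


def default_trait_effects(
    registry: TraitRegistry | None = None,
    d_stable: float = 0.2,
    d_plastic: float = 1.3,
) -> dict[str, TraitEffect]:
    """Planted effects for the 9 default leaf traits, signed along each
    trait's registered LW direction (stable |d|=0.2, plastic |d|=1.3)."""
    reg = registry if registry is not None else default_registry()
    effects = {}
    for trait in DEFAULT_TRAIT_PARAMS:
        sign = reg.direction_sign(trait)
        effects[trait] = TraitEffect(d_stable=sign * d_stable, d_plastic=sign * d_plastic)
    return effects


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment.

    ``trial_shift_sd`` and ``genotype_offset_sd`` are expressed in
    residual-sd units per trait, so their relative magnitude is uniform
    across traits with very different scales.
    """

    n_genotypes: int = 21
    n_indica: int = 2
    n_trials: int = 2
    n_replicates: int = 8
    class_assignment: dict[str, str] | None = None
    trait_effects: dict[str, TraitEffect] | None = None
    baseline: dict[str, float] | None = None
    residual_sd: dict[str, float] | None = None
    trial_shift_sd: float = 0.3
    genotype_offset_sd: float = 0.5
    delta13c_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DELTA13C_COEFFICIENTS)
    )
    delta13c_intercept: float = DEFAULT_DELTA13C_INTERCEPT
    delta13c_noise_sd: float = DEFAULT_DELTA13C_NOISE_SD
    seed: int = 0

    def resolved(self, registry: TraitRegistry) -> "SimulationConfig":
        """Fill None fields with defaults and validate against ``registry``."""
        cfg = replace(self)
        if cfg.trait_effects is None:
            cfg.trait_effects = default_trait_effects(registry)
        for trait in cfg.trait_effects:
            if trait not in registry:
                raise ConfigError(f"trait {trait!r} in trait_effects is not registered")
            if trait not in DEFAULT_TRAIT_PARAMS and (
                cfg.baseline is None or cfg.residual_sd is None
            ):
                raise ConfigError(
                    f"trait {trait!r} has no default baseline/residual_sd; "
                    "supply both explicitly"
                )
        if cfg.baseline is None:
            cfg.baseline = {t: DEFAULT_TRAIT_PARAMS[t][0] for t in cfg.trait_effects}
        if cfg.residual_sd is None:
            cfg.residual_sd = {t: DEFAULT_TRAIT_PARAMS[t][1] for t in cfg.trait_effects}
        if cfg.class_assignment is None:
            cfg.class_assignment = default_class_assignment(cfg.n_genotypes)
        _validate(cfg, registry)
        return cfg


def _validate(cfg: SimulationConfig, registry: TraitRegistry) -> None:
    if cfg.n_genotypes < 1 or cfg.n_trials < 1 or cfg.n_replicates < 1:
        raise ConfigError("n_genotypes, n_trials and n_replicates must be positive")
    if not 0 <= cfg.n_indica <= cfg.n_genotypes:
        raise ConfigError("n_indica must lie in [0, n_genotypes]")
    for trait in cfg.trait_effects:
        if trait not in registry:
            raise ConfigError(f"trait {trait!r} in trait_effects is not registered")
    for trait in cfg.delta13c_coefficients:
        if trait not in cfg.trait_effects:
            raise ConfigError(
                f"delta13C coefficient refers to unsimulated trait {trait!r}"
            )
    for source in ("baseline", "residual_sd"):
        mapping = getattr(cfg, source)
        missing = set(cfg.trait_effects) - set(mapping)
        if missing:
            raise ConfigError(f"{source} missing for trait(s): {sorted(missing)}")
    if any(sd <= 0 for sd in cfg.residual_sd.values()):
        raise ConfigError("residual sds must be strictly positive")
    if cfg.delta13c_noise_sd <= 0:
        raise ConfigError("delta13c_noise_sd must be strictly positive")
    if cfg.trial_shift_sd < 0 or cfg.genotype_offset_sd < 0:
        raise ConfigError("shift sds must be non-negative")
    genotypes = {_genotype_name(i, cfg.n_genotypes) for i in range(cfg.n_genotypes)}
    extra = set(cfg.class_assignment) - genotypes
    missing = genotypes - set(cfg.class_assignment)
    if extra or missing:
        raise ConfigError(
            f"class_assignment mismatch: extra={sorted(extra)}, missing={sorted(missing)}"
        )
    bad = {g: c for g, c in cfg.class_assignment.items() if c not in (STABLE, PLASTIC)}
    if bad:
        raise ConfigError(f"class labels must be 'stable' or 'plastic': {bad}")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery tests."""

    class_assignment: dict[str, str]
    informative_traits: list[str]
    delta13c_coefficients: dict[str, float]
    planted_d: dict[str, TraitEffect]

    def to_dict(self) -> dict:
        return {
            "class_assignment": dict(self.class_assignment),
            "informative_traits": list(self.informative_traits),
            "delta13c_coefficients": dict(self.delta13c_coefficients),
            "planted_d": {
                t: {"d_stable": e.d_stable, "d_plastic": e.d_plastic}
                for t, e in self.planted_d.items()
            },
        }


def _genotype_name(i: int, n_genotypes: int) -> str:
    width = max(2, len(str(n_genotypes)))
    return f"G{i + 1:0{width}d}"


def _stream(seed: int, *tokens: str) -> np.random.Generator:
    """Independent, reproducible RNG stream keyed by (seed, tokens).

    Per-trait streams mean that adding or removing a trait from a config
    leaves the draws of every other trait unchanged.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_dataset(
    config: SimulationConfig,
    registry: TraitRegistry | None = None,
) -> tuple[TraitTable, GroundTruth]:
    """Draw one synthetic experiment.

    Returns the long-format :class:`TraitTable` (including the coupled
    delta13C trait when coefficients are configured) and the
    :class:`GroundTruth` describing the planted structure.  Identical config
    and seed give identical output.
    """
    reg = registry if registry is not None else default_registry()
    cfg = config.resolved(reg)

    genotypes = [_genotype_name(i, cfg.n_genotypes) for i in range(cfg.n_genotypes)]
    subspecies = {
        g: ("indica" if i < cfg.n_indica else "japonica") for i, g in enumerate(genotypes)
    }
    trials = [f"T{t + 1}" for t in range(cfg.n_trials)]
    treatments = ["PW", "LW"]

    n_geno, n_trial, n_rep = cfg.n_genotypes, cfg.n_trials, cfg.n_replicates
    n_plants = n_geno * 2 * n_trial * n_rep

    # Fixed plant layout shared by all traits so delta13C can be coupled
    # plant-wise to the informative traits.
    geno_idx = np.repeat(np.arange(n_geno), 2 * n_trial * n_rep)
    trt_idx = np.tile(np.repeat(np.arange(2), n_trial * n_rep), n_geno)
    trial_idx = np.tile(np.repeat(np.arange(n_trial), n_rep), n_geno * 2)
    rep_idx = np.tile(np.arange(1, n_rep + 1), n_geno * 2 * n_trial)

    class_is_plastic = np.array(
        [cfg.class_assignment[g] == PLASTIC for g in genotypes], dtype=bool
    )

    trait_values: dict[str, np.ndarray] = {}
    for trait, effect in cfg.trait_effects.items():
        rng = _stream(cfg.seed, "trait", trait)
        sd = cfg.residual_sd[trait]
        geno_offsets = rng.normal(0.0, cfg.genotype_offset_sd * sd, size=n_geno)
        trial_shifts = rng.normal(0.0, cfg.trial_shift_sd * sd, size=n_trial)
        d_per_geno = np.where(class_is_plastic, effect.d_plastic, effect.d_stable)
        values = (
            cfg.baseline[trait]
            + geno_offsets[geno_idx]
            + trial_shifts[trial_idx]
            + (trt_idx == 1) * d_per_geno[geno_idx] * sd
            + rng.normal(0.0, sd, size=n_plants)
        )
        trait_values[trait] = values

    informative = [t for t, c in cfg.delta13c_coefficients.items() if c != 0.0]
    if informative:
        rng = _stream(cfg.seed, "trait", "delta13C")
        signal = np.full(n_plants, cfg.delta13c_intercept)
        for trait in informative:
            x = trait_values[trait]
            z = (x - x.mean()) / x.std(ddof=1)
            signal = signal + cfg.delta13c_coefficients[trait] * z
        trait_values["delta13C"] = signal + rng.normal(
            0.0, cfg.delta13c_noise_sd, size=n_plants
        )

    frames = []
    geno_arr = np.array(genotypes)[geno_idx]
    for trait, values in trait_values.items():
        frames.append(
            pd.DataFrame(
                {
                    "genotype": geno_arr,
                    "subspecies": [subspecies[g] for g in geno_arr],
                    "treatment": np.array(treatments)[trt_idx],
                    "trial": np.array(trials)[trial_idx],
                    "replicate": rep_idx,
                    "trait": trait,
                    "week": 0,
                    "value": values,
                }
            )
        )
    table = TraitTable(
        pd.concat(frames, ignore_index=True),
        provenance=f"ricewue.simulate seed={cfg.seed}",
    )
    truth = GroundTruth(
        class_assignment=dict(cfg.class_assignment),
        informative_traits=informative,
        delta13c_coefficients={t: cfg.delta13c_coefficients[t] for t in informative},
        planted_d=dict(cfg.trait_effects),
    )
    return table, truth


def generate_pls_benchmark(
    n_samples: int = 300_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, float]]:
    """Plant-level trait matrix for the delta13C proxy-recovery benchmark.

    Draws ``n_samples`` independent plants for the 9 default leaf traits on
    their natural scales and a delta13C response equal to the planted linear
    combination of the standardized informative traits plus noise (R^2 ~ 0.7
    at the default noise sd).  Returns (X, y, coefficients).

    The population VIP of the weakest informative trait (PhiPSII,
    coefficient 0.4 of 9 predictors) is sqrt(9 * 0.16 / 1.41) ~ 1.01 — only
    1% above the conventional VIP > 1 cutoff — so resolving the planted
    ordering against that cutoff needs a standard error on VIP below ~0.008,
    hence the large default sample size.
    """
    rng = _stream(seed, "pls_benchmark")
    columns = {}
    z_cols = {}
    for trait, (baseline, sd) in DEFAULT_TRAIT_PARAMS.items():
        z = rng.normal(size=n_samples)
        z_cols[trait] = z
        columns[trait] = baseline + sd * z
    y = np.full(n_samples, DEFAULT_DELTA13C_INTERCEPT)
    for trait, coef in DEFAULT_DELTA13C_COEFFICIENTS.items():
        y = y + coef * z_cols[trait]
    y = y + rng.normal(0.0, DEFAULT_DELTA13C_NOISE_SD, size=n_samples)
    return pd.DataFrame(columns), y, dict(DEFAULT_DELTA13C_COEFFICIENTS)


def generate_spectrum(
    peaks: list[dict],
    wn_range: tuple[float, float] = (400.0, 4000.0),
    step: float = 2.0,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Gaussian peaks on a linear baseline over an ascending wavenumber grid.

    Each peak is ``{"center": cm-1, "height": absorbance, "width": sd cm-1}``;
    ``baseline`` is (intercept, slope per cm-1).  Additive Gaussian noise with
    sd ``noise_sd`` is applied when positive.
    """
    lo, hi = wn_range
    if not hi > lo:
        raise ConfigError("wavenumber range must be non-empty (hi > lo)")
    if step <= 0:
        raise ConfigError("step must be positive")
    wn = np.arange(lo, hi + step / 2, step)
    absorbance = baseline[0] + baseline[1] * wn
    for peak in peaks:
        center, height, width = peak["center"], peak["height"], peak["width"]
        if not lo <= center <= hi:
            raise ConfigError(f"peak center {center} outside range {wn_range}")
        if width <= 0:
            raise ConfigError("peak width must be positive")
        absorbance = absorbance + height * np.exp(-0.5 * ((wn - center) / width) ** 2)
    if noise_sd > 0:
        rng = _stream(seed, "spectrum")
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=wn.size)
    return Spectrum(wavenumbers=wn, absorbance=absorbance)


def generate_water_loss_series(
    initial_weight: float,
    retention_rate: float,
    times: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> WaterLossSeries:
    """Detached-leaf weights declining exponentially with time.

    ``retention_rate`` is the fraction of weight retained per hour, so
    ``weight(t) = w0 * rate**(t/60)`` for t in minutes, with optional
    multiplicative log-normal noise at t > 0 (t = 0 is the exact initial
    weight by construction).
    """
    if initial_weight <= 0:
        raise ConfigError("initial_weight must be positive")
    if not 0 < retention_rate <= 1:
        raise ConfigError("retention_rate must lie in (0, 1]")
    t = np.asarray(times, dtype=float)
    if t.size == 0 or t[0] != 0:
        raise ConfigError("times must start at 0")
    if np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ConfigError("times must be non-negative and strictly ascending")
    weights = initial_weight * retention_rate ** (t / 60.0)
    if noise_sd > 0:
        rng = _stream(seed, "water_loss")
        factors = np.exp(rng.normal(0.0, noise_sd, size=t.size))
        factors[0] = 1.0
        weights = weights * factors
    return water_loss_series(t.tolist(), weights.tolist())
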