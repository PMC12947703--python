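"""Composite Multi-Trait Index (CMTI) and genotype strategy classification.

The CMTI summarizes how strongly each genotype adjusts a panel of selected
traits under limited water.  The pipeline is:

1. *Prioritise* traits — by Cohen's d magnitude (|d| >= threshold), by
   PLS-VIP (VIP > threshold), or an explicit list.
2. *Normalize* directionally to a 0-1 scale across genotypes.  In the
   default ``plasticity`` mode the raw score per genotype and trait is the
   signed relative treatment change (LW - PW)/|PW| multiplied by +1 when the
   change follows the trait's expected LW direction and -1 when it opposes
   it, then min-max scaled across genotypes.  The ``treatment_level`` mode
   instead min-max scales per-treatment genotype means per trait (reflecting
   traits expected to decrease), yielding one row per genotype x treatment.
3. *CMTI* = unweighted mean of the normalized values per row; rank 1 is the
   highest index (strongest adaptive adjustment).
4. *Classify* into two strategy groups by the exact 1-D two-class split that
   minimizes total within-class sum of squares: the lower-CMTI class is
   labelled *stable* (constitutive tolerance), the higher *plastic*
   (adaptive adjustment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError
from .pls import VIPResult, fit_pls1, vip_scores
from .registry import TraitRegistry, default_registry
from .stats import EffectSizeResult, effect_sizes_by_trait
from .table import TraitTable

STABLE = "stable"
PLASTIC = "plastic"


@dataclass
class CMTIConfig:
    prioritisation: str = "cohens_d"  # cohens_d | pls_vip | explicit
    d_threshold: float = 0.8
    vip_threshold: float = 1.0
    traits: list[str] | None = None  # explicit mode
    normalization_mode: str = "plasticity"  # plasticity | treatment_level
    effect_level: str = "genotype_mean"
    pls_components: int = 2
    registry: TraitRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        if self.prioritisation not in ("cohens_d", "pls_vip", "explicit"):
            raise ConfigError(f"unknown prioritisation mode {self.prioritisation!r}")
        if self.normalization_mode not in ("plasticity", "treatment_level"):
            raise ConfigError(f"unknown normalization mode {self.normalization_mode!r}")
        if self.d_threshold <= 0 or self.vip_threshold <= 0:
            raise ConfigError("thresholds must be positive")


@dataclass
class CMTIResult:
    """Per-row composite index, rank (1 = highest) and strategy class."""

    table: pd.DataFrame  # columns: cmti, rank, strategy_class
    traits_used: list[str]
    normalized_matrix: pd.DataFrame


def _drop_neutral(traits: list[str], registry: TraitRegistry) -> list[str]:
    kept = []
    for t in traits:
        if t in registry and registry.direction_sign(t) == 0:
            warnings.warn(
                f"trait {t!r} has neutral LW direction; excluded from CMTI",
                stacklevel=3,
            )
            continue
        kept.append(t)
    return kept


def prioritise_traits(
    effects: list[EffectSizeResult] | None = None,
    vip: VIPResult | None = None,
    config: CMTIConfig | None = None,
) -> list[str]:
    """Select the trait panel according to the configured prioritisation mode.

    Neutral-direction traits are excluded with a warning; an empty selection
    raises, with a hint to relax the threshold.
    """
    cfg = config if config is not None else CMTIConfig()
    if cfg.prioritisation == "cohens_d":
        if not effects:
            raise ConfigError("cohens_d prioritisation requires effect-size results")
        chosen = [e.trait for e in effects if abs(e.d) >= cfg.d_threshold]
    elif cfg.prioritisation == "pls_vip":
        if vip is None:
            raise ConfigError("pls_vip prioritisation requires a VIP result")
        chosen = list(vip.selected)
    else:
        if not cfg.traits:
            raise ConfigError("explicit prioritisation requires a trait list")
        chosen = list(cfg.traits)
    chosen = _drop_neutral(chosen, cfg.registry)
    if not chosen:
        raise ConfigError(
            "no traits selected for the CMTI; relax d_threshold/vip_threshold "
            "or pass an explicit trait list"
        )
    return chosen


def _minmax(column: pd.Series) -> pd.Series | None:
    lo, hi = column.min(), column.max()
    if hi == lo:
        return None
    return (column - lo) / (hi - lo)


def normalize_traits(
    table: TraitTable,
    traits: list[str],
    registry: TraitRegistry | None = None,
    mode: str = "plasticity",
) -> pd.DataFrame:
    """Directional 0-1 normalization of the selected traits.

    Returns a matrix with values in [0, 1]; rows are genotypes in
    ``plasticity`` mode and (genotype, treatment) pairs in
    ``treatment_level`` mode.  Traits constant across rows are dropped with
    a warning.
    """
    reg = registry if registry is not None else default_registry()
    traits = _drop_neutral(list(traits), reg)
    if not traits:
        raise ConfigError("no non-neutral traits to normalize")
    missing = [t for t in traits if t not in table.traits]
    if missing:
        raise ConfigError(f"trait(s) absent from table: {', '.join(missing)}")
    wide = table.mean_matrix(traits=traits, index=("genotype", "treatment"))
    if wide[traits].isna().any().any():
        raise ConfigError("every genotype needs means under both PW and LW")

    if mode == "plasticity":
        lw = wide.xs("LW", level="treatment")
        pw = wide.xs("PW", level="treatment")
        if len(lw) < 2:
            raise ConfigError("at least 2 genotypes are required")
        if not lw.index.equals(pw.index):
            raise ConfigError("every genotype needs means under both PW and LW")
        columns = {}
        for trait in traits:
            if (pw[trait] == 0).any():
                geno = pw.index[pw[trait] == 0][0]
                raise DegenerateDataError(
                    f"PW mean of trait {trait!r} is zero for genotype {geno!r}; "
                    "relative change undefined"
                )
            sign = reg.direction_sign(trait)
            raw = sign * (lw[trait] - pw[trait]) / pw[trait].abs()
            scaled = _minmax(raw)
            if scaled is None:
                warnings.warn(
                    f"trait {trait!r} constant across genotypes; dropped", stacklevel=2
                )
                continue
            columns[trait] = scaled
        if not columns:
            raise DegenerateDataError("all selected traits were constant")
        return pd.DataFrame(columns)

    if mode == "treatment_level":
        if wide.index.get_level_values("genotype").nunique() < 2:
            raise ConfigError("at least 2 genotypes are required")
        columns = {}
        for trait in traits:
            scaled = _minmax(wide[trait])
            if scaled is None:
                warnings.warn(
                    f"trait {trait!r} constant across rows; dropped", stacklevel=2
                )
                continue
            if reg.direction_sign(trait) < 0:
                scaled = 1.0 - scaled
            columns[trait] = scaled
        if not columns:
            raise DegenerateDataError("all selected traits were constant")
        return pd.DataFrame(columns)

    raise ConfigError(f"unknown normalization mode {mode!r}")


def compute_cmti(normalized: pd.DataFrame) -> CMTIResult:
    """CMTI per row: the unweighted mean of the normalized trait values.

    Rank 1 is the highest CMTI (strongest adaptive adjustment); ties keep
    row order, so ranking is deterministic.  Classes are not assigned here —
    see :func:`classify_genotypes`.
    """
    if normalized.shape[1] == 0:
        raise ConfigError("empty trait set")
    values = normalized.to_numpy(dtype=float)
    if np.any((values < -1e-9) | (values > 1 + 1e-9)):
        raise ConfigError("normalized matrix must lie in [0, 1]")
    cmti = normalized.mean(axis=1)
    order = cmti.sort_values(ascending=False, kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    out = pd.DataFrame(
        {
            "cmti": cmti,
            "rank": ranks.reindex(cmti.index).astype(int),
            "strategy_class": pd.Series(pd.NA, index=cmti.index, dtype="object"),
        }
    )
    return CMTIResult(
        table=out,
        traits_used=[str(c) for c in normalized.columns],
        normalized_matrix=normalized,
    )


def classify_genotypes(cmti_values: Mapping) -> dict:
    """Exact two-class 1-D clustering of CMTI values.

    All G-1 split points of the sorted values are scanned and the split
    minimizing total within-class sum of squares is chosen (ties go to the
    more balanced split, then to the smaller lower class).  The lower-CMTI
    class is labelled ``stable``, the higher ``plastic``.  If every value is
    identical a single-class (all stable) result is returned with a warning.
    """
    items = sorted(cmti_values.items(), key=lambda kv: (kv[1], str(kv[0])))
    if len(items) < 2:
        raise ConfigError("at least 2 genotypes are required for classification")
    names = [k for k, _ in items]
    x = np.array([v for _, v in items], dtype=float)
    if np.all(x == x[0]):
        warnings.warn("all CMTI values identical; single-class result", stacklevel=2)
        return {name: STABLE for name in names}

    g = len(x)
    best = None  # (ss, imbalance, k)
    for k in range(1, g):
        lo, hi = x[:k], x[k:]
        ss = float(((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum())
        key = (ss, abs(g - 2 * k), k)
        if best is None or _split_better(key, best):
            best = key
    k = best[2]
    labels = {}
    for i, name in enumerate(names):
        labels[name] = STABLE if i < k else PLASTIC
    return labels


def _split_better(candidate: tuple, incumbent: tuple, tol: float = 1e-12) -> bool:
    ss_c, bal_c, k_c = candidate
    ss_i, bal_i, k_i = incumbent
    if ss_c < ss_i - tol:
        return True
    if ss_c > ss_i + tol:
        return False
    return (bal_c, k_c) < (bal_i, k_i)


def vip_from_table(
    table: TraitTable,
    response: str = "delta13C",
    config: CMTIConfig | None = None,
) -> VIPResult:
    """Fit PLS1 on genotype x treatment trait means and score VIP.

    Predictors are every trait in the table except the response.
    """
    cfg = config if config is not None else CMTIConfig()
    if response not in table.traits:
        raise ConfigError(f"response trait {response!r} absent from table")
    predictors = [t for t in table.traits if t != response]
    wide = table.mean_matrix(traits=predictors + [response], index=("genotype", "treatment"))
    if wide.isna().any().any():
        raise ConfigError("incomplete genotype x treatment means for PLS")
    model = fit_pls1(wide[predictors], wide[response], n_components=cfg.pls_components)
    return vip_scores(model, threshold=cfg.vip_threshold)


def run_cmti(
    table: TraitTable,
    config: CMTIConfig | None = None,
    effects: list[EffectSizeResult] | None = None,
    vip: VIPResult | None = None,
) -> CMTIResult:
    """End-to-end CMTI: prioritise -> normalize -> index -> classify.

    Effect sizes / VIP scores are computed from the table when not supplied.
    In ``treatment_level`` mode rows are genotype x treatment pairs and the
    classification applies to those rows.
    """
    cfg = config if config is not None else CMTIConfig()
    if cfg.prioritisation == "cohens_d" and effects is None:
        effects = effect_sizes_by_trait(table, level=cfg.effect_level)
    if cfg.prioritisation == "pls_vip" and vip is None:
        vip = vip_from_table(table, config=cfg)
    traits = prioritise_traits(effects=effects, vip=vip, config=cfg)
    normalized = normalize_traits(
        table, traits, registry=cfg.registry, mode=cfg.normalization_mode
    )
    result = compute_cmti(normalized)
    labels = classify_genotypes(result.table["cmti"].to_dict())
    result.table["strategy_class"] = result.table.index.map(labels)
    return result
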