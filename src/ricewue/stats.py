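"""Treatment-contrast statistics.

Cohen's d effect-size screening of the PW-vs-LW contrast (with small-sample
Hedges correction), the Welch unequal-variance two-sample t test, the
balanced two-way ANOVA decomposition, trait Pearson correlation matrices
with strong-pair flagging, and PCA of the trait correlation matrix with
eigenvalue/variance accounting.

Sign convention: the contrast is always LW minus PW, so a positive effect
size means the trait is higher under limited water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DegenerateDataError, UnbalancedDesignError
from .table import TraitTable


# --------------------------------------------------------------------------
# effect sizes

@dataclass(frozen=True)
class EffectSizeResult:
    """Per-trait standardized mean difference (LW - PW) with group summaries."""

    trait: str
    mean_pw: float
    mean_lw: float
    sd_pw: float
    sd_lw: float
    n_pw: int
    n_lw: int
    pooled_sd: float
    d: float
    hedges_g: float


def cohens_d(group: np.ndarray, reference: np.ndarray, trait: str = "") -> EffectSizeResult:
    """Cohen's d of ``group`` minus ``reference`` on the pooled sd scale.

    d = (mean(group) - mean(reference)) / s_p with
    s_p = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)); the Hedges correction
    multiplies d by 1 - 3/(4N - 9) to remove small-sample bias.  The per-trait
    driver passes (LW, PW) so the sign follows the LW - PW convention.
    """
    a = np.asarray(group, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each group needs at least 2 values")
    n1, n2 = a.size, b.size
    s1, s2 = a.std(ddof=1), b.std(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise DegenerateDataError(
            f"pooled standard deviation is zero{f' for trait {trait!r}' if trait else ''}"
        )
    d = (a.mean() - b.mean()) / pooled
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return EffectSizeResult(
        trait=trait,
        mean_pw=float(b.mean()),
        mean_lw=float(a.mean()),
        sd_pw=float(s2),
        sd_lw=float(s1),
        n_pw=n2,
        n_lw=n1,
        pooled_sd=float(pooled),
        d=float(d),
        hedges_g=float(d * correction),
    )


def effect_sizes_by_trait(
    table: TraitTable,
    level: str = "genotype_mean",
) -> list[EffectSizeResult]:
    """One LW-vs-PW effect size per trait.

    ``level="genotype_mean"`` (default) compares per-genotype means — one
    value per genotype per treatment — avoiding pseudo-replication of plants
    within genotype; ``level="replicate"`` pools all individual observations.
    Traits observed in only one treatment are skipped with a warning.
    """
    if level not in ("genotype_mean", "replicate"):
        raise ConfigError(f"unknown level {level!r}")
    results = []
    for trait in table.traits:
        sub = table.df[table.df["trait"] == trait]
        if level == "genotype_mean":
            sub = (
                sub.groupby(["genotype", "treatment"], as_index=False)["value"].mean()
            )
        lw = sub.loc[sub["treatment"] == "LW", "value"].to_numpy()
        pw = sub.loc[sub["treatment"] == "PW", "value"].to_numpy()
        if lw.size < 2 or pw.size < 2:
            warnings.warn(
                f"trait {trait!r}: both treatments required; skipped", stacklevel=2
            )
            continue
        results.append(cohens_d(lw, pw, trait=trait))
    return results


def effect_sizes_frame(results: list[EffectSizeResult]) -> pd.DataFrame:
    """Tabulate :class:`EffectSizeResult` objects (one row per trait)."""
    return pd.DataFrame([vars(r) for r in results])


# --------------------------------------------------------------------------
# Welch t

@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> TestResult:
    """Two-sided Welch (unequal-variance) two-sample t test.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b); df by Welch-Satterthwaite,
    which reduces to 2(n-1) for equal n and equal sample variances.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateDataError("both groups have zero variance")
    sea2 = va / a.size
    seb2 = vb / b.size
    se = np.sqrt(sea2 + seb2)
    t = (a.mean() - b.mean()) / se
    df = (sea2 + seb2) ** 2 / (
        sea2**2 / (a.size - 1) + seb2**2 / (b.size - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(min(p, 1.0)))


# --------------------------------------------------------------------------
# balanced two-way ANOVA

def anova_two_way_balanced(
    table: TraitTable,
    trait: str,
    factor_a: str = "treatment",
    factor_b: str = "subspecies",
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA for a balanced design.

    Sums of squares follow the standard balanced decomposition
    SS_A + SS_B + SS_AxB + SS_error = SS_total; F ratios are taken against
    the error mean square.  Unbalanced designs raise
    :class:`UnbalancedDesignError` — hierarchical/unbalanced data call for a
    mixed model, which is outside this module's remit.

    Returns a DataFrame indexed by source with columns ss, df, ms, F, p.
    """
    df = table.df[table.df["trait"] == trait]
    if df.empty:
        raise ConfigError(f"trait {trait!r} absent from table")
    counts = df.groupby([factor_a, factor_b]).size()
    levels_a = df[factor_a].nunique()
    levels_b = df[factor_b].nunique()
    if levels_a < 2 or levels_b < 2:
        raise UnbalancedDesignError(
            f"both factors need >= 2 levels (got {levels_a} x {levels_b})"
        )
    if len(counts) != levels_a * levels_b or counts.nunique() != 1:
        raise UnbalancedDesignError(
            f"two-way ANOVA requires a complete balanced {factor_a} x {factor_b} "
            "design with equal cell counts"
        )
    r = int(counts.iloc[0])
    if r < 2:
        raise UnbalancedDesignError("at least 2 observations per cell are required")

    y = df["value"].to_numpy()
    grand = y.mean()
    a_means = df.groupby(factor_a)["value"].mean()
    b_means = df.groupby(factor_b)["value"].mean()
    cell_means = df.groupby([factor_a, factor_b])["value"].mean()

    ss_a = levels_b * r * float(((a_means - grand) ** 2).sum())
    ss_b = levels_a * r * float(((b_means - grand) ** 2).sum())
    interaction = cell_means.copy()
    for (la, lb), m in cell_means.items():
        interaction.loc[(la, lb)] = m - a_means[la] - b_means[lb] + grand
    ss_ab = r * float((interaction**2).sum())
    fitted = df.set_index([factor_a, factor_b]).index.map(cell_means)
    ss_err = float(((y - np.asarray(fitted)) ** 2).sum())

    df_a = levels_a - 1
    df_b = levels_b - 1
    df_ab = df_a * df_b
    df_err = levels_a * levels_b * (r - 1)

    rows = {}
    ms_err = ss_err / df_err
    for name, ss, dof in (
        (factor_a, ss_a, df_a),
        (factor_b, ss_b, df_b),
        (f"{factor_a}:{factor_b}", ss_ab, df_ab),
    ):
        ms = ss / dof
        if ms_err > 0:
            fval = ms / ms_err
            p = float(sps.f.sf(fval, dof, df_err))
        else:
            fval, p = np.inf if ss > 0 else np.nan, 0.0 if ss > 0 else np.nan
        rows[name] = {"ss": ss, "df": dof, "ms": ms, "F": fval, "p": p}
    rows["residual"] = {
        "ss": ss_err, "df": df_err, "ms": ms_err, "F": np.nan, "p": np.nan
    }
    return pd.DataFrame(rows).T[["ss", "df", "ms", "F", "p"]]


# --------------------------------------------------------------------------
# correlations

@dataclass
class CorrelationMatrix:
    traits: list[str]
    r: pd.DataFrame
    strong_pairs: list[tuple[str, str, float]]
    threshold: float


def correlation_matrix(
    table: TraitTable,
    traits: list[str] | None = None,
    threshold: float = 0.5,
    by: str = "treatment",
) -> CorrelationMatrix:
    """Pearson correlations on a genotype-mean trait matrix.

    ``by="treatment"`` treats each genotype x treatment mean as a sample (the
    treatment contrast contributes to the correlations); ``by="pooled"``
    averages over treatments first so only between-genotype variation
    remains.  Pairs with |r| >= ``threshold`` are flagged as strong.
    Constant traits get an undefined (NaN) row/column and are excluded from
    flagging.
    """
    if by not in ("treatment", "pooled"):
        raise ConfigError(f"unknown grouping {by!r}")
    index = ("genotype", "treatment") if by == "treatment" else ("genotype",)
    wide = table.mean_matrix(traits=traits, index=index)
    if wide.shape[0] < 3:
        raise DegenerateDataError("at least 3 samples are required for correlations")
    constant = wide.columns[wide.std(ddof=1) == 0].tolist()
    r = wide.corr(method="pearson")
    for trait in constant:
        r.loc[trait, :] = np.nan
        r.loc[:, trait] = np.nan
    np.fill_diagonal(r.values, 1.0)
    names = list(r.columns)
    strong = []
    for i, ti in enumerate(names):
        for tj in names[i + 1:]:
            if ti in constant or tj in constant:
                continue
            val = float(r.loc[ti, tj])
            if abs(val) >= threshold:
                strong.append((ti, tj, val))
    return CorrelationMatrix(traits=names, r=r, strong_pairs=strong, threshold=threshold)


# --------------------------------------------------------------------------
# PCA on the correlation matrix

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    proportions: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame


def explained_proportions(eigenvalues, n_traits: int | None = None) -> np.ndarray:
    """Variance proportions (%) for correlation-matrix PCA eigenvalues.

    For PCA of a correlation matrix the total variance equals the number of
    traits p, so each component explains eigenvalue / p of the total.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = n_traits if n_traits is not None else lam.size
    if p <= 0:
        raise ConfigError("number of traits must be positive")
    return 100.0 * lam / p


def pca_correlation(matrix: pd.DataFrame | np.ndarray) -> PCAResult:
    """PCA via eigendecomposition of the trait correlation matrix.

    ``matrix`` is samples x traits (a DataFrame keeps trait/sample labels).
    Columns are standardized (z-scores, ddof=1); eigenvalues are returned in
    non-increasing order and sum to the trait count; each loading column is
    oriented so its largest-magnitude entry is positive; scores are the
    projections of the standardized samples.
    """
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        trait_names = list(matrix.columns)
        sample_index = matrix.index
    else:
        X = np.asarray(matrix, dtype=float)
        trait_names = [f"x{j + 1}" for j in range(X.shape[1])]
        sample_index = pd.RangeIndex(X.shape[0])
    n, p = X.shape
    if p < 2 or n < 3:
        raise DegenerateDataError("PCA needs >= 2 traits and >= 3 samples")
    sds = X.std(axis=0, ddof=1)
    constant = [trait_names[j] for j in np.flatnonzero(sds == 0)]
    if constant:
        raise DegenerateDataError(f"constant trait(s): {', '.join(constant)}")
    Z = (X - X.mean(axis=0)) / sds
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for k in range(p):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    comps = [f"PC{k + 1}" for k in range(p)]
    loadings = pd.DataFrame(eigvecs, index=trait_names, columns=comps)
    scores = pd.DataFrame(Z @ eigvecs, index=sample_index, columns=comps)
    return PCAResult(
        eigenvalues=eigvals,
        proportions=explained_proportions(eigvals, p),
        loadings=loadings,
        scores=scores,
    )


def pca_from_table(table: TraitTable, traits: list[str] | None = None) -> PCAResult:
    """PCA of the genotype x treatment mean trait matrix of a table."""
    wide = table.mean_matrix(traits=traits, index=("genotype", "treatment"))
    return pca_correlation(wide)
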