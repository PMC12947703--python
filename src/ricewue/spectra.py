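"""ATR-FTIR band semi-quantification.

Leaf cuticular/epicuticular wax (CEW) is semi-quantified as the integrated
absorbance over 2800-3000 cm-1 (symmetric/asymmetric C-H stretching of
methyl and methylene groups of cutin, waxes and cutan).  Flavonols are
semi-quantified as the summed integral over five fingerprint bands
(1125-1140, 1205-1225, 1270-1310, 1435-1475 and 1605-1620 cm-1; aromatic
ring, C=C and O-H vibrations).

Integration is trapezoidal over a local linear ("rubber-band endpoint")
baseline: the straight line through the band's two endpoint absorbances is
subtracted and the positive residual integrated.  Negative residuals are
clipped at zero, since the indices are semi-quantitative abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError, SchemaError

WAVENUMBER_RANGE = (400.0, 4000.0)


@dataclass
class Spectrum:
    """One spectrum: ascending wavenumbers (cm-1) with absorbance per point."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape or self.wavenumbers.ndim != 1:
            raise ConfigError("wavenumbers and absorbance must be equal-length 1-D arrays")
        if self.wavenumbers.size < 2:
            raise ConfigError("a spectrum needs at least 2 points")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise IntegrityError("wavenumbers must be strictly ascending")


@dataclass(frozen=True)
class BandDefinition:
    """A named wavenumber interval [lo, hi] within the mid-IR range."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError(f"band {self.name!r}: lo must be < hi")
        if not (WAVENUMBER_RANGE[0] <= self.lo and self.hi <= WAVENUMBER_RANGE[1]):
            raise ConfigError(
                f"band {self.name!r} must lie within {WAVENUMBER_RANGE} cm-1"
            )


CEW_BAND = BandDefinition("CEW", 2800.0, 3000.0)

FLAVONOL_BANDS = (
    BandDefinition("flavonol_CH_bend", 1125.0, 1140.0),
    BandDefinition("flavonol_CC_stretch", 1205.0, 1225.0),
    BandDefinition("flavonol_CC_OH", 1270.0, 1310.0),
    BandDefinition("flavonol_ring_OH", 1435.0, 1475.0),
    BandDefinition("flavonol_CO_C2C3", 1605.0, 1620.0),
)


def read_spectrum(path: str, dialect: str = "comma") -> Spectrum:
    """Read a two-column (wavenumber, absorbance) delimited text file.

    A header row is accepted and skipped if non-numeric; comment lines
    starting with ``#`` are ignored.
    """
    sep = {"comma": ",", ",": ",", "tab": "\t", "\t": "\t"}.get(dialect)
    if sep is None:
        raise SchemaError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'")
    raw = pd.read_csv(path, sep=sep, comment="#", header=None, dtype=str)
    if raw.shape[1] < 2:
        raise SchemaError(f"{path}: expected two columns (wavenumber, absorbance)")
    first_numeric = pd.to_numeric(raw.iloc[0], errors="coerce").notna().all()
    data = raw if first_numeric else raw.iloc[1:]
    values = data.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise SchemaError(f"{path}: non-numeric spectral values")
    return Spectrum(values.iloc[:, 0].to_numpy(), values.iloc[:, 1].to_numpy())


def band_index(
    spectrum: Spectrum,
    band: BandDefinition,
    baseline: str = "local_linear",
) -> float:
    """Integrated absorbance (absorbance * cm-1) over one band.

    ``baseline="local_linear"`` subtracts the straight line through the
    band's endpoint absorbances before integrating the positive residual;
    ``baseline="none"`` integrates the raw absorbance (clipped at zero).
    """
    if baseline not in ("local_linear", "none"):
        raise ConfigError(f"unknown baseline mode {baseline!r}")
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    if band.lo < wn[0] or band.hi > wn[-1]:
        raise ConfigError(
            f"band {band.name!r} [{band.lo}, {band.hi}] outside spectrum range "
            f"[{wn[0]}, {wn[-1]}]"
        )
    mask = (wn >= band.lo) & (wn <= band.hi)
    if mask.sum() < 3:
        raise ConfigError(
            f"band {band.name!r}: fewer than 3 points inside the band "
            "(spectral resolution too coarse)"
        )
    x = wn[mask]
    y = ab[mask]
    if baseline == "local_linear":
        slope = (y[-1] - y[0]) / (x[-1] - x[0])
        y = y - (y[0] + slope * (x - x[0]))
    y = np.clip(y, 0.0, None)
    return float(np.trapezoid(y, x))


def cew_index(spectrum: Spectrum, baseline: str = "local_linear") -> float:
    """CEW semi-quantification: integral over the 2800-3000 cm-1 C-H band."""
    return band_index(spectrum, CEW_BAND, baseline=baseline)


def flavonol_index(spectrum: Spectrum, baseline: str = "local_linear") -> float:
    """Flavonol semi-quantification: summed integral over the five
    fingerprint bands."""
    return sum(band_index(spectrum, band, baseline=baseline) for band in FLAVONOL_BANDS)


def timecourse_contrast(
    table,
    trait: str = "CEW",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-week PW-vs-LW Welch contrasts of a time-resolved trait.

    ``table`` is a :class:`~ricewue.table.TraitTable` containing the trait at
    several weeks.  Returns one row per week with group means, Welch t, df,
    two-sided p and a significance flag at ``alpha``.  Weeks with a single
    treatment are skipped with a warning.
    """
    from .stats import welch_t  # local import: avoid module cycle

    df = table.df[table.df["trait"] == trait]
    if df.empty:
        raise ConfigError(f"trait {trait!r} absent from table")
    rows = []
    for week, group in df.groupby("week"):
        pw = group.loc[group["treatment"] == "PW", "value"].to_numpy()
        lw = group.loc[group["treatment"] == "LW", "value"].to_numpy()
        if len(pw) < 2 or len(lw) < 2:
            warnings.warn(
                f"week {week}: both treatments needed for trait {trait!r}; skipped",
                stacklevel=2,
            )
            continue
        result = welch_t(lw, pw)
        rows.append(
            {
                "week": week,
                "mean_pw": pw.mean(),
                "mean_lw": lw.mean(),
                "t": result.statistic,
                "df": result.df,
                "p": result.p,
                "significant": result.p < alpha,
            }
        )
    return pd.DataFrame(rows)
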