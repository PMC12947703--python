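"""Long-format phenotype table container and delimited-text I/O.

The canonical interchange format is a delimited text file (CSV by default,
TSV via ``dialect="tab"``) with one observation per row and columns

    genotype, subspecies, treatment, trial, replicate, trait, week, value

``treatment`` is PW (ponded water) or LW (limited water); ``week`` indexes
time-resolved traits (FTIR band indices are measured repeatedly through the
season) and is 0 for single-time-point traits.  The combination
(genotype, treatment, trial, replicate, trait, week) must be unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError

KEY_COLUMNS = ["genotype", "treatment", "trial", "replicate", "trait", "week"]
COLUMNS = ["genotype", "subspecies", "treatment", "trial", "replicate", "trait", "week", "value"]

TREATMENTS = ("PW", "LW")
SUBSPECIES = ("japonica", "indica")

_DIALECTS = {"comma": ",", ",": ",", "tab": "\t", "\t": "\t"}


def _canonical_treatment(value: str) -> str:
    token = str(value).strip().upper()
    if token not in TREATMENTS:
        raise ParseError(f"unknown treatment {value!r}; expected one of {TREATMENTS}")
    return token


def _canonical_subspecies(value: str) -> str:
    token = str(value).strip().lower()
    if token not in SUBSPECIES:
        raise ParseError(f"unknown subspecies {value!r}; expected one of {SUBSPECIES}")
    return token


@dataclass
class TraitTable:
    """Validated long-format trait observations.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; validation
    runs on construction (finite values, canonical treatment/subspecies
    tokens, unique observation keys, non-empty).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = df[COLUMNS].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["trial"] = df["trial"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["treatment"] = df["treatment"].map(_canonical_treatment)
        df["subspecies"] = df["subspecies"].map(_canonical_subspecies)
        df["replicate"] = _to_int(df["replicate"], "replicate", minimum=1)
        df["week"] = _to_int(df["week"], "week", minimum=0)
        df["value"] = _to_float(df["value"])
        if len(df) == 0:
            raise IntegrityError("trait table must contain at least one observation")
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            first = df.loc[dup, KEY_COLUMNS].iloc[0].to_dict()
            raise IntegrityError(f"duplicate observation key: {first}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.df["genotype"].unique())

    def subset(self, **filters) -> "TraitTable":
        """Return a new table filtered by column equality, e.g.
        ``table.subset(trait="gs", treatment="LW")``."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in filters.items():
            if col not in self.df.columns:
                raise KeyError(f"unknown column {col!r}")
            values = val if isinstance(val, (list, tuple, set)) else [val]
            mask &= self.df[col].isin(list(values))
        return TraitTable(self.df[mask], provenance=self.provenance)

    def mean_matrix(
        self,
        traits: list[str] | None = None,
        index: tuple[str, ...] = ("genotype", "treatment"),
    ) -> pd.DataFrame:
        """Pivot to a wide matrix of mean trait values.

        Rows are the requested grouping (default genotype x treatment), one
        column per trait, cell = mean over all remaining replication levels.
        """
        df = self.df
        if traits is not None:
            df = df[df["trait"].isin(traits)]
        wide = df.pivot_table(index=list(index), columns="trait", values="value", aggfunc="mean")
        if traits is not None:
            wide = wide[[t for t in traits if t in wide.columns]]
        wide.columns.name = None
        return wide


def _to_float(series: pd.Series) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce").astype(float)
    bad = converted.isna() | ~np.isfinite(converted)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"non-numeric or non-finite value {series.iloc[row]!r} in row {row + 1}")
    return converted


def _to_int(series: pd.Series, name: str, minimum: int) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna() | (converted != converted.round()) | (converted < minimum)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"column {name!r}: invalid value {series.iloc[row]!r} in row {row + 1} "
            f"(integer >= {minimum} required)"
        )
    return converted.astype(int)


def read_trait_table(path: str, dialect: str = "comma") -> TraitTable:
    """Read a long-format trait table from delimited text.

    Treatment and subspecies tokens are case-insensitive on input and
    canonicalized (PW/LW, lowercase subspecies).  Comment lines starting
    with ``#`` are ignored.
    """
    sep = _DIALECTS.get(dialect)
    if sep is None:
        raise SchemaError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'")
    try:
        raw = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise IntegrityError(f"{path}: file contains no data") from None
    return TraitTable(raw, provenance=str(path))


def write_trait_table(table: TraitTable, path: str, dialect: str = "comma") -> None:
    """Write a table so that :func:`read_trait_table` reproduces it exactly.

    Values are serialized with ``repr`` round-trip precision.
    """
    sep = _DIALECTS.get(dialect)
    if sep is None:
        raise SchemaError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'")
    table.df.to_csv(path, sep=sep, index=False, float_format=None)
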