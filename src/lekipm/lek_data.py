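"""Lek-count survey series: reading, validation, imputation, effort adjustment.

The annual index for lekking grouse is the "high male count" M_t: the maximum
number of males seen on surveyed lek areas in year t.  Survey effort varies, so
counts are weighted by the proportion of lek areas surveyed, w_t = l_t / L.
Raw annual growth rates are ratios of effort-adjusted counts,
lambda_t = (M_t / w_t) / (M_{t-1} / w_{t-1}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SCHEMA = {"year": "year", "males": "males", "lek_areas": "lek_areas"}

__all__ = [
    "LekCountSeries",
    "EffortConfig",
    "RawGrowthSeries",
    "read_lek_counts",
    "impute_missing",
    "effort_weights",
    "raw_growth",
    "growth_audit_frame",
]


@dataclass
class LekCountSeries:
    """Per-year high male counts and survey effort.

    Missing counts are NaN.  Years must be consecutive calendar years.
    ``imputed`` flags years whose count was filled in by :func:`impute_missing`.
    """

    years: np.ndarray
    males: np.ndarray
    lek_areas: np.ndarray
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.males = np.asarray(self.males, dtype=float)
        self.lek_areas = np.asarray(self.lek_areas, dtype=float)
        if self.imputed is None:
            self.imputed = np.zeros(self.years.shape, dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        n = len(self.years)
        if not (len(self.males) == len(self.lek_areas) == len(self.imputed) == n):
            raise ValueError("years, males, lek_areas, imputed must share length")
        if n == 0:
            raise ValueError("empty series")
        if not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be consecutive (step 1)")
        present = ~np.isnan(self.males)
        if np.any(self.males[present] < 0):
            raise ValueError("male counts must be non-negative")
        lpresent = ~np.isnan(self.lek_areas)
        if np.any(self.lek_areas[lpresent] < 1):
            raise ValueError("lek_areas must be >= 1 where present")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def is_complete(self) -> bool:
        """True when no count or effort value is missing."""
        return not (np.isnan(self.males).any() or np.isnan(self.lek_areas).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "males": self.males,
                "lek_areas": self.lek_areas,
                "imputed": self.imputed,
            }
        )


@dataclass(frozen=True)
class EffortConfig:
    """Total number of lek areas L, the denominator of the effort weight."""

    total_areas: int

    def __post_init__(self) -> None:
        if self.total_areas < 1:
            raise ValueError("total_areas must be a positive integer")

    @classmethod
    def from_series(cls, series: LekCountSeries) -> "EffortConfig":
        """Data-driven default: L = maximum observed effort."""
        l = series.lek_areas[~np.isnan(series.lek_areas)]
        if len(l) == 0:
            raise ValueError("series has no effort values")
        return cls(total_areas=int(np.max(l)))


@dataclass(frozen=True)
class RawGrowthSeries:
    """Raw effort-adjusted growth rates; year t labels the transition t-1 -> t."""

    years: np.ndarray
    lambda_raw: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "lambda_raw", np.asarray(self.lambda_raw, dtype=float))
        if len(self.years) != len(self.lambda_raw):
            raise ValueError("years and lambda_raw must share length")


def read_lek_counts(path, schema: dict | None = None) -> LekCountSeries:
    """Read a lek-count CSV into a validated :class:`LekCountSeries`.

    The file needs a header row with columns for year, male count, and number
    of lek areas surveyed (default names ``year, males, lek_areas``; override
    via ``schema``).  Missing cells may be blank or ``NA``.  Years absent from
    the file but inside the observed range are inserted as missing.

    Raises
    ------
    ValueError
        on duplicate years or non-numeric cells (reported with row index).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for key in ("year", "males", "lek_areas"):
        if schema[key] not in df.columns:
            raise ValueError(f"column {schema[key]!r} not found in {path}")

    def parse(col: str, allow_missing: bool) -> np.ndarray:
        raw = df[schema[col]].str.strip()
        blank = raw.isin(["", "NA", "NaN", "nan"])
        vals = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = (~blank) & vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {raw.iloc[row]!r} in column {schema[col]!r}, row {row}"
            )
        if not allow_missing and blank.any():
            row = int(np.flatnonzero(blank)[0])
            raise ValueError(f"missing value in column {schema[col]!r}, row {row}")
        return vals.to_numpy(dtype=float)

    years = parse("year", allow_missing=False)
    if np.any(years != np.round(years)):
        raise ValueError("years must be integers")
    years = years.astype(int)
    uniq, counts = np.unique(years, return_counts=True)
    if np.any(counts > 1):
        raise ValueError(f"duplicate year {int(uniq[np.argmax(counts > 1)])}")

    males = parse("males", allow_missing=True)
    lek_areas = parse("lek_areas", allow_missing=True)

    order = np.argsort(years)
    years, males, lek_areas = years[order], males[order], lek_areas[order]

    # complete interior gaps as missing years
    full = np.arange(years[0], years[-1] + 1)
    m_full = np.full(full.shape, np.nan)
    l_full = np.full(full.shape, np.nan)
    idx = years - years[0]
    m_full[idx] = males
    l_full[idx] = lek_areas
    return LekCountSeries(years=full, males=m_full, lek_areas=l_full)


def impute_missing(series: LekCountSeries) -> LekCountSeries:
    """Fill missing counts with the average of the two adjacent years.

    Effort for an imputed year is likewise the (rounded) mean of the adjacent
    years' effort.  Missing values at the series endpoints or in consecutive
    years cannot be bracketed and raise.  Idempotent.
    """
    m = series.males.copy()
    l = series.lek_areas.copy()
    flags = series.imputed.copy()
    miss = np.flatnonzero(np.isnan(m))
    if len(miss) == 0 and not np.isnan(l).any():
        return LekCountSeries(series.years.copy(), m, l, flags)
    if len(miss) > 0:
        if miss[0] == 0 or miss[-1] == series.n_years - 1:
            raise ValueError(
                f"cannot impute endpoint year {int(series.years[miss[0] if miss[0] == 0 else miss[-1]])}"
            )
        if np.any(np.diff(miss) == 1):
            raise ValueError("cannot impute consecutive missing years")
    for i in miss:
        m[i] = 0.5 * (m[i - 1] + m[i + 1])
        flags[i] = True
    lmiss = np.flatnonzero(np.isnan(l))
    if len(lmiss) > 0:
        if lmiss[0] == 0 or lmiss[-1] == series.n_years - 1 or np.any(np.diff(lmiss) == 1):
            raise ValueError("cannot impute effort at endpoints or consecutive years")
        for i in lmiss:
            l[i] = np.round(0.5 * (l[i - 1] + l[i + 1]))
    return LekCountSeries(series.years.copy(), m, l, flags)


def effort_weights(series: LekCountSeries, cfg: EffortConfig) -> np.ndarray:
    """Per-year effort weight w_t = l_t / L, in (0, 1]."""
    l = series.lek_areas
    if np.isnan(l).any():
        raise ValueError("effort missing for some years; impute first")
    if np.any(l > cfg.total_areas):
        bad = int(series.years[np.argmax(l > cfg.total_areas)])
        raise ValueError(f"lek_areas exceeds total_areas={cfg.total_areas} in year {bad}")
    return l / float(cfg.total_areas)


def raw_growth(series: LekCountSeries, weights: np.ndarray) -> RawGrowthSeries:
    """Raw growth rates of the effort-adjusted index.

    lambda_t = (M_t / w_t) / (M_{t-1} / w_{t-1}), labelled by the year t the
    transition leads into.  All counts must be positive (the log-scale model
    is undefined at zero).
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != series.n_years:
        raise ValueError("weights length must match series")
    if np.isnan(series.males).any():
        raise ValueError("series has missing counts; impute first")
    adjusted = series.males / weights
    if np.any(adjusted <= 0):
        bad = int(series.years[np.argmax(adjusted <= 0)])
        raise ValueError(f"non-positive adjusted count in year {bad}")
    lam = adjusted[1:] / adjusted[:-1]
    return RawGrowthSeries(years=series.years[1:], lambda_raw=lam)


def growth_audit_frame(series: LekCountSeries, weights: np.ndarray) -> pd.DataFrame:
    """Tidy per-year table of weights, adjusted counts, and raw growth rates."""
    g = raw_growth(series, weights)
    lam = np.concatenate([[np.nan], g.lambda_raw])
    return pd.DataFrame(
        {
            "year": series.years,
            "males": series.males,
            "omega": np.asarray(weights, dtype=float),
            "adjusted": series.males / np.asarray(weights, dtype=float),
            "lambda_raw": lam,
            "imputed": series.imputed,
        }
    )
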