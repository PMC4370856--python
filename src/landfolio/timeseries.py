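"""Annual price/yield series: loading, validation, rescaling, statistics.

A crop's market history is kept as paired annual observations of producer
price (US$ per Mg) and yield (Mg per ha).  Keeping the pairing intact matters:
the within-year dependence of price and yield is what a joint-year bootstrap
is designed to preserve.

All series in a table must cover the same set of years.  Years are labels
only — nothing is interpolated or gap-filled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CropSeries",
    "SeriesTable",
    "SeriesStats",
    "load_series_table",
    "packaged_series_path",
    "rescale_to_current",
    "series_stats",
]


class SeriesValidationError(ValueError):
    """Raised when a series table violates its structural invariants."""


@dataclass(frozen=True)
class CropSeries:
    """One land-use option's annual (year, price, yield) records.

    Parameters
    ----------
    crop_id
        Option identifier, e.g. ``"banana"``.
    years, prices, yields
        Aligned arrays; years strictly increasing, prices/yields nonnegative.
    currency, mass_unit, area_unit
        Unit metadata; defaults are US$, Mg and ha.
    """

    crop_id: str
    years: np.ndarray
    prices: np.ndarray
    yields: np.ndarray
    currency: str = "US$"
    mass_unit: str = "Mg"
    area_unit: str = "ha"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        prices = np.asarray(self.prices, dtype=float)
        yields = np.asarray(self.yields, dtype=float)
        if not (len(years) == len(prices) == len(yields)):
            raise SeriesValidationError(f"{self.crop_id}: ragged record arrays")
        if len(np.unique(years)) != len(years):
            raise SeriesValidationError(f"{self.crop_id}: duplicate years")
        if np.any(np.diff(years) <= 0):
            raise SeriesValidationError(f"{self.crop_id}: years not sorted")
        if np.any(prices < 0) or np.any(yields < 0):
            raise SeriesValidationError(f"{self.crop_id}: negative price or yield")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "prices", prices)
        object.__setattr__(self, "yields", yields)

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class SeriesTable:
    """Map crop_id -> CropSeries over one shared year range."""

    series: dict[str, CropSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        year_sets = {c: tuple(s.years) for c, s in self.series.items()}
        if len(set(year_sets.values())) > 1:
            raise SeriesValidationError(
                "series do not cover identical year sets: "
                + ", ".join(f"{c}:{len(y)}y" for c, y in year_sets.items())
            )

    @property
    def crops(self) -> list[str]:
        return list(self.series)

    @property
    def years(self) -> np.ndarray:
        first = next(iter(self.series.values()))
        return first.years

    def __getitem__(self, crop_id: str) -> CropSeries:
        return self.series[crop_id]

    def __len__(self) -> int:
        return len(self.series)

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: year column plus <crop>_price / <crop>_yield columns."""
        data: dict[str, np.ndarray] = {"year": self.years}
        for c, s in self.series.items():
            data[f"{c}_price"] = s.prices
            data[f"{c}_yield"] = s.yields
        return pd.DataFrame(data)


def packaged_series_path() -> Path:
    """Path of the packaged 1970-2009 FAOSTAT price/yield fixture."""
    return Path(
        importlib.resources.files("landfolio.data") / "faostat_1970_2009.csv"
    )


def load_series_table(path: str | Path | None = None) -> SeriesTable:
    """Load a wide-layout CSV (``year, <crop>_price, <crop>_yield, ...``).

    With no argument the packaged 1970-2009 five-crop series is loaded.
    Missing cells and ragged year coverage are errors; the loader never
    imputes.
    """
    path = packaged_series_path() if path is None else Path(path)
    try:
        df = pd.read_csv(path, comment="#")  # tolerate provenance headers
    except ValueError as exc:  # malformed numerics surface from the C parser
        raise SeriesValidationError(f"{path}: {exc}") from exc
    if "year" not in df.columns:
        raise SeriesValidationError(f"{path}: no 'year' column")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise SeriesValidationError(
                f"{path}: non-numeric cell in column '{col}' (row {row})"
            )
        if df[col].isna().any():
            row = int(df[col][df[col].isna()].index[0])
            raise SeriesValidationError(
                f"{path}: missing value in column '{col}' (row {row})"
            )
    crops = []
    for col in df.columns:
        if col.endswith("_price"):
            crop = col[: -len("_price")]
            if f"{crop}_yield" not in df.columns:
                raise SeriesValidationError(f"{path}: '{crop}' has price but no yield")
            crops.append(crop)
    if not crops:
        raise SeriesValidationError(f"{path}: no <crop>_price columns found")
    df = df.sort_values("year")
    series = {
        c: CropSeries(
            crop_id=c,
            years=df["year"].to_numpy(int),
            prices=df[f"{c}_price"].to_numpy(float),
            yields=df[f"{c}_yield"].to_numpy(float),
        )
        for c in crops
    }
    return SeriesTable(series)


def rescale_to_current(
    series: CropSeries, current_price: float, current_yield: float
) -> CropSeries:
    """Rescale a series so its mean price/yield equal current levels.

    Each annual price is divided by the series mean price and multiplied by
    ``current_price`` (yields likewise).  This is a linear map, so the
    coefficient of variation of each column — and every Pearson correlation
    with any other column — is unchanged; only the level moves.
    """
    if len(series) < 2:
        raise SeriesValidationError(f"{series.crop_id}: need >= 2 records")
    mp, my = series.prices.mean(), series.yields.mean()
    if mp <= 0 or my <= 0:
        raise ZeroDivisionError(
            f"{series.crop_id}: zero mean price or yield, cannot rescale"
        )
    return replace(
        series,
        prices=series.prices / mp * current_price,
        yields=series.yields / my * current_yield,
    )


@dataclass(frozen=True)
class SeriesStats:
    crop_id: str
    price_mean: float
    price_sd: float
    price_cv: float
    yield_mean: float
    yield_sd: float
    yield_cv: float
    n_years: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def series_stats(series: CropSeries) -> SeriesStats:
    """Mean, sample SD (n-1) and CV for the price and yield columns."""
    if len(series) < 2:
        raise SeriesValidationError(f"{series.crop_id}: need >= 2 records")
    pm, ym = series.prices.mean(), series.yields.mean()
    ps = series.prices.std(ddof=1)
    ys = series.yields.std(ddof=1)
    return SeriesStats(
        crop_id=series.crop_id,
        price_mean=pm,
        price_sd=ps,
        price_cv=ps / pm,
        yield_mean=ym,
        yield_sd=ys,
        yield_cv=ys / ym,
        n_years=len(series),
    )
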