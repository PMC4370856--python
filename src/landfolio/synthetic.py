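"""Synthetic joint price/yield series with controlled statistical structure.

Emulates the shape of national commodity statistics — per-crop linear trends,
wide price dispersion, moderate yield dispersion, positive within-year
price-yield dependence, near-zero cross-crop dependence — so that every
pipeline stage can be exercised, and parameter recovery asserted, without the
packaged historical fixture.

Marginals are lognormal around the trend line (prices and yields cannot go
negative); dependence is induced through a Gaussian copula.  Requested
correlations are Pearson correlations of the *generated values*: the copula
correlation is adjusted upward to compensate for the attenuation a lognormal
transform applies to Gaussian correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import nearest_psd
from .timeseries import CropSeries, SeriesTable

__all__ = ["SyntheticCrop", "SyntheticSeriesSpec", "generate_series", "recover_parameters"]


@dataclass(frozen=True)
class SyntheticCrop:
    """Target moments of one synthetic crop.

    Trends are linear in US$/Mg (resp. Mg/ha) per year, centered so the
    series mean stays at ``price_mean`` / ``yield_mean``.  ``price_yield_rho``
    is the within-year Pearson correlation of price and yield.
    """

    crop_id: str
    price_mean: float
    price_cv: float
    yield_mean: float
    yield_cv: float
    price_trend: float = 0.0
    yield_trend: float = 0.0
    price_yield_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.price_cv < 0 or self.yield_cv < 0:
            raise ValueError(f"{self.crop_id}: CVs must be >= 0")
        if not -1 <= self.price_yield_rho <= 1:
            raise ValueError(f"{self.crop_id}: correlation out of [-1, 1]")


@dataclass(frozen=True)
class SyntheticSeriesSpec:
    """Joint spec: crops, series length and cross-crop price correlation."""

    crops: tuple[SyntheticCrop, ...]
    n_years: int = 40
    start_year: int = 1970
    cross_rho: np.ndarray | None = None  # crop x crop, applied to price shocks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("need at least 2 years")
        if self.cross_rho is not None:
            c = np.asarray(self.cross_rho, dtype=float)
            k = len(self.crops)
            if c.shape != (k, k) or not np.allclose(c, c.T):
                raise ValueError("cross_rho must be a symmetric crop x crop matrix")
            object.__setattr__(self, "cross_rho", c)


def _sigma(cv: float) -> float:
    """Lognormal shape parameter giving the requested CV."""
    return float(np.sqrt(np.log1p(cv**2)))


def _copula_rho(target: float, s1: float, s2: float) -> float:
    """Gaussian correlation whose lognormal image has Pearson ``target``.

    Inverts corr_LN = (exp(rho s1 s2) - 1) / sqrt((e^{s1^2}-1)(e^{s2^2}-1));
    unreachable targets (|corr_LN| has a ceiling below 1 for unequal shapes)
    are clamped to the boundary.
    """
    if s1 == 0 or s2 == 0 or target == 0:
        return 0.0
    denom = np.sqrt(np.expm1(s1**2) * np.expm1(s2**2))
    arg = 1.0 + target * denom
    if arg <= 0:
        return -1.0
    return float(np.clip(np.log(arg) / (s1 * s2), -1.0, 1.0))


def generate_series(spec: SyntheticSeriesSpec) -> SeriesTable:
    """Draw a SeriesTable with the requested first/second-moment structure.

    Assembly: one Gaussian shock per (crop, variable, year); within a year,
    a crop's price and yield shocks are correlated (copula-adjusted), price
    shocks of different crops follow ``cross_rho``, and yield shocks of
    different crops are independent.  Values are lognormal around the trend,
    so negatives are impossible; zero-CV columns are exactly their trend.
    """
    k = len(spec.crops)
    rng = np.random.default_rng(spec.seed)
    # joint correlation over 2k coordinates: (price_0..price_{k-1}, yield_0..)
    sig_p = [_sigma(c.price_cv) for c in spec.crops]
    sig_y = [_sigma(c.yield_cv) for c in spec.crops]
    R = np.eye(2 * k)
    for i, c in enumerate(spec.crops):
        R[i, k + i] = R[k + i, i] = _copula_rho(c.price_yield_rho, sig_p[i], sig_y[i])
    if spec.cross_rho is not None:
        for i in range(k):
            for j in range(i + 1, k):
                rho = _copula_rho(spec.cross_rho[i, j], sig_p[i], sig_p[j])
                R[i, j] = R[j, i] = rho
    R = nearest_psd(R)
    z = rng.multivariate_normal(np.zeros(2 * k), R, size=spec.n_years, method="svd")

    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    t_centered = np.arange(spec.n_years) - (spec.n_years - 1) / 2.0
    series: dict[str, CropSeries] = {}
    for i, c in enumerate(spec.crops):
        price_trend = c.price_mean + c.price_trend * t_centered
        yield_trend = c.yield_mean + c.yield_trend * t_centered
        if np.any(price_trend <= 0) or np.any(yield_trend <= 0):
            raise ValueError(f"{c.crop_id}: trend line crosses zero")
        sp, sy = sig_p[i], sig_y[i]
        prices = price_trend * np.exp(sp * z[:, i] - sp**2 / 2.0)
        yields = yield_trend * np.exp(sy * z[:, k + i] - sy**2 / 2.0)
        series[c.crop_id] = CropSeries(
            crop_id=c.crop_id, years=years, prices=prices, yields=yields
        )
    return SeriesTable(series)


def recover_parameters(table: SeriesTable) -> dict[str, dict[str, float]]:
    """Per-crop moment estimates for generator/estimator round-trip checks.

    Returns mean, sample CV, linear trend slope for prices and yields, and
    the within-year price-yield Pearson correlation.
    """
    out: dict[str, dict[str, float]] = {}
    t = np.arange(len(table.years), dtype=float)
    for cid in table.crops:
        s = table[cid]
        if len(s) < 10:
            raise ValueError(f"{cid}: need >= 10 years for recovery")
        pm, ym = s.prices.mean(), s.yields.mean()
        if pm == 0 or ym == 0:
            raise ValueError(f"{cid}: degenerate series")
        p_sd, y_sd = s.prices.std(ddof=1), s.yields.std(ddof=1)
        rho = (
            float(np.corrcoef(s.prices, s.yields)[0, 1])
            if p_sd > 0 and y_sd > 0
            else 0.0
        )
        out[cid] = {
            "price_mean": float(pm),
            "price_cv": float(p_sd / pm),
            "price_trend": float(np.polyfit(t, s.prices, 1)[0]),
            "yield_mean": float(ym),
            "yield_cv": float(y_sd / ym),
            "yield_trend": float(np.polyfit(t, s.yields, 1)[0]),
            "price_yield_rho": rho,
        }
    return out
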