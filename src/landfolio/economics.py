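"""Deterministic cash flows and annuities for annual crops, perennials and
plantation forestry.

Every land-use option is valued as the annuity of its net-revenue stream over
a common planning horizon (default 30 years, discount rate 5%): the constant
yearly payment whose discounted sum equals the net present value of the
stream.  The annuity shares the unit of an annual crop's yearly net revenue
(US$ ha^-1 yr^-1), which makes options with very different time structures
directly comparable.

Timing conventions
------------------
Perennials are replanted every ``cycle_length`` years.  By default the
establishment cost is charged at the replacement years inside the horizon
(t = cycle_length, 2*cycle_length, ... < T) while the initial planting at
t = 0 is treated as outside the annuity window; ``establishment_timing =
"cycle_start"`` additionally charges the t = 0 planting.  Forestry revenues
are booked at the silvicultural intervention years of the management plan,
with per-cycle lump revenues and harvesting costs allocated across
interventions proportionally to removed volume.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DiscountSpec",
    "CropSpec",
    "Intervention",
    "ForestrySpec",
    "CashflowSeries",
    "annual_net_revenue",
    "build_cashflows",
    "annuity",
    "tree_volume",
    "stand_removals",
    "forestry_cashflows",
    "load_default_specs",
]


@dataclass(frozen=True)
class DiscountSpec:
    """Discount rate ``d`` per year and planning horizon in years."""

    d: float = 0.05
    horizon: int = 30

    def __post_init__(self) -> None:
        if self.d <= -1:
            raise ValueError("discount rate must exceed -1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 year")

    @property
    def q(self) -> float:
        return 1.0 + self.d

    @property
    def annuity_factor(self) -> float:
        """Factor converting a horizon-T NPV into a constant yearly payment.

        For d = 0 the factor degenerates to the arithmetic mean, 1/T
        (removable singularity).
        """
        if self.d == 0:
            return 1.0 / self.horizon
        qT = self.q**self.horizon
        return self.d * qT / (qT - 1.0)


@dataclass(frozen=True)
class CropSpec:
    """Economic coefficients of one agricultural land-use option.

    ``cycle_length`` is the number of years between replantings (1 for annual
    crops, which have no establishment cost).
    """

    crop_id: str
    price: float  # US$/Mg
    yield_: float  # Mg/ha
    annual_cost: float  # US$/ha/yr
    establishment_cost: float = 0.0  # US$/ha at each replanting
    cycle_length: int = 1
    establishment_timing: str = "replacement"  # or "cycle_start"

    def __post_init__(self) -> None:
        for name in ("price", "yield_", "annual_cost", "establishment_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.crop_id}: {name} must be >= 0")
        if self.cycle_length < 1:
            raise ValueError(f"{self.crop_id}: cycle_length must be >= 1")
        if self.establishment_timing not in ("replacement", "cycle_start"):
            raise ValueError(f"{self.crop_id}: unknown establishment_timing")


@dataclass(frozen=True)
class Intervention:
    """One silvicultural intervention of a management plan.

    ``year`` is relative to the start of the rotation cycle.  ``revenue`` and
    ``cost`` are the amounts booked at this intervention (US$/ha); see
    :meth:`ForestrySpec.with_allocated_totals` for the volume-proportional
    allocation of per-cycle lump sums.
    """

    year: int
    dbh: float  # m
    height: float  # m
    form_factor: float
    removal_fraction: float
    revenue: float = 0.0
    cost: float = 0.0


@dataclass(frozen=True)
class ForestrySpec:
    """Management plan and economics of a plantation forestry option."""

    crop_id: str
    density: float  # planted trees/ha
    mortality: float  # fraction of seedlings lost, applied once
    establishment_cost: float  # US$/ha per cycle
    cycle_length: int  # rotation length, years
    interventions: tuple[Intervention, ...]
    price_cv: float = 0.10
    growth_cv: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.mortality <= 1:
            raise ValueError(f"{self.crop_id}: mortality must be in [0, 1]")
        remaining = 1.0
        for iv in self.interventions:
            if not 0 <= iv.removal_fraction <= 1:
                raise ValueError(f"{self.crop_id}: removal fraction out of [0, 1]")
            if iv.year > self.cycle_length:
                raise ValueError(
                    f"{self.crop_id}: intervention year {iv.year} beyond cycle"
                )
            remaining *= 1.0 - iv.removal_fraction
        if remaining < -1e-12:
            raise ValueError(f"{self.crop_id}: removals exceed standing stock")

    def with_allocated_totals(
        self, cycle_revenue: float, cycle_harvest_cost: float
    ) -> "ForestrySpec":
        """Spread per-cycle lump revenue/cost over interventions by volume.

        The management plan prices a whole rotation (one revenue figure, one
        harvesting-cost figure); individual thinnings and the final felling
        receive shares proportional to the volume they remove.
        """
        removed = stand_removals(self)
        total = removed.sum()
        if total <= 0:
            raise ValueError(f"{self.crop_id}: no removed volume to allocate to")
        shares = removed / total
        ivs = tuple(
            Intervention(
                year=iv.year,
                dbh=iv.dbh,
                height=iv.height,
                form_factor=iv.form_factor,
                removal_fraction=iv.removal_fraction,
                revenue=cycle_revenue * s,
                cost=cycle_harvest_cost * s,
            )
            for iv, s in zip(self.interventions, shares)
        )
        return ForestrySpec(
            crop_id=self.crop_id,
            density=self.density,
            mortality=self.mortality,
            establishment_cost=self.establishment_cost,
            cycle_length=self.cycle_length,
            interventions=ivs,
            price_cv=self.price_cv,
            growth_cv=self.growth_cv,
        )


@dataclass(frozen=True)
class CashflowSeries:
    """Net revenues n_t (US$/ha) for t = 1..T, plus an optional t = 0 outlay."""

    values: np.ndarray
    t0_outlay: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


def annual_net_revenue(spec: CropSpec, price: float, yield_: float) -> float:
    """Yearly net revenue: price * yield - annual cost (may be negative)."""
    return price * yield_ - spec.annual_cost


def _establishment_years(cycle_length: int, horizon: int) -> list[int]:
    return list(range(cycle_length, horizon, cycle_length))


def build_cashflows(
    spec: CropSpec,
    prices: np.ndarray,
    yields: np.ndarray,
    disc: DiscountSpec,
) -> CashflowSeries:
    """Per-year net revenues with establishment costs at replanting years."""
    prices = np.asarray(prices, dtype=float)
    yields = np.asarray(yields, dtype=float)
    T = disc.horizon
    if len(prices) != T or len(yields) != T:
        raise ValueError(
            f"{spec.crop_id}: need price/yield vectors of length {T}, "
            f"got {len(prices)}/{len(yields)}"
        )
    n = prices * yields - spec.annual_cost
    t0 = 0.0
    if spec.establishment_cost > 0 and spec.cycle_length >= 1:
        for t in _establishment_years(spec.cycle_length, T):
            n[t - 1] -= spec.establishment_cost
        if spec.establishment_timing == "cycle_start":
            t0 = spec.establishment_cost
    return CashflowSeries(values=n, t0_outlay=t0)


def annuity(cash: CashflowSeries, disc: DiscountSpec) -> float:
    """Annualized NPV of a cash-flow stream.

    r = [sum_t n_t q^-t] * (q-1) q^T / (q^T - 1); the annuity of a level
    stream equals that level for any d > 0, and the d = 0 limit is the plain
    average.
    """
    if len(cash) != disc.horizon:
        raise ValueError("cash-flow length does not match the horizon")
    t = np.arange(1, disc.horizon + 1)
    npv = float(cash.values @ disc.q ** (-t.astype(float))) - cash.t0_outlay
    return npv * disc.annuity_factor


def tree_volume(dbh: float, height: float, form_factor: float) -> float:
    """Stem volume (m3) as a form-factor-reduced cylinder over the DBH disc."""
    if dbh <= 0 or height <= 0 or form_factor <= 0:
        raise ValueError("dbh, height and form factor must be positive")
    return math.pi / 4.0 * dbh**2 * height * form_factor


def stand_removals(spec: ForestrySpec) -> np.ndarray:
    """Removed volume (m3/ha) per intervention, applied chronologically.

    Seedling mortality thins the planted density once; each intervention then
    removes its fraction of the *currently standing* stems at that
    intervention's per-tree volume.
    """
    stems = spec.density * (1.0 - spec.mortality)
    out = []
    for iv in sorted(spec.interventions, key=lambda iv: iv.year):
        removed_stems = stems * iv.removal_fraction
        if removed_stems > 0 and stems <= 0:
            raise ValueError(f"{spec.crop_id}: removal from an empty stand")
        out.append(removed_stems * tree_volume(iv.dbh, iv.height, iv.form_factor))
        stems -= removed_stems
    return np.array(out)


def forestry_cashflows(
    spec: ForestrySpec,
    disc: DiscountSpec,
    price_multipliers: np.ndarray | None = None,
    growth_multipliers: np.ndarray | None = None,
    establishment_timing: str = "replacement",
) -> CashflowSeries:
    """Expand the per-cycle management plan over the horizon.

    ``price_multipliers`` / ``growth_multipliers`` hold one positive factor
    per rotation cycle; intervention revenues scale with their product while
    harvesting and establishment costs stay fixed.  A final cycle cut off by
    the horizon is truncated: only interventions falling inside the horizon
    are booked.
    """
    T = disc.horizon
    n_cycles = math.ceil(T / spec.cycle_length)
    ones = np.ones(n_cycles)
    pm = ones if price_multipliers is None else np.asarray(price_multipliers, float)
    gm = ones if growth_multipliers is None else np.asarray(growth_multipliers, float)
    if len(pm) < n_cycles or len(gm) < n_cycles:
        raise ValueError(f"{spec.crop_id}: need one multiplier per cycle ({n_cycles})")
    if np.any(pm <= 0) or np.any(gm <= 0):
        raise ValueError(f"{spec.crop_id}: multipliers must be positive")

    n = np.zeros(T)
    t0 = 0.0
    for c in range(n_cycles):
        start = c * spec.cycle_length
        if start == 0:
            if establishment_timing == "cycle_start":
                t0 = spec.establishment_cost
        elif start < T:
            n[start - 1] -= spec.establishment_cost
        for iv in spec.interventions:
            t = start + iv.year
            if t <= T:
                n[t - 1] += iv.revenue * pm[c] * gm[c] - iv.cost
    return CashflowSeries(values=n, t0_outlay=t0)


# ---------------------------------------------------------------------------
# Packaged default coefficients


def load_default_specs(
    path: str | Path | None = None,
) -> tuple[DiscountSpec, dict[str, CropSpec], dict[str, ForestrySpec]]:
    """Load the packaged (or a user-supplied JSON) coefficient set.

    Returns the discount spec, agricultural crop specs and forestry specs
    with per-cycle revenue/cost lumps already allocated to interventions.
    """
    if path is None:
        path = importlib.resources.files("landfolio.data") / "crop_coefficients.json"
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    disc = DiscountSpec(**cfg.get("discount", {}))
    crops = {
        cid: CropSpec(crop_id=cid, **kw) for cid, kw in cfg.get("crops", {}).items()
    }
    forestry = {}
    for cid, kw in cfg.get("forestry", {}).items():
        ivs = tuple(Intervention(**iv) for iv in kw.pop("interventions"))
        cycle_revenue = kw.pop("cycle_revenue")
        cycle_harvest_cost = kw.pop("cycle_harvest_cost")
        spec = ForestrySpec(crop_id=cid, interventions=ivs, **kw)
        forestry[cid] = spec.with_allocated_totals(cycle_revenue, cycle_harvest_cost)
    return disc, crops, forestry
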