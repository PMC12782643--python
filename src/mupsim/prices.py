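"""Price-paid distributions and minimum-unit-price (MUP) transforms.

A price distribution records the share of a subgroup's weekly units bought
at each price-per-unit point for one beverage category.  An MUP is a legal
floor: introducing or raising it censors the distribution from below
(every purchase below the threshold is re-priced at the threshold);
lowering or removing it lets affected purchases fall back to their
original (never-censored) price, which every point carries alongside its
current price.  Prices are held internally in pence with an epsilon guard
so threshold comparisons are exact at band edges.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .categories import (
    BEVERAGE_LABELS,
    N_BEVERAGES,
    N_SUBGROUPS,
    subgroup_fields,
)

_EPS = 1e-9
_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class InflationSeries:
    """Annual price index (RPI or CPIH), base year 2017 = 1.0."""

    index_name: str
    values: dict[int, float]

    def __post_init__(self) -> None:
        years = sorted(self.values)
        if years != list(range(years[0], years[-1] + 1)):
            raise ValueError("inflation series must cover contiguous years")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("index values must be strictly positive")

    def factor(self, from_year: int, to_year: int) -> float:
        if from_year not in self.values or to_year not in self.values:
            raise KeyError(
                f"{self.index_name} series missing year "
                f"{from_year if from_year not in self.values else to_year}"
            )
        return self.values[to_year] / self.values[from_year]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index_name": self.index_name,
             "year": sorted(self.values),
             "value": [self.values[y] for y in sorted(self.values)]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InflationSeries":
        return cls(
            index_name=str(df["index_name"].iloc[0]),
            values=dict(zip(df["year"].astype(int), df["value"].astype(float))),
        )


@dataclass(frozen=True)
class PriceDistribution:
    """Binned unit shares over price-per-unit points for one subgroup x beverage.

    ``prices`` are current prices in £/unit, sorted ascending; ``shares``
    are positive and sum to one; ``original_prices`` are the never-MUP'd
    prices of the same purchase masses (equal to ``prices`` where no MUP
    has bitten).
    """

    prices: np.ndarray
    shares: np.ndarray
    original_prices: np.ndarray = None
    subgroup: int | None = None
    beverage: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.prices, dtype=float)
        s = np.asarray(self.shares, dtype=float)
        if p.size == 0:
            raise ValueError("empty price distribution")
        if p.shape != s.shape:
            raise ValueError("prices and shares must align")
        if np.any(p <= 0):
            raise ValueError("prices must be positive")
        if np.any(s <= 0):
            raise ValueError("shares must be positive")
        if abs(s.sum() - 1.0) > _SHARE_TOL * max(1.0, p.size):
            raise ValueError(f"shares must sum to 1, got {s.sum()!r}")
        if np.any(np.diff(p) < 0):
            raise ValueError("points must be sorted ascending by price")
        o = self.original_prices
        o = p.copy() if o is None else np.asarray(o, dtype=float)
        object.__setattr__(self, "prices", p)
        object.__setattr__(self, "shares", s)
        object.__setattr__(self, "original_prices", o)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.prices.tolist(), self.shares.tolist()))

    def mean_price(self) -> float:
        """Share-weighted mean price per unit (£)."""
        return float(np.dot(self.prices, self.shares))


def apply_mup(dist: PriceDistribution, threshold: float) -> PriceDistribution:
    """Censor a price distribution from below at ``threshold`` £/unit."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    new = np.where(dist.prices < threshold - _EPS, threshold, dist.prices)
    return replace(dist, prices=new)


def remove_or_lower_mup(
    current: PriceDistribution,
    pre_mup_reference: PriceDistribution,
    new_threshold: float | None = None,
) -> PriceDistribution:
    """Revert MUP-censored purchases, then re-censor at ``new_threshold``.

    Purchases whose original price is below the new threshold (or all
    previously raised purchases, if the MUP is removed) return to their
    original price; the remainder keep it anyway because ``current`` was
    produced from ``pre_mup_reference`` by :func:`apply_mup`.
    """
    if current.prices.shape != pre_mup_reference.prices.shape or not np.allclose(
        current.shares, pre_mup_reference.shares, rtol=0, atol=1e-12
    ):
        raise ValueError("purchase masses of current and reference do not match")
    restored = replace(current, prices=pre_mup_reference.prices.copy())
    if new_threshold is None:
        return restored
    return apply_mup(restored, new_threshold)


def uprate_prices(
    dist: PriceDistribution,
    index: InflationSeries,
    from_year: int,
    to_year: int,
) -> PriceDistribution:
    """Scale all prices by the inflation factor between two years."""
    f = index.factor(from_year, to_year)
    return replace(
        dist, prices=dist.prices * f, original_prices=dist.original_prices * f
    )


@dataclass(frozen=True)
class PriceChangeSummary:
    """Mean-price comparison for one subgroup x beverage."""

    mean_price_before: float
    mean_price_after: float

    @property
    def pct_change(self) -> float:
        return 100.0 * (self.mean_price_after - self.mean_price_before) / self.mean_price_before


def summarise_price_change(
    before: PriceDistribution, after: PriceDistribution
) -> PriceChangeSummary:
    if before.subgroup != after.subgroup or before.beverage != after.beverage:
        raise ValueError("distributions refer to different subgroup or beverage")
    return PriceChangeSummary(before.mean_price(), after.mean_price())


def mean_spend_per_drinker(dist: PriceDistribution, units: float) -> float:
    """Weekly spend (£) for a drinker buying ``units`` at the distribution's mean price."""
    if units < 0:
        raise ValueError("units must be non-negative")
    return units * dist.mean_price()


# --------------------------------------------------------------------------
# Policy schedules


@dataclass(frozen=True)
class PolicySchedule:
    """Nominal MUP threshold by year (None = no MUP) plus index names.

    ``price_inflation_index`` uprates underlying prices year on year;
    ``mup_inflation_index`` is the index used to hold the threshold
    constant in real terms.
    """

    name: str
    mup_by_year: dict[int, float | None]
    price_inflation_index: str = "RPI"
    mup_inflation_index: str = "CPIH"

    def __post_init__(self) -> None:
        years = sorted(self.mup_by_year)
        if years != list(range(years[0], years[-1] + 1)):
            raise ValueError("policy schedule years must be contiguous")
        for y, t in self.mup_by_year.items():
            if t is not None and t <= 0:
                raise ValueError(f"threshold for {y} must be positive")

    @property
    def years(self) -> list[int]:
        return sorted(self.mup_by_year)

    def threshold(self, year: int) -> float | None:
        return self.mup_by_year[year]

    def to_yaml(self, path) -> None:
        payload = {
            "name": self.name,
            "price_inflation_index": self.price_inflation_index,
            "mup_inflation_index": self.mup_inflation_index,
            "mup_by_year": {int(y): t for y, t in self.mup_by_year.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "PolicySchedule":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            name=payload["name"],
            mup_by_year={int(y): t for y, t in payload["mup_by_year"].items()},
            price_inflation_index=payload.get("price_inflation_index", "RPI"),
            mup_inflation_index=payload.get("mup_inflation_index", "CPIH"),
        )


def build_schedule(
    name: str,
    threshold_2019: float | None,
    mup_index: InflationSeries,
    start_year: int = 2017,
    end_year: int = 2040,
    initial_threshold: float = 0.50,
    initial_year: int = 2018,
    policy_year: int = 2019,
    price_index_name: str = "RPI",
) -> PolicySchedule:
    """Standard appraisal schedule: no MUP before ``initial_year``, £0.50
    from 2018, the scenario threshold from ``policy_year``, uprated in
    real terms (by ``mup_index``) from the following year onwards.
    """
    sched: dict[int, float | None] = {}
    for y in range(start_year, end_year + 1):
        if y < initial_year:
            sched[y] = None
        elif y < policy_year:
            sched[y] = initial_threshold
        elif threshold_2019 is None:
            sched[y] = None
        else:
            sched[y] = threshold_2019 * mup_index.factor(policy_year, max(y, policy_year))
    return PolicySchedule(
        name=name,
        mup_by_year=sched,
        price_inflation_index=price_index_name,
        mup_inflation_index=mup_index.index_name,
    )


# --------------------------------------------------------------------------
# Vectorised set of all 8,000 distributions


@dataclass
class PriceDistributionSet:
    """All subgroup x beverage price distributions in flat arrays.

    ``price_pence``/``original_pence`` are current and never-censored
    prices in pence; ``share`` sums to one within each (subgroup,
    beverage) cell.  Transforms mirror the single-distribution functions
    but run vectorised across all 8,000 cells.
    """

    subgroup_id: np.ndarray
    beverage_id: np.ndarray
    price_pence: np.ndarray
    original_pence: np.ndarray
    share: np.ndarray
    _cell: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._cell = self.subgroup_id.astype(np.int64) * N_BEVERAGES + self.beverage_id
        if np.any(self.share <= 0):
            raise ValueError("shares must be positive")
        sums = np.bincount(self._cell, weights=self.share,
                           minlength=N_SUBGROUPS * N_BEVERAGES)
        filled = sums > 0
        if np.any(np.abs(sums[filled] - 1.0) > 1e-6):
            raise ValueError("cell shares must each sum to 1")

    def copy(self) -> "PriceDistributionSet":
        return PriceDistributionSet(
            subgroup_id=self.subgroup_id,
            beverage_id=self.beverage_id,
            price_pence=self.price_pence.copy(),
            original_pence=self.original_pence.copy(),
            share=self.share,
        )

    def apply_mup(self, threshold: float | None) -> None:
        """In place: current price = max(original-path price, threshold £)."""
        if threshold is not None:
            t = threshold * 100.0
            np.copyto(
                self.price_pence,
                np.where(self.price_pence < t - _EPS, t, self.price_pence),
            )

    def set_from_original(self, threshold: float | None) -> None:
        """In place: current price = original price censored at threshold (£)."""
        np.copyto(self.price_pence, self.original_pence)
        self.apply_mup(threshold)

    def uprate(self, factor: float) -> None:
        self.price_pence *= factor
        self.original_pence *= factor

    def mean_price(self) -> np.ndarray:
        """(800, 10) array of share-weighted mean prices in £; NaN where empty."""
        size = N_SUBGROUPS * N_BEVERAGES
        num = np.bincount(self._cell, weights=self.price_pence * self.share,
                          minlength=size)
        den = np.bincount(self._cell, weights=self.share, minlength=size)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den / 100.0
        return out.reshape(N_SUBGROUPS, N_BEVERAGES)

    def get(self, subgroup: int, beverage: int) -> PriceDistribution:
        m = (self.subgroup_id == subgroup) & (self.beverage_id == beverage)
        if not np.any(m):
            raise KeyError(f"no distribution for subgroup {subgroup}, beverage {beverage}")
        order = np.argsort(self.price_pence[m], kind="stable")
        return PriceDistribution(
            prices=self.price_pence[m][order] / 100.0,
            shares=self.share[m][order] / self.share[m].sum(),
            original_prices=self.original_pence[m][order] / 100.0,
            subgroup=subgroup,
            beverage=BEVERAGE_LABELS[beverage],
        )

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        fields_ = subgroup_fields(self.subgroup_id)
        df = pd.DataFrame(fields_)
        df["beverage"] = np.asarray(BEVERAGE_LABELS)[self.beverage_id]
        df["price_pence"] = self.price_pence
        df["original_price_pence"] = self.original_pence
        df["share"] = self.share
        df["subgroup_id"] = self.subgroup_id
        df["beverage_id"] = self.beverage_id
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PriceDistributionSet":
        return cls(
            subgroup_id=df["subgroup_id"].to_numpy(np.int64),
            beverage_id=df["beverage_id"].to_numpy(np.int64),
            price_pence=df["price_pence"].to_numpy(float),
            original_pence=df["original_price_pence"].to_numpy(float),
            share=df["share"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path) -> "PriceDistributionSet":
        return cls.from_frame(pd.read_csv(path))
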