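"""Vectorised container for the simulated adult population.

Individuals are stored column-wise in numpy arrays: a row is one simulated
adult carrying demographics (age, sex, income quintile, SIMD quintile,
smoking group), a survey weight (persons represented in the national
population), a 10-vector of weekly alcohol units by beverage category, an
alive flag, and a per-year history of total weekly units used for lagged
risk evaluation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import (
    BEVERAGE_LABELS,
    N_BEVERAGES,
    age_band_index,
    subgroup_index,
)
from .consumption import DrinkerGroupThresholds, assign_drinker_group


@dataclass
class Population:
    """Column-wise collection of simulated individuals.

    ``units`` has shape (n, 10): weekly UK units by beverage category
    (1 unit = 8 g ethanol).  ``history`` holds one (n,) array of total
    weekly units per completed simulation year, oldest first.
    """

    age: np.ndarray              # int, years, >= 18
    sex: np.ndarray              # int8: 0 female, 1 male
    income_quintile: np.ndarray  # int8 in 1..5
    simd_quintile: np.ndarray    # int8 in 1..5 (1 = least deprived)
    smoking_group: np.ndarray    # int8 in 0..4
    weight: np.ndarray           # float, persons represented, > 0
    units: np.ndarray            # float (n, 10), >= 0
    alive: np.ndarray = None     # bool
    history: list[np.ndarray] = field(default_factory=list)
    thresholds: DrinkerGroupThresholds = field(default_factory=DrinkerGroupThresholds)

    def __post_init__(self) -> None:
        n = len(self.age)
        if self.alive is None:
            self.alive = np.ones(n, dtype=bool)
        self.units = np.asarray(self.units, dtype=float)
        if self.units.shape != (n, N_BEVERAGES):
            raise ValueError(
                f"units must have shape ({n}, {N_BEVERAGES}), got {self.units.shape}"
            )
        if np.any(self.units < 0):
            raise ValueError("weekly units must be non-negative")
        if np.any(self.weight <= 0):
            raise ValueError("survey weights must be positive")

    def __len__(self) -> int:
        return len(self.age)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(len(self))

    @property
    def total_units(self) -> np.ndarray:
        """Total weekly units across all 10 beverage categories."""
        return self.units.sum(axis=1)

    @property
    def drinker_group(self) -> np.ndarray:
        """Drinker-group index (0 abstainer .. 3 harmful) from current intake."""
        return assign_drinker_group(self.total_units, self.sex, self.thresholds)

    @property
    def age_band(self) -> np.ndarray:
        return age_band_index(self.age)

    @property
    def subgroup_id(self) -> np.ndarray:
        """Current subgroup id in 0..799 (refreshed as consumption changes)."""
        return subgroup_index(
            self.age_band, self.sex, self.income_quintile,
            self.smoking_group, self.drinker_group,
        )

    def stratum_id(self) -> np.ndarray:
        """Outcome stratum (age band x sex x SIMD quintile), 0..39."""
        return (self.age_band * 2 + self.sex) * 5 + (self.simd_quintile - 1)

    def copy(self) -> "Population":
        return Population(
            age=self.age.copy(),
            sex=self.sex.copy(),
            income_quintile=self.income_quintile.copy(),
            simd_quintile=self.simd_quintile.copy(),
            smoking_group=self.smoking_group.copy(),
            weight=self.weight.copy(),
            units=self.units.copy(),
            alive=self.alive.copy(),
            history=[h.copy() for h in self.history],
            thresholds=self.thresholds,
        )

    def record_year(self) -> None:
        """Append the current total weekly units to the consumption history."""
        self.history.append(self.total_units.copy())

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        """One row per individual; beverage units in labelled columns."""
        df = pd.DataFrame(
            {
                "id": self.ids,
                "age": self.age,
                "sex": np.where(self.sex == 1, "male", "female"),
                "income_quintile": self.income_quintile,
                "simd_quintile": self.simd_quintile,
                "smoking_group": self.smoking_group,
                "drinker_group": self.drinker_group,
                "weight": self.weight,
                "alive": self.alive,
            }
        )
        for j, label in enumerate(BEVERAGE_LABELS):
            df[f"units[{label}]"] = self.units[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Population":
        units = np.column_stack(
            [df[f"units[{label}]"].to_numpy(float) for label in BEVERAGE_LABELS]
        )
        return cls(
            age=df["age"].to_numpy(int),
            sex=(df["sex"].to_numpy() == "male").astype(np.int8),
            income_quintile=df["income_quintile"].to_numpy(np.int8),
            simd_quintile=df["simd_quintile"].to_numpy(np.int8),
            smoking_group=df["smoking_group"].to_numpy(np.int8),
            weight=df["weight"].to_numpy(float),
            units=units,
            alive=df["alive"].to_numpy(bool),
        )

    @classmethod
    def from_csv(cls, path) -> "Population":
        return cls.from_frame(pd.read_csv(path))
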