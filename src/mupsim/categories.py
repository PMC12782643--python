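"""Shared categorical vocabulary: beverages, age bands, drinker groups, subgroups.

The population is partitioned into 800 subgroups (4 age bands x 2 sexes x
5 income quintiles x 5 smoking groups x 4 drinker groups).  Alcohol is
tracked over 10 beverage categories: five drink types (beer, cider, wine,
spirits, RTDs) in each of two purchase channels (off-trade shops,
on-trade licensed premises).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AGE_BANDS: tuple[str, ...] = ("18-24", "25-34", "35-49", "50+")
AGE_BAND_LOWER = np.array([18, 25, 35, 50])
SEXES: tuple[str, ...] = ("female", "male")
SMOKING_GROUPS: tuple[str, ...] = (
    "non-smoker", ">0-10", ">10-20", ">20-30", ">30",
)
DRINKER_GROUPS: tuple[str, ...] = ("abstainer", "moderate", "hazardous", "harmful")
CONDITION_GROUPS: tuple[str, ...] = (
    "liver disease",
    "mental & behavioural due to alcohol",
    "cancers",
    "cardiovascular",
    "injuries",
    "other",
)

N_AGE_BANDS = len(AGE_BANDS)
N_SEXES = 2
N_INCOME = 5
N_SMOKING = len(SMOKING_GROUPS)
N_DRINKER_GROUPS = len(DRINKER_GROUPS)
N_SUBGROUPS = N_AGE_BANDS * N_SEXES * N_INCOME * N_SMOKING * N_DRINKER_GROUPS  # 800
N_SIMD = 5  # SIMD quintiles; 1 = least deprived, 5 = most deprived


@dataclass(frozen=True)
class BeverageCategory:
    """One of the 10 beverage categories (drink type x purchase channel)."""

    name: str     # beer, cider, wine, spirits, rtds
    channel: str  # off-trade, on-trade

    @property
    def label(self) -> str:
        return f"{self.channel}:{self.name}"


DRINK_TYPES: tuple[str, ...] = ("beer", "cider", "wine", "spirits", "rtds")
CHANNELS: tuple[str, ...] = ("off-trade", "on-trade")
BEVERAGES: tuple[BeverageCategory, ...] = tuple(
    BeverageCategory(name, channel) for channel in CHANNELS for name in DRINK_TYPES
)
N_BEVERAGES = len(BEVERAGES)  # 10
BEVERAGE_LABELS: tuple[str, ...] = tuple(b.label for b in BEVERAGES)
ON_TRADE_MASK = np.array([b.channel == "on-trade" for b in BEVERAGES])


def age_band_index(age: np.ndarray) -> np.ndarray:
    """Map integer ages (>=18) to age-band indices 0..3."""
    age = np.asarray(age)
    return np.searchsorted(AGE_BAND_LOWER, age, side="right") - 1


def subgroup_index(
    age_band: np.ndarray,
    sex: np.ndarray,
    income_quintile: np.ndarray,
    smoking_group: np.ndarray,
    drinker_group: np.ndarray,
) -> np.ndarray:
    """Flatten the five categorical axes into a subgroup id in 0..799.

    ``sex`` is coded 0 = female, 1 = male; ``income_quintile`` is 1..5;
    ``smoking_group`` and ``drinker_group`` are 0-based category indices.
    """
    idx = np.asarray(age_band)
    idx = idx * N_SEXES + np.asarray(sex)
    idx = idx * N_INCOME + (np.asarray(income_quintile) - 1)
    idx = idx * N_SMOKING + np.asarray(smoking_group)
    idx = idx * N_DRINKER_GROUPS + np.asarray(drinker_group)
    return idx


def subgroup_drinker_group(subgroup_id: np.ndarray) -> np.ndarray:
    """Recover the drinker-group index from a subgroup id."""
    return np.asarray(subgroup_id) % N_DRINKER_GROUPS


def subgroup_fields(subgroup_id: np.ndarray) -> dict[str, np.ndarray]:
    """Invert :func:`subgroup_index` into its five categorical components."""
    idx = np.asarray(subgroup_id)
    drinker = idx % N_DRINKER_GROUPS
    idx = idx // N_DRINKER_GROUPS
    smoking = idx % N_SMOKING
    idx = idx // N_SMOKING
    income = idx % N_INCOME + 1
    idx = idx // N_INCOME
    sex = idx % N_SEXES
    age_band = idx // N_SEXES
    return {
        "age_band": age_band,
        "sex": sex,
        "income_quintile": income,
        "smoking_group": smoking,
        "drinker_group": drinker,
    }
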