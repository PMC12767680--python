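"""Energy shares, sodium estimation and hyper-palatability classification.

Energy shares (E%) use the EU labelling conversion factors: fat 37 kJ/g,
carbohydrate and sugar 17 kJ/g, divided by the *declared* total energy in
kJ/100 g.  Sodium is estimated as 40% of declared salt.  Products are then
classified against the three hyper-palatability criteria (fat+sodium,
fat+sugar, carbohydrate+sodium); meeting two or more puts a product in the
"fits more than one" class, and beverages are excluded from the
classification altogether.

Energy-share thresholds are strict (>); sodium thresholds are non-strict
(≥).  The fat threshold of the fat+sodium criterion defaults to 5 E% and is
configurable (``fat_sodium_fat_epct``) because the primary literature on
the criterion uses 25 E%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KJ_PER_G_FAT",
    "KJ_PER_G_CARB",
    "SODIUM_PER_SALT",
    "EnergyShares",
    "HPThresholds",
    "HPClass",
    "energy_shares",
    "classify_hp",
    "annotate_nutrition",
]

KJ_PER_G_FAT = 37.0
KJ_PER_G_CARB = 17.0
SODIUM_PER_SALT = 0.40


class HPClass:
    """Hyper-palatability labels."""

    NOT_HP = "NotHP"
    FAT_SUGAR = "FatSugar"
    FAT_SODIUM = "FatSodium"
    CARB_SODIUM = "CarbSodium"
    FITS_MORE_THAN_ONE = "FitsMoreThanOne"
    EXCLUDED_BEVERAGE = "ExcludedBeverage"

    ALL = (NOT_HP, FAT_SUGAR, FAT_SODIUM, CARB_SODIUM, FITS_MORE_THAN_ONE,
           EXCLUDED_BEVERAGE)


@dataclass(frozen=True)
class EnergyShares:
    e_pct_fat: float
    e_pct_carb: float
    e_pct_sugar: float
    e_pct_carb_nosugar: float
    sodium_g: float  # g per 100 g product


@dataclass(frozen=True)
class HPThresholds:
    fat_sodium_fat_epct: float = 5.0
    fat_sodium_sodium_pct: float = 0.30
    fat_sugar_fat_epct: float = 20.0
    fat_sugar_sugar_epct: float = 20.0
    carb_sodium_carb_epct: float = 40.0
    carb_sodium_sodium_pct: float = 0.20


def energy_shares(
    fat_g: float,
    carb_g: float,
    sugar_g: float,
    salt_g: float,
    energy_kj: float,
) -> EnergyShares:
    """Compute E% shares and estimated sodium from declared nutrition.

    Requires a positive declared energy; records without one cannot survive
    eligibility.  Carbohydrate-without-sugar is clamped at zero as a guard
    (declared sugar above carbohydrate is filtered out upstream).
    """
    if energy_kj is None or not np.isfinite(energy_kj) or energy_kj <= 0:
        raise ValueError("energy_kj must be positive to compute energy shares")
    fat_g = 0.0 if fat_g is None or not np.isfinite(fat_g) else fat_g
    carb_g = 0.0 if carb_g is None or not np.isfinite(carb_g) else carb_g
    sugar_g = 0.0 if sugar_g is None or not np.isfinite(sugar_g) else sugar_g
    salt_g = 0.0 if salt_g is None or not np.isfinite(salt_g) else salt_g
    scale = 100.0 / energy_kj
    return EnergyShares(
        e_pct_fat=fat_g * KJ_PER_G_FAT * scale,
        e_pct_carb=carb_g * KJ_PER_G_CARB * scale,
        e_pct_sugar=sugar_g * KJ_PER_G_CARB * scale,
        e_pct_carb_nosugar=max(carb_g - sugar_g, 0.0) * KJ_PER_G_CARB * scale,
        sodium_g=SODIUM_PER_SALT * salt_g,
    )


def classify_hp(
    shares: EnergyShares,
    is_beverage: bool = False,
    thresholds: HPThresholds | None = None,
) -> str:
    """Assign the hyper-palatability class for one product."""
    if is_beverage:
        return HPClass.EXCLUDED_BEVERAGE
    t = thresholds or HPThresholds()
    crit_fat_sodium = (
        shares.e_pct_fat > t.fat_sodium_fat_epct
        and shares.sodium_g >= t.fat_sodium_sodium_pct
    )
    crit_fat_sugar = (
        shares.e_pct_fat > t.fat_sugar_fat_epct
        and shares.e_pct_sugar > t.fat_sugar_sugar_epct
    )
    crit_carb_sodium = (
        shares.e_pct_carb_nosugar > t.carb_sodium_carb_epct
        and shares.sodium_g >= t.carb_sodium_sodium_pct
    )
    n_met = sum([crit_fat_sodium, crit_fat_sugar, crit_carb_sodium])
    if n_met == 0:
        return HPClass.NOT_HP
    if n_met > 1:
        return HPClass.FITS_MORE_THAN_ONE
    if crit_fat_sodium:
        return HPClass.FAT_SODIUM
    if crit_fat_sugar:
        return HPClass.FAT_SUGAR
    return HPClass.CARB_SODIUM


def annotate_nutrition(
    products: pd.DataFrame,
    thresholds: HPThresholds | None = None,
    beverage_group: str = "Beverages",
) -> pd.DataFrame:
    """Append E% shares, sodium and the HP class to a products frame."""
    out = products.copy()
    cols = {k: [] for k in
            ("e_pct_fat", "e_pct_sugar", "e_pct_carb", "e_pct_carb_nosugar",
             "sodium_g", "hp_class")}
    for _, row in out.iterrows():
        sh = energy_shares(
            row.get("fat_g"), row.get("carb_g"), row.get("sugar_g"),
            row.get("salt_g"), row.get("energy_kj"),
        )
        cols["e_pct_fat"].append(sh.e_pct_fat)
        cols["e_pct_sugar"].append(sh.e_pct_sugar)
        cols["e_pct_carb"].append(sh.e_pct_carb)
        cols["e_pct_carb_nosugar"].append(sh.e_pct_carb_nosugar)
        cols["sodium_g"].append(sh.sodium_g)
        cols["hp_class"].append(
            classify_hp(sh, row.get("group") == beverage_group, thresholds)
        )
    for k, v in cols.items():
        out[k] = v
    return out
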