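"""Reading raw product tables, eligibility filtering and food-group harmonization.

Product records arrive from two source databases with different schemas and
group vocabularies.  Eligibility removes, in a fixed linear order mirroring
an inclusion flow chart: non-food items, products without an ingredient
list, products with unrealistic declared nutrition, and duplicates (same
GTIN or same normalized name).  Each excluded record is tallied under the
*first* rule it violates, so the input count always equals eligible + sum
of tallies.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .lexicon import Lexicon, detect_ets, load_default_lexicon

__all__ = [
    "FOOD_GROUPS",
    "NUTRIENT_COLUMNS",
    "EXCLUSION_REASONS",
    "EligibilityReport",
    "read_products",
    "load_default_group_map",
    "harmonize_food_group",
    "is_unrealistic",
    "apply_eligibility",
    "annotate_ets",
]

#: the 16-group taxonomy every product is mapped onto
FOOD_GROUPS: tuple[str, ...] = (
    "Desserts & Ice Creams",
    "Beverages",
    "Fish & Shellfish",
    "Meat & Poultry",
    "Fats, Margarine & Spreads",
    "Premade Food & Dinner Kits",
    "Snacks, Chocolate & Sweets",
    "Bakery, Cakes & Pastries",
    "Eggs & Dairy Products",
    "Grains, Baking Mixes & Cereals",
    "Baking Condiments",
    "Sauces, Dressings & Other Dinner Condiments",
    "Processed Fruits & Vegetables",
    "Fruit, Vegetables & Legumes",
    "Infant Food",
    "Others",
)

NUTRIENT_COLUMNS = ("fat_g", "satfat_g", "carb_g", "sugar_g", "protein_g", "salt_g")

CANONICAL_COLUMNS = (
    "gtin",
    "name",
    "source",
    "raw_group",
    "is_food",
    "ingredient_text",
    "energy_kj",
    "energy_kcal",
) + NUTRIENT_COLUMNS

#: exclusion reasons in flow-chart order; first triggered reason is charged
EXCLUSION_REASONS = (
    "non_food",
    "no_ingredients",
    "nutrient_gt_100",
    "sugar_gt_carb",
    "satfat_gt_fat",
    "no_energy",
    "energy_gt_4200",
    "bad_kj_kcal_ratio",
    "duplicate",
)

# declared kJ/kcal must sit in 4.184 +/- 0.2 unless the product is
# essentially energy-free (kJ < 10 and kcal < 2)
RATIO_LO, RATIO_HI = 3.984, 4.384
ENERGY_MAX_KJ = 4200.0


@dataclass
class EligibilityReport:
    """Counts of input, per-reason exclusions and eligible products."""

    n_input: int
    tallies: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )
    n_eligible: int = 0

    def check(self) -> None:
        if self.n_input != self.n_eligible + sum(self.tallies.values()):
            raise AssertionError("eligibility conservation violated")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "tallies": self.tallies,
                "n_eligible": self.n_eligible,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def read_products(path: str | Path, schema: Mapping[str, str] | str | Path | None = None) -> pd.DataFrame:
    """Read a raw product table (CSV or JSON-lines) into canonical columns.

    ``schema`` maps source column names to canonical field names; it may be
    a mapping or a path to a YAML file containing one.  Missing canonical
    columns are added as NA.
    """
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson", ".json"}:
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path)
    if schema is not None:
        if not isinstance(schema, Mapping):
            schema = yaml.safe_load(Path(schema).read_text())
        df = df.rename(columns=dict(schema))
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    for col in ("energy_kj", "energy_kcal") + NUTRIENT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[list(CANONICAL_COLUMNS)].copy()


def load_default_group_map() -> dict[str, str]:
    with resources.files("etscan.data").joinpath("food_groups.yml").open(
        "r", encoding="utf-8"
    ) as fh:
        return {str(k).lower(): str(v) for k, v in yaml.safe_load(fh).items()}


def harmonize_food_group(
    raw_group: str | None, mapping: Mapping[str, str] | None = None
) -> str | None:
    """Map a raw source group label onto the 16-group taxonomy.

    Already-canonical names pass through; unmapped non-empty labels fall
    back to "Others"; an absent label returns ``None`` (needs manual
    assignment).
    """
    if raw_group is None or (isinstance(raw_group, float) and np.isnan(raw_group)):
        return None
    raw = str(raw_group).strip()
    if not raw:
        return None
    if raw in FOOD_GROUPS:
        return raw
    mapping = load_default_group_map() if mapping is None else mapping
    return mapping.get(raw.lower(), "Others")


def _num(value) -> float | None:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(v) else v


def is_unrealistic(record: Mapping) -> list[str]:
    """List every unrealistic-nutrition rule a record violates.

    Rules, each only evaluable when its fields are present: any single
    nutrient above 100 g/100 g; sugar above total carbohydrate; saturated
    fat above total fat; no declared energy; more than 4,200 kJ/100 g;
    declared kJ/kcal ratio outside [3.984, 4.384].  The ratio check is
    skipped for near-zero-energy products (kJ < 10 and kcal < 2).
    """
    reasons: list[str] = []
    nutrients = {c: _num(record.get(c)) for c in NUTRIENT_COLUMNS}
    if any(v is not None and v > 100.0 for v in nutrients.values()):
        reasons.append("nutrient_gt_100")
    sugar, carb = nutrients["sugar_g"], nutrients["carb_g"]
    if sugar is not None and carb is not None and sugar > carb:
        reasons.append("sugar_gt_carb")
    satfat, fat = nutrients["satfat_g"], nutrients["fat_g"]
    if satfat is not None and fat is not None and satfat > fat:
        reasons.append("satfat_gt_fat")
    kj = _num(record.get("energy_kj"))
    kcal = _num(record.get("energy_kcal"))
    if kj is None or kj <= 0:
        reasons.append("no_energy")
    elif kj > ENERGY_MAX_KJ:
        reasons.append("energy_gt_4200")
    if kj is not None and kcal is not None and kj > 0:
        low_energy = kj < 10 and kcal < 2
        if not low_energy:
            if kcal <= 0 or not (RATIO_LO <= kj / kcal <= RATIO_HI):
                reasons.append("bad_kj_kcal_ratio")
    return reasons


def _norm_name(name) -> str:
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return ""
    return re.sub(r"\s+", " ", str(name)).strip().casefold()


def apply_eligibility(
    records: pd.DataFrame,
    group_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Apply the full eligibility cascade and return eligible products.

    Exclusion order: non-food, missing ingredient list, unrealistic
    nutrition (first violated sub-rule charged), duplicates.  Duplicates are
    resolved after a deterministic stable sort by (source, gtin), keeping
    the first record per GTIN and per normalized name.  The returned frame
    gains a harmonized ``group`` column.
    """
    report = EligibilityReport(n_input=len(records))
    if len(records) == 0:
        out = records.copy()
        out["group"] = pd.Series(dtype=object)
        return out, report

    df = records.copy().reset_index(drop=True)
    reason = pd.Series([None] * len(df), dtype=object)

    is_food = df["is_food"].fillna(True).astype(bool)
    reason[~is_food] = "non_food"

    no_ingr = df["ingredient_text"].isna() | (
        df["ingredient_text"].astype(str).str.strip() == ""
    )
    reason[reason.isna() & no_ingr] = "no_ingredients"

    for idx in df.index[reason.isna()]:
        bad = is_unrealistic(df.loc[idx])
        if bad:
            reason[idx] = bad[0]

    # duplicates: deterministic sort, first occurrence per GTIN / name wins
    survivors = df.index[reason.isna()]
    sub = df.loc[survivors].copy()
    sub["_name_key"] = sub["name"].map(_norm_name)
    sub["_gtin_key"] = sub["gtin"].astype(str).str.strip()
    order = sub.sort_values(["source", "_gtin_key"], kind="stable").index
    seen_gtin: set[str] = set()
    seen_name: set[str] = set()
    for idx in order:
        g = sub.at[idx, "_gtin_key"]
        n = sub.at[idx, "_name_key"]
        dup = (g != "" and g.lower() not in {"none", "nan"} and g in seen_gtin) or (
            n != "" and n in seen_name
        )
        if dup:
            reason[idx] = "duplicate"
        else:
            if g != "":
                seen_gtin.add(g)
            if n != "":
                seen_name.add(n)

    for r in reason.dropna():
        report.tallies[r] += 1
    keep = df.loc[reason.isna()].copy()
    report.n_eligible = len(keep)
    report.check()

    mapping = load_default_group_map() if group_map is None else group_map
    keep["group"] = [
        harmonize_food_group(rg, mapping) or "Others" for rg in keep["raw_group"]
    ]
    return keep.reset_index(drop=True), report


def annotate_ets(products: pd.DataFrame, lexicon: Lexicon | None = None) -> pd.DataFrame:
    """Add detected ETS codes (``ets_codes`` frozensets) and ``n_ets`` counts."""
    lex = load_default_lexicon() if lexicon is None else lexicon
    out = products.copy()
    out["ets_codes"] = [
        frozenset(detect_ets(t if isinstance(t, str) else "", lex))
        for t in out["ingredient_text"]
    ]
    out["n_ets"] = out["ets_codes"].map(len)
    return out
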