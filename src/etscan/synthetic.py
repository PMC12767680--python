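"""Seed-reproducible synthetic food market with analytic ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: two source schemas with different food-group vocabularies,
ingredient texts mixing E-numbers, plaintext names, misspellings and
subclass tokens, correlated additive inclusion, per-group nutrition
profiles, and injected ineligible/duplicate records.

Additive co-occurrence within a food group follows an *archetype mixture*:
a product first draws an archetype ``a`` with weight ``w_a`` and then
includes each additive ``c`` independently with probability ``p_{a,c}``.
The mixture has closed forms for the marginal P(c) = Σ_a w_a p_{a,c}, the
k-way at-least probability P(S) = Σ_a w_a ∏_{c∈S} p_{a,c}, and hence the
fold enrichment FE(S) = P(S) / ∏_{c∈S} P(c), which recovery tests compare
against pipeline estimates.  A single-archetype group is exactly
independent (FE ≡ 1).

Nutrition is drawn per group: total solids ~ Beta, split into
fat/carbohydrate/protein/other by a Dirichlet, sugar and saturated fat as
Beta fractions of their parents (so sugar ≤ carbohydrate and saturated fat
≤ fat hold by construction), salt log-normal, and declared energy derived
from the macros with mild noise so clean records always pass the
eligibility filters.  Defects are then injected at configured rates, each
violating exactly its own rule, with exact per-reason ground-truth counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .ingest import EXCLUSION_REASONS, FOOD_GROUPS, load_default_group_map
from .lexicon import Lexicon, load_default_lexicon
from .nutrition import HPClass, classify_hp, energy_shares

__all__ = [
    "Archetype",
    "GroupSpec",
    "MarketConfig",
    "GroundTruth",
    "generate_market",
    "render_ingredient_text",
    "sample_ets_sets",
    "sample_profile_for_class",
    "RENDER_STYLES",
]

RENDER_STYLES = ("enumber", "name", "misspelling", "subclass")

# benign ingredients that never match the additive lexicon
FILLERS = (
    "water", "sugar", "salt", "wheat flour", "rapeseed oil", "skimmed milk",
    "yeast", "tomato", "rice", "spices", "natural flavouring", "vinegar",
    "potato starch", "cocoa mass", "egg", "onion", "cream", "barley malt",
)

_FUNCTION_WORDS = ("stabiliser", "emulsifier", "thickener")

_DEFAULT_NUTRITION = {
    "solids_a": 2.0, "solids_b": 3.0,
    "fat_share": 2.0, "carb_share": 4.0, "protein_share": 2.0, "other_share": 2.0,
    "sugar_frac_a": 1.5, "sugar_frac_b": 4.0,
    "satfat_frac_a": 2.0, "satfat_frac_b": 3.0,
    "salt_med": 0.8, "salt_sigma": 0.6,
}


@dataclass(frozen=True)
class Archetype:
    weight: float
    probs: dict[str, float]


@dataclass
class GroupSpec:
    n: int
    archetypes: list[Archetype]
    nutrition: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NUTRITION))


@dataclass
class MarketConfig:
    """Generative parameters of the synthetic market."""

    groups: dict[str, GroupSpec]
    style_probs: dict[str, float]
    defect_rates: dict[str, float]
    seed: int = 0

    def validate(self) -> None:
        for name, spec in self.groups.items():
            if spec.n < 0:
                raise ValueError(f"group {name!r}: negative size")
            w = sum(a.weight for a in spec.archetypes)
            if not math.isclose(w, 1.0, abs_tol=1e-9):
                raise ValueError(f"group {name!r}: archetype weights sum to {w}")
            for a in spec.archetypes:
                for code, p in a.probs.items():
                    if not (0.0 <= p <= 1.0):
                        raise ValueError(
                            f"group {name!r}: P({code}) = {p} outside [0, 1]"
                        )
            nut = spec.nutrition
            for key in _DEFAULT_NUTRITION:
                v = nut.get(key)
                if v is None or (key != "salt_med" and v <= 0):
                    raise ValueError(f"group {name!r}: bad nutrition param {key}={v}")
        s = sum(self.style_probs.get(k, 0.0) for k in RENDER_STYLES)
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError(f"style probabilities sum to {s}, expected 1")
        for reason, rate in self.defect_rates.items():
            if reason not in EXCLUSION_REASONS:
                raise ValueError(f"unknown defect reason {reason!r}")
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"defect rate {reason}={rate} outside [0, 1)")

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.groups.values())

    @classmethod
    def from_dict(cls, raw: Mapping) -> "MarketConfig":
        groups = {}
        for name, g in raw["groups"].items():
            archetypes = [
                Archetype(weight=float(a["weight"]),
                          probs={str(c): float(p) for c, p in (a.get("probs") or {}).items()})
                for a in g["archetypes"]
            ]
            nut = dict(_DEFAULT_NUTRITION)
            nut.update(g.get("nutrition") or {})
            groups[str(name)] = GroupSpec(n=int(g["n"]), archetypes=archetypes,
                                          nutrition=nut)
        cfg = cls(
            groups=groups,
            style_probs={k: float(v) for k, v in raw["style_probs"].items()},
            defect_rates={k: float(v) for k, v in raw["defect_rates"].items()},
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarketConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls, seed: int | None = None, scale: float = 1.0) -> "MarketConfig":
        """The packaged "norway-like" market, optionally size-scaled."""
        with resources.files("etscan.data").joinpath("market_norway_like.yml").open(
            "r", encoding="utf-8"
        ) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls.from_dict(raw)
        if seed is not None:
            cfg.seed = int(seed)
        if scale != 1.0:
            for spec in cfg.groups.values():
                spec.n = max(1, int(round(spec.n * scale)))
        return cfg


@dataclass
class GroundTruth:
    """Per-product truth labels plus analytic mixture quantities."""

    ets_sets: list[frozenset]
    hp_class: list[str | None]
    defects: list[str | None]
    groups: list[str]
    config: MarketConfig
    expected_tallies: dict[str, int]

    def marginal(self, group: str, code: str) -> float:
        spec = self.config.groups[group]
        return sum(a.weight * a.probs.get(code, 0.0) for a in spec.archetypes)

    def at_least_prob(self, group: str, combo: Iterable[str]) -> float:
        spec = self.config.groups[group]
        combo = list(combo)
        return sum(
            a.weight * float(np.prod([a.probs.get(c, 0.0) for c in combo]))
            for a in spec.archetypes
        )

    def fold_enrichment(self, group: str, combo: Iterable[str]) -> float:
        combo = list(combo)
        denom = float(np.prod([self.marginal(group, c) for c in combo]))
        if denom == 0:
            return math.nan
        return self.at_least_prob(group, combo) / denom


def sample_ets_sets(spec: GroupSpec, n: int, rng: np.random.Generator) -> list[frozenset]:
    """Draw n additive sets from a group's archetype mixture."""
    weights = np.array([a.weight for a in spec.archetypes])
    choice = rng.choice(len(spec.archetypes), size=n, p=weights / weights.sum())
    out: list[frozenset] = []
    for i in range(n):
        a = spec.archetypes[choice[i]]
        if not a.probs:
            out.append(frozenset())
            continue
        codes = list(a.probs)
        u = rng.random(len(codes))
        out.append(frozenset(c for c, uu in zip(codes, u) if uu < a.probs[c]))
    return out


def _enumber_token(code: str, rng: np.random.Generator) -> str:
    digits = code[1:]
    forms = (f"E{digits}", f"E {digits}", f"E-{digits}", f"e{digits}")
    return forms[rng.integers(0, len(forms))]


def _subclass_token(code: str, lexicon: Lexicon, rng: np.random.Generator) -> str | None:
    subs = [s for s, main in lexicon.subclass_map.items() if main == code]
    if not subs:
        return None
    return sorted(subs)[rng.integers(0, len(subs))]


def render_ingredient_text(
    ets_set: Iterable[str],
    lexicon: Lexicon | None = None,
    rng: np.random.Generator | None = None,
    style: str | None = None,
    style_probs: Mapping[str, float] | None = None,
) -> str:
    """Render an additive set into a realistic ingredient list.

    Every rendered additive token is guaranteed to be detected back as its
    main-class code (round-trip property).  ``style`` forces one rendering
    style for all tokens; otherwise each token draws a style from
    ``style_probs``.  Styles without material for a code (no misspelling
    recorded, no subclasses) fall back to plaintext / E-number form.
    """
    lexicon = load_default_lexicon() if lexicon is None else lexicon
    rng = np.random.default_rng() if rng is None else rng
    probs = style_probs or {s: 1.0 / len(RENDER_STYLES) for s in RENDER_STYLES}

    n_fill = int(rng.integers(3, 7))
    tokens = list(rng.choice(FILLERS, size=n_fill, replace=False))
    for code in sorted(ets_set):
        entry = lexicon.entries[code]
        st = style
        if st is None:
            p = np.array([probs.get(s, 0.0) for s in RENDER_STYLES])
            st = RENDER_STYLES[rng.choice(len(RENDER_STYLES), p=p / p.sum())]
        if st == "enumber":
            tok = _enumber_token(code, rng)
        elif st == "name":
            names = (entry.canonical_name,) + entry.synonyms
            tok = names[rng.integers(0, len(names))]
        elif st == "misspelling":
            if entry.misspellings:
                tok = entry.misspellings[rng.integers(0, len(entry.misspellings))]
            else:
                tok = entry.canonical_name
        elif st == "subclass":
            tok = _subclass_token(code, lexicon, rng) or _enumber_token(code, rng)
        else:
            raise ValueError(f"unknown rendering style {st!r}")
        if rng.random() < 0.25:
            fn = _FUNCTION_WORDS[rng.integers(0, len(_FUNCTION_WORDS))]
            tok = f"{fn} ({tok})"
        tokens.append(tok)
    order = rng.permutation(len(tokens))
    return ", ".join(tokens[i] for i in order)


def _sample_nutrition(nut: Mapping[str, float], rng: np.random.Generator) -> dict:
    solids = 100.0 * rng.beta(nut["solids_a"], nut["solids_b"])
    shares = rng.dirichlet(
        [nut["fat_share"], nut["carb_share"], nut["protein_share"], nut["other_share"]]
    )
    fat = solids * shares[0]
    carb = solids * shares[1]
    protein = solids * shares[2]
    sugar = carb * rng.beta(nut["sugar_frac_a"], nut["sugar_frac_b"])
    satfat = fat * rng.beta(nut["satfat_frac_a"], nut["satfat_frac_b"])
    salt = min(float(rng.lognormal(math.log(max(nut["salt_med"], 1e-3)),
                                   nut["salt_sigma"])), 8.0)
    energy = (37.0 * fat + 17.0 * carb + 17.0 * protein) * rng.uniform(0.98, 1.06)
    energy = float(np.clip(energy, 50.0, 4200.0))
    energy = round(energy, 1)
    kcal = _consistent_kcal(energy)
    return {
        "energy_kj": energy,
        "energy_kcal": kcal,
        "fat_g": round(fat, 2),
        "satfat_g": round(min(satfat, fat), 2),
        "carb_g": round(carb, 2),
        "sugar_g": round(min(sugar, carb), 2),
        "protein_g": round(protein, 2),
        "salt_g": round(salt, 3),
    }


def _consistent_kcal(kj: float) -> int:
    """Integer kcal whose kJ/kcal ratio sits in the accepted band."""
    k = max(int(round(kj / 4.184)), 1)
    if kj / k > 4.384:
        k += 1
    elif kj / k < 3.984:
        k = max(k - 1, 1)
    return k


def _raw_group_labels() -> dict[str, list[str]]:
    inverse: dict[str, list[str]] = {g: [g] for g in FOOD_GROUPS}
    for raw, canon in load_default_group_map().items():
        inverse.setdefault(canon, [canon]).append(raw)
    return {g: sorted(v) for g, v in inverse.items()}


def generate_market(
    config: MarketConfig, lexicon: Lexicon | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the raw product table plus exact ground truth.

    Output is reproducible for a fixed config and seed.  Injected defects
    each violate exactly one eligibility rule, are disjoint across rules,
    and their per-reason counts are returned in ``truth.expected_tallies``
    (duplicates are extra appended rows sharing a clean row's GTIN).
    """
    config.validate()
    lexicon = load_default_lexicon() if lexicon is None else lexicon
    rng = np.random.default_rng(config.seed)
    raw_labels = _raw_group_labels()

    rows: list[dict] = []
    ets_sets: list[frozenset] = []
    groups: list[str] = []
    counter = 0
    for gname, spec in config.groups.items():
        sets = sample_ets_sets(spec, spec.n, rng)
        labels = raw_labels.get(gname, [gname])
        for s in sets:
            nut = _sample_nutrition(spec.nutrition, rng)
            source = "db_A" if rng.random() < 0.5 else "db_B"
            row = {
                "gtin": str(7000000000000 + counter),
                "name": f"Product {counter:06d}",
                "source": source,
                "raw_group": labels[rng.integers(0, len(labels))],
                "is_food": True,
                "ingredient_text": render_ingredient_text(
                    s, lexicon, rng, style_probs=config.style_probs
                ),
                **nut,
            }
            rows.append(row)
            ets_sets.append(s)
            groups.append(gname)
            counter += 1

    n_clean = len(rows)
    defects: list[str | None] = [None] * n_clean
    tallies = {r: 0 for r in EXCLUSION_REASONS}

    # disjoint defect assignment over existing rows (duplicates appended)
    mutating = [r for r in EXCLUSION_REASONS if r != "duplicate"]
    wanted = {r: int(round(config.defect_rates.get(r, 0.0) * n_clean)) for r in mutating}
    pool = rng.permutation(n_clean)
    cursor = 0
    for reason in mutating:
        for _ in range(wanted[reason]):
            if cursor >= n_clean:
                break
            i = int(pool[cursor])
            cursor += 1
            _inject_defect(rows[i], reason)
            defects[i] = reason
            tallies[reason] += 1

    n_dup = int(round(config.defect_rates.get("duplicate", 0.0) * n_clean))
    clean_idx = [i for i in range(n_clean) if defects[i] is None]
    if n_dup and clean_idx:
        picks = rng.choice(len(clean_idx), size=n_dup, replace=False)
        for j in picks:
            src = rows[clean_idx[int(j)]]
            dup = dict(src)
            dup["name"] = src["name"] + " (dup)"
            rows.append(dup)
            ets_sets.append(ets_sets[clean_idx[int(j)]])
            groups.append(groups[clean_idx[int(j)]])
            defects.append("duplicate")
            tallies["duplicate"] += 1

    records = pd.DataFrame(rows)

    hp: list[str | None] = []
    for row, gname, defect in zip(rows, groups, defects):
        kj = row.get("energy_kj")
        if defect is not None and (kj is None or not np.isfinite(kj) or kj <= 0):
            hp.append(None)
            continue
        shares = energy_shares(
            row["fat_g"], row["carb_g"], row["sugar_g"], row["salt_g"], kj
        )
        hp.append(classify_hp(shares, gname == "Beverages"))

    truth = GroundTruth(
        ets_sets=ets_sets,
        hp_class=hp,
        defects=defects,
        groups=groups,
        config=config,
        expected_tallies=tallies,
    )
    return records, truth


def _inject_defect(row: dict, reason: str) -> None:
    if reason == "non_food":
        row["is_food"] = False
    elif reason == "no_ingredients":
        row["ingredient_text"] = ""
    elif reason == "nutrient_gt_100":
        row["protein_g"] = 150.0
    elif reason == "sugar_gt_carb":
        row["carb_g"] = min(row["carb_g"], 80.0)
        row["sugar_g"] = row["carb_g"] + 5.0
    elif reason == "satfat_gt_fat":
        row["fat_g"] = min(row["fat_g"], 80.0)
        row["satfat_g"] = row["fat_g"] + 5.0
    elif reason == "no_energy":
        row["energy_kj"] = np.nan
        row["energy_kcal"] = np.nan
    elif reason == "energy_gt_4200":
        row["energy_kj"] = 4800.0
        row["energy_kcal"] = _consistent_kcal(4800.0)
    elif reason == "bad_kj_kcal_ratio":
        row["energy_kcal"] = int(round(row["energy_kj"] / 3.0))
    else:
        raise ValueError(f"cannot inject defect {reason!r}")


def sample_profile_for_class(
    label: str, rng: np.random.Generator, energy_kj: float = 1000.0
) -> dict:
    """Nutrition profile lying strictly inside one HP criterion region.

    Returns declared-nutrition keyword arguments for
    :func:`etscan.nutrition.energy_shares` such that the classifier must
    return ``label``.  Useful for label-recovery checks.
    """
    def g_fat(epct):  # grams giving a target fat E%
        return epct * energy_kj / 3700.0

    def g_carb(epct):
        return epct * energy_kj / 1700.0

    u = rng.uniform
    if label == HPClass.FAT_SODIUM:
        fat_e = u(6, 18)          # above 5, below the fat+sugar threshold
        sugar_e = u(0, 15)
        carbns_e = u(0, 35)
        salt = u(0.80, 2.0)       # sodium >= 0.32
    elif label == HPClass.FAT_SUGAR:
        fat_e = u(22, 40)
        sugar_e = u(22, 40)
        carbns_e = u(0, 35)
        salt = u(0.0, 0.45)       # sodium < 0.18: criteria 1 and 3 both off
    elif label == HPClass.CARB_SODIUM:
        fat_e = u(0, 4.5)         # criterion 1 off regardless of sodium
        sugar_e = u(0, 15)
        carbns_e = u(42, 70)
        salt = u(0.55, 2.0)       # sodium >= 0.22
    elif label == HPClass.FITS_MORE_THAN_ONE:
        fat_e = u(22, 40)         # criteria 1 and 2 both on
        sugar_e = u(22, 40)
        carbns_e = u(0, 35)
        salt = u(0.80, 2.0)
    elif label == HPClass.NOT_HP:
        fat_e = u(0, 4.5)
        sugar_e = u(0, 15)
        carbns_e = u(0, 35)
        salt = u(0.0, 0.45)
    else:
        raise ValueError(f"cannot construct a profile for label {label!r}")
    carb_g = g_carb(sugar_e + carbns_e)
    sugar_g = g_carb(sugar_e)
    return {
        "fat_g": g_fat(fat_e),
        "carb_g": carb_g,
        "sugar_g": sugar_g,
        "salt_g": salt,
        "energy_kj": energy_kj,
    }
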