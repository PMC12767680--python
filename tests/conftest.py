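from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from etscan.lexicon import load_default_lexicon
from etscan.stats import PresenceMatrix


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


def _valid_record(i: int, **overrides) -> dict:
    rec = {
        "gtin": f"70000000{i:05d}",
        "name": f"Fixture product {i}",
        "source": "db_A",
        "raw_group": "iskrem",
        "is_food": True,
        "ingredient_text": "water, sugar, karagenan",
        "energy_kj": 1000.0,
        "energy_kcal": 239.0,  # ratio 4.184
        "fat_g": 10.0,
        "satfat_g": 3.0,
        "carb_g": 20.0,
        "sugar_g": 10.0,
        "protein_g": 5.0,
        "salt_g": 1.0,
    }
    rec.update(overrides)
    return rec


@pytest.fixture()
def twelve_record_fixture() -> pd.DataFrame:
    """Hand-enumerated eligibility fixture: 3 valid + one violation per rule.

    Expected outcome: 3 eligible, every exclusion tally equal to 1.
    """
    rows = [
        _valid_record(0),
        _valid_record(1),
        _valid_record(2),
        _valid_record(3, is_food=False),
        _valid_record(4, ingredient_text=""),
        _valid_record(5, fat_g=101.0, satfat_g=3.0),
        _valid_record(6, sugar_g=25.0, carb_g=20.0),
        _valid_record(7, satfat_g=12.0, fat_g=10.0),
        _valid_record(8, energy_kj=np.nan, energy_kcal=np.nan),
        _valid_record(9, energy_kj=4500.0, energy_kcal=1076.0),  # ratio 4.182
        _valid_record(10, energy_kj=1000.0, energy_kcal=300.0),  # ratio 3.33
        _valid_record(11, gtin="7000000000000", name="Same barcode, other name"),
    ]
    rows[0]["gtin"] = "7000000000000"
    return pd.DataFrame(rows)


def sets_to_matrix(sets, codes, group: str = "g") -> PresenceMatrix:
    """Build a PresenceMatrix directly from additive sets (test helper)."""
    arr = np.zeros((len(sets), len(codes)), dtype=bool)
    pos = {c: j for j, c in enumerate(codes)}
    for i, s in enumerate(sets):
        for c in s:
            if c in pos:
                arr[i, pos[c]] = True
    data = pd.DataFrame(arr, columns=list(codes))
    return PresenceMatrix(data=data, groups=pd.Series([group] * len(sets)), group=group)
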