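"""E400–E499 additive dictionary and ingredient-list detection.

The additive class E400–E499 covers emulsifiers, thickeners and stabilizers
(ETS).  Ingredient lists declare them either by E-number ("E407", "E 407",
"E-407", subclass tokens like "E472a") or by name ("carrageenan",
"guarkjernemel"), frequently misspelled.  Each lexicon entry therefore
carries a compiled regular expression covering the E-number form, every
literal synonym/misspelling, and optional hand-written pattern fragments
(the carrageenan pattern ``(c|k)ar*age*nan`` is the template style).

Detection returns the deduplicated set of main-class codes: subclass tokens
(E472a, E472b, …) count as their main class, and an additive listed twice in
one product counts once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EtsEntry",
    "Lexicon",
    "compile_lexicon",
    "load_default_lexicon",
    "detect_ets",
    "lump",
    "LUMP_GROUPS",
]

#: paper-style lumps of near-identical additives, applied before enrichment
#: testing: alginates, sugar alcohols, phosphates, fatty-acid derivatives.
LUMP_GROUPS: dict[str, tuple[int, int]] = {
    "E40x": (400, 404),
    "E42x": (420, 422),
    "E45x": (450, 452),
    "E47x": (470, 477),
}

_CODE_RE = re.compile(r"^E4[0-9]{2}[a-z]?$")

# subclass tokens that fold into a main class (E472a–f etc.)
_SUBCLASSES: dict[str, list[str]] = {
    "E407": ["E407a"],
    "E450": ["E450i", "E450ii"],
    "E470": ["E470a", "E470b"],
    "E472": [f"E472{c}" for c in "abcdef"],
}

_BOUND_L = r"(?<![a-z0-9])"
_BOUND_R = r"(?![a-z0-9])"


@dataclass(frozen=True)
class EtsEntry:
    """One additive: its code, names, matching pattern and metadata."""

    code: str
    canonical_name: str
    synonyms: tuple[str, ...]
    misspellings: tuple[str, ...]
    pattern: str
    lump_group: str  # one of LUMP_GROUPS keys or "self"
    fate: str  # "non_absorbed" | "absorbed"
    regex: re.Pattern = field(repr=False, compare=False, default=None)

    def enumber_pattern(self) -> str:
        digits = re.sub(r"[^0-9]", "", self.code)
        return rf"e[ -]?{digits}(?:[a-f]|i{{1,3}})?"


@dataclass
class Lexicon:
    """Compiled additive dictionary keyed by main-class code."""

    entries: dict[str, EtsEntry]
    subclass_map: dict[str, str]

    @property
    def codes(self) -> list[str]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, code: str) -> EtsEntry:
        return self.entries[code]

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "code": e.code,
                "canonical_name": e.canonical_name,
                "synonyms": "|".join(e.synonyms),
                "misspellings": "|".join(e.misspellings),
                "lump_group": e.lump_group,
                "fate": e.fate,
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows).sort_values("code").reset_index(drop=True)


def _build_pattern(code: str, names: Sequence[str], extra: Sequence[str]) -> str:
    digits = re.sub(r"[^0-9]", "", code)
    alts = [rf"e[ -]?{digits}(?:[a-f]|i{{1,3}})?"]
    alts += [p for p in extra if p]
    alts += [re.escape(n) for n in names if n]
    body = "|".join(alts)
    return rf"{_BOUND_L}(?:{body}){_BOUND_R}"


def compile_lexicon(definitions: pd.DataFrame | Iterable[Mapping]) -> Lexicon:
    """Compile an additive table into a matching-ready :class:`Lexicon`.

    ``definitions`` needs columns/keys ``code``, ``canonical_name``,
    ``synonyms`` (pipe-separated), ``misspellings`` (pipe-separated),
    ``extra_patterns`` (pipe-separated regex fragments), ``lump_group``,
    ``fate``.  Duplicate codes are rejected.
    """
    if isinstance(definitions, pd.DataFrame):
        rows = definitions.to_dict("records")
    else:
        rows = list(definitions)

    entries: dict[str, EtsEntry] = {}
    for row in rows:
        code = str(row["code"]).strip()
        if not _CODE_RE.match(code):
            raise ValueError(f"invalid E-number code: {code!r}")
        if code in entries:
            raise ValueError(f"duplicate additive code in definitions: {code}")

        def _split(key: str) -> tuple[str, ...]:
            raw = row.get(key) or ""
            if isinstance(raw, float):  # NaN from pandas
                raw = ""
            return tuple(s.strip() for s in str(raw).split("|") if s.strip())

        synonyms = _split("synonyms")
        misspellings = _split("misspellings")
        extra = _split("extra_patterns")
        names = (str(row["canonical_name"]).strip(),) + synonyms + misspellings
        pattern = _build_pattern(code, names, extra)
        lump_group = str(row.get("lump_group", "self")).strip() or "self"
        fate = str(row.get("fate", "absorbed")).strip()
        entries[code] = EtsEntry(
            code=code,
            canonical_name=names[0],
            synonyms=synonyms,
            misspellings=misspellings,
            pattern=pattern,
            lump_group=lump_group,
            fate=fate,
            regex=re.compile(pattern, re.IGNORECASE),
        )

    subclass_map = {
        sub: main
        for main, subs in _SUBCLASSES.items()
        if main in entries
        for sub in subs
    }

    lex = Lexicon(entries=entries, subclass_map=subclass_map)
    _validate(lex)
    return lex


def _validate(lex: Lexicon) -> None:
    # no two entries may claim the same bare E-number token
    for code in lex.entries:
        token = code.lower()
        owners = [c for c, e in lex.entries.items() if e.regex.search(token)]
        if owners != [code]:
            raise ValueError(
                f"bare token {token!r} matched by {owners}, expected only {code}"
            )
    for sub, main in lex.subclass_map.items():
        if main not in lex.entries:
            raise ValueError(f"subclass {sub} maps to unknown code {main}")


def load_default_lexicon() -> Lexicon:
    """Load and compile the packaged 59-entry E400–E499 table."""
    with resources.files("etscan.data").joinpath("ets_lexicon.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        table = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    return compile_lexicon(table)


def detect_ets(ingredient_text: str | None, lexicon: Lexicon) -> set[str]:
    """Return the set of main-class ETS codes declared in an ingredient list.

    Matching is case-insensitive over the lowercased text.  Overlapping hits
    are resolved longest-match-wins ("methyl cellulose" does not additionally
    count as plain cellulose), and repeats of one additive count once.
    Unmatched or empty text yields the empty set.
    """
    if not ingredient_text or not isinstance(ingredient_text, str):
        return set()
    text = ingredient_text.lower()
    hits: list[tuple[int, int, str]] = []
    for code, entry in lexicon.entries.items():
        for m in entry.regex.finditer(text):
            hits.append((m.start(), m.end(), code))
    found: set[str] = set()
    for s, e, code in hits:
        swallowed = any(
            c2 != code and s2 <= s and e <= e2 and (e2 - s2) > (e - s)
            for s2, e2, c2 in hits
        )
        if not swallowed:
            found.add(code)
    return found


def lump(code: str) -> str:
    """Project a main-class code onto its lump group (identity otherwise).

    E400–E404 → E40x, E420–E422 → E42x, E450–E452 → E45x, E470–E477 → E47x.
    Already-lumped tokens pass through, making the map a projection.
    """
    if code in LUMP_GROUPS:
        return code
    m = re.match(r"^E(4[0-9]{2})[a-z]?$", code)
    if not m:
        raise ValueError(f"not a valid E400-series code: {code!r}")
    num = int(m.group(1))
    for name, (lo, hi) in LUMP_GROUPS.items():
        if lo <= num <= hi:
            return name
    return code
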