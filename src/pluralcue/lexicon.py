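"""Packaged lexical distributions and lexicon-file utilities.

The German noun lexicon statistics used throughout the package are the
published percentage tables derived from the CELEX lexical database: the
gender-conditional plural-class percentages for the full noun lexicon and for
monosyllabic nouns only, plus the gender marginals for both.  The percentages
are stored exactly as printed (integers summing to 100 per row) and divided
by 100 at the point of use, so no re-rounding ever occurs.

CELEX itself is licensed and is not parsed or shipped; these marginal tables
are the interface the rest of the package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .infotheory import (
    Gender,
    GenderClassTable,
    InfoSummary,
    PluralClass,
)

__all__ = [
    "LexiconEntry",
    "LexiconTableSet",
    "builtin_tables",
    "info_summary",
    "load_lexicon",
    "load_table_csv",
    "save_table_csv",
    "toy_lexicon_path",
]

# Plural-class percentages per gender for the full noun lexicon
# (rows F, M, N in class order en, e, zero, s, er, other; each row sums to 100).
_OVERALL_ROWS = {
    Gender.F: (94, 3, 0, 1, 0, 1),
    Gender.M: (13, 45, 34, 5, 1, 2),
    Gender.N: (2, 39, 26, 9, 17, 7),
}
# Class percentages pooled over all genders ("All" row).  Used directly as
# p_All by the gender-ignoring simulator, not recomputed as a weighted mixture.
_OVERALL_ALL = (45, 26, 18, 4, 4, 3)
# Gender marginal (%) for the full lexicon.
_OVERALL_WEIGHTS = (42, 38, 20)

# Same quantities restricted to monosyllabic nouns.
_MONO_ROWS = {
    Gender.F: (61, 25, 1, 11, 0, 2),
    Gender.M: (7, 76, 1, 14, 2, 1),
    Gender.N: (3, 43, 17, 14, 21, 1),
}
_MONO_WEIGHTS = (13, 64, 23)


@dataclass(frozen=True)
class LexiconEntry:
    """One noun: singular spelling, grammatical gender, plural class."""

    spelling: str
    gender: Gender
    plural_class: PluralClass

    def __post_init__(self) -> None:
        if not self.spelling:
            raise ValueError("empty spelling")


@dataclass(frozen=True)
class LexiconTableSet:
    """The packaged distribution tables.

    Attributes
    ----------
    overall
        Gender-conditional class table for the full noun lexicon, with the
        lexicon-wide gender marginal as weights.
    overall_all
        The pooled class distribution over all genders, as its own vector
        (percent scale).
    monosyllable
        The same table restricted to monosyllabic nouns, weighted by the
        monosyllable gender marginal.
    """

    overall: GenderClassTable
    overall_all: tuple
    monosyllable: GenderClassTable

    def overall_row(self, g: Gender) -> tuple:
        return _OVERALL_ROWS[g]

    def monosyllable_row(self, g: Gender) -> tuple:
        return _MONO_ROWS[g]


def builtin_tables() -> LexiconTableSet:
    """The packaged printed tables, cell-for-cell as published."""
    overall = GenderClassTable(
        [_OVERALL_ROWS[g] for g in Gender],
        gender_weights=_OVERALL_WEIGHTS,
    )
    mono = GenderClassTable(
        [_MONO_ROWS[g] for g in Gender],
        gender_weights=_MONO_WEIGHTS,
    )
    return LexiconTableSet(overall=overall, overall_all=_OVERALL_ALL, monosyllable=mono)


def info_summary(t: GenderClassTable) -> InfoSummary:
    """H(C), H(C|G), MI(C;G) and MI/H for a gender-by-class table."""
    return InfoSummary.from_table(t)


_GENDER_BY_LABEL = {g.value: g for g in Gender}
_CLASS_BY_LABEL = {c.value: c for c in PluralClass}


def load_lexicon(path) -> list[LexiconEntry]:
    """Read a lexicon CSV with columns ``spelling,gender,plural_class``.

    Unknown gender or class labels raise a ValueError naming the offending
    line (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"spelling", "gender", "plural_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"lexicon CSV needs columns {sorted(required)}")
    entries = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            gender = _GENDER_BY_LABEL[row.gender]
            plural_class = _CLASS_BY_LABEL[row.plural_class.lower()]
            entries.append(LexiconEntry(row.spelling, gender, plural_class))
        except KeyError as exc:
            raise ValueError(f"line {idx}: unknown label {exc.args[0]!r}") from exc
        except ValueError as exc:
            raise ValueError(f"line {idx}: {exc}") from exc
    return entries


def tally(entries) -> GenderClassTable:
    """Count entries into a gender-by-class table (empirical gender weights)."""
    import numpy as np

    counts = np.zeros((len(Gender), len(PluralClass)))
    gi = {g: i for i, g in enumerate(Gender)}
    ci = {c: i for i, c in enumerate(PluralClass)}
    for e in entries:
        counts[gi[e.gender], ci[e.plural_class]] += 1
    return GenderClassTable(counts)


def load_table_csv(path) -> GenderClassTable:
    """Read a gender-by-class table CSV (``gender,en,...,other[,weight]``)."""
    return GenderClassTable.from_frame(pd.read_csv(path))


def save_table_csv(t: GenderClassTable, path) -> None:
    t.to_frame().to_csv(path, index=False)


def toy_lexicon_path() -> Path:
    """Path to the small packaged demonstration lexicon (synthetic toy data)."""
    return Path(resources.files("pluralcue.data") / "toy_lexicon.csv")
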