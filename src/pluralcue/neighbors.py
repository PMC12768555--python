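"""Orthographic-neighborhood analysis.

A stimulus's orthographic neighborhood is the set of lexicon words within a
normalized Levenshtein distance threshold (default 0.5) of its spelling,
used as a cheap proxy for fine-grained phonological similarity.  The
gender-by-class table of a stimulus's neighbors yields a per-stimulus
information summary: how much of the plural-class variation among
orthographically similar real nouns is conditioned on their gender.

Normalization divides the raw edit distance by the stimulus length by
default; dividing by the longer of the two spellings is available since the
convention is ambiguous and the neighbor sets differ at the margin.
Comparison is case-folded but umlaut-preserving (ö != o).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .infotheory import Gender, GenderClassTable, InfoSummary, PluralClass
from .lexicon import LexiconEntry

__all__ = [
    "NeighborSet",
    "EmptyNeighborhoodError",
    "levenshtein",
    "normalized_distance",
    "find_neighbors",
    "neighborhood_info",
    "neighborhood_table",
]


class EmptyNeighborhoodError(ValueError):
    """Signals a stimulus with no neighbors (a real outcome, not zero MI)."""


def levenshtein(a: str, b: str) -> int:
    """Minimal number of character insertions, deletions and substitutions.

    Plain Wagner-Fischer with two rows; operates on Python strings, so
    umlauted characters are single symbols.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,          # delete
                cur[j - 1] + 1,       # insert
                prev[j - 1] + (ca != cb),  # substitute
            )
        prev = cur
    return prev[-1]


def normalized_distance(stimulus: str, word: str, norm: str = "stimulus") -> float:
    """Levenshtein distance divided by a word length, case-insensitively.

    ``norm="stimulus"`` divides by the stimulus length; ``norm="max"`` by the
    longer of the two spellings.
    """
    if not stimulus:
        raise ValueError("empty stimulus")
    d = levenshtein(stimulus.lower(), word.lower())
    if norm == "stimulus":
        length = len(stimulus)
    elif norm == "max":
        length = max(len(stimulus), len(word))
    else:
        raise ValueError(f"unknown normalization {norm!r}")
    return d / length


@dataclass(frozen=True)
class NeighborSet:
    """A stimulus with its in-threshold lexicon neighbors."""

    stimulus: str
    neighbors: tuple  # of (LexiconEntry, raw_distance, normalized_distance)

    def __len__(self) -> int:
        return len(self.neighbors)

    def entries(self) -> list[LexiconEntry]:
        return [e for e, _, _ in self.neighbors]


def find_neighbors(
    stimulus: str,
    lexicon: list[LexiconEntry],
    threshold: float = 0.5,
    norm: str = "stimulus",
) -> NeighborSet:
    """All lexicon entries within the normalized-distance threshold.

    Exact spelling matches of the stimulus itself are excluded (a novel word
    should not be its own neighbor); duplicate lexicon spellings each count.
    An empty result is a legitimate outcome for phonologically atypical
    stimuli.
    """
    if not lexicon:
        raise ValueError("empty lexicon")
    found = []
    for entry in lexicon:
        if entry.spelling.lower() == stimulus.lower():
            continue
        nd = normalized_distance(stimulus, entry.spelling, norm=norm)
        if nd <= threshold:
            raw = levenshtein(stimulus.lower(), entry.spelling.lower())
            found.append((entry, raw, nd))
    return NeighborSet(stimulus, tuple(found))


def neighborhood_table(ns: NeighborSet) -> GenderClassTable:
    """Gender-by-class counts of a neighbor set (empirical gender weights)."""
    if len(ns) == 0:
        raise EmptyNeighborhoodError(f"{ns.stimulus!r} has no neighbors")
    counts = np.zeros((len(Gender), len(PluralClass)))
    gi = {g: i for i, g in enumerate(Gender)}
    ci = {c: i for i, c in enumerate(PluralClass)}
    for entry in ns.entries():
        counts[gi[entry.gender], ci[entry.plural_class]] += 1
    return GenderClassTable(counts)


def neighborhood_info(ns: NeighborSet) -> InfoSummary:
    """Information summary of the neighbor gender-by-class table."""
    return InfoSummary.from_table(neighborhood_table(ns))


def neighborhood_report(
    stimuli,
    lexicon: list[LexiconEntry],
    threshold: float = 0.5,
    norm: str = "stimulus",
) -> pd.DataFrame:
    """Per-stimulus neighborhood statistics; NaN info for empty neighborhoods."""
    rows = []
    for stim in stimuli:
        ns = find_neighbors(stim, lexicon, threshold=threshold, norm=norm)
        row = {"stimulus": stim, "n_neighbors": len(ns)}
        if len(ns) > 0:
            info = neighborhood_info(ns)
            row.update(
                h_bits=info.entropy_bits, mi_bits=info.mi_bits, ratio=info.ratio
            )
        else:
            row.update(h_bits=np.nan, mi_bits=np.nan, ratio=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
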