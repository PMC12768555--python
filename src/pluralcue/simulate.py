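"""Multinomial hypothesis simulators for per-speaker plural-class production.

Three generative regimes are modeled, each describing how a speaker might (or
might not) condition plural-class choice on grammatical gender when inflecting
24 novel nouns:

* ``H0`` -- gender-ignoring: every item's class is drawn i.i.d. from the
  pooled lexicon class distribution p_All, regardless of gender.
* ``H1`` -- lexicon-level conditioning: classes are drawn from the
  gender-specific class distributions of the full noun lexicon.
* ``H2`` -- phonologically mediated conditioning: as H1, but using the class
  distributions of monosyllabic nouns only (the stratum the novel stimuli
  belong to).

Two experimental designs are supported.  In the fixed-gender design each
simulated participant produces 8 items per gender (24 total).  In the
sampled-gender design the participant first assigns a gender to each of the
24 items by multinomial sampling from a gender marginal, then produces a
class per item conditional on the assigned gender.

Each simulated participant is summarized by the plug-in entropy H(C) of their
24 productions, the mutual information MI(C;G) with the genders they saw or
chose (weighted by their own empirical gender counts), and the normalized
ratio y = MI/H, which is the response modeled downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infotheory import Gender, GenderClassTable, InfoSummary, PluralClass
from .lexicon import builtin_tables

__all__ = [
    "Design",
    "HypothesisSpec",
    "ParticipantCounts",
    "ParticipantSummary",
    "hypothesis_spec",
    "simulate_participant",
    "summarize",
    "simulate_cohort",
    "cohort_frame",
]

N_ITEMS = 24
ITEMS_PER_GENDER = 8


class Design(enum.Enum):
    FIXED_GENDER = "fixed"      # 8 items presented per gender
    SAMPLED_GENDER = "sampled"  # participant assigns gender, then inflects


@dataclass(frozen=True)
class HypothesisSpec:
    """A named generative regime: per-gender class probabilities + design.

    For H0 all three gender rows are the same pooled vector, so the table is
    rank one and gender carries no information by construction.
    """

    name: str
    class_probs: np.ndarray = field(repr=False)  # (3 genders, 6 classes)
    design: Design
    gender_weights: np.ndarray = field(repr=False, default=None)

    def __init__(self, name, class_probs, design, gender_weights=None):
        probs = np.asarray(class_probs, dtype=float)
        if probs.shape != (len(Gender), len(PluralClass)):
            raise ValueError("class_probs must be 3 genders x 6 classes")
        probs = probs / probs.sum(axis=1, keepdims=True)
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "class_probs", probs)
        object.__setattr__(self, "design", Design(design))
        if self.design is Design.SAMPLED_GENDER:
            if gender_weights is None:
                raise ValueError("sampled-gender design requires gender_weights")
            w = np.asarray(gender_weights, dtype=float)
            gender_weights = w / w.sum()
        object.__setattr__(self, "gender_weights", gender_weights)


def hypothesis_spec(
    name: str,
    design: Design | str = Design.FIXED_GENDER,
    gender_weights=None,
) -> HypothesisSpec:
    """Build the standard spec for ``h0``, ``h1`` or ``h2``.

    ``h0`` repeats the pooled lexicon class distribution for every gender;
    ``h1`` uses the full-lexicon gender-conditional rows; ``h2`` the
    monosyllable rows.  For the sampled-gender design the default gender
    marginal is the full-lexicon one for h0/h1 and the monosyllable one for
    h2 (monosyllabic nouns have a markedly different gender mix); pass
    ``gender_weights`` to override.
    """
    tables = builtin_tables()
    key = name.lower()
    if key == "h0":
        row = np.asarray(tables.overall_all, dtype=float)
        probs = np.tile(row, (3, 1))
        default_w = tables.overall.gender_weights
    elif key == "h1":
        probs = tables.overall.raw
        default_w = tables.overall.gender_weights
    elif key == "h2":
        probs = tables.monosyllable.raw
        default_w = tables.monosyllable.gender_weights
    else:
        raise ValueError(f"unknown hypothesis {name!r}")
    design = Design(design)
    if design is Design.FIXED_GENDER:
        return HypothesisSpec(key, probs, design)
    w = default_w if gender_weights is None else gender_weights
    return HypothesisSpec(key, probs, design, gender_weights=w)


@dataclass(frozen=True)
class ParticipantCounts:
    """One simulated participant's gender-by-class production counts."""

    counts: np.ndarray  # (3, 6) integer

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(Gender), len(PluralClass)) or c.sum() != N_ITEMS:
            raise ValueError(f"counts must be 3x6 and total {N_ITEMS}")


@dataclass(frozen=True)
class ParticipantSummary:
    """Per-speaker information summary; ``ratio`` is the regression response."""

    participant_id: int
    h_bits: float
    mi_bits: float
    ratio: float


def simulate_participant(spec: HypothesisSpec, rng: np.random.Generator) -> ParticipantCounts:
    """Draw one participant's 24 productions under the given regime.

    Draw order is fixed (genders first under the sampled design, then class
    draws in F, M, N order) so cohorts are bit-reproducible for a seed.
    """
    if spec.design is Design.FIXED_GENDER:
        per_gender = np.full(len(Gender), ITEMS_PER_GENDER)
    else:
        per_gender = rng.multinomial(N_ITEMS, spec.gender_weights)
    counts = np.vstack(
        [rng.multinomial(n, p) for n, p in zip(per_gender, spec.class_probs)]
    )
    return ParticipantCounts(counts)


def summarize(counts: ParticipantCounts, participant_id: int = 0) -> ParticipantSummary:
    """Plug-in H, MI and MI/H from one participant's count table.

    Gender weights are the participant's own empirical gender counts, so a
    gender with zero sampled items contributes nothing to the conditional
    entropy.
    """
    table = GenderClassTable(np.asarray(counts.counts, dtype=float))
    info = InfoSummary.from_table(table)
    return ParticipantSummary(participant_id, info.entropy_bits, info.mi_bits, info.ratio)


def simulate_cohort(spec: HypothesisSpec, n: int, seed) -> list[ParticipantSummary]:
    """Simulate ``n`` independent participants; reproducible given ``seed``."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    return [simulate_participant_summary(spec, rng, i) for i in range(n)]


def simulate_participant_summary(
    spec: HypothesisSpec, rng: np.random.Generator, participant_id: int
) -> ParticipantSummary:
    return summarize(simulate_participant(spec, rng), participant_id)


def cohort_frame(cohort: list[ParticipantSummary]) -> pd.DataFrame:
    """Long-format cohort table (participant_id, h_bits, mi_bits, ratio)."""
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in cohort],
            "h_bits": [s.h_bits for s in cohort],
            "mi_bits": [s.mi_bits for s in cohort],
            "ratio": [s.ratio for s in cohort],
        }
    )
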