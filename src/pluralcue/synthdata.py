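"""Synthetic behavioral-experiment generator.

The original production experiments (novel-noun plural elicitation with
counterbalanced or self-assigned grammatical gender, run online with German
speakers) did not release raw per-trial data.  This module generates
synthetic stand-in cohorts with the same trial structure so the whole
pipeline -- classification of raw plural strings, per-speaker information
summaries, Bayes-factor classification -- can be exercised and validated
end to end.

Each synthetic participant follows one latent production strategy drawn from
a mixture:

* ``IGNORE`` -- plural class sampled from the pooled lexicon distribution,
  ignoring gender (the behavior of the null regime);
* ``LEXICON`` -- class sampled from the full-lexicon gender-conditional rows;
* ``MONOSYLLABLE`` -- class sampled from the monosyllable-stratum rows
  (gender conditioning mediated by word shape);
* ``SUPER`` -- a deterministic rule (feminine -> -(e)n, otherwise -e),
  modeling the occasional participant with super-lexical gender conditioning.

The generator is strategy-level by design: it has no item-specific effects
(no analogy of a novel noun to a particular real neighbor), so it emulates
the experimental designs, not every phonological nuance of real speakers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .infotheory import Gender, PluralClass
from .lexicon import builtin_tables

__all__ = [
    "STIMULI",
    "Strategy",
    "StrategyMixture",
    "ProductionRecord",
    "generate_cohort",
    "records_frame",
    "render_plural_form",
    "classify_plural",
    "recover_mixture",
]

# The 24 monosyllabic novel-noun stimuli used across all three experiments.
STIMULI = (
    "Bral", "Nuhl", "Raun", "Bnaupf", "Fneik", "Pleik",
    "Kach", "Pind", "Spand", "Bneik", "Fnöhk", "Pnähf",
    "Klot", "Pisch", "Spert", "Bnöhk", "Pläk", "Pröng",
    "Mur", "Pund", "Vag", "Fnahf", "Plaupf", "Snauk",
)


class Strategy(enum.Enum):
    IGNORE = "ignore"
    LEXICON = "lexicon"
    MONOSYLLABLE = "monosyllable"
    SUPER = "super"


@dataclass(frozen=True)
class StrategyMixture:
    """Mixture weights over latent production strategies."""

    ignore: float = 1.0
    lexicon: float = 0.0
    monosyllable: float = 0.0
    super_: float = 0.0

    def weights(self) -> np.ndarray:
        w = np.array([self.ignore, self.lexicon, self.monosyllable, self.super_], float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("mixture weights must be non-negative, not all zero")
        return w / w.sum()


@dataclass(frozen=True)
class ProductionRecord:
    """One trial of one participant."""

    participant_id: int
    experiment: str           # exp1 | exp2 | exp3
    list_id: int              # 1..3 counterbalancing list (0 for exp3)
    item: str
    gender: Gender            # shown (exp1/2) or chosen (exp3)
    raw_plural: str
    plural_class: PluralClass
    strategy: Strategy        # latent ground truth, kept for validation


_UMLAUT_MAP = str.maketrans({"ä": "a", "ö": "o", "ü": "u", "Ä": "A", "Ö": "O", "Ü": "U"})


def render_plural_form(singular: str, c: PluralClass, rng=None) -> str:
    """Spell out a plural form realizing the given class on a singular stem.

    OTHER is rendered with the out-of-class suffix "-se", which none of the
    five real classes claim, so rendering round-trips through
    :func:`classify_plural` for every class.
    """
    if not singular:
        raise ValueError("empty singular")
    suffix = {
        PluralClass.EN: "en",
        PluralClass.E: "e",
        PluralClass.ER: "er",
        PluralClass.S: "s",
        PluralClass.ZERO: "",
        PluralClass.OTHER: "se",
    }[c]
    return singular + suffix


def classify_plural(singular: str, plural: str) -> PluralClass:
    """Map a raw plural string to its suffix-defined class.

    Umlaut alternations are normalized away before comparison (the class
    taxonomy covers suffixes only, so an umlaut-only plural counts as the
    null marker).  Suffix matching is longest-first against the de-umlauted
    stem: -en / -n (after stem-final e) -> EN, -er -> ER, -se or any other
    residue -> OTHER, -e -> E, -s -> S, no residue -> ZERO.
    """
    if not singular or not plural:
        raise ValueError("empty input")
    stem = singular.translate(_UMLAUT_MAP).lower()
    form = plural.translate(_UMLAUT_MAP).lower()
    if not form.startswith(stem):
        return PluralClass.OTHER
    residue = form[len(stem):]
    if residue == "":
        return PluralClass.ZERO
    if residue in ("en", "n"):
        return PluralClass.EN
    if residue == "er":
        return PluralClass.ER
    if residue == "e":
        return PluralClass.E
    if residue == "s":
        return PluralClass.S
    return PluralClass.OTHER


def _strategy_rows(strategy: Strategy) -> np.ndarray:
    tables = builtin_tables()
    if strategy is Strategy.IGNORE:
        return np.tile(np.asarray(tables.overall_all, float), (3, 1))
    if strategy is Strategy.LEXICON:
        return tables.overall.raw
    if strategy is Strategy.MONOSYLLABLE:
        return tables.monosyllable.raw
    raise ValueError(strategy)


def _super_class(gender: Gender) -> PluralClass:
    return PluralClass.EN if gender is Gender.F else PluralClass.E


def generate_cohort(
    n: int,
    mixture: StrategyMixture,
    experiment: str = "exp1",
    seed=0,
    gender_weights=None,
) -> list[ProductionRecord]:
    """Generate per-trial production records for ``n`` synthetic participants.

    exp1/exp2 counterbalance gender across three lists: within a list each
    participant sees 8 items per gender, and each item carries a different
    gender in each list.  exp3 instead draws each participant's gender
    assignments from a gender marginal (default: the monosyllable-stratum
    marginal, which matches how speakers actually gender these word shapes).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if experiment not in ("exp1", "exp2", "exp3"):
        raise ValueError(f"unknown experiment {experiment!r}")
    rng = np.random.default_rng(seed)
    weights = mixture.weights()
    strategies = list(Strategy)
    genders = list(Gender)
    classes = list(PluralClass)
    if gender_weights is None:
        gender_weights = builtin_tables().monosyllable.gender_weights
    gender_weights = np.asarray(gender_weights, float)
    gender_weights = gender_weights / gender_weights.sum()

    records: list[ProductionRecord] = []
    for pid in range(n):
        strategy = strategies[rng.choice(len(strategies), p=weights)]
        if experiment == "exp3":
            list_id = 0
            item_genders = [genders[g] for g in rng.choice(3, size=len(STIMULI), p=gender_weights)]
        else:
            list_id = pid % 3 + 1
            # item k carries gender (k + list) mod 3: 8 per gender per list,
            # and each item rotates through all genders across lists
            item_genders = [genders[(k + list_id) % 3] for k in range(len(STIMULI))]
        rows = None if strategy is Strategy.SUPER else _strategy_rows(strategy)
        for k, item in enumerate(STIMULI):
            g = item_genders[k]
            if strategy is Strategy.SUPER:
                c = _super_class(g)
            else:
                p = rows[genders.index(g)]
                c = classes[rng.choice(len(classes), p=p / p.sum())]
            records.append(
                ProductionRecord(
                    participant_id=pid,
                    experiment=experiment,
                    list_id=list_id,
                    item=item,
                    gender=g,
                    raw_plural=render_plural_form(item, c),
                    plural_class=c,
                    strategy=strategy,
                )
            )
    return records


def records_frame(records: list[ProductionRecord]) -> pd.DataFrame:
    """Long-format trial table in the on-disk CSV layout."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "experiment": [r.experiment for r in records],
            "list_id": [r.list_id for r in records],
            "item": [r.item for r in records],
            "gender": [r.gender.value for r in records],
            "raw_plural": [r.raw_plural for r in records],
            "plural_class": [r.plural_class.value for r in records],
        }
    )


def summarize_records(records: list[ProductionRecord]):
    """Per-participant information summaries from trial records."""
    from .infotheory import GenderClassTable, InfoSummary
    from .simulate import ParticipantSummary

    genders = list(Gender)
    classes = list(PluralClass)
    by_pid: dict[int, np.ndarray] = {}
    for r in records:
        t = by_pid.setdefault(r.participant_id, np.zeros((3, 6)))
        t[genders.index(r.gender), classes.index(r.plural_class)] += 1
    out = []
    for pid in sorted(by_pid):
        info = InfoSummary.from_table(GenderClassTable(by_pid[pid]))
        out.append(ParticipantSummary(pid, info.entropy_bits, info.mi_bits, info.ratio))
    return out


def recover_mixture(
    records: list[ProductionRecord],
    posteriors: dict,
    n_boot: int = 200,
    seed=0,
) -> pd.DataFrame:
    """Best-fit-hypothesis fractions for a cohort, with bootstrap CIs.

    Classifies every participant under the fitted hypothesis models and
    reports, per hypothesis label, the fraction of participants it best
    fits, with a percentile bootstrap interval over participants.
    """
    from .bayes import classify_participant

    summaries = summarize_records(records)
    if not summaries:
        raise ValueError("no participants to classify")
    labels = np.array(
        [classify_participant(s, posteriors).best_fit for s in summaries]
    )
    rng = np.random.default_rng(seed)
    hyps = sorted(posteriors)
    rows = []
    n = labels.size
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    for hyp in hyps:
        frac = float((labels == hyp).mean())
        boot = (labels[boot_idx] == hyp).mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append({"hypothesis": hyp, "fraction": frac, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
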