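"""Plug-in information measures for categorical linguistic variables.

Everything here operates on plain probability vectors or gender-by-class
contingency tables and computes maximum-likelihood ("plug-in") estimates of
Shannon entropy, conditional entropy, mutual information, the normalized
ratio MI/H, and KL divergence.  All quantities are reported in bits
(logarithm base 2) unless another base is requested.

Plug-in estimation is deliberate: the hypothesis-testing design built on top
of these measures simulates its null distribution, which absorbs the upward
small-sample bias of plug-in MI, so bias-corrected estimators (Miller-Madow,
NSB, ...) are intentionally not provided.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PluralClass",
    "Gender",
    "ProbVector",
    "GenderClassTable",
    "InfoSummary",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "normalized_mi",
    "kl_divergence",
    "baseline_letter_conditioning",
]

_SUM_TOL = 1e-9


class PluralClass(enum.Enum):
    """The six suffix-defined German plural classes, in canonical order.

    German plurals are marked by a suffix, an umlaut, both, or neither; this
    analysis follows the convention of classifying by suffix only: -(e)n, -e,
    the null marker, -s, -er, and a catch-all "other".
    """

    EN = "en"
    E = "e"
    ZERO = "zero"
    S = "s"
    ER = "er"
    OTHER = "other"


class Gender(enum.Enum):
    """The three German grammatical genders (feminine, masculine, neuter)."""

    F = "F"
    M = "M"
    N = "N"


PLURAL_CLASSES = tuple(PluralClass)
GENDERS = tuple(Gender)


class InvalidDistributionError(ValueError):
    """Raised for negative entries, zero totals, or shape mismatches."""


class UndefinedDivergenceError(ValueError):
    """Raised when KL(p || q) is infinite: q has a zero cell where p > 0."""


@dataclass(frozen=True)
class ProbVector:
    """A normalized categorical distribution.

    Construction accepts raw counts or probabilities; entries must be
    non-negative with a positive total and are renormalized to sum to one.
    """

    probs: np.ndarray

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise InvalidDistributionError("probability vector must be 1-D and nonempty")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise InvalidDistributionError("probability entries must be finite and >= 0")
        total = arr.sum()
        if total <= 0:
            raise InvalidDistributionError("probability entries must not sum to zero")
        object.__setattr__(self, "probs", arr / total)

    def __len__(self) -> int:
        return self.probs.size

    def __array__(self, dtype=None, copy=None):
        return np.array(self.probs, dtype=dtype)


def _as_probs(p) -> np.ndarray:
    if isinstance(p, ProbVector):
        return p.probs
    return ProbVector(p).probs


@dataclass(frozen=True)
class GenderClassTable:
    """A gender-by-class table of counts or probabilities plus gender weights.

    Rows index genders, columns plural classes.  Each row is normalized into
    a conditional distribution P(class | gender); ``gender_weights`` holds
    P(gender).  When counts are given and no weights are supplied, the
    weights default to the row totals (the empirical gender marginal).
    An all-zero row is permitted and carries weight 0.
    """

    rows: np.ndarray          # (n_genders, n_classes), conditional P(c|g)
    gender_weights: np.ndarray
    raw: np.ndarray = field(repr=False, default=None)

    def __init__(self, cells, gender_weights=None) -> None:
        cells = np.asarray(cells, dtype=float)
        if cells.ndim != 2 or cells.size == 0:
            raise InvalidDistributionError("table must be 2-D and nonempty")
        if np.any(cells < 0) or not np.all(np.isfinite(cells)):
            raise InvalidDistributionError("table cells must be finite and >= 0")
        row_totals = cells.sum(axis=1)
        if cells.sum() <= 0:
            raise InvalidDistributionError("table must have at least one positive cell")
        if gender_weights is None:
            weights = row_totals / row_totals.sum()
        else:
            weights = _as_probs(gender_weights)
            if weights.size != cells.shape[0]:
                raise InvalidDistributionError("gender_weights length must match row count")
        rows = np.zeros_like(cells)
        nz = row_totals > 0
        rows[nz] = cells[nz] / row_totals[nz, None]
        if np.any(weights[~nz] > 0):
            raise InvalidDistributionError("zero row with positive gender weight")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "gender_weights", weights)
        object.__setattr__(self, "raw", cells)

    @property
    def n_genders(self) -> int:
        return self.rows.shape[0]

    @property
    def n_classes(self) -> int:
        return self.rows.shape[1]

    def marginal(self) -> ProbVector:
        """Class marginal P(c) = sum_g P(g) P(c|g)."""
        return ProbVector(self.gender_weights @ self.rows)

    def joint(self) -> np.ndarray:
        """Joint P(g, c) as a dense array."""
        return self.gender_weights[:, None] * self.rows

    def transpose(self) -> "GenderClassTable":
        """The table with classes conditioning genders (roles swapped)."""
        return GenderClassTable(self.joint().T)

    # -- CSV round-trip ------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenderClassTable":
        cols = [c.value for c in PLURAL_CLASSES]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise InvalidDistributionError(f"missing class columns: {missing}")
        cells = df[cols].to_numpy(dtype=float)
        weights = df["weight"].to_numpy(dtype=float) if "weight" in df.columns else None
        return cls(cells, gender_weights=weights)

    def to_frame(self, genders=None, use_raw: bool = True) -> pd.DataFrame:
        cells = self.raw if use_raw else self.rows
        labels = [g.value for g in GENDERS] if genders is None else list(genders)
        df = pd.DataFrame(cells, columns=[c.value for c in PLURAL_CLASSES])
        df.insert(0, "gender", labels[: self.n_genders])
        df["weight"] = self.gender_weights
        return df


@dataclass(frozen=True)
class InfoSummary:
    """H(C), H(C|G), MI(C;G) in bits, and the normalized ratio MI/H."""

    entropy_bits: float
    conditional_entropy_bits: float
    mi_bits: float
    ratio: float

    @classmethod
    def from_table(cls, table: GenderClassTable) -> "InfoSummary":
        h = entropy(table.marginal())
        hc = conditional_entropy(table)
        mi = max(h - hc, 0.0)
        return cls(h, hc, mi, (mi / h) if h > 0 else 0.0)


def _xlogx(p: np.ndarray) -> np.ndarray:
    # 0 log 0 == 0 by convention
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def entropy(p) -> float:
    """Shannon entropy H(p) = -sum p log2 p, in bits."""
    probs = _as_probs(p)
    return float(-_xlogx(probs).sum())


def conditional_entropy(t: GenderClassTable) -> float:
    """H(C|G) = sum_g P(g) H(C | G=g), in bits; zero-weight genders drop out."""
    per_gender = -_xlogx(t.rows).sum(axis=1)
    return float(t.gender_weights @ per_gender)


def mutual_information(t: GenderClassTable) -> float:
    """MI(C;G) = H(C) - H(C|G), in bits; clipped at 0 against roundoff."""
    return max(entropy(t.marginal()) - conditional_entropy(t), 0.0)


def normalized_mi(t: GenderClassTable) -> float:
    """MI(C;G)/H(C) in [0, 1]; defined as 0 when H(C) = 0 (no variation,
    hence none of it conditioned on gender)."""
    h = entropy(t.marginal())
    if h <= 0.0:
        return 0.0
    return min(mutual_information(t) / h, 1.0)


def kl_divergence(p, q, smoothing: float = 1e-6, base: float = 2.0) -> float:
    """KL(p || q) = sum_x p(x) log p(x)/q(x) with additive smoothing.

    Both vectors receive additive mass ``smoothing`` per cell and are
    renormalized before the sum, which keeps the divergence finite when the
    reference q has zero cells on p's support.  With ``smoothing=0`` such a
    configuration raises :class:`UndefinedDivergenceError`.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    pa, qa = _as_probs(p), _as_probs(q)
    if pa.size != qa.size:
        raise InvalidDistributionError("p and q must share a category set")
    if smoothing > 0:
        pa = (pa + smoothing) / (pa + smoothing).sum()
        qa = (qa + smoothing) / (qa + smoothing).sum()
    support = pa > 0
    if np.any(qa[support] <= 0):
        raise UndefinedDivergenceError(
            "q assigns zero probability on p's support; use smoothing > 0"
        )
    val = float(np.sum(pa[support] * (np.log(pa[support]) - np.log(qa[support]))))
    return max(val, 0.0) / np.log(base)


def baseline_letter_conditioning(entries) -> InfoSummary:
    """Gender-free baseline: condition plural class on vowel-letter content.

    Builds a four-level variable over the singular spelling -- contains the
    letter "a" only, "i" only, both, or neither -- and returns the InfoSummary
    of that variable against plural class.  This is a deliberately arbitrary
    conditioning variable: its MI with plural class calibrates how much
    apparent conditioning a lexically irrelevant feature produces.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("empty lexicon")
    counts = np.zeros((4, len(PLURAL_CLASSES)))
    class_index = {c: i for i, c in enumerate(PLURAL_CLASSES)}
    for e in entries:
        s = e.spelling.lower()
        level = (1 if "a" in s else 0) + (2 if "i" in s else 0)
        counts[level, class_index[e.plural_class]] += 1
    keep = counts.sum(axis=1) > 0
    return InfoSummary.from_table(GenderClassTable(counts[keep]))
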