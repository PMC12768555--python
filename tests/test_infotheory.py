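"""Unit and property tests for the plug-in information measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pluralcue.infotheory import (
    GenderClassTable,
    InfoSummary,
    InvalidDistributionError,
    ProbVector,
    UndefinedDivergenceError,
    baseline_letter_conditioning,
    conditional_entropy,
    entropy,
    kl_divergence,
    mutual_information,
    normalized_mi,
)
from pluralcue.lexicon import LexiconEntry, builtin_tables
from pluralcue.infotheory import Gender, PluralClass

ALL_ROW = (0.45, 0.26, 0.18, 0.04, 0.04, 0.03)


# ---------------------------------------------------------------------------
# oracles: direct double-sum evaluations, independent of the implementation
# ---------------------------------------------------------------------------

def oracle_entropy(p):
    p = np.asarray(p, float)
    p = p / p.sum()
    return float(sum(-x * np.log2(x) for x in p if x > 0))


def oracle_cond_entropy(cells, weights):
    cells = np.asarray(cells, float)
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    total = 0.0
    for g in range(cells.shape[0]):
        row = cells[g] / cells[g].sum()
        total += weights[g] * sum(-x * np.log2(x) for x in row if x > 0)
    return total


def oracle_mi(cells, weights):
    cells = np.asarray(cells, float)
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    rows = cells / cells.sum(axis=1, keepdims=True)
    marginal = weights @ rows
    return oracle_entropy(marginal) - oracle_cond_entropy(cells, weights)


def random_table(rng, n_g=3, n_c=6):
    cells = rng.integers(1, 30, size=(n_g, n_c)).astype(float)
    return cells


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, expected, tol",
    [
        ((0.5, 0.5), 1.0, 1e-12),
        ((1, 0, 0, 0, 0, 0), 0.0, 1e-12),
        (ALL_ROW, 1.98, 0.02),  # pooled lexicon class distribution
    ],
)
def test_entropy_values(p, expected, tol):
    assert entropy(ProbVector(p)) == pytest.approx(expected, abs=tol)


def test_entropy_rejects_invalid():
    with pytest.raises(InvalidDistributionError):
        ProbVector((-0.1, 1.1))
    with pytest.raises(InvalidDistributionError):
        ProbVector((0.0, 0.0))


# ---------------------------------------------------------------------------
# conditional entropy / MI / ratio
# ---------------------------------------------------------------------------

def test_conditional_entropy_identical_rows_equals_row_entropy():
    t = GenderClassTable([ALL_ROW] * 3, gender_weights=(1, 1, 1))
    assert conditional_entropy(t) == pytest.approx(entropy(ProbVector(ALL_ROW)), abs=1e-12)
    assert mutual_information(t) == pytest.approx(0.0, abs=1e-9)


def test_conditional_entropy_full_lexicon_near_printed_value():
    # from the printed (rounded) percentage tables; the exact-count value is 1.31
    t = builtin_tables().overall
    assert conditional_entropy(t) == pytest.approx(1.31, abs=0.04)


def test_mutual_information_perfect_prediction():
    t = GenderClassTable(np.eye(3), gender_weights=(1, 1, 1))
    assert mutual_information(t) == pytest.approx(np.log2(3), abs=1e-9)
    assert normalized_mi(t) == pytest.approx(1.0, abs=1e-9)


def test_monosyllable_table_reproduces_printed_summary():
    info = InfoSummary.from_table(builtin_tables().monosyllable)
    assert info.mi_bits == pytest.approx(0.30, abs=0.02)
    assert info.ratio == pytest.approx(0.17, abs=0.01)


def test_normalized_mi_zero_entropy_convention():
    t = GenderClassTable([[5, 0, 0], [3, 0, 0]])
    assert normalized_mi(t) == 0.0


def test_measures_match_direct_oracle_on_random_tables(rng):
    for _ in range(300):
        cells = random_table(rng)
        weights = rng.integers(1, 10, size=3).astype(float)
        t = GenderClassTable(cells, gender_weights=weights)
        assert conditional_entropy(t) == pytest.approx(
            oracle_cond_entropy(cells, weights), abs=1e-9
        )
        assert mutual_information(t) == pytest.approx(
            oracle_mi(cells, weights), abs=1e-9
        )


def test_bounds_decomposition_and_symmetry(rng):
    for _ in range(300):
        t = GenderClassTable(random_table(rng))
        h_c = entropy(t.marginal())
        h_g = entropy(ProbVector(t.gender_weights))
        mi = mutual_information(t)
        assert -1e-9 <= mi <= min(h_c, h_g) + 1e-9
        assert h_c - conditional_entropy(t) - mi == pytest.approx(0.0, abs=1e-9)
        assert mutual_information(t.transpose()) == pytest.approx(mi, abs=1e-9)


def test_table_rejects_zero_row_with_positive_weight():
    with pytest.raises(InvalidDistributionError):
        GenderClassTable([[1, 1], [0, 0]], gender_weights=(0.5, 0.5))


# ---------------------------------------------------------------------------
# KL divergence
# ---------------------------------------------------------------------------

def test_kl_identical_is_zero():
    assert kl_divergence((0.5, 0.5), (0.5, 0.5), smoothing=0) == 0.0


def test_kl_closed_form_one_bit():
    assert kl_divergence((1, 0), (0.5, 0.5), smoothing=0) == pytest.approx(1.0, abs=1e-12)


def test_kl_matches_direct_sum_with_smoothing():
    p, q, eps = np.array([0.6, 0.4, 0.0]), np.array([0.2, 0.3, 0.5]), 1e-6
    ps = (p + eps) / (p + eps).sum()
    qs = (q + eps) / (q + eps).sum()
    direct = sum(a * np.log2(a / b) for a, b in zip(ps, qs) if a > 0)
    assert kl_divergence(p, q, smoothing=eps) == pytest.approx(direct, abs=1e-9)


def test_kl_zero_cell_without_smoothing_is_undefined():
    with pytest.raises(UndefinedDivergenceError):
        kl_divergence((0.6, 0.4), (1.0, 0.0), smoothing=0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.integers(1, 50), min_size=2, max_size=6),
    st.data(),
)
def test_kl_nonnegative_zero_iff_equal(counts, data):
    p = np.array(counts, float)
    q = np.array(data.draw(st.lists(st.integers(1, 50), min_size=len(p), max_size=len(p))), float)
    d = kl_divergence(p, q, smoothing=0)
    assert d >= 0
    if np.allclose(p / p.sum(), q / q.sum()):
        assert d == pytest.approx(0.0, abs=1e-12)
    assert kl_divergence(p, p, smoothing=0) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# letter-conditioning baseline
# ---------------------------------------------------------------------------

def _entry(spelling, cls):
    return LexiconEntry(spelling, Gender.M, cls)


def test_letter_baseline_constant_variable_gives_zero_mi():
    entries = [_entry("Bock", PluralClass.E), _entry("Tor", PluralClass.E),
               _entry("Huhn", PluralClass.ER)]  # none contain a or i
    info = baseline_letter_conditioning(entries)
    assert info.mi_bits == pytest.approx(0.0, abs=1e-9)


def test_letter_baseline_deterministic_mapping_gives_full_mi():
    entries = [_entry("Hand", PluralClass.E), _entry("Wand", PluralClass.E),
               _entry("Kind", PluralClass.ER), _entry("Wirt", PluralClass.ER)]
    info = baseline_letter_conditioning(entries)
    assert info.mi_bits == pytest.approx(info.entropy_bits, abs=1e-9)
    assert info.ratio == pytest.approx(1.0, abs=1e-9)


def test_letter_baseline_matches_contingency_oracle(toy_lexicon):
    info = baseline_letter_conditioning(toy_lexicon)
    # brute-force contingency table
    levels, classes = {}, [c for c in PluralClass]
    for e in toy_lexicon:
        s = e.spelling.lower()
        key = ("a" in s, "i" in s)
        row = levels.setdefault(key, np.zeros(len(classes)))
        row[classes.index(e.plural_class)] += 1
    cells = np.array(list(levels.values()))
    weights = cells.sum(axis=1)
    assert info.mi_bits == pytest.approx(oracle_mi(cells, weights), abs=1e-9)
    assert info.entropy_bits == pytest.approx(
        oracle_entropy(cells.sum(axis=0)), abs=1e-9
    )


def test_letter_baseline_empty_lexicon_errors():
    with pytest.raises(ValueError):
        baseline_letter_conditioning([])
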