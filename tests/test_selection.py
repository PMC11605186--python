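"""Fisher's exact test against the enumeration oracle, BH correctness,
set-difference labeling, high-confidence filtering, balanced sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bh_stepup, fisher_enum_p
from epicrossnet.exceptions import (
    EvaluationError,
    ParameterError,
    SamplingError,
    SelectionError,
)
from epicrossnet.selection import (
    LabeledSiteSet,
    associate_catalog,
    balance_sample,
    bh_adjust,
    cancer_specific_labels,
    fisher_association,
    filter_high_confidence,
    haldane_odds_ratio,
    select_pan_cancer,
)
from epicrossnet.simulate import GeneratorParams, generate_catalog


def _result_from_table(a, b, c, d):
    row = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    classes = np.array(["cancer"] * (a + b) + ["normal"] * (c + d))
    return fisher_association(row, classes, site_id="s")


def test_worked_table():
    """a=9,b=1,c=1,d=9: OR=81, log2 ~ 6.340, p = 202/184756."""
    r = _result_from_table(9, 1, 1, 9)
    assert r.odds_ratio == pytest.approx(81.0)
    assert r.log2_or == pytest.approx(np.log2(81), abs=1e-3)
    assert r.p_value == pytest.approx(202 / 184756, abs=1e-12)


def test_symmetric_table_is_null():
    r = _result_from_table(5, 5, 5, 5)
    assert r.odds_ratio == pytest.approx(1.0)
    assert r.log2_or == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)


def test_haldane_correction_on_zero_cells():
    r = _result_from_table(10, 0, 0, 10)
    assert r.odds_ratio == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))
    assert r.log2_or == pytest.approx(np.log2(441), abs=1e-3)
    assert r.p_value == pytest.approx(fisher_enum_p(10, 0, 0, 10), abs=1e-12)
    # the correction never fires on a zero-free table
    assert haldane_odds_ratio(2, 3, 4, 5) == pytest.approx((2 * 5) / (3 * 4))


def test_fisher_matches_enumeration_on_random_tables():
    """200 random tables with margins <= 30 agree with the exact-rational
    enumeration of the conditional hypergeometric to 1e-10."""
    rng = np.random.default_rng(0)
    for _ in range(200):
        r1, r2 = rng.integers(1, 31, 2)
        a = int(rng.integers(0, r1 + 1))
        c = int(rng.integers(0, r2 + 1))
        res = _result_from_table(a, int(r1 - a), c, int(r2 - c))
        assert res.p_value == pytest.approx(
            fisher_enum_p(a, r1 - a, c, r2 - c), abs=1e-10)


@given(a=st.integers(0, 15), b=st.integers(1, 15),
       c=st.integers(1, 15), d=st.integers(0, 15))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_odds_ratio_monotone_in_a(a, b, c, d):
    """With b, c, d fixed, increasing a never decreases the odds ratio."""
    assert haldane_odds_ratio(a + 1, b, c, d) >= haldane_odds_ratio(a, b, c, d)


def test_fisher_rejects_single_class():
    with pytest.raises(EvaluationError):
        fisher_association(np.array([1, 0]), np.array(["cancer", "cancer"]))


def test_bh_hand_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert bh_adjust([0.04]) == pytest.approx([0.04])


def test_bh_matches_stepup_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = rng.random(50)
        assert np.allclose(bh_adjust(p), bh_stepup(p), atol=1e-12)


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_bh_preserves_rank_order(p):
    q = bh_adjust(np.array(p))
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q >= np.array(p) - 1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ParameterError):
        bh_adjust([0.5, 1.2])


def test_filter_high_confidence(small_catalog):
    filtered = filter_high_confidence(small_catalog, 2)
    expected = sum(1 for s in small_catalog.sites if s.study_support >= 2)
    assert len(filtered.sites) == expected
    assert all(s.study_support >= 2 for s in filtered.sites)
    # min=1 is the identity
    assert len(filter_high_confidence(small_catalog, 1).sites) == len(
        small_catalog.sites)


def test_cancer_specific_labels():
    lab = cancer_specific_labels({"s1", "s2", "s3"}, {"s2", "s4"})
    assert lab.positives == {"s1", "s3"}
    assert lab.negatives == {"s4"}
    with pytest.raises(SelectionError):
        cancer_specific_labels({"s1"}, {"s1"})
    disjoint = cancer_specific_labels({"a", "b"}, {"c"})
    assert disjoint.positives == {"a", "b"} and disjoint.negatives == {"c"}


def test_select_pan_cancer_strict_boundary():
    from epicrossnet.selection import OddsRatioResult

    mk = lambda sid, lor, q: OddsRatioResult(sid, 5, 5, 5, 5, 2.0 ** lor, lor,
                                             0.01, q)
    results = [mk("hit", 6.34, 0.002), mk("edge", 2.0, 0.001),
               mk("neg", -4.0, 0.001), mk("null", 0.0, 0.9)]
    lab = select_pan_cancer(results)
    assert lab.positives == {"hit"}  # log2_or == 2 exactly is excluded
    assert lab.negatives == {"neg"}
    with pytest.raises(SelectionError):
        select_pan_cancer([mk("x", 0.0, 0.9)])


def test_selection_invariant_to_site_order():
    params = GeneratorParams(n_sites=600, seed=21)
    cat = generate_catalog(params)
    lab1 = select_pan_cancer(associate_catalog(cat))
    perm = np.random.default_rng(0).permutation(len(cat.sites))
    lab2 = select_pan_cancer(associate_catalog(cat.subset(perm)))
    assert lab1.positives == lab2.positives
    assert lab1.negatives == lab2.negatives


def test_balance_sample():
    lab = LabeledSiteSet(positives={f"p{i}" for i in range(5)},
                         negatives={f"n{i}" for i in range(100)})
    b1 = balance_sample(lab, seed=3)
    assert len(b1.negatives) == 5
    assert b1.negatives <= lab.negatives
    b2 = balance_sample(lab, seed=3)
    assert b1.negatives == b2.negatives  # determinism
    tiny = LabeledSiteSet(positives={"p1", "p2"}, negatives={"n1"})
    with pytest.raises(SamplingError):
        balance_sample(tiny, seed=0)
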