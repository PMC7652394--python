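"""Matched sister-pair extraction, scoring, and the chi-square test."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from lineagefate.pairs import (
    chisq_2x2,
    compare_pairs,
    event_probability,
    find_matched_pairs,
)
from lineagefate.trees import build_trees

from conftest import make_dataset, make_record


def _division_with(mn_side=None, extra=()):
    """Root dividing into aa/ab; `mn_side` daughter carries MN."""
    recs = [
        make_record(cell_id="a", t_nebd=17.0, t_division=17.5,
                    interphase_duration=17.0, mitotic_duration=0.5),
        make_record(cell_id="aa", parent_id="a", t_birth=17.5, censored=True,
                    micronuclei=(mn_side == "aa")),
        make_record(cell_id="ab", parent_id="a", t_birth=17.5, censored=True,
                    micronuclei=(mn_side == "ab")),
    ]
    return recs + list(extra)


def test_discordant_division_yields_one_pair():
    pairs = find_matched_pairs(build_trees(make_dataset(_division_with("aa"))))
    assert len(pairs) == 1
    p = pairs[0]
    assert p.mn_positive_id == "aa" and p.mn_negative_id == "ab"


def test_concordant_divisions_yield_no_pair():
    for side in (None, "both"):
        recs = _division_with(None)
        if side == "both":
            recs[1] = make_record(cell_id="aa", parent_id="a", t_birth=17.5,
                                  censored=True, micronuclei=True)
            recs[2] = make_record(cell_id="ab", parent_id="a", t_birth=17.5,
                                  censored=True, micronuclei=True)
        assert find_matched_pairs(build_trees(make_dataset(recs))) == []


def test_mn_in_grandchild_counts_for_the_side():
    extra = [make_record(cell_id="aba", parent_id="ab", t_birth=30.0,
                         censored=True, micronuclei=True)]
    recs = _division_with(None, extra)
    recs[2] = make_record(cell_id="ab", parent_id="a", t_birth=17.5,
                          t_nebd=29.5, t_division=30.0, interphase_duration=12.0,
                          mitotic_duration=0.5)
    # 'ab' itself is MN-negative but its subtree contains MN
    pairs = find_matched_pairs(build_trees(make_dataset(recs)))
    assert len(pairs) == 1 and pairs[0].mn_positive_id == "ab"


def test_tripolar_divisions_are_skipped():
    recs = [
        make_record(cell_id="a", t_nebd=17.0, t_division=17.5, tripolar=True,
                    interphase_duration=17.0, mitotic_duration=0.5),
        make_record(cell_id="aa", parent_id="a", t_birth=17.5, censored=True,
                    micronuclei=True),
        make_record(cell_id="ab", parent_id="a", t_birth=17.5, censored=True),
        make_record(cell_id="ac", parent_id="a", t_birth=17.5, censored=True),
    ]
    assert find_matched_pairs(build_trees(make_dataset(recs))) == []


def test_verdict_extra_abnormalities_on_mn_side():
    # MN+ daughter later shows another MN and dies; MN- daughter is clean
    extra = [
        make_record(cell_id="aaa", parent_id="aa", t_birth=30.0, micronuclei=True,
                    death=True),
        make_record(cell_id="aab", parent_id="aa", t_birth=30.0, censored=True),
    ]
    recs = _division_with("aa", extra)
    recs[1] = make_record(cell_id="aa", parent_id="a", t_birth=17.5, micronuclei=True,
                          t_nebd=29.5, t_division=30.0, interphase_duration=12.0,
                          mitotic_duration=0.5)
    pairs = find_matched_pairs(build_trees(make_dataset(recs)))
    # index MN discounted; the extra MN + death still outweigh the clean side
    # (the MN+ side also has more mitoses, which partially offsets)
    assert pairs[0].verdict == "MN_plus_more"


def test_verdict_tie_when_balanced():
    pairs = find_matched_pairs(build_trees(make_dataset(_division_with("aa"))))
    # only the index MN differs, and it is discounted -> tie
    assert pairs[0].verdict == "tie"
    comp = compare_pairs(pairs)
    assert comp["ties"] == 1 and comp["mn_plus_more"] == 0


def test_pair_sides_partition_the_descendants(small_trees):
    for tree in small_trees:
        for p in find_matched_pairs([tree]):
            pos = set(tree.subtree_ids(p.mn_positive_id))
            neg = set(tree.subtree_ids(p.mn_negative_id))
            assert not pos & neg
            kids = tree.children[p.division_cell_id]
            desc = set().union(*(tree.subtree_ids(k) for k in kids))
            assert pos | neg == desc


def test_expected_pair_count_matches_enumeration_on_depth2_trees():
    # full depth-2 trees, every non-root cell MN ~ Bernoulli(q) iid:
    #   root division: each side (daughter + 2 grandkids) is MN+ w.p.
    #   s = 1-(1-q)^3 -> discordance 2 s (1-s)
    #   each daughter division: sides are single grandkids -> 2 q (1-q)
    rng = np.random.default_rng(17)
    q, n_trees = 0.2, 3000
    recs = []
    for i in range(n_trees):
        lid = f"T{i}"
        recs.append(make_record(lineage_id=lid, cell_id="a", t_nebd=10.0,
                                t_division=10.5, interphase_duration=10.0,
                                mitotic_duration=0.5))
        for d in ("aa", "ab"):
            recs.append(make_record(lineage_id=lid, cell_id=d, parent_id="a",
                                    t_birth=10.5, t_nebd=20.0, t_division=20.5,
                                    interphase_duration=9.5, mitotic_duration=0.5,
                                    micronuclei=bool(rng.random() < q)))
            for g in "ab":
                recs.append(make_record(lineage_id=lid, cell_id=d + g, parent_id=d,
                                        t_birth=20.5, censored=True,
                                        micronuclei=bool(rng.random() < q)))
    pairs = find_matched_pairs(build_trees(make_dataset(recs)))
    s = 1 - (1 - q) ** 3
    expected = n_trees * (2 * s * (1 - s) + 2 * 2 * q * (1 - q))
    sd = np.sqrt(n_trees) * 1.2  # conservative: per-tree counts in {0,1,2,3}
    assert abs(len(pairs) - expected) < 4 * sd


# ---- chi-square ----------------------------------------------------------

def test_chisq_balanced_table_is_zero():
    assert chisq_2x2(np.array([[10, 10], [10, 10]]))["statistic"] == 0.0


def test_chisq_published_sister_pair_table():
    out = chisq_2x2(np.array([[12, 31], [0, 43]]))
    expected = 86 * (12 * 43 - 31 * 0) ** 2 / (43 * 43 * 12 * 74)
    assert abs(out["statistic"] - expected) < 1e-12
    assert abs(out["statistic"] - 13.946) < 1e-3
    assert out["df"] == 1 and out["p_value"] < 0.001


def test_chisq_agrees_with_scipy_on_random_tables():
    rng = np.random.default_rng(9)
    for _ in range(20):
        t = rng.integers(1, 50, (2, 2))
        mine = chisq_2x2(t)["statistic"]
        ref = chi2_contingency(t, correction=False).statistic
        assert abs(mine - ref) < 1e-12
        swapped = chisq_2x2(t[::-1])["statistic"]
        assert abs(mine - swapped) < 1e-12


def test_chisq_zero_margin_rejected():
    with pytest.raises(ValueError):
        chisq_2x2(np.array([[0, 0], [5, 5]]))


def test_event_probability_estimators():
    est = event_probability(12, 43)
    assert abs(est["mle"] - 0.2791) < 1e-4
    assert abs(est["jeffreys_mean"] - 12.5 / 44) < 1e-12
    assert abs(est["laplace_mean"] - 13 / 45) < 1e-12
    assert 0.27 < est["beta_median"] < 0.29
    assert event_probability(0, 10, "mle") == 0.0
    with pytest.raises(ValueError):
        event_probability(1, 0)
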