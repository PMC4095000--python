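"""Fisher right-tail test and pathway over-representation.

The independent oracle enumerates every 2x2 table with the observed
margins and sums exact rational point probabilities (math.comb over
Fraction), so it shares no code path with the log-gamma implementation.
"""

import math
import random
from fractions import Fraction

import numpy as np
import pytest

from cardionet.enrichment import (
    ContingencyTable2x2,
    EnrichmentResult,
    apply_benjamini_hochberg,
    enrich_pathways,
    enrich_per_compound,
    fisher_right_tail,
    make_universe,
    split_basic_disease,
)
from cardionet.types import (
    CardionetError,
    Compound,
    CompoundClass,
    LinkType,
    PathwayCategory,
    PathwaySet,
)


def exact_right_tail(a, b, c, d):
    """Enumerate all tables with margins (a+b, c+d) x (a+c, b+d)."""
    n, K, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, n + K - N), min(n, K)
    total = Fraction(0)
    denom = math.comb(N, n)
    for x in range(a, hi + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return total


def test_right_tail_is_one_at_minimum():
    assert fisher_right_tail(ContingencyTable2x2(0, 4, 4, 0)) == 1.0
    assert fisher_right_tail(ContingencyTable2x2(0, 1, 1, 100)) == 1.0


def test_known_small_tables():
    # enumeration over margins (4,4)/(4,4): 17/70 and the single extreme table
    assert fisher_right_tail(ContingencyTable2x2(3, 1, 1, 3)) == pytest.approx(
        17 / 70, rel=1e-12
    )
    assert fisher_right_tail(ContingencyTable2x2(4, 0, 0, 4)) == pytest.approx(
        1 / 70, rel=1e-12
    )


def test_matches_exact_enumeration_on_random_tables():
    rng = random.Random(20240319)
    checked = 0
    while checked < 1000:
        N = rng.randint(2, 40)
        a = rng.randint(0, N)
        b = rng.randint(0, N - a)
        c = rng.randint(0, N - a - b)
        d = N - a - b - c
        if a + b == 0 or a + c == 0:
            continue
        got = fisher_right_tail(ContingencyTable2x2(a, b, c, d))
        want = float(exact_right_tail(a, b, c, d))
        assert got == pytest.approx(want, rel=1e-12, abs=1e-15), (a, b, c, d)
        checked += 1


@pytest.mark.parametrize("table", [(1, 0, 3, 0), (2, 0, 0, 5), (1, 3, 2, 0), (3, 2, 1, 0)])
def test_boundary_tables_match_enumeration(table):
    got = fisher_right_tail(ContingencyTable2x2(*table))
    assert got == pytest.approx(float(exact_right_tail(*table)), rel=1e-12)


def test_degenerate_tables_rejected():
    with pytest.raises(CardionetError):
        ContingencyTable2x2(-1, 1, 1, 1)
    with pytest.raises(CardionetError):
        ContingencyTable2x2(0, 0, 0, 0)
    with pytest.raises(CardionetError):
        fisher_right_tail(ContingencyTable2x2(0, 0, 3, 3))  # a+b == 0


def test_monotone_in_a_with_margins_fixed():
    # shift mass along the diagonal: margins (a+b, a+c) stay fixed
    n, K, N = 10, 8, 30
    last = 1.1
    for a in range(max(0, n + K - N), min(n, K) + 1):
        p = fisher_right_tail(ContingencyTable2x2(a, n - a, K - a, N - n - K + a))
        assert p <= last + 1e-15
        last = p


def test_swap_b_c_leaves_tail_unchanged():
    rng = random.Random(5)
    for _ in range(50):
        a, b, c, d = (rng.randint(0, 12) for _ in range(4))
        if a + b == 0 or a + c == 0 or b + c + a + d == 0:
            continue
        if a + c == 0 or a + b == 0:
            continue
        t1 = fisher_right_tail(ContingencyTable2x2(a, b, c, d))
        t2 = fisher_right_tail(ContingencyTable2x2(a, c, b, d))
        assert t1 == pytest.approx(t2, rel=1e-12)


# --- pathway-level API ------------------------------------------------------


def test_exact_overlap_pathway_is_significant():
    universe = {f"T{i}" for i in range(20)}
    members = {f"T{i}" for i in range(10)}
    pw = [PathwaySet("P1", "basic p", members=frozenset(members))]
    (res,) = enrich_pathways(set(members), pw, universe)
    t = res.table
    assert (t.a, t.b, t.c, t.d) == (10, 0, 0, 10)
    assert res.p_value == pytest.approx(1 / math.comb(20, 10), rel=1e-12)
    assert res.significant


def test_disjoint_pathway_p_is_one():
    universe = {f"T{i}" for i in range(20)}
    pw = [PathwaySet("P1", "basic p", members=frozenset({"T10", "T11"}))]
    (res,) = enrich_pathways({"T0", "T1"}, pw, universe)
    assert res.p_value == 1.0
    assert not res.significant


def test_results_sorted_by_p_then_id():
    universe = {f"T{i}" for i in range(30)}
    pw = [
        PathwaySet("B", "basic b", members=frozenset({"T0", "T1", "T2"})),
        PathwaySet("A", "basic a", members=frozenset({"T0", "T1", "T2"})),
        PathwaySet("C", "basic c", members=frozenset({"T20", "T21"})),
    ]
    res = enrich_pathways({"T0", "T1", "T2"}, pw, universe)
    assert [r.pathway_id for r in res] == ["A", "B", "C"]


def test_empty_inputs_rejected():
    with pytest.raises(CardionetError):
        enrich_pathways(set(), [], {"T1"})
    with pytest.raises(CardionetError):
        enrich_pathways({"T1"}, [], set())


def test_single_target_compound_p_exactly_alpha_not_significant():
    universe = {f"T{i}" for i in range(100)}
    pw = [PathwaySet("P1", "basic p", members=frozenset({"T0"}))]
    comp = Compound("c1", "drug", CompoundClass.WESTERN_DRUG, [("T0", LinkType.DIRECT)])
    res01 = enrich_per_compound([comp], {}, pw, universe, alpha=0.01)["c1"][0]
    assert res01.p_value == pytest.approx(1 / 100, rel=1e-12)
    assert not res01.significant  # strict p < alpha at p == alpha
    res05 = enrich_per_compound([comp], {}, pw, universe, alpha=0.05)["c1"][0]
    assert res05.significant


def test_compound_without_universe_targets_skipped_with_warning():
    universe = {"T1"}
    pw = [PathwaySet("P1", "basic p", members=frozenset({"T1"}))]
    lost = Compound("c2", "x", CompoundClass.WESTERN_DRUG, [("ZZ", LinkType.DIRECT)])
    with pytest.warns(UserWarning, match="c2"):
        out = enrich_per_compound([lost], {}, pw, universe)
    assert "c2" not in out


def test_identical_target_sets_give_identical_results():
    universe = {f"T{i}" for i in range(40)}
    pw = [PathwaySet("P1", "basic p", members=frozenset({"T0", "T1", "T5"}))]
    c1 = Compound("c1", "x", CompoundClass.WESTERN_DRUG, [("T0", LinkType.DIRECT), ("T5", LinkType.DIRECT)])
    c2 = Compound("c2", "y", CompoundClass.WESTERN_DRUG, [("T0", LinkType.DIRECT), ("T5", LinkType.DIRECT)])
    out = enrich_per_compound([c1, c2], {}, pw, universe)
    assert [(r.pathway_id, r.p_value) for r in out["c1"]] == [
        (r.pathway_id, r.p_value) for r in out["c2"]
    ]


def test_split_basic_disease_fraction():
    sets = [
        PathwaySet(f"b{i}", "basic x", PathwayCategory.BASIC, frozenset({"T"}))
        for i in range(43)
    ] + [
        PathwaySet(f"d{i}", "disease x", PathwayCategory.DISEASE, frozenset({"T"}))
        for i in range(22)
    ]
    basic, diseased, frac = split_basic_disease(sets)
    assert (len(basic), len(diseased)) == (43, 22)
    assert frac == pytest.approx(22 / 65)
    assert frac >= 0.33
    assert split_basic_disease(sets[:43])[2] == 0.0
    assert split_basic_disease(sets[43:])[2] == 1.0
    with pytest.raises(CardionetError):
        split_basic_disease([])


def test_split_on_enrichment_results_needs_index():
    pw = PathwaySet("P1", "disease x", PathwayCategory.DISEASE, frozenset({"T"}))
    res = [EnrichmentResult("s", "P1", ContingencyTable2x2(1, 0, 0, 1), 0.5, False)]
    _, diseased, frac = split_basic_disease(res, {"P1": pw})
    assert frac == 1.0 and len(diseased) == 1
    with pytest.raises(CardionetError):
        split_basic_disease(res)


def test_benjamini_hochberg_mode_is_more_conservative():
    universe = {f"T{i}" for i in range(50)}
    pws = [
        PathwaySet(f"P{i}", "basic p", members=frozenset({f"T{i}", f"T{i+1}"}))
        for i in range(10)
    ]
    res = enrich_pathways({"T0", "T1", "T2"}, pws, universe, alpha=0.05)
    bh = apply_benjamini_hochberg(res, alpha=0.05)
    assert sum(r.significant for r in bh) <= sum(r.significant for r in res)


def test_make_universe_modes(tiny_dataset):
    union = make_universe("pathway-union", tiny_dataset.pathways)
    assert union == {"T1", "T2"}
    annotated = make_universe("annotated", annotations=tiny_dataset.annotations)
    assert annotated == {"T1", "T2", "T3"}
    with pytest.raises(CardionetError):
        make_universe("galactic")


def test_null_type_one_error_is_conservative():
    """Uniform random target sets should reject at most ~alpha per pathway."""
    rng = np.random.default_rng(11)
    N, K, n = 400, 60, 200
    # p-value depends only on the overlap a; precompute with our implementation
    p_of_a = np.array(
        [
            fisher_right_tail(ContingencyTable2x2(a, n - a, K - a, N - n - K + a))
            for a in range(min(n, K) + 1)
        ]
    )
    draws = rng.hypergeometric(K, N - K, n, size=10_000)
    type_i = float(np.mean(p_of_a[draws] < 0.01))
    assert type_i <= 0.015
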