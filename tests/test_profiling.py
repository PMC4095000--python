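"""Target-level statistics: TTD tallies, d/t, profiles, TF enrichment."""

import numpy as np
import pytest

from cardionet.profiling import (
    MultiTargetClass,
    ProfileAxis,
    classify_multitarget_compounds,
    compute_dt,
    domain_count_profile,
    dt_table,
    family_profile,
    location_profile,
    tally_ttd,
    tf_enrichment,
)
from cardionet.synthetic import SyntheticConfig, generate_dataset
from cardionet.types import (
    CardionetError,
    Compound,
    CompoundClass,
    LinkType,
    Location,
    PathwaySet,
    ProteinFamily,
    TargetAnnotation,
    TTDStatus,
    round_half_up,
)


def _ann(tid, status=TTDStatus.ABSENT, n_dis=0, family=ProteinFamily.OTHER, **kw):
    return TargetAnnotation(
        tid,
        ttd_status=status,
        diseases=frozenset(f"d{tid}{i}" for i in range(n_dis)),
        family=family,
        **kw,
    )


def test_tally_reproduces_published_western_census(paper_ds, paper_groups):
    tally = tally_ttd(paper_groups["western"], paper_ds.annotations, "western")
    assert tally.denominator == 204
    assert tally.per_status_count[TTDStatus.SUCCESSFUL] == 81
    assert tally.per_status_pct[TTDStatus.SUCCESSFUL] == 39.7
    assert tally.in_ttd_count == 127
    assert tally.in_ttd_pct == 62.3


def test_tally_reproduces_published_herbal_direct_census(paper_ds, paper_groups):
    tally = tally_ttd(paper_groups["herbal_direct"], paper_ds.annotations, "herbal")
    assert tally.per_status_count[TTDStatus.SUCCESSFUL] == 32
    assert tally.per_status_pct[TTDStatus.SUCCESSFUL] == 27.1
    assert tally.in_ttd_pct == 65.3


def test_tally_all_absent_and_empty_group():
    anns = {f"T{i}": _ann(f"T{i}") for i in range(5)}
    tally = tally_ttd(set(anns), anns, "g")
    assert tally.in_ttd_count == 0 and tally.in_ttd_pct == 0.0
    with pytest.raises(CardionetError):
        tally_ttd(set(), anns, "g")


def test_tally_conservation_invariant_on_random_groups():
    rng = np.random.default_rng(3)
    statuses = list(TTDStatus)
    for _ in range(25):
        anns = {
            f"T{i}": _ann(f"T{i}", statuses[rng.integers(len(statuses))])
            for i in range(int(rng.integers(1, 40)))
        }
        tally = tally_ttd(set(anns), anns, "g")
        assert sum(tally.per_status_count[s] for s in statuses if s is not TTDStatus.ABSENT) == tally.in_ttd_count
        assert tally.in_ttd_count + tally.per_status_count[TTDStatus.ABSENT] == tally.denominator


@pytest.mark.parametrize(
    "group,status,n,assoc,printed",
    [
        ("western", TTDStatus.SUCCESSFUL, 81, 221, 2.73),
        ("western", TTDStatus.CLINICAL_TRIAL, 15, 45, 3.0),
        ("western", TTDStatus.RESEARCH, 29, 56, 1.93),
        ("herbal_direct", TTDStatus.SUCCESSFUL, 32, 160, 5.0),
        ("herbal_direct", TTDStatus.CLINICAL_TRIAL, 10, 39, 3.9),
        ("herbal_direct", TTDStatus.RESEARCH, 32, 76, 2.38),
    ],
)
def test_dt_reproduces_published_rows(paper_ds, paper_groups, group, status, n, assoc, printed):
    row = compute_dt(paper_groups[group], paper_ds.annotations, status, group)
    assert (row.n_targets, row.n_disease_associations) == (n, assoc)
    assert round_half_up(row.dt_value, 2) == printed


def test_dt_constant_case_and_empty_status():
    anns = {f"T{i}": _ann(f"T{i}", TTDStatus.SUCCESSFUL, n_dis=3) for i in range(7)}
    row = compute_dt(set(anns), anns, TTDStatus.SUCCESSFUL, "g")
    assert row.dt_value == 3.0
    with pytest.raises(CardionetError):
        compute_dt(set(anns), anns, TTDStatus.RESEARCH, "g")


def test_dt_linearity_under_disjoint_union():
    rng = np.random.default_rng(4)
    a = {f"A{i}": _ann(f"A{i}", TTDStatus.SUCCESSFUL, int(rng.integers(0, 8))) for i in range(12)}
    b = {f"B{i}": _ann(f"B{i}", TTDStatus.SUCCESSFUL, int(rng.integers(0, 8))) for i in range(5)}
    both = {**a, **b}
    da = compute_dt(set(a), both, TTDStatus.SUCCESSFUL, "a")
    db = compute_dt(set(b), both, TTDStatus.SUCCESSFUL, "b")
    dm = compute_dt(set(both), both, TTDStatus.SUCCESSFUL, "ab")
    weighted = (da.dt_value * da.n_targets + db.dt_value * db.n_targets) / dm.n_targets
    assert dm.dt_value == pytest.approx(weighted, rel=1e-12)


def test_dt_table_skips_missing_stages(paper_ds, paper_groups):
    rows = dt_table(paper_groups["western"], paper_ds.annotations, "western")
    assert [r.ttd_status for r in rows] == [
        TTDStatus.SUCCESSFUL,
        TTDStatus.CLINICAL_TRIAL,
        TTDStatus.RESEARCH,
    ]


def test_domain_count_profile_bins():
    anns = {
        "T1": _ann("T1", domain_ids=("a",)),
        "T2": _ann("T2", domain_ids=("b",)),
        "T3": _ann("T3", domain_ids=("a", "b")),
    }
    prof = domain_count_profile(set(anns), anns, "g")
    assert prof.axis is ProfileAxis.DOMAIN_COUNT
    assert dict((b[0], b[1]) for b in prof.bins) == {"1": 2, "2": 1}
    assert sum(b[2] for b in prof.bins) == pytest.approx(1.0)

    bare = {f"T{i}": _ann(f"T{i}") for i in range(4)}
    prof0 = domain_count_profile(set(bare), bare, "g")
    assert prof0.bins == (("0", 4, 1.0),)


def test_family_profile_counts_each_target_once():
    anns = {
        "T1": _ann("T1", family=ProteinFamily.ENZYME),
        "T2": _ann("T2", family=ProteinFamily.ENZYME),
        "T3": _ann("T3", family=ProteinFamily.RECEPTOR),
        "T4": _ann("T4"),  # unannotated family counts under "other"
    }
    prof = family_profile(set(anns), anns, "g")
    bins = {b[0]: b[2] for b in prof.bins}
    assert bins["enzyme"] == pytest.approx(0.5)
    assert bins["receptor"] == pytest.approx(0.25)
    assert bins["other"] == pytest.approx(0.25)
    assert sum(b[2] for b in prof.bins) == pytest.approx(1.0)


def test_location_profile_counts_per_compartment():
    anns = {
        "T1": _ann("T1", locations=frozenset({Location.CYTOPLASM, Location.NUCLEUS})),
        "T2": _ann("T2", locations=frozenset({Location.CYTOPLASM})),
    }
    prof = location_profile(set(anns), anns, "g")
    bins = {b[0]: b[1] for b in prof.bins}
    assert bins["cytoplasm"] == 2 and bins["nucleus"] == 1
    # multi-compartment targets make fractions sum above 1
    assert sum(b[2] for b in prof.bins) == pytest.approx(1.5)


def test_planted_family_fraction_recovered():
    weights = dict(SyntheticConfig().family_weights)
    weights["herbal"] = (0.6, 0.1, 0.1, 0.1, 0.05, 0.025, 0.025)
    ds, truth = generate_dataset(
        SyntheticConfig(seed=42, n_targets_per_class=500, n_shared_targets=0, family_weights=weights)
    )
    prof = family_profile(set(truth.herbal_targets), ds.annotations, "herbal")
    enzyme_frac = {b[0]: b[2] for b in prof.bins}["enzyme"]
    assert abs(enzyme_frac - 0.6) < 0.05


def test_planted_domain_mean_orders_profiles():
    ds, truth = generate_dataset(SyntheticConfig(seed=9, n_shared_targets=0))
    anns = ds.annotations
    mean_h = np.mean([len(anns[t].domain_ids) for t in truth.herbal_targets])
    mean_w = np.mean([len(anns[t].domain_ids) for t in truth.western_targets])
    assert mean_h > mean_w  # planted 2.5 vs 1.5


def test_dt_gap_recovery_over_seeds():
    """Planted disease-count means 5 vs 2.5 at n=100/class: the mean
    estimated gap over 50 seeds lands within 0.5 of the planted gap."""
    gaps = []
    for seed in range(50):
        ds, truth = generate_dataset(
            SyntheticConfig(seed=seed, n_targets_per_class=100, n_shared_targets=0)
        )
        anns = ds.annotations
        mh = np.mean([anns[t].disease_count for t in truth.herbal_targets])
        mw = np.mean([anns[t].disease_count for t in truth.western_targets])
        gaps.append(mh - mw)
    assert abs(np.mean(gaps) - 2.5) < 0.5


def test_tf_enrichment_directionality(paper_ds, paper_groups):
    herb = tf_enrichment(paper_groups["herbal_direct"], paper_ds.annotations, "herbal")
    west = tf_enrichment(paper_groups["western"], paper_ds.annotations, "western")
    assert (herb.n_tf_targets, west.n_tf_targets) == (11, 10)
    assert herb.p_value < 0.01
    assert west.p_value > 0.05


def test_tf_enrichment_zero_tfs_gives_p_one():
    anns = {f"T{i}": _ann(f"T{i}") for i in range(10)}
    res = tf_enrichment(set(anns), anns, "g")
    assert res.p_value == 1.0


def test_tf_enrichment_monotone_in_tf_count():
    last = 1.1
    for k in range(0, 12):
        anns = {
            f"T{i}": _ann(f"T{i}", is_tf=i < k) for i in range(20)
        }
        p = tf_enrichment(set(anns), anns, "g").p_value
        assert p <= last + 1e-12
        last = p


def test_tf_enrichment_small_universe_rejected():
    anns = {f"T{i}": _ann(f"T{i}") for i in range(10)}
    with pytest.raises(CardionetError):
        tf_enrichment(set(anns), anns, "g", universe_size=5)


def test_classify_multitarget_compounds():
    anns = {
        "T1": _ann("T1", family=ProteinFamily.CHANNEL_TRANSPORTER),
        "T2": _ann("T2", family=ProteinFamily.CHANNEL_TRANSPORTER),
        "T3": _ann("T3", family=ProteinFamily.ENZYME),
        "T4": _ann("T4", family=ProteinFamily.RECEPTOR),
        "T5": _ann("T5", family=ProteinFamily.ENZYME),
    }
    pathways = [PathwaySet("P", "basic p", members=frozenset({"T3", "T4"}))]
    mk = lambda cid, ts: Compound(
        cid, cid, CompoundClass.WESTERN_DRUG, [(t, LinkType.DIRECT) for t in ts]
    )
    compounds = [
        mk("subtypes", ["T1", "T2"]),
        mk("mono", ["T1"]),
        mk("process", ["T3", "T4"]),
        mk("neither", ["T1", "T5"]),
    ]
    with pytest.warns(UserWarning):
        out = classify_multitarget_compounds(
            compounds + [Compound("void", "void", CompoundClass.WESTERN_DRUG, [])],
            anns,
            pathways,
        )
    assert out["subtypes"] is MultiTargetClass.SAME_FAMILY_MULTI
    assert out["mono"] is MultiTargetClass.SINGLE_TARGET
    assert out["process"] is MultiTargetClass.SAME_PROCESS_MULTI
    assert out["neither"] is MultiTargetClass.OTHER
    assert out["void"] is MultiTargetClass.OTHER
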