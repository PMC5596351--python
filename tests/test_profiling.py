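import numpy as np
import pytest

import hitseries as hs

R = hs.ActivityRecord


def _mms(core, members):
    return hs.MMS(core=core, members=frozenset(members),
                  substituents={m: f"*{m}" for m in members})


def _matrix_from_sets(tested, active, targets=None):
    """Build a primary-assay matrix from per-member tested/active sets."""
    records = []
    targets = targets or {}
    for member, assays in tested.items():
        for a in sorted(assays):
            outcome = "active" if a in active.get(member, set()) else "inactive"
            records.append(R(member, f"a{a:03d}", outcome, "primary", targets.get(a)))
    return hs.ingest_records(records)


# -- the three series parameters ---------------------------------------------


def test_hand_enumerated_two_member_series():
    """A tested in 1..10 (1 active), B in 6..15 (2 active): union 15,
    3 active assays, shared 5, of which 2 mixed."""
    matrix = _matrix_from_sets(
        {"A": set(range(1, 11)), "B": set(range(6, 16))},
        {"A": {1}, "B": {6, 7}},
    )
    p = hs.profile_mms(_mms("*c1ccccc1", {"A", "B"}), matrix)
    assert p.n_union_assays == 15
    assert p.n_union_active == 3
    assert p.hr == pytest.approx(3 / 15)
    assert p.n_shared_assays == 5
    assert p.overlap == pytest.approx(5 / 15)
    assert p.inconsistent == pytest.approx(2 / 5)
    assert p.per_member["A"].n_tested == 10 and p.per_member["A"].n_active == 1


def test_identical_profiles_give_full_overlap_no_inconsistency():
    matrix = _matrix_from_sets(
        {"A": {1, 2, 3}, "B": {1, 2, 3}}, {"A": {1}, "B": {1}}
    )
    p = hs.profile_mms(_mms("*c1ccccc1", {"A", "B"}), matrix)
    assert p.overlap == 1.0
    assert p.inconsistent == 0.0


def test_disjoint_tested_sets_leave_inconsistency_undefined():
    matrix = _matrix_from_sets({"A": {1, 2}, "B": {3, 4}}, {})
    p = hs.profile_mms(_mms("*c1ccccc1", {"A", "B"}), matrix)
    assert p.overlap == 0.0
    assert p.inconsistent is None


def test_member_missing_from_matrix_is_an_error():
    matrix = _matrix_from_sets({"A": {1}}, {})
    with pytest.raises(KeyError, match="B"):
        hs.profile_mms(_mms("*c1ccccc1", {"A", "B"}), matrix)


def test_profile_only_counts_primary_assays():
    from conftest import toy_records

    extra = [R("A", "conf1", "active", "confirmatory"), R("B", "conf1", "active", "confirmatory")]
    matrix = hs.ingest_records(toy_records() + extra)
    p = hs.profile_mms(_mms("*c1ccccc1", {"A", "B"}), matrix)
    assert p.n_union_assays == 15  # confirmatory assay not in the union


def test_shared_assay_partition_identity_on_random_series():
    """consistent_active + consistent_inactive + inconsistent = shared."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        k = rng.integers(2, 5)
        members = [f"m{j}" for j in range(k)]
        tested = {m: set(rng.choice(30, size=rng.integers(5, 25), replace=False)) for m in members}
        active = {m: {a for a in tested[m] if rng.random() < 0.3} for m in members}
        matrix = _matrix_from_sets(tested, active)
        p = hs.profile_mms(_mms("*cX", members), matrix)
        shared = set.intersection(*tested.values())
        ca = sum(1 for a in shared if all(a in active[m] for m in members))
        ci = sum(1 for a in shared if all(a not in active[m] for m in members))
        assert p.n_shared_assays == len(shared)
        if shared:
            n_inc = round(p.inconsistent * p.n_shared_assays)
            assert ca + ci + n_inc == len(shared)
        else:
            assert p.inconsistent is None


def test_series_growth_monotonicity_and_permutation_invariance():
    rng = np.random.default_rng(7)
    tested = {m: set(rng.choice(40, size=20, replace=False)) for m in ["a", "b", "c"]}
    active = {m: {x for x in tested[m] if rng.random() < 0.2} for m in tested}
    matrix = _matrix_from_sets(tested, active)
    p2 = hs.profile_mms(_mms("*cX", {"a", "b"}), matrix)
    p3 = hs.profile_mms(_mms("*cX", {"a", "b", "c"}), matrix)
    assert p3.n_union_assays >= p2.n_union_assays
    assert p3.n_shared_assays <= p2.n_shared_assays
    # member order cannot matter: frozenset members, same profile values
    p3b = hs.profile_mms(_mms("*cX", {"c", "b", "a"}), matrix)
    assert (p3.hr, p3.overlap, p3.inconsistent) == (p3b.hr, p3b.overlap, p3b.inconsistent)


def test_hr_bounds_from_member_activity():
    rng = np.random.default_rng(13)
    tested = {m: set(rng.choice(50, size=30, replace=False)) for m in ["a", "b"]}
    active = {m: {x for x in tested[m] if rng.random() < 0.25} for m in tested}
    matrix = _matrix_from_sets(tested, active)
    p = hs.profile_mms(_mms("*cX", {"a", "b"}), matrix)
    lo = max(len(active[m]) for m in active) / p.n_union_assays
    hi = min(1.0, sum(len(active[m]) for m in active) / p.n_union_assays)
    assert lo <= p.hr <= hi


# -- target-based hit rate -----------------------------------------------------


def test_target_hit_rate_counts_targets_not_assays():
    # 4 assays on 2 targets; activity only on target T1
    matrix = _matrix_from_sets(
        {"A": {1, 2, 3, 4}, "B": {1, 2, 3, 4}},
        {"A": {1}, "B": {2}},
        targets={1: "T1", 2: "T1", 3: "T2", 4: "T2"},
    )
    p = hs.profile_mms(_mms("*cX", {"A", "B"}), matrix)
    assert p.target_hr == pytest.approx(1 / 2)


def test_target_hit_rate_undefined_without_annotations():
    matrix = _matrix_from_sets({"A": {1, 2}, "B": {1, 2}}, {"A": {1}})
    assert hs.target_hit_rate(_mms("*cX", {"A", "B"}), matrix) is None


def test_target_hit_rate_equals_assay_hit_rate_under_bijection():
    # one assay per target: the two rates coincide on annotated assays
    rng = np.random.default_rng(3)
    tested = {m: set(rng.choice(20, size=15, replace=False)) for m in ["a", "b"]}
    active = {m: {x for x in tested[m] if rng.random() < 0.3} for m in tested}
    targets = {a: f"T{a}" for a in range(20)}
    matrix = _matrix_from_sets(tested, active, targets=targets)
    p = hs.profile_mms(_mms("*cX", {"a", "b"}), matrix)
    assert p.target_hr == pytest.approx(p.hr)


# -- rank fusion -----------------------------------------------------------------


def _profile_stub(core, hr, overlap, inconsistent):
    mms = _mms(core, {f"{core}_1", f"{core}_2"})
    return hs.MMSProfile(
        mms=mms, n_union_assays=100, n_union_active=int(hr * 100),
        n_shared_assays=int(overlap * 100), hr=hr, overlap=overlap,
        inconsistent=inconsistent, target_hr=None,
        per_member={},
    )


def test_single_profile_ranks_first_everywhere():
    (r,) = hs.rank_series([_profile_stub("c1", 0.1, 0.5, 0.1)])
    assert (r.rank_hr, r.rank_overlap, r.rank_inconsistent, r.fused_score) == (1, 1, 1, 1)


def test_dominating_profile_ranks_first():
    worse = _profile_stub("worse", 0.05, 0.4, 0.3)
    better = _profile_stub("better", 0.20, 0.9, 0.0)
    ranked = hs.rank_series([worse, better])
    assert ranked[0].mms.core == "better"
    assert ranked[0].fused_score == 1.0 and ranked[1].fused_score == 2.0


def test_undefined_inconsistency_ranks_last_on_that_criterion():
    defined = _profile_stub("defined", 0.1, 0.5, 0.9)
    undefined = _profile_stub("undef", 0.1, 0.5, None)
    ranked = {r.mms.core: r for r in hs.rank_series([defined, undefined])}
    assert ranked["undef"].rank_inconsistent > ranked["defined"].rank_inconsistent


def test_fused_ordering_matches_bruteforce_mean_of_ranks():
    rng = np.random.default_rng(21)
    profiles = [
        _profile_stub(f"core{i:03d}", float(rng.random()), float(rng.random()),
                      float(rng.random()) if rng.random() > 0.1 else None)
        for i in range(100)
    ]
    ranked = hs.rank_series(profiles)

    # independent oracle: average ranks computed by explicit counting
    def avg_rank(values):
        order = {}
        for i, v in enumerate(values):
            less = sum(1 for w in values if w < v)
            eq = sum(1 for w in values if w == v)
            order[i] = less + (eq + 1) / 2
        return order

    hr_r = avg_rank([-p.hr for p in profiles])
    ov_r = avg_rank([-p.overlap for p in profiles])
    inc_r = avg_rank([np.inf if p.inconsistent is None else p.inconsistent for p in profiles])
    fused = {
        profiles[i].mms.core: (hr_r[i] + ov_r[i] + inc_r[i]) / 3 for i in range(len(profiles))
    }
    expected = sorted(fused, key=lambda c: (fused[c], c))
    assert [r.mms.core for r in ranked] == expected
    for r in ranked:
        assert r.fused_score == pytest.approx(fused[r.mms.core])
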