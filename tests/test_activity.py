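import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hitseries as hs

R = hs.ActivityRecord


# -- ingestion and deduplication ---------------------------------------------


def test_any_active_wins_duplicate_resolution():
    matrix = hs.ingest_records(
        [R("c1", "a1", "active", "primary"), R("c1", "a1", "inactive", "primary")]
    )
    assert matrix.outcome("c1", "a1", "primary") == "active"
    # order-independent
    matrix2 = hs.ingest_records(
        [R("c1", "a1", "inactive", "primary"), R("c1", "a1", "active", "primary")]
    )
    assert matrix2.outcome("c1", "a1", "primary") == "active"


def test_confirmatory_only_compound_has_undefined_hit_rate():
    matrix = hs.ingest_records([R("c1", "a1", "active", "confirmatory")])
    (profile,) = hs.compound_profiles(matrix)
    assert profile.n_tested_primary == 0
    assert profile.hit_rate is None
    assert profile.n_active_confirmatory == 1


def test_inconclusive_kept_in_matrix_but_excluded_from_counts():
    matrix = hs.ingest_records(
        [
            R("c1", "a1", "active", "primary"),
            R("c1", "a2", "inactive", "primary"),
            R("c1", "a3", "inconclusive", "primary"),
        ]
    )
    assert len(matrix) == 3
    (profile,) = hs.compound_profiles(matrix)
    assert profile.n_tested_primary == 2
    assert profile.n_active_primary == 1


def test_unknown_tokens_rejected():
    with pytest.raises(ValueError, match="maybe"):
        R("c1", "a1", "maybe", "primary")
    with pytest.raises(ValueError, match="tertiary"):
        R("c1", "a1", "active", "tertiary")


def test_malformed_row_reports_line_number(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("compound_id\tassay_id\toutcome\tstage\ttarget_id\nc1\ta1\n")
    with pytest.raises(ValueError, match=":2"):
        hs.read_activity_table(path)


def test_activity_table_round_trip(tmp_path):
    records = [
        R("c1", "a1", "active", "primary", "T1"),
        R("c2", "a2", "inactive", "confirmatory", None),
    ]
    path = tmp_path / "act.tsv"
    hs.write_activity_table(path, records)
    assert hs.read_activity_table(path) == records


# -- profiles ------------------------------------------------------------------


def test_hit_rate_arithmetic_and_bounds():
    recs = [R("c1", f"a{k}", "active" if k == 0 else "inactive", "primary") for k in range(10)]
    recs += [R("c2", f"a{k}", "active", "primary") for k in range(4)]
    profiles = {p.compound_id: p for p in hs.compound_profiles(hs.ingest_records(recs))}
    assert profiles["c1"].hit_rate == pytest.approx(0.10)
    assert profiles["c2"].hit_rate == 1.0


@settings(derandomize=True, max_examples=30)
@given(
    st.lists(
        st.tuples(st.integers(0, 5), st.integers(0, 20), st.sampled_from(["active", "inactive"])),
        min_size=1,
        max_size=60,
    ),
    st.randoms(use_true_random=False),
)
def test_hit_rate_invariant_to_order_and_duplicates(entries, rnd):
    records = [R(f"c{c}", f"a{a}", o, "primary") for c, a, o in entries]
    shuffled = records[:] + records[: len(records) // 2]
    rnd.shuffle(shuffled)
    base = {p.compound_id: p.hit_rate for p in hs.compound_profiles(hs.ingest_records(records))}
    perm = {p.compound_id: p.hit_rate for p in hs.compound_profiles(hs.ingest_records(shuffled))}
    assert base == perm


# -- boxplot summaries -----------------------------------------------------------


def test_boxplot_symmetric_and_degenerate_cases():
    s = hs.summarize_distribution([1, 2, 3, 4, 5])
    assert (s.lower_whisker, s.q1, s.median, s.q3, s.upper_whisker) == (1, 2, 3, 4, 5)
    c = hs.summarize_distribution([7, 7, 7])
    assert (c.lower_whisker, c.q1, c.median, c.q3, c.upper_whisker) == (7, 7, 7, 7, 7)
    with pytest.raises(ValueError):
        hs.summarize_distribution([])


def test_boxplot_whisker_excludes_far_outlier():
    s = hs.summarize_distribution([0, 0, 0, 0, 100])
    # IQR = 0, so the whiskers collapse onto the box and 100 is an outlier
    assert s.upper_whisker == 0


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=1000))
def test_boxplot_agrees_with_sorted_quantile_oracle(values):
    s = hs.summarize_distribution(values)
    arr = np.sort(np.asarray(values))
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    assert s.q1 == pytest.approx(q1)
    assert s.median == pytest.approx(med)
    assert s.q3 == pytest.approx(q3)
    assert s.lower_whisker <= s.q1 <= s.median <= s.q3 <= s.upper_whisker
    iqr = q3 - q1
    assert s.lower_whisker == min(arr[arr >= q1 - 1.5 * iqr].min(), q1)
    assert s.upper_whisker == max(arr[arr <= q3 + 1.5 * iqr].max(), q3)


# -- selection cascade -------------------------------------------------------------


def _profile(cid: str, tested: int, active: int) -> hs.CompoundProfile:
    return hs.CompoundProfile(cid, tested, active, 0, 0)


def test_fixed_threshold_cascade_keeps_strictly_above_high():
    profiles = [
        _profile("p05", 1000, 5),
        _profile("p10", 1000, 10),
        _profile("p20", 1000, 20),
        _profile("p30", 1000, 30),
    ]
    thresholds = hs.SelectionThresholds(
        min_assays_exclusive=0, bulk_hit_rate_upper=0.01, high_hit_rate_exclusive=0.018
    )
    selected, used, summaries = hs.selection_cascade(profiles, thresholds)
    assert selected == {"p20", "p30"}
    assert used == thresholds
    assert len(summaries) == 3


def test_strictness_at_every_boundary():
    # tested exactly equal to the frequency threshold is excluded
    profiles = [_profile("at", 257, 10), _profile("above", 258, 10)]
    thresholds = hs.SelectionThresholds(257, 0.01, 0.018)
    selected, _, _ = hs.selection_cascade(profiles, thresholds)
    assert selected == {"above"}
    # hit rate exactly equal to high_hit_rate_exclusive is excluded,
    # exactly equal to bulk_hit_rate_upper is kept in the bulk stage
    profiles = [_profile("bulk_edge", 1000, 10), _profile("high_edge", 1000, 18),
                _profile("winner", 1000, 19)]
    selected, _, summaries = hs.selection_cascade(
        profiles, hs.SelectionThresholds(0, 0.01, 0.018)
    )
    assert selected == {"winner"}
    # the bulk-stage summary covers the three compounds with hr >= 1.0%
    assert summaries[1].median == pytest.approx(0.018)


def test_derived_thresholds_follow_the_quantile_recipe():
    rng = np.random.default_rng(5)
    tested = rng.integers(100, 800, size=400)
    actives = rng.binomial(tested, 0.01)
    profiles = [_profile(f"c{i}", int(t), int(a)) for i, (t, a) in enumerate(zip(tested, actives))]
    selected, thresholds, _ = hs.selection_cascade(profiles)
    assert thresholds.min_assays_exclusive == pytest.approx(np.percentile(tested, 25))
    stage1 = [p for p in profiles if p.n_tested_primary > thresholds.min_assays_exclusive]
    bulk = [p.hit_rate for p in stage1 if p.hit_rate >= 0.01]
    assert thresholds.high_hit_rate_exclusive == pytest.approx(np.median(bulk))
    assert selected == {
        p.compound_id for p in stage1 if p.hit_rate > thresholds.high_hit_rate_exclusive
    }


def test_uniformly_low_hit_rates_fail_at_the_bulk_stage():
    # varying assay frequency, identical 0.4% hit rate everywhere
    profiles = [_profile(f"c{i}", 250 * (i % 4 + 1), i % 4 + 1) for i in range(50)]
    with pytest.raises(hs.StageError) as excinfo:
        hs.selection_cascade(profiles)
    assert excinfo.value.stage == "bulk"


def test_raising_high_threshold_never_adds_compounds():
    rng = np.random.default_rng(11)
    tested = rng.integers(50, 600, size=300)
    actives = rng.binomial(tested, rng.uniform(0.001, 0.08, size=300))
    profiles = [_profile(f"c{i}", int(t), int(a)) for i, (t, a) in enumerate(zip(tested, actives))]
    previous = None
    for high in (0.015, 0.02, 0.03, 0.05):
        selected, _, _ = hs.selection_cascade(
            profiles, hs.SelectionThresholds(0, 0.01, high)
        )
        if previous is not None:
            assert selected <= previous
        previous = selected


# -- confirmatory consistency ---------------------------------------------------


def test_confirmatory_consistency_bounds():
    recs = [
        R("c1", "a1", "active", "primary"),
        R("c1", "ca1", "active", "confirmatory"),
        R("c2", "a1", "active", "primary"),
    ]
    matrix = hs.ingest_records(recs)
    assert hs.confirmatory_consistency(matrix, {"c1"}) == 1.0
    assert hs.confirmatory_consistency(matrix, {"c2"}) == 0.0
    assert hs.confirmatory_consistency(matrix, {"c1", "c2"}) == 0.5
    with pytest.raises(ValueError):
        hs.confirmatory_consistency(matrix, set())
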