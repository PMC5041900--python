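"""Variant filtering, sharing classification, drivers, and count tests."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ithkit.variants import (
    CATEGORY_GERMLINE,
    CATEGORY_PRIVATE,
    CATEGORY_SHARED,
    CATEGORY_TRUNCAL,
    ContextUnavailableError,
    call_candidate_drivers,
    classify_sharing,
    compare_driver_counts,
    compare_private_counts,
    count_private_mutations,
    detect_homopolymer_runs,
    filter_variants,
    near_homopolymer,
    wilcoxon_rank_sum,
)

from conftest import make_call, make_meta

NO_RUN_FLANK = "ACGTACGTACGTACGTACGTA"  # 21 bp, no homopolymer


# ----------------------------------------------------------------------
# homopolymer runs
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACGT", []),
        ("AAAACGGGG", [(1, 4, "A"), (6, 9, "G")]),
        ("AAAAA", [(1, 5, "A")]),  # maximal run, not two overlapping ones
        ("NNNNN", []),
        ("TTTTTTTTTT", [(1, 10, "T")]),
        ("ACGTTTTACG", [(4, 7, "T")]),
    ],
)
def test_homopolymer_run_detection(seq, expected):
    assert detect_homopolymer_runs(seq) == expected


def test_homopolymer_rejects_bad_input():
    with pytest.raises(ValueError, match="non-IUPAC"):
        detect_homopolymer_runs("ACGX")
    with pytest.raises(ValueError, match="min_len"):
        detect_homopolymer_runs("ACGT", min_len=1)


def test_near_homopolymer_brute_force_over_all_run_placements():
    """Slide a 4-bp run across a 21-bp window; compare against a brute-force
    oracle that enumerates every constant substring and measures distances."""

    def oracle(seq, offset, span):
        best = None
        for i in range(len(seq)):
            for j in range(i + 4, len(seq) + 1):
                sub = seq[i:j]
                if len(set(sub)) == 1 and sub[0] != "N":
                    lo, hi = offset + 1, offset + span  # 1-based affected span
                    if i + 1 > hi:
                        dist = i + 1 - hi
                    elif j < lo:
                        dist = lo - j
                    else:
                        dist = 0
                    best = dist if best is None else min(best, dist)
        return best is not None and best <= 1

    base = list("ACGTACGTACGTACGTACGTA")
    for start in range(0, 18):
        seq = base.copy()
        for k in range(start, start + 4):
            seq[k] = "A"
        seq = "".join(seq)
        for span in (1, 2):  # SNV and a 2-bp deletion span
            got = near_homopolymer(seq, 10, "A" * span, "A")
            assert got == oracle(seq, 10, span), (seq, start, span)


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------
def test_filter_rules_and_order():
    calls = [
        make_call(pos=1, gq=59, vaf=0.5),                      # GQ below threshold
        make_call(pos=2, gq=99, vaf=0.09),                     # VAF below threshold
        make_call(pos=3, gq=60, vaf=0.10),                     # both at the boundary: kept
        make_call(pos=4, flank="ACGTACAAAACGTACGTACGT", flank_offset=10),  # adjacent run
        make_call(pos=5),                                      # clean
    ]
    kept = filter_variants(calls)
    assert [c.pos for c in kept] == [3, 5]


def test_filter_homopolymer_distance_boundary():
    # run ending immediately before the variant -> excluded;
    # one intervening base -> kept
    adjacent = "ACGTACAAAA" + "C" + "ACGTACGTAC"   # run ends at offset 9, variant at 10
    gap_one = "ACGTCAAAAG" + "C" + "ACGTACGTAC"    # run ends two before the variant
    assert near_homopolymer(adjacent, 10, "C", "T") is True
    assert near_homopolymer(gap_one, 10, "C", "T") is False


def test_filter_empty_input_and_idempotence(small_cohort):
    assert filter_variants([]) == []
    once = filter_variants(small_cohort.variant_calls)
    assert filter_variants(once) == once


def test_filter_removes_exactly_the_injected_violations(small_cohort):
    truth = small_cohort.truth.variants
    kept = filter_variants(small_cohort.variant_calls)
    kept_keys = {(c.patient_id, *c.key) for c in kept}
    for key in truth.should_filter:
        assert key not in kept_keys
    for key in truth.categories:
        assert key in kept_keys


def test_missing_flank_raises_without_reference():
    call = make_call(flank=None, flank_offset=None)
    with pytest.raises(ContextUnavailableError, match="context unavailable"):
        filter_variants([call])


def test_missing_flank_resolved_via_reference_accessor():
    class Ref:
        def fetch(self, chrom, start0, end0):
            return "ACGT" * 200  # no runs

    call = make_call(flank=None, flank_offset=None, pos=50)
    assert filter_variants([call], reference=Ref()) == [call]


# ----------------------------------------------------------------------
# sharing classification
# ----------------------------------------------------------------------
def _calls_for_pattern(meta, pattern_samples, pos=500):
    return [
        make_call(sample_id=s.sample_id, patient_id=s.patient_id, pos=pos)
        for s in pattern_samples
    ]


def test_sharing_examples():
    meta = make_meta(n_patients=2, n_neph=3)
    by_id = {m.sample_id: m for m in meta}
    # private to the biopsy, absent from all normals
    sharing = classify_sharing(_calls_for_pattern(meta, [by_id["SU01_Bx"]]), meta)
    sc = sharing[("SU01", ("chr1", 500, "A", "T"))]
    assert sc.category == CATEGORY_PRIVATE and sc.tumor_specific
    # present in all 4 tumor samples
    tumors = [m for m in meta if m.patient_id == "SU01" and m.is_tumor]
    sc = classify_sharing(_calls_for_pattern(meta, tumors), meta)[("SU01", ("chr1", 500, "A", "T"))]
    assert sc.category == CATEGORY_TRUNCAL and sc.tumor_specific
    # 2 of 3 nephrectomies only
    two = [by_id["SU01_Nx1"], by_id["SU01_Nx3"]]
    sc = classify_sharing(_calls_for_pattern(meta, two), meta)[("SU01", ("chr1", 500, "A", "T"))]
    assert sc.category == CATEGORY_SHARED
    # present in own normal -> germline, never somatic
    sc = classify_sharing(
        _calls_for_pattern(meta, [by_id["SU01_N"], by_id["SU01_Bx"]]), meta
    )[("SU01", ("chr1", 500, "A", "T"))]
    assert sc.category == CATEGORY_GERMLINE and not sc.tumor_specific
    # present in ANOTHER patient's normal -> still truncal but not tumor-specific
    sc = classify_sharing(
        _calls_for_pattern(meta, tumors + [by_id["SU02_N"]]), meta
    )[("SU01", ("chr1", 500, "A", "T"))]
    assert sc.category == CATEGORY_TRUNCAL and not sc.tumor_specific


@pytest.mark.parametrize("n_tumor", [2, 3, 4, 5])
def test_sharing_matches_exhaustive_enumeration(n_tumor):
    """Every non-empty presence pattern over k tumor samples classifies per the
    definition: all -> truncal, one -> private, else shared."""
    meta = make_meta(n_patients=1, n_neph=n_tumor - 1)
    tumors = [m for m in meta if m.is_tumor]
    for r in range(1, n_tumor + 1):
        for combo in itertools.combinations(tumors, r):
            sharing = classify_sharing(_calls_for_pattern(meta, list(combo)), meta)
            sc = sharing[("SU01", ("chr1", 500, "A", "T"))]
            if r == n_tumor:
                expected = CATEGORY_TRUNCAL
            elif r == 1:
                expected = CATEGORY_PRIVATE
            else:
                expected = CATEGORY_SHARED
            assert sc.category == expected


def test_patient_without_tumor_samples_errors():
    from ithkit.design import SampleMeta

    meta = [SampleMeta("P_N", "P", "normal", "na")]
    calls = [make_call(sample_id="P_N", patient_id="P")]
    with pytest.raises(ValueError, match="no tumor samples"):
        classify_sharing(calls, meta)


# ----------------------------------------------------------------------
# drivers
# ----------------------------------------------------------------------
def test_driver_rules():
    calls = [
        make_call(pos=1, consequence="stop_gained"),
        make_call(pos=2, consequence="missense_variant", sift="tolerated", polyphen="benign"),
        make_call(pos=3, consequence="synonymous_variant"),
        make_call(pos=4, consequence="missense_variant", sift="deleterious"),
        make_call(pos=5, consequence="missense_variant", polyphen="possibly_damaging"),
        make_call(pos=6, consequence="frameshift_variant"),
    ]
    out = {d.key[1]: d for d in call_candidate_drivers(calls)}
    assert out[1].is_candidate_driver and out[1].rationale == "consequence:stop_gained"
    assert not out[2].is_candidate_driver and out[2].rationale is None
    assert not out[3].is_candidate_driver
    assert out[4].is_candidate_driver and "sift" in out[4].rationale
    assert out[5].is_candidate_driver and "polyphen" in out[5].rationale
    assert out[6].is_candidate_driver


def test_unknown_consequence_strict_vs_lenient():
    calls = [make_call(consequence="weird_term")]
    with pytest.raises(ValueError, match="unknown consequence"):
        call_candidate_drivers(calls, strict=True)
    out = call_candidate_drivers(calls, strict=False)
    assert not out[0].is_candidate_driver


# ----------------------------------------------------------------------
# private counts
# ----------------------------------------------------------------------
def test_private_counts_from_simulator_truth(small_cohort):
    calls = filter_variants(small_cohort.variant_calls)
    sharing = classify_sharing(calls, small_cohort.meta)
    table = count_private_mutations(sharing, small_cohort.meta)
    truth = small_cohort.truth.variants.private_counts
    for pid, per_sample in truth.items():
        bx = [s for s in per_sample if s.endswith("_Bx")][0]
        assert table.loc[pid, "biopsy"] == per_sample[bx]
        nx = sorted(s for s in per_sample if "_Nx" in s)
        for k, s in enumerate(nx):
            assert table.loc[pid, f"neph_{k + 1}"] == per_sample[s]
        assert table.loc[pid, "neph_median"] == np.median([per_sample[s] for s in nx])


def test_private_counts_hand_example():
    meta = make_meta(n_patients=1, n_neph=3)
    by_id = {m.sample_id: m for m in meta}
    calls = []
    plan = {"SU01_Bx": 3, "SU01_Nx1": 1, "SU01_Nx2": 0, "SU01_Nx3": 2}
    pos = 100
    for sample, n in plan.items():
        for _ in range(n):
            calls.append(make_call(sample_id=sample, patient_id="SU01", pos=pos))
            pos += 1
    # one shared variant must not contribute to any private count
    calls += _calls_for_pattern(meta, [by_id["SU01_Nx1"], by_id["SU01_Nx2"]], pos=999)
    sharing = classify_sharing(calls, meta)
    table = count_private_mutations(sharing, meta)
    assert table.loc["SU01", "biopsy"] == 3
    assert table.loc["SU01", "neph_median"] == 1
    assert table.loc["SU01", ["neph_1", "neph_2", "neph_3"]].tolist() == [1, 0, 2]


def test_compare_private_counts_closed_form():
    import pandas as pd

    df = pd.DataFrame({"biopsy": [1, 2, 3, 4], "neph_median": [2, 3, 4, 5]})
    res = compare_private_counts(df)
    assert res["t"] == pytest.approx(-1.0954, abs=1e-3)
    assert res["p"] == pytest.approx(0.3155, abs=1e-3)
    assert res["df"] == 6
    assert sum(res["split"].values()) == 4


def test_compare_private_counts_degenerate():
    import pandas as pd

    same = pd.DataFrame({"biopsy": [2, 2, 2], "neph_median": [2, 2, 2]})
    res = compare_private_counts(same)
    assert res["p"] == 1.0 and res["split"]["equal"] == 3
    diff = pd.DataFrame({"biopsy": [2, 2], "neph_median": [3, 3]})
    res = compare_private_counts(diff)
    assert np.isnan(res["p"]) and res["note"] is not None


# ----------------------------------------------------------------------
# Wilcoxon rank-sum
# ----------------------------------------------------------------------
def test_wilcoxon_exact_enumeration_example():
    res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert res["method"] == "exact"
    assert res["p"] == pytest.approx(0.1)


def test_wilcoxon_identical_groups_p_one():
    res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert res["p"] == pytest.approx(1.0)


def test_wilcoxon_order_invariance():
    a, b = [3, 1, 2, 7], [5, 4, 6]
    r1 = wilcoxon_rank_sum(a, b)
    r2 = wilcoxon_rank_sum(sorted(a, reverse=True), sorted(b))
    assert r1["p"] == pytest.approx(r2["p"])


@given(
    x=st.lists(st.integers(0, 5), min_size=2, max_size=5),
    y=st.lists(st.integers(0, 5), min_size=2, max_size=5),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_wilcoxon_exact_matches_full_enumeration(x, y):
    """Exact p equals the direct tail enumeration over all rank assignments."""
    from scipy.stats import rankdata

    res = wilcoxon_rank_sum(x, y)
    pooled = np.array(x + y, float)
    ranks = rankdata(pooled)
    t_obs = ranks[: len(x)].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), len(x))]
    lower = np.mean([s <= t_obs + 1e-9 for s in sums])
    upper = np.mean([s >= t_obs - 1e-9 for s in sums])
    assert res["p"] == pytest.approx(min(1.0, 2 * min(lower, upper)))


def test_driver_count_table(small_cohort):
    calls = filter_variants(small_cohort.variant_calls)
    sharing = classify_sharing(calls, small_cohort.meta)
    drivers = call_candidate_drivers(calls)
    table = compare_driver_counts(drivers, sharing, small_cohort.meta)
    assert {"mean_biopsy", "mean_nephrectomy", "p"} <= set(table.columns)
    ok = table["p"].dropna()
    assert ((ok >= 0) & (ok <= 1)).all()
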