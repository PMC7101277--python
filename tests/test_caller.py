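"""Likelihood-ratio scoring and the quality-filter stack."""

from math import inf, lgamma, log, log1p

import numpy as np
import pandas as pd
import pytest

from poolseq.caller import (EXCLUSION_FLAGS, FilterThresholds, apply_filters,
                            filter_ledger, flag_low_coverage, score_candidate,
                            score_candidates)

from conftest import make_call_row, scored_calls


def oracle_score(k: int, n: int, eps: float) -> float:
    """Independent brute-force Phred likelihood-ratio via explicit log-pmf."""
    def logpmf(k, n, p):
        if p == 0.0:
            return 0.0 if k == 0 else -inf
        return (lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)
                + k * log(p) + (n - k) * log1p(-p))

    f0 = eps / 3.0
    f_hat = max(k / n, f0)
    return max(0.0, 10.0 * (logpmf(k, n, f_hat) - logpmf(k, n, f0)) / log(10.0))


@pytest.mark.parametrize(
    "alt_count,depth,eps",
    [(60, 2400, 1e-3), (1, 2400, 1e-3), (5, 400, 1e-3), (12, 1000, 5e-3),
     (240, 2400, 1e-3), (0, 2400, 1e-3)],
)
def test_score_matches_brute_force_oracle(alt_count, depth, eps):
    assert score_candidate(alt_count, depth, eps) == pytest.approx(
        oracle_score(alt_count, depth, eps), rel=1e-9, abs=1e-12
    )


def test_zero_alt_count_scores_zero():
    assert score_candidate(0, 2400, 1e-3) == 0.0


def test_score_nondecreasing_as_error_rate_falls():
    scores = [score_candidate(60, 2400, eps)
              for eps in (9e-3, 5e-3, 2e-3, 1e-3, 5e-4, 1e-4)]
    assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))


def test_depth_zero_rejected():
    with pytest.raises(ValueError):
        score_candidate(0, 0, 1e-3)
    with pytest.raises(ValueError):
        score_candidates(pd.DataFrame([make_call_row(depth=0, alt_count=0)]), 1e-3)


def test_vectorized_scoring_matches_scalar():
    rows = [make_call_row(alt_count=k, depth=n)
            for k, n in ((0, 400), (3, 400), (60, 2400), (200, 2000))]
    calls = score_candidates(pd.DataFrame(rows), 1e-3)
    for row in calls.itertuples():
        assert row.score == pytest.approx(
            score_candidate(row.alt_count, row.depth, 1e-3), rel=1e-12)
        assert row.allele_fraction == row.alt_count / row.depth


class TestBoundarySemantics:
    """'over 5'/'over 15' are strict; the keep windows are inclusive."""

    def _flags(self, **kwargs):
        calls = scored_calls([make_call_row(**kwargs)])
        return calls["flags"].iat[0], bool(calls["pass"].iat[0])

    def test_score_exactly_five_fails(self):
        # construct a call whose score lands exactly on the threshold by
        # thresholding directly: score 5.0 must not pass "over 5"
        calls = scored_calls([make_call_row(alt_count=60)])
        calls.loc[:, "score"] = 5.0
        refiltered = apply_filters(calls.drop(columns=["flags", "pass"]))
        assert "low_score" in refiltered["flags"].iat[0]

    def test_bq_exactly_fifteen_fails(self):
        flags, ok = self._flags(mean_bq=15.0)
        assert "low_bq" in flags and not ok

    def test_bq_just_above_fifteen_passes(self):
        flags, ok = self._flags(mean_bq=15.01)
        assert ok

    @pytest.mark.parametrize("fwd", [0.20, 0.80])
    def test_strand_band_edges_pass(self, fwd):
        _, ok = self._flags(fwd_frac=fwd)
        assert ok

    @pytest.mark.parametrize("fwd", [0.199, 0.801, 0.85, 0.0, 1.0])
    def test_strand_outside_band_fails(self, fwd):
        flags, ok = self._flags(fwd_frac=fwd)
        assert "strand_bias" in flags and not ok

    @pytest.mark.parametrize("af", [0.01, 0.10])
    def test_fraction_window_edges_pass(self, af):
        _, ok = self._flags(alt_count=int(af * 10000), depth=10000)
        assert ok

    def test_fraction_fifteen_percent_fails(self):
        flags, ok = self._flags(alt_count=360, depth=2400)  # AF 0.15
        assert "fraction_out_of_range" in flags and not ok

    def test_low_bq_example_excluded(self):
        flags, ok = self._flags(mean_bq=10.0)
        assert "low_bq" in flags and not ok


def test_filters_commute_with_independent_predicates():
    """'pass' equals the conjunction of the four per-call predicates, so any
    application order gives the same surviving set."""
    rng = np.random.default_rng(0)
    rows = [
        make_call_row(
            alt_count=int(rng.integers(0, 300)),
            depth=2400,
            mean_bq=float(rng.uniform(0, 40)),
            fwd_frac=float(rng.uniform(0, 1)),
        )
        for _ in range(200)
    ]
    calls = scored_calls(rows)
    th = FilterThresholds()
    expected = (
        (calls["score"] > th.min_score)
        & (calls["mean_bq"] > th.min_bq)
        & calls["fwd_frac"].between(th.strand_lo, th.strand_hi)
        & calls["allele_fraction"].between(th.af_lo, th.af_hi)
    )
    assert (calls["pass"] == expected).all()


def test_malformed_thresholds_rejected():
    with pytest.raises(ValueError):
        FilterThresholds(af_lo=0.10, af_hi=0.01)
    with pytest.raises(ValueError):
        FilterThresholds(strand_lo=0.8, strand_hi=0.2)


@pytest.mark.parametrize("depth,flagged", [(999, True), (1000, False), (1001, False)])
def test_low_coverage_review_boundary(depth, flagged):
    calls = scored_calls([make_call_row(depth=depth, alt_count=depth // 40)])
    assert bool(calls["low_coverage_review"].iat[0]) is flagged
    # review never excludes
    assert bool(calls["pass"].iat[0])


def test_all_high_depth_input_unchanged_by_review_flag():
    calls = scored_calls([make_call_row(depth=2400), make_call_row(depth=1500)])
    assert not calls["low_coverage_review"].any()
    without = calls.drop(columns=["low_coverage_review"])
    pd.testing.assert_frame_equal(
        without, flag_low_coverage(without, 1000).drop(columns=["low_coverage_review"])
    )


def test_ledger_conserves_candidates():
    rng = np.random.default_rng(1)
    rows = [
        make_call_row(
            alt_count=int(rng.integers(0, 400)),
            mean_bq=float(rng.uniform(0, 40)),
            fwd_frac=float(rng.uniform(0, 1)),
        )
        for _ in range(500)
    ]
    calls = scored_calls(rows)
    ledger = filter_ledger(calls)
    assert sum(ledger.values()) == len(calls)
    assert ledger["survivors"] == int(calls["pass"].sum())
    assert set(ledger) == set(EXCLUSION_FLAGS) | {"survivors"}
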