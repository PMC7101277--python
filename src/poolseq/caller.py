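"""Low-allele-fraction variant calling on pooled pileup counts.

At pooled depth of a few thousand reads, sequencing error alone produces
alt-allele observations at nearly every targeted position, so candidate
generation must be followed by aggressive filtering.  The candidate score is
a Phred-scaled binomial likelihood ratio comparing the maximum-likelihood
allele fraction against the error-only model:

    score = 10 * log10[ Binom(k | n, f_hat) / Binom(k | n, eps/3) ],
    f_hat = max(k / n, eps / 3),

clipped below at zero.  The filter stack then keeps a call only if its score
exceeds 5 Phred, its mean base quality exceeds 15, its forward-strand
fraction lies within [0.20, 0.80], and its allele fraction lies within
[1%, 10%] (below: indistinguishable from error; above: three or more allele
copies in one pool — too common for a highly penetrant rare variant).
Calls at pools with depth under 1000x are additionally flagged for manual
review but are not auto-excluded.

Filters are independent per call, so a variant survives end-to-end only when
its calls pass in both pools of its carrier's pair — the decoder enforces
the pairing itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "FilterThresholds",
    "score_candidate",
    "score_candidates",
    "apply_filters",
    "flag_low_coverage",
    "filter_ledger",
    "EXCLUSION_FLAGS",
]

# fixed priority order used when one call trips several filters
EXCLUSION_FLAGS = ("low_score", "low_bq", "strand_bias", "fraction_out_of_range")

_LOG10 = np.log(10.0)


@dataclass(frozen=True)
class FilterThresholds:
    """Quality-filter thresholds.

    ``min_score`` and ``min_bq`` are strict lower bounds ("over 5", "over
    15"); the strand and allele-fraction windows are inclusive keep-ranges.
    ``review_depth`` is the strict coverage bound below which calls are
    flagged for manual review.
    """

    min_score: float = 5.0
    min_bq: float = 15.0
    strand_lo: float = 0.20
    strand_hi: float = 0.80
    af_lo: float = 0.01
    af_hi: float = 0.10
    review_depth: int = 1000

    def __post_init__(self) -> None:
        if self.strand_lo >= self.strand_hi:
            raise ValueError("strand window: lower bound must be < upper bound")
        if self.af_lo >= self.af_hi:
            raise ValueError("allele-fraction window: lower bound must be < upper bound")
        if not (0 <= self.strand_lo and self.strand_hi <= 1):
            raise ValueError("strand window must lie within [0, 1]")
        if not (0 <= self.af_lo and self.af_hi <= 1):
            raise ValueError("allele-fraction window must lie within [0, 1]")


def score_candidate(alt_count: int, depth: int, error_rate: float) -> float:
    """Phred-scaled likelihood-ratio score for one pileup entry."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    f0 = error_rate / 3.0
    f_hat = max(alt_count / depth, f0)
    ll1 = binom.logpmf(alt_count, depth, f_hat)
    ll0 = binom.logpmf(alt_count, depth, f0)
    return float(max(0.0, 10.0 * (ll1 - ll0) / _LOG10))


def score_candidates(counts: pd.DataFrame, error_rate: float) -> pd.DataFrame:
    """Score every pileup entry; adds ``allele_fraction`` and ``score``.

    Vectorized version of `score_candidate` over the pileup table.
    """
    calls = counts.copy()
    if len(calls) == 0:
        calls["allele_fraction"] = pd.Series(dtype=float)
        calls["score"] = pd.Series(dtype=float)
        return calls
    k = calls["alt_count"].to_numpy(dtype=np.int64)
    n = calls["depth"].to_numpy(dtype=np.int64)
    if (n <= 0).any():
        raise ValueError("depth must be positive for all candidate entries")
    f0 = error_rate / 3.0
    af = k / n
    f_hat = np.maximum(af, f0)
    score = 10.0 * (binom.logpmf(k, n, f_hat) - binom.logpmf(k, n, f0)) / _LOG10
    calls["allele_fraction"] = af
    calls["score"] = np.maximum(0.0, score)
    return calls


def apply_filters(
    calls: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Apply the quality-filter stack; flags failures instead of deleting.

    Adds a semicolon-joined ``flags`` column and a boolean ``pass`` column
    (true iff no exclusion flag is set).  Filters commute: each is a pure
    per-call predicate, so any application order yields the same result.
    """
    th = thresholds or FilterThresholds()
    out = calls.copy()
    if len(out) == 0:
        out["flags"] = pd.Series(dtype=str)
        out["pass"] = pd.Series(dtype=bool)
        return out
    failed = {
        "low_score": ~(out["score"] > th.min_score).to_numpy(),
        "low_bq": ~(out["mean_bq"] > th.min_bq).to_numpy(),
        "strand_bias": ~out["fwd_frac"].between(th.strand_lo, th.strand_hi).to_numpy(),
        "fraction_out_of_range": ~out["allele_fraction"].between(th.af_lo, th.af_hi).to_numpy(),
    }
    joined = np.full(len(out), "", dtype=object)
    for name in EXCLUSION_FLAGS:
        joined = joined + np.where(failed[name], name + ";", "")
    flags = np.array([f.rstrip(";") for f in joined], dtype=object)
    out["flags"] = flags
    out["pass"] = flags == ""
    return out


def flag_low_coverage(
    calls: pd.DataFrame, depth_threshold: int = 1000
) -> pd.DataFrame:
    """Flag calls with depth strictly under ``depth_threshold`` for review.

    Review-flagged calls are NOT excluded (``pass`` is untouched); they are
    carried so downstream reports can list them separately.
    """
    out = calls.copy()
    out["low_coverage_review"] = out["depth"] < depth_threshold
    return out


def filter_ledger(calls: pd.DataFrame) -> dict[str, int]:
    """Per-reason exclusion counts (each excluded call tallied once, by its
    highest-priority flag) plus survivors; sums to the total candidate count."""
    ledger = {name: 0 for name in EXCLUSION_FLAGS}
    survivors = 0
    for flags in calls.get("flags", pd.Series(dtype=str)):
        if flags == "":
            survivors += 1
        else:
            ledger[flags.split(";")[0]] += 1
    ledger["survivors"] = survivors
    return ledger
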