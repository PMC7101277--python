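"""Case-control carrier-burden statistics.

The burden comparison counts distinct individuals carrying at least one
qualifying variant in each cohort and compares the carrier proportions.
The headline statistic is the ratio of carrier proportions (risk ratio)

    ratio = (carriers_a / n_a) / (carriers_b / n_b),

reported to two decimals, with the classical odds ratio

    OR = carriers_a * (n_b - carriers_b) / ((n_a - carriers_a) * carriers_b)

alongside, clearly labeled: on carrier tables of this kind the two differ
(e.g. 48/463 vs 31/480 gives ratio 1.61 but OR 1.67), and the proportion
ratio is what the per-table printed values correspond to.  Significance is
assessed with a two-sided Fisher exact test computed by full enumeration of
the hypergeometric support (the "minimum-likelihood" two-sided convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "CarrierTable",
    "BurdenResult",
    "tabulate_carriers",
    "ratio_statistic",
    "odds_ratio",
    "fisher_exact_two_sided",
    "burden_result",
    "round_half_away",
    "percentage",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for ratios/percentages)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def percentage(carriers: int, n: int, ndigits: int = 2) -> float:
    """Carrier percentage, rounded half away from zero."""
    return round_half_away(100.0 * carriers / n, ndigits)


@dataclass(frozen=True)
class CarrierTable:
    """Distinct-carrier counts for two cohorts under one variant tier."""

    carriers_a: int
    n_a: int
    carriers_b: int
    n_b: int
    label: str = "all"
    tier: str = "all"

    def __post_init__(self) -> None:
        if self.n_a <= 0 or self.n_b <= 0:
            raise ValueError("cohort sizes must be positive")
        for c, n in ((self.carriers_a, self.n_a), (self.carriers_b, self.n_b)):
            if not 0 <= c <= n:
                raise ValueError(f"carrier count {c} outside [0, {n}]")


@dataclass(frozen=True)
class BurdenResult:
    table: CarrierTable
    ratio: float  # carrier-proportion ratio; inf when carriers_b == 0
    odds_ratio: float  # classical OR; nan when a cell is zero
    p_two_sided: float
    pct_a: float
    pct_b: float


def ratio_statistic(t: CarrierTable) -> float:
    """Ratio of carrier proportions; ``inf`` when the control side is zero
    (and ``nan`` for 0/0)."""
    pa = t.carriers_a / t.n_a
    pb = t.carriers_b / t.n_b
    if pb == 0.0:
        return math.nan if pa == 0.0 else math.inf
    return pa / pb


def odds_ratio(t: CarrierTable) -> float:
    """Classical 2x2 odds ratio; ``nan`` when any cell is zero (no
    continuity correction is applied)."""
    a, b = t.carriers_a, t.n_a - t.carriers_a
    c, d = t.carriers_b, t.n_b - t.carriers_b
    if min(a, b, c, d) == 0:
        return math.nan
    return (a * d) / (b * c)


def fisher_exact_two_sided(t: CarrierTable) -> float:
    """Two-sided Fisher exact p by enumeration of the hypergeometric support.

    Conditional on the margins, the count of cohort-A carriers follows
    Hypergeom(N, K, n_a) with N = n_a + n_b total subjects and
    K = carriers_a + carriers_b total carriers.  The two-sided p sums the
    probabilities of all tables no more likely than the observed one
    (with a small relative tolerance against floating-point ties).
    """
    N = t.n_a + t.n_b
    K = t.carriers_a + t.carriers_b
    lo = max(0, K - t.n_b)
    hi = min(K, t.n_a)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, t.n_a)
    observed = hypergeom.pmf(t.carriers_a, N, K, t.n_a)
    p = float(pmf[pmf <= observed * (1.0 + 1e-9)].sum())
    return min(1.0, p)


def burden_result(t: CarrierTable) -> BurdenResult:
    return BurdenResult(
        table=t,
        ratio=ratio_statistic(t),
        odds_ratio=odds_ratio(t),
        p_two_sided=fisher_exact_two_sided(t),
        pct_a=percentage(t.carriers_a, t.n_a),
        pct_b=percentage(t.carriers_b, t.n_b),
    )


def _carrier_samples(
    prioritized: pd.DataFrame,
    subset: set[str] | None,
    tiers: set[str] | None,
) -> set[str]:
    carriers: set[str] = set()
    for row in prioritized.itertuples():
        if row.tier == "excluded":
            continue
        if tiers is not None and row.tier not in tiers:
            continue
        gene = getattr(row, "gene", None)
        if subset is not None and gene not in subset:
            continue
        if isinstance(row.carriers, str) and row.carriers:
            carriers.update(row.carriers.split(";"))
    return carriers


def tabulate_carriers(
    prioritized_a: pd.DataFrame,
    prioritized_b: pd.DataFrame,
    n_a: int,
    n_b: int,
    subset: set[str] | None = None,
    tiers: set[str] | None = None,
    label: str = "all",
) -> CarrierTable:
    """Count distinct carrier individuals per cohort.

    ``tiers`` of None counts every non-excluded variant; pass
    ``{"likely_pathogenic", "known_pathogenic"}`` for the pathogenic burden.
    A sample carrying several qualifying variants is counted once.
    """
    ca = _carrier_samples(prioritized_a, subset, tiers)
    cb = _carrier_samples(prioritized_b, subset, tiers)
    tier_label = "all" if tiers is None else "+".join(sorted(tiers))
    return CarrierTable(
        carriers_a=len(ca), n_a=n_a, carriers_b=len(cb), n_b=n_b,
        label=label, tier=tier_label,
    )


def burden_report(tables: list[CarrierTable]) -> pd.DataFrame:
    """Tabular report of burden results for a list of carrier tables."""
    rows = []
    for t in tables:
        r = burden_result(t)
        rows.append({
            "label": t.label, "tier": t.tier,
            "carriers_a": t.carriers_a, "n_a": t.n_a,
            "carriers_b": t.carriers_b, "n_b": t.n_b,
            "pct_a": r.pct_a, "pct_b": r.pct_b,
            "ratio": round_half_away(r.ratio, 2) if math.isfinite(r.ratio) else r.ratio,
            "odds_ratio": round_half_away(r.odds_ratio, 2)
            if math.isfinite(r.odds_ratio) else r.odds_ratio,
            "p_two_sided": round_half_away(r.p_two_sided, 4),
        })
    return pd.DataFrame(rows)
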