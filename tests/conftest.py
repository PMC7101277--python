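import numpy as np
import pandas as pd
import pytest

from poolseq.caller import apply_filters, flag_low_coverage, score_candidates
from poolseq.design import build_design
from poolseq.regions import Region
from poolseq.simulate import CoverageModel, ErrorModel, VariantSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_design():
    """30 samples over 12 pools of capacity 6 (feasible, unsaturated)."""
    return build_design(30, 12, 6, seed=7, cohort_label="toy")


@pytest.fixture(scope="session")
def study_design():
    """The study-scale geometry: 463 samples, 48 pools of 20."""
    return build_design(463, 48, 20, seed=11, cohort_label="cases")


@pytest.fixture()
def toy_regions():
    return [Region("chr1", 100, 159, "GENEA"), Region("chr2", 500, 539, "GENEB")]


def make_call_row(
    pool_id=0, contig="chr1", pos=100, ref="A", alt="T",
    depth=2400, alt_count=60, mean_bq=30.0, fwd_frac=0.5,
):
    return {
        "pool_id": pool_id, "contig": contig, "pos": pos, "ref": ref,
        "alt": alt, "depth": depth, "alt_count": alt_count,
        "mean_bq": mean_bq, "fwd_frac": fwd_frac,
    }


def scored_calls(rows, error_rate=1e-3):
    """Pileup rows -> scored, filtered, coverage-flagged call table."""
    counts = pd.DataFrame(rows)
    calls = score_candidates(counts, error_rate)
    calls = apply_filters(calls)
    return flag_low_coverage(calls)


def run_cohort_stages(design, regions, variants, cov=None, err=None, seed=0):
    """simulate -> score -> filter -> review-flag, returning (calls, truth)."""
    err = err or ErrorModel()
    counts, truth = simulate_cohort(design, regions, variants, cov, err, seed=seed)
    calls = score_candidates(counts, err.error_rate)
    calls = apply_filters(calls)
    return flag_low_coverage(calls), truth
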