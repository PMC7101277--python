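"""Synthetic pooled pileup generation: dilution, noise and artifact models."""

import numpy as np
import pandas as pd
import pytest

from poolseq.design import build_design
from poolseq.regions import Region
from poolseq.simulate import (CoverageModel, ErrorModel, VariantSpec,
                              inject_artifacts, simulate_cohort,
                              write_pileups_tsv)


def _singleton(design, contig="chr1", pos=100, ref="A", alt="T", zyg="het",
               sample=None):
    sample = sample or design.sample_ids[0]
    return VariantSpec(contig, pos, ref, alt, carriers={sample: zyg})


def test_truth_table_expected_fractions(small_design, toy_regions):
    het = _singleton(small_design, pos=100, zyg="het")
    hom = _singleton(small_design, pos=101, ref="C", alt="G", zyg="hom",
                     sample=small_design.sample_ids[1])
    _, truth = simulate_cohort(
        small_design, toy_regions, [het, hom], err=ErrorModel(error_rate=0.0)
    )
    two_n = 2 * small_design.pool_size
    by_pos = truth.set_index("pos")
    for pos, copies in ((100, 1), (101, 2)):
        fracs = dict(
            part.split(":") for part in by_pos.loc[pos, "expected_fraction"].split(";")
        )
        assert len(fracs) == 2  # both carrier pools, no others
        assert all(float(f) == pytest.approx(copies / two_n) for f in fracs.values())


def test_no_signal_no_noise_yields_empty_table(small_design, toy_regions):
    counts, truth = simulate_cohort(
        small_design, toy_regions, [], err=ErrorModel(error_rate=0.0)
    )
    assert len(counts) == 0
    assert len(truth) == 0


def test_noiseless_counts_only_in_carrier_pools(small_design, toy_regions):
    v = _singleton(small_design)
    counts, _ = simulate_cohort(
        small_design, toy_regions, [v], err=ErrorModel(error_rate=0.0), seed=5
    )
    carrier_pools = set(small_design.pools_of(v.carriers and list(v.carriers)[0]))
    assert set(counts["pool_id"]) <= carrier_pools
    assert (counts["alt"] == "T").all()
    expected = 1 / (2 * small_design.pool_size)
    af = counts["alt_count"] / counts["depth"]
    assert af.between(expected / 2, expected * 2).all()  # binomial spread


def test_unknown_carrier_and_outside_site_raise(small_design, toy_regions):
    with pytest.raises(ValueError, match="not in cohort"):
        simulate_cohort(
            small_design, toy_regions,
            [VariantSpec("chr1", 100, "A", "T", carriers={"ghost": "het"})],
        )
    with pytest.raises(ValueError, match="outside the target regions"):
        simulate_cohort(
            small_design, toy_regions, [_singleton(small_design, pos=99999)]
        )


def test_same_seed_byte_identical(small_design, toy_regions, tmp_path):
    v = _singleton(small_design)
    paths = []
    for run in ("a", "b"):
        counts, truth = simulate_cohort(
            small_design, toy_regions, [v], err=ErrorModel(), seed=123
        )
        counts, artifacts = inject_artifacts(
            counts, toy_regions, ErrorModel(artifact_rate=0.01), seed=9,
            pools=range(small_design.n_pools),
        )
        p = tmp_path / f"{run}.tsv"
        write_pileups_tsv(counts, p)
        truth.to_csv(tmp_path / f"{run}.truth.tsv", sep="\t", index=False)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()
    assert (tmp_path / "a.truth.tsv").read_bytes() == (tmp_path / "b.truth.tsv").read_bytes()


def test_error_rate_produces_widespread_low_fraction_noise(small_design, toy_regions):
    counts, _ = simulate_cohort(
        small_design, toy_regions, [], err=ErrorModel(error_rate=5e-3), seed=1
    )
    # noise appears across many pool-site combinations but at tiny fractions
    assert len(counts) > 100
    af = counts["alt_count"] / counts["depth"]
    assert af.max() < 0.01


def test_artifact_rate_zero_leaves_counts_unchanged(small_design, toy_regions):
    counts, _ = simulate_cohort(
        small_design, toy_regions, [_singleton(small_design)], seed=3
    )
    out, artifacts = inject_artifacts(counts, toy_regions, ErrorModel(), seed=3)
    assert len(artifacts) == 0
    pd.testing.assert_frame_equal(out, counts)


def test_artifacts_are_disqualified_and_disjoint(small_design, toy_regions):
    v = _singleton(small_design)
    counts, truth = simulate_cohort(small_design, toy_regions, [v], seed=3)
    err = ErrorModel(artifact_rate=0.02, artifact_strand_level=0.95)
    out, artifacts = inject_artifacts(
        counts, toy_regions, err, seed=4,
        pools=range(small_design.n_pools),
        exclude_keys={(v.contig, v.pos, v.alt)},
    )
    assert len(artifacts) > 10
    assert len(out) == len(counts) + len(artifacts)
    # every artifact fails base quality or strand balance by construction
    disqualified = (artifacts["mean_bq"] < 15) | (
        (artifacts["fwd_frac"] < 0.2) | (artifacts["fwd_frac"] > 0.8)
    )
    assert disqualified.all()
    truth_keys = set(zip(truth["contig"], truth["pos"], truth["alt"]))
    art_keys = set(zip(artifacts["contig"], artifacts["pos"], artifacts["alt"]))
    assert not art_keys & truth_keys


def test_strand_level_forces_extreme_fractions(small_design, toy_regions):
    counts, _ = simulate_cohort(small_design, toy_regions, [], seed=0)
    err = ErrorModel(artifact_rate=0.05, artifact_strand_level=0.95)
    _, artifacts = inject_artifacts(
        counts, toy_regions, err, seed=1, pools=range(small_design.n_pools)
    )
    strandy = artifacts[(artifacts["fwd_frac"] < 0.2) | (artifacts["fwd_frac"] > 0.8)]
    assert len(strandy) > 0
    assert ((strandy["fwd_frac"] > 0.8) | (strandy["fwd_frac"] < 0.2)).all()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"error_rate": 0.5},
        {"error_rate": -1e-4},
        {"artifact_strand_level": 0.5},
        {"artifact_rate": 2.0},
    ],
)
def test_error_model_validation(kwargs):
    with pytest.raises(ValueError):
        ErrorModel(**kwargs)


def test_coverage_floor_is_respected(small_design, toy_regions):
    cov = CoverageModel(mean_depth=500.0, sd_depth=400.0, min_depth=400)
    counts, _ = simulate_cohort(
        small_design, toy_regions,
        [_singleton(small_design)], cov=cov,
        err=ErrorModel(error_rate=5e-3), seed=8,
    )
    assert (counts["depth"] >= 400).all()
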