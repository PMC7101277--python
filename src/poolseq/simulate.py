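"""Synthetic pooled pileup generation.

Emulates the read-count evidence a targeted pooled-sequencing experiment
produces, without simulating reads: for each pool and targeted site the
generator draws a depth, then per non-reference allele a binomial alt-read
count whose success probability combines the diluted carrier fraction with a
per-base substitution error rate.  A heterozygous singleton in a pool of 20
diploid samples contributes one allele copy out of 40, i.e. an expected alt
fraction of 2.5%; two copies (a homozygote, or two carriers in one pool)
give 5%.

Base-quality and strand summaries are drawn from separate distributions for
true-variant evidence versus error/artifact evidence, so the downstream
quality filters (mean base quality > 15, strand fraction within [0.2, 0.8])
can be exercised from both sides.  `inject_artifacts` plants additional
artifact entries that are, by construction, disqualified by at least one of
those two filters, and returns them in a companion list for specificity
scoring.

The pileup table schema (TSV-serializable) is:
``pool_id, contig, pos, ref, alt, depth, alt_count, mean_bq, fwd_frac``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import PoolDesign
from .regions import Region, region_sites, site_in_regions

__all__ = [
    "CoverageModel",
    "ErrorModel",
    "VariantSpec",
    "simulate_cohort",
    "inject_artifacts",
    "read_pileups_tsv",
    "write_pileups_tsv",
]

BASES = ("A", "C", "G", "T")

PILEUP_COLUMNS = [
    "pool_id", "contig", "pos", "ref", "alt",
    "depth", "alt_count", "mean_bq", "fwd_frac",
]

# annotation payload columns carried through the truth table so the
# prioritizer fixture can be built without a live database
ANNOTATION_COLUMNS = [
    "gene", "consequence", "splice_offset", "max_freq",
    "hom_seen", "condel", "cadd", "known_functional",
]


@dataclass(frozen=True)
class CoverageModel:
    """Per-pool, per-site depth: rounded normal truncated below at a floor.

    Defaults match the patient-pool regime of the targeted experiment this
    package models: mean 2396x, SD 574x, with essentially all targeted sites
    above 400x (the floor).
    """

    mean_depth: float = 2396.0
    sd_depth: float = 574.0
    min_depth: int = 400

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.sd_depth < 0 or self.min_depth < 0:
            raise ValueError("coverage model requires mean > 0, sd >= 0, floor >= 0")


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing-noise and artifact model.

    ``error_rate`` is the per-base substitution error rate epsilon, spread
    uniformly over the three non-reference alleles (epsilon/3 each).  True
    alleles and artifacts carry distinct base-quality distributions that
    bracket the BQ > 15 filter; strand-biased artifacts sit outside the
    [0.2, 0.8] keep band at level ``artifact_strand_level`` (mirrored to
    either strand).  ``artifact_rate`` is the per pool-site probability that
    `inject_artifacts` plants an artifact entry.
    """

    error_rate: float = 1e-3
    true_bq_mean: float = 30.0
    true_bq_sd: float = 3.0
    artifact_bq_mean: float = 8.0
    artifact_bq_sd: float = 3.0
    noise_bq_mean: float = 10.0
    noise_bq_sd: float = 4.0
    true_strand_sd: float = 0.05
    artifact_strand_level: float = 0.95
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.01:
            raise ValueError("error_rate must lie in [0, 0.01)")
        if not 0.8 < self.artifact_strand_level <= 1.0:
            raise ValueError("artifact_strand_level must lie in (0.8, 1.0]")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be a probability")


@dataclass(frozen=True)
class VariantSpec:
    """A planted rare variant: site, alleles, carriers and annotation payload.

    ``carriers`` maps sample id -> zygosity ("het" contributes one allele
    copy to each of the carrier's two pools, "hom" two copies).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    carriers: Mapping[str, str]
    annotation: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")
        for zyg in self.carriers.values():
            if zyg not in ("het", "hom"):
                raise ValueError(f"zygosity must be het|hom, got {zyg!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


def reference_base(contig: str, pos: int) -> str:
    """Deterministic pseudo-reference base for sites without a planted variant."""
    return BASES[zlib.crc32(f"{contig}:{pos}".encode()) % 4]


def _copies_per_pool(
    design: PoolDesign, variants: Sequence[VariantSpec]
) -> dict[tuple[str, int, str, str], dict[int, int]]:
    copies: dict[tuple[str, int, str, str], dict[int, int]] = {}
    for v in variants:
        per_pool = copies.setdefault(v.key, {})
        for sample, zyg in v.carriers.items():
            if sample not in design.assignment:
                raise ValueError(
                    f"carrier {sample!r} of {v.contig}:{v.pos} is not in "
                    f"cohort {design.cohort_label!r}"
                )
            n = 1 if zyg == "het" else 2
            for pool in design.pools_of(sample):
                per_pool[pool] = per_pool.get(pool, 0) + n
    return copies


def _truth_table(
    design: PoolDesign,
    variants: Sequence[VariantSpec],
    copies: Mapping[tuple[str, int, str, str], Mapping[int, int]],
) -> pd.DataFrame:
    rows = []
    two_n = 2 * design.pool_size
    for v in variants:
        per_pool = copies[v.key]
        rows.append({
            "contig": v.contig,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "carriers": ";".join(
                f"{s}:{z}" for s, z in sorted(v.carriers.items())
            ),
            "pool_copies": ";".join(
                f"{p}:{c}" for p, c in sorted(per_pool.items())
            ),
            "expected_fraction": ";".join(
                f"{p}:{c / two_n:.10g}" for p, c in sorted(per_pool.items())
            ),
            **{col: v.annotation.get(col, np.nan) for col in ANNOTATION_COLUMNS},
        })
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "carriers",
                                       "pool_copies", "expected_fraction",
                                       *ANNOTATION_COLUMNS])


def simulate_cohort(
    design: PoolDesign,
    regions: Sequence[Region],
    variants: Sequence[VariantSpec],
    cov: CoverageModel | None = None,
    err: ErrorModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-pool per-site pileup counts plus a ground-truth table.

    For a site carrying ``c`` planted allele copies in a pool of ``K``
    samples, the alt-read success probability is
    ``p = f * (1 - eps) + eps / 3`` with ``f = c / (2 K)`` (a true alt read
    can itself be miscalled; any read can be miscalled into the alt).
    Rows are emitted only for observed alt alleles (alt_count > 0).

    Deterministic given ``seed``: same inputs, byte-identical tables.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    cov = cov or CoverageModel()
    err = err or ErrorModel()
    for v in variants:
        if not site_in_regions(regions, v.contig, v.pos):
            raise ValueError(
                f"variant site {v.contig}:{v.pos} lies outside the target regions"
            )
    copies = _copies_per_pool(design, variants)

    sites = [(c, p) for c, p, _ in region_sites(regions)]
    refs = {}
    for key in copies:
        refs[key[:2]] = key[2]
    ref_by_site = [refs.get(s, reference_base(*s)) for s in sites]

    # planted-copy lookup indexed by (site index, alt base)
    site_index = {s: i for i, s in enumerate(sites)}
    planted: dict[tuple[int, str], dict[int, int]] = {}
    for (contig, pos, ref, alt), per_pool in copies.items():
        planted[(site_index[(contig, pos)], alt)] = dict(per_pool)

    rng = np.random.default_rng(seed)
    n_sites = len(sites)
    eps = err.error_rate
    two_n = 2 * design.pool_size
    frames = []
    for pool in range(design.n_pools):
        depth = np.maximum(
            cov.min_depth,
            np.rint(rng.normal(cov.mean_depth, cov.sd_depth, size=n_sites)),
        ).astype(np.int64)
        for alt in BASES:
            mask = np.array([r != alt for r in ref_by_site])
            p = np.full(n_sites, eps / 3.0)
            truth = np.zeros(n_sites, dtype=bool)
            for (si, a), per_pool in planted.items():
                if a == alt and pool in per_pool:
                    f = per_pool[pool] / two_n
                    p[si] = min(1.0, f * (1.0 - eps) + eps / 3.0)
                    truth[si] = True
            k = rng.binomial(depth, p) * mask
            obs = np.flatnonzero(k > 0)
            if obs.size == 0:
                continue
            is_true = truth[obs]
            bq = np.where(
                is_true,
                rng.normal(err.true_bq_mean, err.true_bq_sd, size=obs.size),
                rng.normal(err.noise_bq_mean, err.noise_bq_sd, size=obs.size),
            )
            fwd = np.where(
                is_true,
                rng.normal(0.5, err.true_strand_sd, size=obs.size),
                rng.normal(0.5, 0.25, size=obs.size),
            )
            frames.append(pd.DataFrame({
                "pool_id": pool,
                "contig": [sites[i][0] for i in obs],
                "pos": [sites[i][1] for i in obs],
                "ref": [ref_by_site[i] for i in obs],
                "alt": alt,
                "depth": depth[obs],
                "alt_count": k[obs],
                "mean_bq": np.round(np.clip(bq, 0.0, None), 2),
                "fwd_frac": np.round(np.clip(fwd, 0.0, 1.0), 4),
            }))
    if frames:
        counts = pd.concat(frames, ignore_index=True)
        counts = counts.sort_values(
            ["pool_id", "contig", "pos", "alt"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        counts = pd.DataFrame(columns=PILEUP_COLUMNS)
    return counts, _truth_table(design, variants, copies)


def _draw_artifact_bq(rng: np.random.Generator, err: ErrorModel) -> float:
    """Artifact base quality, guaranteed below the BQ filter threshold (15)."""
    for _ in range(100):
        bq = rng.normal(err.artifact_bq_mean, err.artifact_bq_sd)
        if 0.0 <= bq < 15.0:
            return float(bq)
    return 8.0


def _draw_artifact_strand(rng: np.random.Generator, err: ErrorModel) -> float:
    """Strand fraction outside the [0.2, 0.8] keep band, on a random strand."""
    level = err.artifact_strand_level
    s = level if rng.random() < 0.5 else 1.0 - level
    fwd = float(np.clip(s + rng.normal(0.0, 0.02), 0.0, 1.0))
    if 0.2 <= fwd <= 0.8:  # guard for levels close to the band edge
        fwd = 0.805 if s > 0.5 else 0.195
    return fwd


def inject_artifacts(
    counts: pd.DataFrame,
    regions: Sequence[Region],
    err: ErrorModel,
    seed: int = 0,
    pools: Sequence[int] | None = None,
    exclude_keys: Iterable[tuple[str, int, str]] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant low-BQ and/or strand-biased artifact entries in single pools.

    Each targeted (pool, site) independently receives an artifact with
    probability ``err.artifact_rate``.  Every artifact is disqualified by
    construction: its mean base quality is below 15 and/or its forward-strand
    fraction lies outside [0.2, 0.8]; its allele fraction is drawn inside the
    callable [1%, 8%] window so that only the quality filters can reject it.

    ``exclude_keys`` are (contig, pos, alt) triples (typically the planted
    truth variants) that artifacts must not collide with.  Returns the
    augmented table and the companion artifact list (same schema).
    """
    if err.artifact_rate == 0.0:
        return counts.copy(), pd.DataFrame(columns=PILEUP_COLUMNS)
    rng = np.random.default_rng(seed)
    if pools is None:
        pools = sorted(counts["pool_id"].unique()) if len(counts) else [0]
    sites = [(c, p) for c, p, _ in region_sites(regions)]
    existing = set(
        zip(counts["pool_id"], counts["contig"], counts["pos"], counts["alt"])
    ) if len(counts) else set()
    excluded = set(exclude_keys)
    depths = counts["depth"].to_numpy() if len(counts) else np.array([2000])

    rows = []
    for pool in pools:
        hit = rng.random(len(sites)) < err.artifact_rate
        for si in np.flatnonzero(hit):
            contig, pos = sites[si]
            ref = reference_base(contig, pos)
            alts = [
                b for b in BASES
                if b != ref
                and (contig, pos, b) not in excluded
                and (pool, contig, pos, b) not in existing
            ]
            if not alts:
                continue
            alt = alts[int(rng.integers(len(alts)))]
            depth = int(depths[int(rng.integers(len(depths)))])
            af = rng.uniform(0.01, 0.08)
            mode = ("low_bq", "strand", "both")[int(rng.integers(3))]
            if mode in ("low_bq", "both"):
                bq = _draw_artifact_bq(rng, err)
            else:
                bq = float(rng.normal(err.true_bq_mean, err.true_bq_sd))
            if mode in ("strand", "both"):
                fwd = _draw_artifact_strand(rng, err)
            else:
                fwd = float(np.clip(rng.normal(0.5, err.true_strand_sd), 0, 1))
            rows.append({
                "pool_id": pool, "contig": contig, "pos": pos,
                "ref": ref, "alt": alt, "depth": depth,
                "alt_count": max(1, int(round(af * depth))),
                "mean_bq": round(max(bq, 0.0), 2),
                "fwd_frac": round(fwd, 4),
            })
            existing.add((pool, contig, pos, alt))
    artifacts = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    combined = pd.concat([counts, artifacts], ignore_index=True)
    combined = combined.sort_values(
        ["pool_id", "contig", "pos", "alt"], kind="mergesort"
    ).reset_index(drop=True)
    return combined, artifacts


def write_pileups_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_pileups_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
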