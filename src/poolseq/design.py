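"""Two-replicate overlapping pool designs.

In pooled sequencing each DNA sample is mixed into exactly two of the
cohort's pools.  A heterozygous variant private to one sample then appears at
low allele fraction in exactly that sample's two pools, so the unordered pool
pair acts as a combinatorial barcode: provided no two samples share a pair,
the carrier of a singleton variant is recovered by intersecting the pools in
which the variant was detected.  This module constructs such designs,
validates their invariants, and exposes the pair -> sample lookup the decoder
relies on.

A design for ``n_samples`` samples over ``n_pools`` pools of capacity
``pool_size`` is feasible when both

* ``2 * n_samples <= n_pools * pool_size`` (slot capacity), and
* ``n_samples <= C(n_pools, 2)`` (enough distinct pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from itertools import combinations
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DesignCapacityError",
    "PoolDesign",
    "build_design",
    "lookup_sample",
    "validate_design",
    "read_design_tsv",
    "write_design_tsv",
]


class DesignCapacityError(ValueError):
    """The requested pool geometry cannot host the cohort."""


@dataclass(frozen=True)
class PoolDesign:
    """A sample -> unordered pool-pair assignment for one cohort.

    Pool ids are dense integers ``0 .. n_pools - 1``; sample ids are opaque
    text labels.  ``assignment`` maps each sample to its sorted pool pair.
    """

    cohort_label: str
    n_pools: int
    pool_size: int
    seed: int
    assignment: Mapping[str, tuple[int, int]]

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)

    @cached_property
    def pair_to_sample(self) -> dict[tuple[int, int], str]:
        """Inverse of ``assignment``; valid only for injective designs."""
        return {pair: s for s, pair in self.assignment.items()}

    def pools_of(self, sample_id: str) -> tuple[int, int]:
        return self.assignment[sample_id]

    def pool_members(self) -> dict[int, list[str]]:
        members: dict[int, list[str]] = {p: [] for p in range(self.n_pools)}
        for sample, (a, b) in self.assignment.items():
            members[a].append(sample)
            members[b].append(sample)
        return members


def _check_feasible(n_samples: int, n_pools: int, pool_size: int) -> None:
    if n_pools < 2:
        raise DesignCapacityError(
            f"pool count: need at least 2 pools, got {n_pools}"
        )
    if pool_size < 1:
        raise DesignCapacityError(
            f"pool size: need at least 1 slot per pool, got {pool_size}"
        )
    if 2 * n_samples > n_pools * pool_size:
        raise DesignCapacityError(
            f"slot capacity: {n_samples} samples need {2 * n_samples} pool "
            f"slots but only {n_pools} x {pool_size} = {n_pools * pool_size} "
            "are available"
        )
    if n_samples > comb(n_pools, 2):
        raise DesignCapacityError(
            f"pair capacity: {n_samples} samples exceed the "
            f"{comb(n_pools, 2)} distinct pool pairs of {n_pools} pools"
        )


def _greedy_fill(
    rng: np.random.Generator, n_samples: int, n_pools: int, pool_size: int
) -> list[tuple[int, int]] | None:
    """One randomized greedy attempt; returns None on a dead end.

    Pairs are drawn with probability proportional to the product of free
    slots, which keeps pool occupancy balanced and makes dead ends rare even
    for fully saturated designs.
    """
    slots = [pool_size] * n_pools
    used: set[tuple[int, int]] = set()
    pairs: list[tuple[int, int]] = []
    for _ in range(n_samples):
        open_pools = [p for p in range(n_pools) if slots[p] > 0]
        candidates = [
            pq for pq in combinations(open_pools, 2) if pq not in used
        ]
        if not candidates:
            return None
        weights = np.array(
            [slots[a] * slots[b] for a, b in candidates], dtype=float
        )
        idx = int(rng.choice(len(candidates), p=weights / weights.sum()))
        a, b = candidates[idx]
        slots[a] -= 1
        slots[b] -= 1
        used.add((a, b))
        pairs.append((a, b))
    return pairs


def build_design(
    n_samples: int,
    n_pools: int,
    pool_size: int,
    seed: int,
    cohort_label: str = "cohort",
    max_restarts: int = 100,
) -> PoolDesign:
    """Construct a valid two-replicate design, deterministically from ``seed``.

    Greedy randomized pairing: repeatedly draw an unused pool pair among pools
    with free slots; on a dead end, restart with the next seed-derived stream.

    Raises
    ------
    DesignCapacityError
        If the geometry is infeasible (message names the violated
        constraint), or if no attempt completes within ``max_restarts``.
    """
    _check_feasible(n_samples, n_pools, pool_size)
    for attempt in range(max_restarts):
        rng = np.random.default_rng([int(seed), attempt])
        pairs = _greedy_fill(rng, n_samples, n_pools, pool_size)
        if pairs is not None:
            assignment = {
                f"{cohort_label}-{i:04d}": pq for i, pq in enumerate(pairs)
            }
            return PoolDesign(
                cohort_label=cohort_label,
                n_pools=n_pools,
                pool_size=pool_size,
                seed=seed,
                assignment=assignment,
            )
    raise DesignCapacityError(
        f"greedy pairing dead-ended in all {max_restarts} restarts for "
        f"(n_samples={n_samples}, n_pools={n_pools}, pool_size={pool_size})"
    )


def lookup_sample(
    design: PoolDesign, pool_pair: tuple[int, int]
) -> str | None:
    """Return the unique sample assigned exactly ``pool_pair``, or None."""
    a, b = pool_pair
    for p in (a, b):
        if not 0 <= p < design.n_pools:
            raise KeyError(f"unknown pool id {p} (design has {design.n_pools} pools)")
    return design.pair_to_sample.get((min(a, b), max(a, b)))


def validate_design(design: PoolDesign) -> list[str]:
    """Check every design invariant; returns a list of violations (empty = valid)."""
    report: list[str] = []
    occupancy = [0] * design.n_pools
    seen_pairs: dict[tuple[int, int], str] = {}
    for sample, pair in design.assignment.items():
        if len(pair) != 2 or pair[0] == pair[1]:
            report.append(f"sample {sample}: pools {pair} are not two distinct pools")
            continue
        a, b = sorted(pair)
        if not (0 <= a < design.n_pools and 0 <= b < design.n_pools):
            report.append(f"sample {sample}: pool id out of range in {pair}")
            continue
        occupancy[a] += 1
        occupancy[b] += 1
        if (a, b) in seen_pairs:
            report.append(
                f"injectivity: samples {seen_pairs[(a, b)]} and {sample} "
                f"share pool pair ({a}, {b})"
            )
        else:
            seen_pairs[(a, b)] = sample
    for p, occ in enumerate(occupancy):
        if occ > design.pool_size:
            report.append(
                f"capacity: pool {p} holds {occ} samples "
                f"(pool_size {design.pool_size})"
            )
    if 2 * design.n_samples > design.n_pools * design.pool_size:
        report.append(
            f"slot arithmetic: {2 * design.n_samples} slots used exceed "
            f"{design.n_pools * design.pool_size} available"
        )
    return report


def write_design_tsv(design: PoolDesign, path) -> None:
    """Serialize as TSV with metadata comment lines; round-trips losslessly."""
    with open(path, "w") as fh:
        fh.write(f"# cohort={design.cohort_label}\n")
        fh.write(f"# n_pools={design.n_pools}\n")
        fh.write(f"# pool_size={design.pool_size}\n")
        fh.write(f"# seed={design.seed}\n")
        fh.write("sample_id\tpool_a\tpool_b\n")
        for sample, (a, b) in design.assignment.items():
            fh.write(f"{sample}\t{a}\t{b}\n")


def read_design_tsv(path) -> PoolDesign:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    table = pd.read_csv(path, sep="\t", comment="#")
    assignment = {
        str(row.sample_id): (int(row.pool_a), int(row.pool_b))
        for row in table.itertuples()
    }
    return PoolDesign(
        cohort_label=meta.get("cohort", "cohort"),
        n_pools=int(meta["n_pools"]),
        pool_size=int(meta["pool_size"]),
        seed=int(meta.get("seed", 0)),
        assignment=assignment,
    )
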