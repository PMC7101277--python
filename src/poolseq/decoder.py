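"""Carrier identification by pool-pattern decoding.

A variant that survives filtering in a set of pools is matched against the
pool design: if exactly two pools support it and that unordered pair is
assigned to one sample, the sample is the carrier (``unique``).  Patterns of
more than two pools are resolved by an exhaustive minimal exact-cover search
over samples whose pool pairs lie inside the supporting set — the smallest
carrier set whose pairs exactly cover the pattern wins (``multi_carrier`` if
the minimal cover is unique, ``ambiguous`` if several tie).  A variant seen
in a single pool, or with no consistent cover of up to ``max_carriers``
samples, is ``undecodable``: a real heterozygous variant must show in both
of its carrier's pools.

Observed allele fractions double as a copy-number estimate: a singleton het
dilutes to 1/(2*pool_size) of the reads (2.5% at pool size 20), a
homozygote or two same-pool carriers to twice that (5%).
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd
import pysam

from .design import PoolDesign

__all__ = ["decode", "estimate_copies", "write_decoded_vcf", "DECODED_COLUMNS"]

DECODED_COLUMNS = [
    "contig", "pos", "ref", "alt", "pools", "status", "carriers",
    "n_carriers", "pool_copies", "mean_allele_fraction", "needs_review",
]


def estimate_copies(fraction: float, pool_size: int) -> int:
    """Nearest whole allele-copy count for an observed pool allele fraction.

    With ``pool_size`` diploid samples per pool there are ``2 * pool_size``
    allele slots, so copies = round(fraction * 2 * pool_size), rounding
    halves up.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"allele fraction {fraction} outside [0, 1]")
    return int(fraction * 2 * pool_size + 0.5)


def _minimal_covers(
    pools: frozenset[int], design: PoolDesign, max_carriers: int
) -> tuple[int, list[tuple[str, ...]]]:
    """All minimal-size sample sets whose pool pairs exactly cover ``pools``."""
    candidates = [
        s for s, pair in design.assignment.items() if set(pair) <= pools
    ]
    for k in range(1, max_carriers + 1):
        covers = []
        for combo in combinations(candidates, k):
            covered = set()
            for s in combo:
                covered.update(design.assignment[s])
            if covered == pools:
                covers.append(combo)
        if covers:
            return k, covers
    return 0, []


def decode(
    calls: pd.DataFrame,
    design: PoolDesign,
    max_carriers: int = 3,
    require_pass: bool = True,
) -> pd.DataFrame:
    """Group surviving calls by variant and assign carrier samples.

    ``calls`` is a scored+filtered call table; with ``require_pass`` only
    rows with ``pass`` true are used (the default).  Raises on pool ids
    absent from the design.  The cover search is capped at ``max_carriers``
    samples per variant: under the 10% allele-fraction ceiling, three or
    more copies per pool are already rejected upstream as too common.
    """
    work = calls
    if require_pass and "pass" in calls.columns:
        work = calls[calls["pass"]]
    if len(work):
        bad = set(work["pool_id"]) - set(range(design.n_pools))
        if bad:
            raise KeyError(f"unknown pool ids in calls: {sorted(bad)}")

    rows = []
    if len(work) == 0:
        return pd.DataFrame(columns=DECODED_COLUMNS)
    for (contig, pos, ref, alt), group in work.groupby(
        ["contig", "pos", "ref", "alt"], sort=True
    ):
        pools = frozenset(int(p) for p in group["pool_id"])
        mean_af = float(group["allele_fraction"].mean())
        needs_review = bool(group.get(
            "low_coverage_review", pd.Series(False, index=group.index)
        ).any())
        if len(pools) < 2:
            status, carriers = "undecodable", ()
        else:
            size, covers = _minimal_covers(pools, design, max_carriers)
            if not covers:
                status, carriers = "undecodable", ()
            elif len(covers) > 1:
                status, carriers = "ambiguous", ()
            elif size == 1:
                status, carriers = "unique", covers[0]
            else:
                status, carriers = "multi_carrier", covers[0]
        per_pool_af = dict(zip(group["pool_id"], group["allele_fraction"]))
        pool_copies = ";".join(
            f"{p}:{estimate_copies(per_pool_af[p], design.pool_size)}"
            for p in sorted(per_pool_af)
        )
        rows.append({
            "contig": contig, "pos": pos, "ref": ref, "alt": alt,
            "pools": ";".join(str(p) for p in sorted(pools)),
            "status": status,
            "carriers": ";".join(sorted(carriers)),
            "n_carriers": len(carriers),
            "pool_copies": pool_copies,
            "mean_allele_fraction": round(mean_af, 6),
            "needs_review": needs_review,
        })
    return pd.DataFrame(rows, columns=DECODED_COLUMNS)


def write_decoded_vcf(decoded: pd.DataFrame, path, design: PoolDesign | None = None) -> None:
    """Write decoded variants as a minimal sites-only VCF.

    Carriers, supporting pools, decoding status and copy estimates go into
    INFO; per-sample genotype columns are omitted (pooled sequencing has no
    per-sample reads).
    """
    header = pysam.VariantHeader()
    header.add_meta("source", "poolseq-decode")
    for line in (
        '##INFO=<ID=POOLS,Number=.,Type=Integer,Description="Supporting pool ids">',
        '##INFO=<ID=CARRIERS,Number=.,Type=String,Description="Decoded carrier sample ids">',
        '##INFO=<ID=STATUS,Number=1,Type=String,Description="Decoding status">',
        '##INFO=<ID=COPIES,Number=.,Type=String,Description="Estimated allele copies per pool">',
        '##INFO=<ID=AF_MEAN,Number=1,Type=Float,Description="Mean allele fraction across supporting pools">',
        '##INFO=<ID=REVIEW,Number=0,Type=Flag,Description="Supported by a pool under the coverage review threshold">',
    ):
        header.add_line(line)
    contigs = sorted(set(decoded["contig"])) if len(decoded) else []
    max_pos = int(decoded["pos"].max()) + 1000 if len(decoded) else 1000
    for contig in contigs:
        header.contigs.add(contig, length=max_pos)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        ordered = decoded.sort_values(["contig", "pos", "alt"], kind="mergesort")
        for row in ordered.itertuples():
            rec = vcf.new_record(
                contig=row.contig,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            rec.info["POOLS"] = tuple(int(p) for p in str(row.pools).split(";"))
            if row.carriers:
                rec.info["CARRIERS"] = tuple(str(row.carriers).split(";"))
            rec.info["STATUS"] = row.status
            rec.info["COPIES"] = tuple(str(row.pool_copies).split(";"))
            rec.info["AF_MEAN"] = float(row.mean_allele_fraction)
            if row.needs_review:
                rec.info["REVIEW"] = True
            vcf.write(rec)
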