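"""Rule-based variant prioritization.

Decoded variants joined with a flat annotation table (gene, consequence,
population frequency, homozygote flag, Condel, CADD, known-functional flag)
pass through a fixed cascade:

1. region filter — keep exonic consequences and splice-affecting variants
   within +/-6 bp of an exon boundary; deeper intronic variants are excluded
   as uninterpretable;
2. rarity filter — exclude variants with maximum population frequency above
   1/1000 in any database, or ever observed homozygous (a variant that common
   cannot be a highly penetrant cause of a severe phenotype);
3. pathogenicity classification — known functionally validated variants are
   ``known_pathogenic``; loss-of-function consequences (nonsense, frameshift,
   canonical splice) are ``likely_pathogenic``; missense variants need both
   in-silico scores to agree (Condel > 0.522 AND CADD > 20); everything else
   that survived the filters is a plain ``rare_RSV``.

Gene-level constraint (pLI > 0.50 and missense Z > 0) is attached as a
metadata flag, not used as a gate: it informs interpretation without
changing carrier counts.  The cascade is a pure function of the annotation
row, so row order is irrelevant and every exclusion carries exactly one
primary reason.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

__all__ = [
    "EXONIC_CONSEQUENCES",
    "LOF_CONSEQUENCES",
    "region_filter",
    "rarity_filter",
    "classify_pathogenicity",
    "prioritize",
]

EXONIC_CONSEQUENCES = {"missense", "nonsense", "frameshift", "synonymous", "other"}
LOF_CONSEQUENCES = {"nonsense", "frameshift", "canonical_splice"}
SPLICE_WINDOW = 6  # bp around the exon boundary still treated as splice-affecting

MAX_FREQUENCY = 1e-3
CONDEL_DAMAGING = 0.522
CADD_DAMAGING = 20.0
PLI_INTOLERANT = 0.50


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, numbers.Real):
        return bool(np.isnan(value))
    return False


def region_filter(consequence: str, splice_offset: float | None = None) -> tuple[bool, str]:
    """(keep, reason): exonic or splice within +/-6 bp passes."""
    if _is_missing(consequence):
        return False, "unannotated"
    if consequence in EXONIC_CONSEQUENCES or consequence == "canonical_splice":
        return True, ""
    if consequence in ("splice_region", "intronic"):
        if not _is_missing(splice_offset) and 0 < splice_offset <= SPLICE_WINDOW:
            return True, ""
        return False, "intronic_beyond_splice_window"
    return False, "non_exonic"


def rarity_filter(max_freq: float, hom_seen) -> tuple[bool, str]:
    """(keep, reason): frequency at most 1/1000 and never seen homozygous.

    Missing annotation excludes conservatively ("unannotated")."""
    if _is_missing(max_freq) or _is_missing(hom_seen):
        return False, "unannotated"
    if max_freq > MAX_FREQUENCY:
        return False, "frequency_above_1_in_1000"
    if bool(hom_seen):
        return False, "database_homozygote"
    return True, ""


def classify_pathogenicity(
    consequence: str,
    condel: float | None,
    cadd: float | None,
    known_functional: bool = False,
) -> str:
    """Tier for a variant that already passed region and rarity filters."""
    if bool(known_functional) and not _is_missing(known_functional):
        return "known_pathogenic"
    if consequence in LOF_CONSEQUENCES:
        return "likely_pathogenic"
    if (
        consequence == "missense"
        and not _is_missing(condel)
        and not _is_missing(cadd)
        and condel > CONDEL_DAMAGING
        and cadd > CADD_DAMAGING
    ):
        return "likely_pathogenic"
    return "rare_RSV"


def gene_constrained(pli: float, mis_z: float) -> bool:
    """Variation-intolerant gene flag: pLI > 0.50 and missense Z > 0."""
    if _is_missing(pli) or _is_missing(mis_z):
        return False
    return pli > PLI_INTOLERANT and mis_z > 0.0


def prioritize(
    decoded: pd.DataFrame,
    annotations: pd.DataFrame,
    constraints: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join decoded variants to annotations and run the cascade.

    ``annotations`` columns: contig, pos, ref, alt, gene, consequence,
    splice_offset, max_freq, hom_seen, condel, cadd, known_functional.
    ``constraints`` columns: gene, pli, mis_z.

    Returns one row per decoded variant with ``tier`` in
    {known_pathogenic, likely_pathogenic, rare_RSV, excluded},
    ``exclusion_reason`` (single primary reason, empty when kept) and the
    gene-level ``constrained_gene`` flag.
    """
    key = ["contig", "pos", "ref", "alt"]
    merged = decoded.merge(annotations, on=key, how="left", suffixes=("", "_ann"))
    if constraints is not None and len(constraints):
        cons = dict(zip(constraints["gene"],
                        zip(constraints["pli"], constraints["mis_z"])))
    else:
        cons = {}

    tiers, reasons, flags = [], [], []
    for row in merged.itertuples():
        consequence = getattr(row, "consequence", None)
        keep, reason = region_filter(consequence, getattr(row, "splice_offset", None))
        if keep:
            keep, reason = rarity_filter(
                getattr(row, "max_freq", None), getattr(row, "hom_seen", None)
            )
        if keep:
            tiers.append(classify_pathogenicity(
                consequence,
                getattr(row, "condel", None),
                getattr(row, "cadd", None),
                getattr(row, "known_functional", False),
            ))
            reasons.append("")
        else:
            tiers.append("excluded")
            reasons.append(reason)
        gene = getattr(row, "gene", None)
        pli, mis_z = cons.get(gene, (np.nan, np.nan))
        flags.append(gene_constrained(pli, mis_z))
    merged["tier"] = tiers
    merged["exclusion_reason"] = reasons
    merged["constrained_gene"] = flags
    return merged
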