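"""End-to-end orchestration: design -> simulate -> call -> decode ->
prioritize -> burden, with an evaluation report against the simulation truth.

A run is fully determined by a `RunConfig` (serializable to YAML, seed
mandatory): two cohorts are designed and simulated independently, artifacts
are injected, the caller and filter stack produce per-pool calls, the
decoder assigns carriers, the prioritization cascade classifies variants
against the generated annotation fixture, and carrier burden is compared
between the cohorts.  `evaluate` scores the run against the planted truth:
sensitivity (a planted variant counts as detected only when decoded to its
exact true carrier set), a specificity proxy (surviving artifacts),
decoding ambiguity, and the per-filter exclusion ledger.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from .caller import (FilterThresholds, apply_filters, filter_ledger,
                     flag_low_coverage, score_candidates)
from .decoder import decode, write_decoded_vcf
from .design import PoolDesign, build_design, write_design_tsv
from .prioritize import prioritize
from .regions import Region, default_panel_regions
from .simulate import (ANNOTATION_COLUMNS, BASES, CoverageModel, ErrorModel,
                       VariantSpec, inject_artifacts, reference_base,
                       region_sites, simulate_cohort)

__all__ = [
    "CohortConfig",
    "RunConfig",
    "EvaluationReport",
    "PipelineResult",
    "random_variant_specs",
    "run_pipeline",
    "evaluate",
]

DEFAULT_SUBSET = ("BDNF", "FTO", "MC3R", "MC4R", "NEGR1", "PPARG", "SIM1")


@dataclass(frozen=True)
class CohortConfig:
    """Pool geometry, coverage regime and planted-variant load of one cohort."""

    label: str
    n_samples: int = 463
    n_pools: int = 48
    pool_size: int = 20
    coverage: CoverageModel = field(default_factory=CoverageModel)
    n_variants: int = 25
    p_hom: float = 0.05
    p_shared: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Complete, seedable configuration of one pipeline run."""

    seed: int
    cases: CohortConfig = field(
        default_factory=lambda: CohortConfig(label="cases")
    )
    controls: CohortConfig = field(
        default_factory=lambda: CohortConfig(
            label="controls",
            n_samples=480,
            coverage=CoverageModel(mean_depth=3428.0, sd_depth=660.0),
            n_variants=20,
        )
    )
    error: ErrorModel = field(default_factory=ErrorModel)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    regions: tuple[Region, ...] = field(
        default_factory=lambda: tuple(default_panel_regions())
    )
    subset_genes: tuple[str, ...] = DEFAULT_SUBSET

    def to_yaml(self, path) -> None:
        doc = {
            "seed": self.seed,
            "cases": _cohort_doc(self.cases),
            "controls": _cohort_doc(self.controls),
            "error": asdict(self.error),
            "thresholds": asdict(self.thresholds),
            "regions": [
                {"contig": r.contig, "start": r.start, "end": r.end, "name": r.name}
                for r in self.regions
            ],
            "subset_genes": list(self.subset_genes),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "seed" not in doc:
            raise ValueError("config must set a seed")
        return cls(
            seed=int(doc["seed"]),
            cases=_cohort_from_doc(doc.get("cases", {}), "cases"),
            controls=_cohort_from_doc(doc.get("controls", {}), "controls"),
            error=ErrorModel(**doc.get("error", {})),
            thresholds=FilterThresholds(**doc.get("thresholds", {})),
            regions=tuple(
                Region(d["contig"], d["start"], d["end"], d.get("name", "."))
                for d in doc["regions"]
            ) if "regions" in doc else tuple(default_panel_regions()),
            subset_genes=tuple(doc.get("subset_genes", DEFAULT_SUBSET)),
        )


def _cohort_doc(c: CohortConfig) -> dict:
    doc = asdict(c)
    return doc


def _cohort_from_doc(doc: dict, label: str) -> CohortConfig:
    doc = dict(doc)
    doc.setdefault("label", label)
    if "coverage" in doc and isinstance(doc["coverage"], dict):
        doc["coverage"] = CoverageModel(**doc["coverage"])
    return CohortConfig(**doc)


def _sample_annotation(rng: np.random.Generator, gene: str) -> dict:
    """Draw an annotation payload with a realistic mix of tiers and reasons."""
    consequence = rng.choice(
        ["missense", "synonymous", "nonsense", "frameshift",
         "canonical_splice", "splice_region", "intronic"],
        p=[0.55, 0.15, 0.05, 0.04, 0.04, 0.07, 0.10],
    )
    if consequence == "splice_region":
        offset = int(rng.integers(1, 7))
    elif consequence == "intronic":
        offset = int(rng.integers(7, 31))
    else:
        offset = np.nan
    max_freq = 0.0 if rng.random() < 0.8 else float(rng.uniform(0.0, 0.003))
    return {
        "gene": gene,
        "consequence": str(consequence),
        "splice_offset": offset,
        "max_freq": max_freq,
        "hom_seen": bool(rng.random() < 0.05),
        "condel": float(rng.uniform(0.0, 1.0)),
        "cadd": float(rng.uniform(0.0, 40.0)),
        "known_functional": bool(rng.random() < 0.05),
    }


def random_variant_specs(
    design: PoolDesign,
    regions: Sequence[Region],
    n_variants: int,
    seed: int,
    p_hom: float = 0.0,
    p_shared: float = 0.0,
    exclude_sites: set[tuple[str, int]] | None = None,
) -> list[VariantSpec]:
    """Plant ``n_variants`` rare variants at distinct sites with random
    carriers and annotation payloads.

    Carriers are singleton heterozygotes by default; with probability
    ``p_hom`` a variant is a single-sample homozygote (two copies, expected
    5% pool fraction), with ``p_shared`` it is shared het by two samples.
    """
    rng = np.random.default_rng(seed)
    sites = [
        (c, p, name) for c, p, name in region_sites(regions)
        if exclude_sites is None or (c, p) not in exclude_sites
    ]
    if n_variants > len(sites):
        raise ValueError(
            f"cannot plant {n_variants} variants in {len(sites)} available sites"
        )
    chosen = rng.choice(len(sites), size=n_variants, replace=False)
    samples = design.sample_ids
    specs = []
    for idx in sorted(int(i) for i in chosen):
        contig, pos, gene = sites[idx]
        ref = reference_base(contig, pos)
        alt = str(rng.choice([b for b in BASES if b != ref]))
        u = rng.random()
        first = samples[int(rng.integers(len(samples)))]
        if u < p_hom:
            carriers = {first: "hom"}
        elif u < p_hom + p_shared:
            second = first
            while second == first:
                second = samples[int(rng.integers(len(samples)))]
            carriers = {first: "het", second: "het"}
        else:
            carriers = {first: "het"}
        specs.append(VariantSpec(
            contig=contig, pos=pos, ref=ref, alt=alt,
            carriers=carriers, annotation=_sample_annotation(rng, gene),
        ))
    return specs


def annotation_table(truths: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Flat annotation fixture assembled from the planted truth payloads."""
    key = ["contig", "pos", "ref", "alt"]
    frames = [t[key + ANNOTATION_COLUMNS] for t in truths if len(t)]
    if not frames:
        return pd.DataFrame(columns=key + ANNOTATION_COLUMNS)
    return (
        pd.concat(frames, ignore_index=True)
        .drop_duplicates(subset=key)
        .reset_index(drop=True)
    )


def default_constraints() -> pd.DataFrame:
    """Gene-constraint fixture: the four variation-intolerant subset genes
    carry pLI > 0.5 and positive missense Z; the rest do not."""
    intolerant = {"BDNF", "NEGR1", "PPARG", "SIM1", "NTRK2"}
    genes = sorted({name for r in default_panel_regions() for name in [r.name]})
    rows = []
    for gene in genes:
        if gene in intolerant:
            rows.append({"gene": gene, "pli": 0.95, "mis_z": 2.0})
        else:
            rows.append({"gene": gene, "pli": 0.10, "mis_z": -0.5})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EvaluationReport:
    """Truth-based scoring of one simulated cohort run."""

    n_planted: int
    n_detected_correct: int
    sensitivity: float | None
    sensitivity_percent: int | None
    n_artifacts: int
    n_artifacts_surviving: int
    ambiguity_rate: float
    ledger: dict[str, int]
    applicable: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def _truth_carriers(entry: str) -> frozenset[str]:
    if not entry:
        return frozenset()
    return frozenset(part.split(":")[0] for part in entry.split(";"))


def evaluate(
    calls: pd.DataFrame,
    decoded: pd.DataFrame,
    truth: pd.DataFrame,
    artifacts: pd.DataFrame | None = None,
) -> EvaluationReport:
    """Score detection against the planted truth.

    A planted variant counts as detected only when a decoded record with the
    same variant key reports exactly its true carrier set.  The specificity
    proxy counts injected artifact entries that survived the filter stack.
    """
    ledger = filter_ledger(calls)
    decoded_map = {}
    for row in decoded.itertuples():
        key = (row.contig, row.pos, row.ref, row.alt)
        decoded_map[key] = (row.status, frozenset(
            row.carriers.split(";")) if row.carriers else frozenset())

    n_planted = len(truth)
    detected = 0
    for row in truth.itertuples():
        key = (row.contig, row.pos, row.ref, row.alt)
        want = _truth_carriers(row.carriers)
        got = decoded_map.get(key)
        if got and got[0] in ("unique", "multi_carrier") and got[1] == want:
            detected += 1

    n_art = 0 if artifacts is None else len(artifacts)
    surviving = 0
    if n_art and len(calls):
        passing = calls[calls["pass"]] if "pass" in calls.columns else calls
        passing_keys = set(zip(
            passing["pool_id"], passing["contig"], passing["pos"], passing["alt"]
        ))
        for row in artifacts.itertuples():
            if (row.pool_id, row.contig, row.pos, row.alt) in passing_keys:
                surviving += 1

    n_decoded = len(decoded)
    n_ambiguous = int((decoded["status"] == "ambiguous").sum()) if n_decoded else 0
    if n_planted == 0:
        return EvaluationReport(
            n_planted=0, n_detected_correct=0, sensitivity=None,
            sensitivity_percent=None, n_artifacts=n_art,
            n_artifacts_surviving=surviving,
            ambiguity_rate=(n_ambiguous / n_decoded) if n_decoded else 0.0,
            ledger=ledger, applicable=False,
        )
    sens = detected / n_planted
    return EvaluationReport(
        n_planted=n_planted,
        n_detected_correct=detected,
        sensitivity=sens,
        sensitivity_percent=int(round(100.0 * sens)),
        n_artifacts=n_art,
        n_artifacts_surviving=surviving,
        ambiguity_rate=(n_ambiguous / n_decoded) if n_decoded else 0.0,
        ledger=ledger,
    )


@dataclass
class CohortRun:
    design: PoolDesign
    variants: list[VariantSpec]
    counts: pd.DataFrame
    artifacts: pd.DataFrame
    calls: pd.DataFrame
    decoded: pd.DataFrame
    prioritized: pd.DataFrame
    truth: pd.DataFrame
    report: EvaluationReport


@dataclass
class PipelineResult:
    config: RunConfig
    cases: CohortRun
    controls: CohortRun
    annotations: pd.DataFrame
    constraints: pd.DataFrame
    burden: pd.DataFrame


def _run_cohort(
    cfg: CohortConfig,
    run: RunConfig,
    stream: int,
    exclude_sites: set[tuple[str, int]],
    constraints: pd.DataFrame,
    annotations_extra: list[pd.DataFrame],
) -> CohortRun:
    seed = int(np.random.default_rng([run.seed, stream]).integers(2**31))
    design = build_design(
        cfg.n_samples, cfg.n_pools, cfg.pool_size,
        seed=seed, cohort_label=cfg.label,
    )
    variants = random_variant_specs(
        design, run.regions, cfg.n_variants, seed=seed + 1,
        p_hom=cfg.p_hom, p_shared=cfg.p_shared, exclude_sites=exclude_sites,
    )
    exclude_sites.update((v.contig, v.pos) for v in variants)
    counts, truth = simulate_cohort(
        design, run.regions, variants, cov=cfg.coverage, err=run.error,
        seed=seed + 2,
    )
    counts, artifacts = inject_artifacts(
        counts, run.regions, run.error, seed=seed + 3,
        pools=range(cfg.n_pools),
        exclude_keys={(v.contig, v.pos, v.alt) for v in variants},
    )
    calls = score_candidates(counts, run.error.error_rate)
    calls = apply_filters(calls, run.thresholds)
    calls = flag_low_coverage(calls, run.thresholds.review_depth)
    decoded = decode(calls, design)
    annotations = annotation_table([truth] + annotations_extra)
    prioritized = prioritize(decoded, annotations, constraints)
    report = evaluate(calls, decoded, truth, artifacts)
    return CohortRun(
        design=design, variants=variants, counts=counts, artifacts=artifacts,
        calls=calls, decoded=decoded, prioritized=prioritized, truth=truth,
        report=report,
    )


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage for both cohorts; identical config -> identical
    outputs.  When ``outdir`` is given, every stage artifact (TSV/VCF/JSON)
    is written there."""
    constraints = default_constraints()
    exclude_sites: set[tuple[str, int]] = set()
    stage = "cases"
    try:
        cases = _run_cohort(config.cases, config, 0, exclude_sites,
                            constraints, [])
        stage = "controls"
        controls = _run_cohort(config.controls, config, 1, exclude_sites,
                               constraints, [cases.truth])
        stage = "burden"
        annotations = annotation_table([cases.truth, controls.truth])
        pathogenic = {"likely_pathogenic", "known_pathogenic"}
        subset = set(config.subset_genes)
        tables = [
            burden_mod.tabulate_carriers(
                cases.prioritized, controls.prioritized,
                config.cases.n_samples, config.controls.n_samples,
                subset=None, tiers=None, label="all_genes"),
            burden_mod.tabulate_carriers(
                cases.prioritized, controls.prioritized,
                config.cases.n_samples, config.controls.n_samples,
                subset=None, tiers=pathogenic, label="all_genes"),
            burden_mod.tabulate_carriers(
                cases.prioritized, controls.prioritized,
                config.cases.n_samples, config.controls.n_samples,
                subset=subset, tiers=None, label="subset"),
            burden_mod.tabulate_carriers(
                cases.prioritized, controls.prioritized,
                config.cases.n_samples, config.controls.n_samples,
                subset=subset, tiers=pathogenic, label="subset"),
        ]
        burden = burden_mod.burden_report(tables)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        config=config, cases=cases, controls=controls,
        annotations=annotations, constraints=constraints, burden=burden,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")
    for run in (result.cases, result.controls):
        label = run.design.cohort_label
        write_design_tsv(run.design, outdir / f"{label}.design.tsv")
        run.counts.to_csv(outdir / f"{label}.pileups.tsv", sep="\t", index=False)
        run.calls.to_csv(outdir / f"{label}.calls.tsv", sep="\t", index=False)
        run.decoded.to_csv(outdir / f"{label}.decoded.tsv", sep="\t", index=False)
        if len(run.decoded):
            write_decoded_vcf(run.decoded, outdir / f"{label}.decoded.vcf")
        run.prioritized.to_csv(
            outdir / f"{label}.prioritized.tsv", sep="\t", index=False)
        run.truth.to_csv(outdir / f"{label}.truth.tsv", sep="\t", index=False)
    result.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    result.constraints.to_csv(outdir / "constraints.tsv", sep="\t", index=False)
    result.burden.to_csv(outdir / "burden.tsv", sep="\t", index=False)
    report = {
        "cases": result.cases.report.to_dict(),
        "controls": result.controls.report.to_dict(),
    }
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(report, fh, indent=2)
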