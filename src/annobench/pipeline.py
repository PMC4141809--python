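"""End-to-end orchestration: community -> reads -> oracle hits ->
protocol annotation -> exclusion sweep -> evaluation summaries.

These helpers wire the stage modules together the way the CLI, the examples
and the acceptance checks use them; each stage remains independently
callable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .alignio import AlignmentHit, ExclusionSpec, apply_exclusion
from .evaluate import EvaluationSummary, ReadClassification, evaluate_dataset
from .profiles import FunctionalProfile, aggregate_profile, copy_numbers
from .protocols import ProtocolConfig, WeightedAssignment, annotate_reads
from .reference import KOCatalog
from .simulate import ReadRecord, generate_reads
from .synthetic import Community, OracleSpec, oracle_align


def simulate_community_reads(
    community: Community, read_length: int = 101, step: int = 1
) -> dict[str, list[ReadRecord]]:
    """Per-genome sliding-window read sets ("datasets")."""
    return {
        g.genome_id: list(generate_reads(g, read_length, step))
        for g in community.genomes
    }


@dataclass
class BenchmarkResult:
    """Everything one (genome dataset, protocol, exclusion) run produced."""

    summary: EvaluationSummary
    classifications: list[ReadClassification]
    assignments: dict[str, WeightedAssignment]


def run_benchmark(
    community: Community,
    reads_by_genome: Mapping[str, Sequence[ReadRecord]],
    hits_by_read: Mapping[str, Sequence[AlignmentHit]],
    protocols: Sequence[str] = ("top_gene",),
    exclusion_modes: Sequence[str] = ("none",),
    multi_policy: str = "exclude",
    top_n: int = 20,
    weighting_mode: str = "complement",
) -> dict[tuple[str, str, str], BenchmarkResult]:
    """Evaluate every (genome, protocol, exclusion) combination.

    Exclusion is applied per genome dataset with that genome's taxon as the
    focal taxon, mirroring the leave-my-clade-out design: the database seen
    by a genome's reads omits its own strain/species/genus.
    """
    cat = community.catalog
    results: dict[tuple[str, str, str], BenchmarkResult] = {}
    for genome_id, reads in reads_by_genome.items():
        genome_hits = {
            r.read_id: list(hits_by_read.get(r.read_id, [])) for r in reads
        }
        focal = community.genome(genome_id).taxon
        for mode in exclusion_modes:
            spec = ExclusionSpec(mode=mode, focal_taxon=focal if mode != "none" else None)
            filtered = apply_exclusion(genome_hits, spec, cat)
            for protocol in protocols:
                config = ProtocolConfig(
                    protocol=protocol, top_n=top_n, weighting_mode=weighting_mode
                )
                assignments = annotate_reads(
                    [r.read_id for r in reads], filtered, config, cat
                )
                summary, classifications = evaluate_dataset(
                    assignments,
                    list(reads),
                    cat,
                    policy=multi_policy,
                    dataset_id=genome_id,
                    protocol=protocol,
                    exclusion=mode,
                )
                results[(genome_id, protocol, mode)] = BenchmarkResult(
                    summary, classifications, assignments
                )
    return results


def pooled_metrics(
    results: Mapping[tuple[str, str, str], BenchmarkResult],
    protocol: str,
    exclusion: str = "none",
) -> tuple[float, float]:
    """(precision_ko, recall_ko) pooled over all genome datasets of one run."""
    from .evaluate import summarize

    classifications: list[ReadClassification] = []
    policy = None
    for (g, p, e), res in results.items():
        if p == protocol and e == exclusion:
            classifications.extend(res.classifications)
            policy = res.summary.multi_policy
    if not classifications:
        raise KeyError(f"no results for protocol={protocol} exclusion={exclusion}")
    s = summarize(classifications, policy or "exclude", protocol=protocol, exclusion=exclusion)
    return s.precision_ko, s.recall_ko


def dataset_profile(
    result: BenchmarkResult,
    catalog: KOCatalog,
    markers: Sequence[str],
    mode: str = "aligned_gene",
) -> FunctionalProfile:
    """Aggregate one run's assignments and estimate copy numbers."""
    profile = aggregate_profile(result.assignments.values(), catalog, mode)
    copy_numbers(profile, markers)
    return profile


def perfect_oracle_run(
    community: Community,
    read_length: int = 101,
    step: int = 1,
    protocols: Sequence[str] = ("top_gene", "top_ko", "top20_genes", "top20_kos"),
    oracle: OracleSpec | None = None,
    exclusion_modes: Sequence[str] = ("none",),
    seed: int = 0,
) -> dict[tuple[str, str, str], BenchmarkResult]:
    """Simulate, oracle-align and evaluate a community in one call."""
    if oracle is None:
        oracle = OracleSpec(seed=seed)
    reads_by_genome = simulate_community_reads(community, read_length, step)
    all_reads = [r for reads in reads_by_genome.values() for r in reads]
    hits = oracle_align(all_reads, community, oracle)
    return run_benchmark(
        community, reads_by_genome, hits, protocols=protocols, exclusion_modes=exclusion_modes
    )
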