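"""Classification of per-read annotations against ground truth, and
precision/recall summaries.

Each considered alignment of a read contributes its fractional weight to one
classification label, judged against the genomic region the read was drawn
from: gene correctness means the subject gene is a gene the read overlaps;
KO correctness means the subject's KO set intersects the source gene's KOs.
Reads from intergenic regions can only ever be wrong (or unannotated), which
is what makes them informative about precision.

Reads spanning more than one origin category (MULTI) are excluded by default
since their correct annotation is ill-defined; the ``coverage_weighted``
policy instead evaluates them as a mixture, weighting each origin category
by its coverage within the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .protocols import WeightedAssignment
from .reference import KOCatalog, Origin, ValidationError
from .simulate import ReadRecord

CLASS_LABELS = (
    "correct_gene_correct_ko",
    "incorrect_gene_correct_ko",
    "incorrect_gene_incorrect_ko",
    "incorrect_gene_no_ko",
    "correct_gene_no_ko",
    "no_result",
    "no_hit",
)

CORRECT_KO_LABELS = ("correct_gene_correct_ko", "incorrect_gene_correct_ko")
CORRECT_GENE_LABELS = ("correct_gene_correct_ko", "correct_gene_no_ko")
UNANNOTATED_LABELS = ("no_result", "no_hit")

MULTI_POLICIES = ("exclude", "coverage_weighted")


@dataclass
class ReadClassification:
    """Weighted classification of one read's annotation outcome."""

    read_id: str
    origin: Origin
    class_weights: dict[str, float] = field(default_factory=dict)
    source_kos: frozenset[str] = frozenset()
    ko_fraction: float = 0.0  # coverage of KO-gene territory within the read
    gene_fraction: float = 0.0  # coverage of any gene territory
    assigned_ko_weight: float = 0.0  # total weight the protocol put on KOs
    correct_ko_weight: float = 0.0
    skipped: bool = False

    def weight(self, label: str) -> float:
        return self.class_weights.get(label, 0.0)


def _label_for_hit(gene_correct: bool, hit_kos: frozenset[str], source_kos: frozenset[str]) -> str:
    if gene_correct:
        return "correct_gene_correct_ko" if hit_kos else "correct_gene_no_ko"
    if not hit_kos:
        return "incorrect_gene_no_ko"
    if hit_kos & source_kos:
        return "incorrect_gene_correct_ko"
    return "incorrect_gene_incorrect_ko"


def classify_read(
    assignment: WeightedAssignment,
    read: ReadRecord,
    catalog: KOCatalog,
    policy: str = "exclude",
) -> ReadClassification:
    """Classify one read's assignment against its recorded provenance.

    Under policy='exclude', MULTI-origin reads are marked skipped.  Under
    'coverage_weighted' a MULTI read's hits are judged against the genes it
    overlaps, and the share of the read lying outside gene/KO territory
    counts any KO assignment as incorrect in proportion.
    """
    if policy not in MULTI_POLICIES:
        raise ValidationError(f"unknown multi-read policy {policy!r}")

    source_kos = frozenset().union(
        *(catalog.kos_of(g) for g in read.gene_ids)
    ) if read.gene_ids else frozenset()
    ko_frac = read.overlap_fractions.get(Origin.KO_GENE, 0.0)
    gene_frac = ko_frac + read.overlap_fractions.get(Origin.NON_KO_GENE, 0.0)
    cls = ReadClassification(
        read_id=read.read_id,
        origin=read.origin,
        source_kos=source_kos,
        ko_fraction=ko_frac if read.origin is not Origin.NON_KO_GENE else 0.0,
        gene_fraction=gene_frac,
    )

    if read.origin is Origin.MULTI and policy == "exclude":
        cls.skipped = True
        return cls

    if assignment.status in UNANNOTATED_LABELS:
        cls.class_weights[assignment.status] = 1.0
        return cls

    for hit in assignment.considered:
        gene_correct = hit.gene_id in read.gene_ids
        if read.origin is Origin.MULTI:
            # mixture over origin categories, weighted by coverage
            w_gene = hit.weight * gene_frac
            w_outside = hit.weight * (1.0 - gene_frac)
            if w_gene > 0:
                label = _label_for_hit(gene_correct, hit.ko_ids, source_kos)
                cls.class_weights[label] = cls.class_weights.get(label, 0.0) + w_gene
            if w_outside > 0:
                label = _label_for_hit(False, hit.ko_ids, frozenset())
                cls.class_weights[label] = cls.class_weights.get(label, 0.0) + w_outside
        else:
            label = _label_for_hit(gene_correct, hit.ko_ids, source_kos)
            cls.class_weights[label] = cls.class_weights.get(label, 0.0) + hit.weight

    # under top20_genes the KO weights can sum below the considered-hit total;
    # record both for precision accounting
    cls.assigned_ko_weight = assignment.total_ko_weight
    cls.correct_ko_weight = sum(cls.weight(l) for l in CORRECT_KO_LABELS)
    return cls


@dataclass
class EvaluationSummary:
    """Dataset-level precision/recall and label totals."""

    dataset_id: str
    protocol: str
    exclusion: str
    multi_policy: str
    recall_ko: float
    precision_ko: float
    recall_gene: float
    n_reads: dict[str, int]
    label_totals: dict[str, float]
    label_totals_by_origin: dict[str, dict[str, float]]

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "dataset_id": self.dataset_id,
            "protocol": self.protocol,
            "exclusion": self.exclusion,
            "multi_policy": self.multi_policy,
            "recall_ko": self.recall_ko,
            "precision_ko": self.precision_ko,
            "recall_gene": self.recall_gene,
        }
        for origin, n in sorted(self.n_reads.items()):
            row[f"n_{origin}"] = n
        for label in CLASS_LABELS:
            row[f"w_{label}"] = self.label_totals.get(label, 0.0)
        return row


def summarize(
    classifications: Sequence[ReadClassification],
    policy: str = "exclude",
    dataset_id: str = "",
    protocol: str = "",
    exclusion: str = "none",
) -> EvaluationSummary:
    """Aggregate per-read classifications into dataset-level metrics.

    recall_ko: correct-KO weight summed over KO-gene-origin reads, divided by
    the number of such reads (unannotated reads count in the denominator —
    a read that produced no alignment is still a missed KO read).
    precision_ko: correct-KO weight divided by all KO-assigned weight across
    every non-skipped read; an empty denominator yields NaN.
    recall_gene: correct-gene weight over gene-origin reads.
    Under policy='coverage_weighted', MULTI reads enter every numerator and
    denominator scaled by their category coverage.
    """
    if not classifications:
        raise ValidationError("no classifications to summarize")
    active = [c for c in classifications if not c.skipped]

    recall_num = recall_den = 0.0
    gene_num = gene_den = 0.0
    prec_num = prec_den = 0.0
    n_reads: dict[str, int] = {}
    label_totals: dict[str, float] = {}
    by_origin: dict[str, dict[str, float]] = {}

    for c in classifications:
        n_reads[c.origin.value] = n_reads.get(c.origin.value, 0) + 1
    for c in active:
        for label, w in c.class_weights.items():
            label_totals[label] = label_totals.get(label, 0.0) + w
            per = by_origin.setdefault(c.origin.value, {})
            per[label] = per.get(label, 0.0) + w
        if c.origin is Origin.KO_GENE:
            recall_den += 1.0
            recall_num += c.correct_ko_weight
        elif c.origin is Origin.MULTI and policy == "coverage_weighted" and c.ko_fraction > 0:
            recall_den += c.ko_fraction
            recall_num += c.correct_ko_weight
        if c.origin in (Origin.KO_GENE, Origin.NON_KO_GENE):
            gene_den += 1.0
            gene_num += sum(c.weight(l) for l in CORRECT_GENE_LABELS)
        elif c.origin is Origin.MULTI and policy == "coverage_weighted" and c.gene_fraction > 0:
            gene_den += c.gene_fraction
            gene_num += sum(c.weight(l) for l in CORRECT_GENE_LABELS)
        prec_num += c.correct_ko_weight
        prec_den += c.assigned_ko_weight

    return EvaluationSummary(
        dataset_id=dataset_id,
        protocol=protocol,
        exclusion=exclusion,
        multi_policy=policy,
        recall_ko=recall_num / recall_den if recall_den else float("nan"),
        precision_ko=prec_num / prec_den if prec_den else float("nan"),
        recall_gene=gene_num / gene_den if gene_den else float("nan"),
        n_reads=n_reads,
        label_totals=label_totals,
        label_totals_by_origin=by_origin,
    )


def evaluate_dataset(
    assignments: Mapping[str, WeightedAssignment],
    reads: Sequence[ReadRecord],
    catalog: KOCatalog,
    policy: str = "exclude",
    **summary_ids: str,
) -> tuple[EvaluationSummary, list[ReadClassification]]:
    """classify_read + summarize over one (dataset, protocol, exclusion) run."""
    classifications = [
        classify_read(assignments[r.read_id], r, catalog, policy) for r in reads
    ]
    return summarize(classifications, policy, **summary_ids), classifications


def overlap_mappability(
    classifications: Sequence[ReadClassification],
    reads: Sequence[ReadRecord],
) -> pd.DataFrame:
    """Mappability of reads that only partially overlap a KO gene.

    Groups MULTI-origin reads by the number of bases overlapping KO-gene
    territory and reports the mean probability of a correct-KO, an
    incorrect-KO, and a no-result outcome; rows sum to 1.  Requires
    classifications produced under policy='coverage_weighted'.
    """
    by_id = {r.read_id: r for r in reads}
    groups: dict[int, list[ReadClassification]] = {}
    for c in classifications:
        if c.origin is not Origin.MULTI or c.skipped:
            continue
        read = by_id[c.read_id]
        overlap_bp = int(round(read.overlap_fractions.get(Origin.KO_GENE, 0.0) * read.length))
        if overlap_bp == 0:
            continue
        groups.setdefault(overlap_bp, []).append(c)
    rows = []
    for bp in sorted(groups):
        cs = groups[bp]
        correct = float(np.mean([c.correct_ko_weight for c in cs]))
        none = float(np.mean([sum(c.weight(l) for l in UNANNOTATED_LABELS) for c in cs]))
        incorrect = float(
            np.mean(
                [
                    sum(
                        c.weight(l)
                        for l in CLASS_LABELS
                        if l not in CORRECT_KO_LABELS and l not in UNANNOTATED_LABELS
                    )
                    for c in cs
                ]
            )
        )
        rows.append(
            {
                "overlap_bp": bp,
                "n_reads": len(cs),
                "p_correct_ko": correct,
                "p_incorrect": incorrect,
                "p_no_result": none,
            }
        )
    return pd.DataFrame(
        rows, columns=["overlap_bp", "n_reads", "p_correct_ko", "p_incorrect", "p_no_result"]
    )


def write_classifications(
    classifications: Sequence[ReadClassification], path: str | Path
) -> None:
    rows = []
    for c in classifications:
        row: dict[str, object] = {
            "read_id": c.read_id,
            "origin": c.origin.value,
            "skipped": int(c.skipped),
            "source_kos": ",".join(sorted(c.source_kos)),
        }
        for label in CLASS_LABELS:
            row[label] = c.weight(label)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summaries(summaries: Iterable[EvaluationSummary], path: str | Path) -> None:
    pd.DataFrame([s.as_row() for s in summaries]).to_csv(path, sep="\t", index=False)
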