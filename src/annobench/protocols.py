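"""The four read-annotation protocols and the P-value weighting scheme.

Given a read's cutoff-filtered, canonically sorted hit list, a protocol
selects which alignments to consider and converts them into fractional KO
weights:

* ``top_gene``    — the minimal-E alignment(s), ties included, whether or not
                    they carry a KO; if none does, the read gets *no result*.
* ``top_ko``      — the minimal-E alignment(s) among KO-bearing hits only;
                    better-scoring non-KO alignments are ignored.
* ``top20_genes`` — the up-to-N (default 20) smallest-E alignments; non-KO
                    hits stay in the weighting and dilute the KO fractions.
* ``top20_kos``   — the KO-bearing hits within the same top-N window, with
                    weights renormalized over them.

Weights derive from each hit's chance-match probability P = 1 − exp(−E).
The default "complement" form gives w_i ∝ exp(−E_i) (better hits weigh
more); the "literal" form w_i ∝ P_i is selectable.  Fractional counts over
the considered hits always sum to unity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignio import AlignmentHit, top_tie_group, truncate_top
from .reference import KOCatalog, ValidationError

PROTOCOLS = ("top_gene", "top_ko", "top20_genes", "top20_kos")
WEIGHTING_MODES = ("complement", "literal")


def pvalue(evalue: float) -> float:
    """Chance-match probability P = 1 − exp(−E); monotone in E, in [0, 1)."""
    if evalue < 0:
        raise ValidationError("E-value must be non-negative")
    return -math.expm1(-evalue)


def weight_hits(evalues: Sequence[float], mode: str = "complement") -> np.ndarray:
    """Normalized weights over a set of considered alignments.

    complement: w_i = (1 − P_i)/Σ(1 − P_j) = exp(−E_i)/Σ exp(−E_j)
    literal:    w_i = P_i/Σ P_j, falling back to uniform when all P are 0
                (e.g. a single perfect hit).
    """
    if len(evalues) == 0:
        raise ValidationError("cannot weight an empty hit list")
    e = np.asarray(evalues, dtype=float)
    if mode == "complement":
        raw = np.exp(-e)
    elif mode == "literal":
        raw = -np.expm1(-e)
        if raw.sum() == 0:
            raw = np.ones_like(raw)
    else:
        raise ValidationError(f"unknown weighting mode {mode!r}")
    return raw / raw.sum()


@dataclass
class ProtocolConfig:
    protocol: str = "top_gene"
    top_n: int = 20
    weighting_mode: str = "complement"
    evalue_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"unknown protocol {self.protocol!r}")
        if self.weighting_mode not in WEIGHTING_MODES:
            raise ValidationError(f"unknown weighting mode {self.weighting_mode!r}")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValidationError("evalue cutoff must be > 0")


@dataclass(frozen=True)
class ConsideredHit:
    gene_id: str
    evalue: float
    pvalue: float
    weight: float
    ko_ids: frozenset[str]


@dataclass
class WeightedAssignment:
    """Fractional KO weights for one read plus the hits that produced them.

    ``status`` is 'annotated' (some KO weight assigned), 'no_result' (hits
    were considered but carried no KO), or 'no_hit' (empty hit list).  KO
    weights sum to 1 except under ``top20_genes``, where non-KO considered
    hits dilute the total below 1.
    """

    read_id: str
    status: str
    ko_weights: dict[str, float] = field(default_factory=dict)
    considered: list[ConsideredHit] = field(default_factory=list)

    @property
    def total_ko_weight(self) -> float:
        return sum(self.ko_weights.values())


def annotate_read(
    read_id: str,
    hits: Sequence[AlignmentHit],
    config: ProtocolConfig,
    catalog: KOCatalog,
) -> WeightedAssignment:
    """Apply one protocol to a read's sorted, filtered hit list."""
    if not hits:
        return WeightedAssignment(read_id, "no_hit")

    proto = config.protocol
    if proto == "top_gene":
        considered = top_tie_group(hits)
        if not any(catalog.kos_of(h.gene_id) for h in considered):
            return WeightedAssignment(read_id, "no_result")
    elif proto == "top_ko":
        ko_hits = [h for h in hits if catalog.kos_of(h.gene_id)]
        if not ko_hits:
            return WeightedAssignment(read_id, "no_result")
        considered = top_tie_group(ko_hits)
    elif proto == "top20_genes":
        considered = truncate_top(hits, config.top_n)
        if not any(catalog.kos_of(h.gene_id) for h in considered):
            return WeightedAssignment(read_id, "no_result")
    else:  # top20_kos
        considered = [h for h in truncate_top(hits, config.top_n) if catalog.kos_of(h.gene_id)]
        if not considered:
            return WeightedAssignment(read_id, "no_result")

    weights = weight_hits([h.evalue for h in considered], config.weighting_mode)
    ko_weights: dict[str, float] = {}
    chits: list[ConsideredHit] = []
    for h, w in zip(considered, weights):
        kos = catalog.kos_of(h.gene_id)
        chits.append(ConsideredHit(h.gene_id, h.evalue, pvalue(h.evalue), float(w), kos))
        if kos:
            # a multi-KO subject splits its weight equally across its KOs
            share = w / len(kos)
            for ko in sorted(kos):
                ko_weights[ko] = ko_weights.get(ko, 0.0) + float(share)
    return WeightedAssignment(read_id, "annotated", ko_weights, chits)


def annotate_reads(
    read_ids: Iterable[str],
    hits_by_read: Mapping[str, Sequence[AlignmentHit]],
    config: ProtocolConfig,
    catalog: KOCatalog,
) -> dict[str, WeightedAssignment]:
    """Annotate every read id, treating reads absent from the hit table as no-hit."""
    return {
        rid: annotate_read(rid, hits_by_read.get(rid, []), config, catalog)
        for rid in read_ids
    }


ASSIGNMENT_COLUMNS = ["read_id", "status", "ko_id", "weight"]


def write_assignments(
    assignments: Mapping[str, WeightedAssignment],
    path: str | Path,
    config: ProtocolConfig | None = None,
) -> None:
    """Per-read assignment TSV, one row per (read, KO); header records the protocol."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(
                f"# protocol={config.protocol} top_n={config.top_n} "
                f"weighting={config.weighting_mode} evalue_cutoff={config.evalue_cutoff}\n"
            )
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for rid, a in assignments.items():
            if a.ko_weights:
                for ko in sorted(a.ko_weights):
                    fh.write(f"{rid}\t{a.status}\t{ko}\t{a.ko_weights[ko]:.10g}\n")
            else:
                fh.write(f"{rid}\t{a.status}\t\t0\n")


def read_assignments(path: str | Path) -> dict[str, WeightedAssignment]:
    """Load an assignment TSV (KO weights only; considered hits are not persisted)."""
    out: dict[str, WeightedAssignment] = {}
    tab = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for _, row in tab.iterrows():
        a = out.setdefault(row["read_id"], WeightedAssignment(row["read_id"], row["status"]))
        if row["ko_id"]:
            a.ko_weights[row["ko_id"]] = a.ko_weights.get(row["ko_id"], 0.0) + float(row["weight"])
    return out
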