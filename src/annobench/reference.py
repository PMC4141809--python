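"""Ground-truth layer: genomes, gene annotations, KO catalog, taxonomy.

A :class:`GenomeRecord` bundles a nucleotide sequence with its gene table and
taxonomic lineage.  Every downstream stage — read simulation, oracle
alignment, evaluation — consults this layer, so validation is strict:
coordinates are checked against the sequence, gene ids must be unique, and
every genomic position is classified into exactly one origin category
(KO gene / non-KO gene / intergenic).

Coordinates in gene tables are 1-based inclusive (GFF-like); internal
arithmetic is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class ValidationError(ValueError):
    """Raised when an input table or sequence violates a contract."""


class Origin(str, Enum):
    """Genomic origin category of a read interval."""

    KO_GENE = "KO_GENE"
    NON_KO_GENE = "NON_KO_GENE"
    INTERGENIC = "INTERGENIC"
    MULTI = "MULTI"


# integer codes used in the per-position category mask
_INTERGENIC, _NON_KO, _KO = 0, 1, 2
_CODE_TO_ORIGIN = {_INTERGENIC: Origin.INTERGENIC, _NON_KO: Origin.NON_KO_GENE, _KO: Origin.KO_GENE}


@dataclass(frozen=True)
class Taxon:
    """Taxonomic lineage of a genome: strain within species within genus."""

    strain_id: str
    species_id: str
    genus_id: str
    higher_lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.species_id or not self.genus_id:
            raise ValidationError("species_id and genus_id must be non-empty")


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with optional KO assignments.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates on the
    genome; ``ko_ids`` may be empty (a non-KO gene).
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    ko_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_ko_gene(self) -> bool:
        return bool(self.ko_ids)


@dataclass
class GenomeRecord:
    """A reference genome: sequence + gene annotations + lineage."""

    genome_id: str
    sequence: str
    taxon: Taxon
    genes: list[GeneRecord] = field(default_factory=list)
    topology: str = "linear"

    _mask: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.topology not in {"linear", "circular"}:
            raise ValidationError(f"{self.genome_id}: unknown topology {self.topology!r}")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"{self.genome_id}: duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.end > len(self.sequence):
                raise ValidationError(
                    f"gene {g.gene_id}: end {g.end} exceeds genome length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def category_mask(self) -> np.ndarray:
        """Per-position origin code (0 intergenic, 1 non-KO gene, 2 KO gene).

        A position covered by at least one KO gene is KO_GENE regardless of
        other overlapping genes; gene-covered positions without KO evidence
        are NON_KO_GENE.  Strand is ignored (translated search is
        strand-agnostic).
        """
        if self._mask is None:
            mask = np.zeros(self.length, dtype=np.int8)
            for g in self.genes:
                if not g.is_ko_gene:
                    seg = mask[g.start - 1 : g.end]
                    np.maximum(seg, _NON_KO, out=seg)
            for g in self.genes:
                if g.is_ko_gene:
                    mask[g.start - 1 : g.end] = _KO
            self._mask = mask
        return self._mask

    def genes_overlapping(self, start: int, length: int) -> list[GeneRecord]:
        """Genes overlapping the 1-based interval [start, start+length-1] (with wrap if circular)."""
        positions = self._positions(start, length)
        lo, hi = int(positions.min()), int(positions.max())
        out = []
        for g in self.genes:
            g0, g1 = g.start - 1, g.end - 1
            if self.topology == "circular" and start - 1 + length > self.length:
                # wrapped interval: membership test on the position set
                if np.any((positions >= g0) & (positions <= g1)):
                    out.append(g)
            elif g0 <= hi and g1 >= lo:
                out.append(g)
        return out

    def ko_copy_numbers(self) -> dict[str, int]:
        """Actual per-KO gene copy counts in this genome (the ground-truth profile)."""
        counts: dict[str, int] = {}
        for g in self.genes:
            for ko in g.ko_ids:
                counts[ko] = counts.get(ko, 0) + 1
        return counts

    def _positions(self, start: int, length: int) -> np.ndarray:
        """0-based positions of a 1-based interval, wrapping on circular genomes."""
        if length <= 0:
            raise ValidationError("interval length must be positive")
        s0 = start - 1
        if self.topology == "circular":
            return (s0 + np.arange(length)) % self.length
        if s0 < 0 or s0 + length > self.length:
            raise ValidationError(
                f"interval {start}..{start + length - 1} outside linear genome "
                f"{self.genome_id} (length {self.length})"
            )
        return s0 + np.arange(length)


def classify_position(
    genome: GenomeRecord, start: int, length: int
) -> tuple[Origin, set[str], dict[Origin, float]]:
    """Classify the genomic interval a read was drawn from.

    Returns ``(origin, supporting_gene_ids, overlap_fractions)``.  The origin
    is MULTI iff the interval spans more than one category; the overlap
    fractions always sum to 1 over the non-MULTI categories.
    """
    positions = genome._positions(start, length)
    codes = genome.category_mask()[positions]
    fractions: dict[Origin, float] = {}
    for code in (_KO, _NON_KO, _INTERGENIC):
        n = int(np.count_nonzero(codes == code))
        if n:
            fractions[_CODE_TO_ORIGIN[code]] = n / length
    gene_ids = {g.gene_id for g in genome.genes_overlapping(start, length)}
    if len(fractions) == 1:
        origin = next(iter(fractions))
        if origin is Origin.INTERGENIC:
            gene_ids = set()
    else:
        origin = Origin.MULTI
    return origin, gene_ids, fractions


GENE_TABLE_COLUMNS = [
    "gene_id",
    "genome_id",
    "start",
    "end",
    "strand",
    "ko_ids",
    "strain_id",
    "species_id",
    "genus_id",
]


def read_genomes(sequence_path: str | Path, annotation_path: str | Path) -> list[GenomeRecord]:
    """Load genomes from a FASTA file plus a 9-column gene table (TSV).

    The FASTA must contain exactly one record per genome_id referenced by the
    table.  Returns one validated :class:`GenomeRecord` per FASTA record.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(sequence_path), "fasta")}
    table = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"gene table missing columns: {missing}")
    genomes: list[GenomeRecord] = []
    for genome_id, rows in table.groupby("genome_id", sort=True):
        if genome_id not in seqs:
            raise ValidationError(f"genome {genome_id} referenced in table but absent from FASTA")
        first = rows.iloc[0]
        taxon = Taxon(first["strain_id"], first["species_id"], first["genus_id"])
        genes = []
        for _, row in rows.iterrows():
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise ValidationError(
                    f"gene {row['gene_id']}: malformed coordinates "
                    f"{row['start']!r}..{row['end']!r}"
                ) from exc
            kos = frozenset(k for k in row["ko_ids"].split(",") if k)
            genes.append(
                GeneRecord(row["gene_id"], genome_id, start, end, row["strand"], kos)
            )
        genomes.append(GenomeRecord(genome_id, seqs[genome_id], taxon, genes))
    return genomes


def read_genome(sequence_path: str | Path, annotation_path: str | Path) -> GenomeRecord:
    """Single-genome convenience wrapper around :func:`read_genomes`."""
    genomes = read_genomes(sequence_path, annotation_path)
    if len(genomes) != 1:
        raise ValidationError(f"expected exactly one genome, found {len(genomes)}")
    return genomes[0]


def write_gene_table(genomes: Sequence[GenomeRecord], path: str | Path) -> None:
    rows = []
    for gm in genomes:
        for g in gm.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "genome_id": gm.genome_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "ko_ids": ",".join(sorted(g.ko_ids)),
                    "strain_id": gm.taxon.strain_id,
                    "species_id": gm.taxon.species_id,
                    "genus_id": gm.taxon.genus_id,
                }
            )
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_genome_fasta(genomes: Sequence[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gm in genomes:
            fh.write(f">{gm.genome_id}\n")
            seq = gm.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


@dataclass
class KOCatalog:
    """Flat maps over the reference universe used by annotation and profiling."""

    ko_to_genes: dict[str, set[str]] = field(default_factory=dict)
    gene_to_kos: dict[str, frozenset[str]] = field(default_factory=dict)
    gene_to_taxon: dict[str, Taxon] = field(default_factory=dict)
    gene_to_genome: dict[str, str] = field(default_factory=dict)
    gene_to_length: dict[str, int] = field(default_factory=dict)
    ko_to_pathways: dict[str, set[str]] = field(default_factory=dict)

    def kos_of(self, gene_id: str) -> frozenset[str]:
        return self.gene_to_kos.get(gene_id, frozenset())

    def mean_gene_length(self, ko: str) -> float:
        genes = self.ko_to_genes.get(ko, set())
        if not genes:
            raise KeyError(f"KO {ko} not in catalog")
        return float(np.mean([self.gene_to_length[g] for g in genes]))

    @property
    def kos(self) -> set[str]:
        return set(self.ko_to_genes)


def build_catalog(
    genomes: Sequence[GenomeRecord],
    ko_to_pathways: Mapping[str, Iterable[str]] | None = None,
) -> KOCatalog:
    """Assemble a :class:`KOCatalog` from annotated genomes.

    Raises on a gene_id reused with conflicting lengths (the catalog is keyed
    by gene_id alone).
    """
    if not genomes:
        raise ValidationError("genome list is empty")
    cat = KOCatalog()
    for gm in genomes:
        for g in gm.genes:
            if g.gene_id in cat.gene_to_length and cat.gene_to_length[g.gene_id] != g.length:
                raise ValidationError(f"gene {g.gene_id}: conflicting lengths across genomes")
            cat.gene_to_length[g.gene_id] = g.length
            cat.gene_to_taxon[g.gene_id] = gm.taxon
            cat.gene_to_genome[g.gene_id] = gm.genome_id
            cat.gene_to_kos[g.gene_id] = g.ko_ids
            for ko in g.ko_ids:
                cat.ko_to_genes.setdefault(ko, set()).add(g.gene_id)
    if ko_to_pathways:
        cat.ko_to_pathways = {ko: set(pws) for ko, pws in ko_to_pathways.items()}
    return cat


CATALOG_COLUMNS = [
    "gene_id",
    "genome_id",
    "length",
    "ko_ids",
    "strain_id",
    "species_id",
    "genus_id",
]


def write_catalog(
    catalog: KOCatalog, genes_path: str | Path, pathways_path: str | Path | None = None
) -> None:
    """Serialize a catalog to its tabular form (lossless round-trip)."""
    rows = []
    for gene_id in sorted(catalog.gene_to_length):
        t = catalog.gene_to_taxon[gene_id]
        rows.append(
            {
                "gene_id": gene_id,
                "genome_id": catalog.gene_to_genome[gene_id],
                "length": catalog.gene_to_length[gene_id],
                "ko_ids": ",".join(sorted(catalog.gene_to_kos[gene_id])),
                "strain_id": t.strain_id,
                "species_id": t.species_id,
                "genus_id": t.genus_id,
            }
        )
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(genes_path, sep="\t", index=False)
    if pathways_path is not None:
        prow = [
            {"ko_id": ko, "pathway_id": pw}
            for ko in sorted(catalog.ko_to_pathways)
            for pw in sorted(catalog.ko_to_pathways[ko])
        ]
        pd.DataFrame(prow, columns=["ko_id", "pathway_id"]).to_csv(
            pathways_path, sep="\t", index=False
        )


def read_catalog(
    genes_path: str | Path, pathways_path: str | Path | None = None
) -> KOCatalog:
    """Inverse of :func:`write_catalog`."""
    table = pd.read_csv(genes_path, sep="\t", dtype=str, keep_default_na=False)
    cat = KOCatalog()
    for _, row in table.iterrows():
        gene_id = row["gene_id"]
        cat.gene_to_length[gene_id] = int(row["length"])
        cat.gene_to_genome[gene_id] = row["genome_id"]
        cat.gene_to_taxon[gene_id] = Taxon(row["strain_id"], row["species_id"], row["genus_id"])
        kos = frozenset(k for k in row["ko_ids"].split(",") if k)
        cat.gene_to_kos[gene_id] = kos
        for ko in kos:
            cat.ko_to_genes.setdefault(ko, set()).add(gene_id)
    if pathways_path is not None:
        ptab = pd.read_csv(pathways_path, sep="\t", dtype=str, keep_default_na=False)
        for _, row in ptab.iterrows():
            cat.ko_to_pathways.setdefault(row["ko_id"], set()).add(row["pathway_id"])
    return cat


def read_pathway_table(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (ko_id, pathway_id) -> KO -> pathway set."""
    tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, set[str]] = {}
    for _, row in tab.iterrows():
        out.setdefault(row["ko_id"], set()).add(row["pathway_id"])
    return out
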