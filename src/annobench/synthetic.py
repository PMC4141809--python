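"""Synthetic communities with declared homology structure, and an oracle
aligner that emits translated-search tables with known ground truth.

The generator builds annotated toy genomes arranged on a strain-within-
species-within-genus taxonomy.  Genes occupy fixed "slots": the genes in
slot *s* across all strains of one genus form a homolog family and (when the
slot is KO-annotated) share one KO.  Marker slots reuse a single global KO
id across all genomes and are single-copy everywhere, mirroring universal
single-copy marker genes.

Sequence content is random nucleotide filler: homology exists only in the
oracle's declared hit structure, not in sequence similarity, because the
pipeline under test consumes alignment tables — this keeps every downstream
number exactly derivable from the specification of the community.

The oracle gives each gene-origin read a hit to its own gene at
``self_evalue``, hits to every same-family homolog at the E-value of the
taxonomic relationship (strain = same-genome paralog, species = sibling
strain, genus = sibling species), an optional cross-genus "remote" hit to a
different-KO gene, and random decoy hits; intergenic reads receive decoys
only.  With probability ``corruption_rate`` a read fails to map: its self
hit and every family hit are dropped, leaving at most decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignio import AlignmentHit, sort_hits
from .reference import (
    GeneRecord,
    GenomeRecord,
    KOCatalog,
    Origin,
    Taxon,
    ValidationError,
    build_catalog,
)
from .simulate import ReadRecord

_LEVEL_ORDER = ("strain", "species", "genus")


@dataclass
class CommunitySpec:
    """Shape and annotation density of a synthetic community."""

    n_genera: int = 2
    species_per_genus: int = 2
    strains_per_species: int = 2
    genes_per_genome: int = 10
    gene_length: int = 300
    intergenic_length: int = 100
    fraction_ko_genes: float = 0.6
    n_markers: int = 2
    duplicated_kos: dict[str, int] = field(default_factory=dict)
    pathways_per_ko: int = 1
    n_pathways: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_ko_genes <= 1:
            raise ValidationError("fraction_ko_genes must lie in [0, 1]")
        if any(c < 1 for c in self.duplicated_kos.values()):
            raise ValidationError("duplicate copy numbers must be >= 1")
        if self.n_markers > int(self.genes_per_genome * self.fraction_ko_genes):
            raise ValidationError("more markers requested than KO gene slots")

    @property
    def n_genomes(self) -> int:
        return self.n_genera * self.species_per_genus * self.strains_per_species


@dataclass
class Community:
    genomes: list[GenomeRecord]
    catalog: KOCatalog
    ko_to_pathways: dict[str, set[str]]
    markers: list[str]
    spec: CommunitySpec
    # gene_id -> (genus_index, slot); same (genus, slot) = same homolog family
    family_of: dict[str, tuple[int, int]] = field(default_factory=dict)

    def genome(self, genome_id: str) -> GenomeRecord:
        return next(g for g in self.genomes if g.genome_id == genome_id)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def build_community(spec: CommunitySpec) -> Community:
    """Deterministically build genomes, catalog, and pathway table from a spec.

    Slot layout per genome: [intergenic] gene_0 [intergenic] gene_1 ... with
    duplicated-KO slots repeated at their declared copy number.  The first
    ``n_markers`` KO slots are global single-copy marker KOs ("KMARK##");
    remaining KO slots carry genus-specific KOs ("K<genus><slot>") so that
    homology never crosses genus boundaries.
    """
    rng = np.random.default_rng(spec.seed)
    n_ko_slots = int(round(spec.genes_per_genome * spec.fraction_ko_genes))
    markers = [f"KMARK{m:02d}" for m in range(spec.n_markers)]

    # map each duplicated KO id to its slot; duplicated ids must be KO slots
    genomes: list[GenomeRecord] = []
    family_of: dict[str, tuple[int, int]] = {}
    ko_to_pathways: dict[str, set[str]] = {}

    def slot_ko(genus: int, slot: int) -> str | None:
        if slot >= n_ko_slots:
            return None
        if slot < spec.n_markers:
            return markers[slot]
        return f"K{genus:02d}{slot:03d}"

    genome_index = 0
    for genus in range(spec.n_genera):
        for species in range(spec.species_per_genus):
            for strain in range(spec.strains_per_species):
                genome_id = f"g{genus}s{species}t{strain}"
                taxon = Taxon(
                    strain_id=genome_id,
                    species_id=f"sp_{genus}_{species}",
                    genus_id=f"genus_{genus}",
                )
                genes: list[GeneRecord] = []
                pos = 1
                gene_n = 0
                for slot in range(spec.genes_per_genome):
                    ko = slot_ko(genus, slot)
                    copies = spec.duplicated_kos.get(ko, 1) if ko else 1
                    for _copy in range(copies):
                        pos += spec.intergenic_length
                        gene_id = f"{genome_id}_n{gene_n:03d}"
                        genes.append(
                            GeneRecord(
                                gene_id=gene_id,
                                genome_id=genome_id,
                                start=pos,
                                end=pos + spec.gene_length - 1,
                                strand="+" if gene_n % 2 == 0 else "-",
                                ko_ids=frozenset({ko}) if ko else frozenset(),
                            )
                        )
                        family_of[gene_id] = (genus, slot)
                        pos += spec.gene_length
                        gene_n += 1
                pos += spec.intergenic_length
                genome_length = pos - 1
                sequence = _random_seq(rng, genome_length)
                genomes.append(GenomeRecord(genome_id, sequence, taxon, genes))
                genome_index += 1

    # round-robin pathway membership over non-marker KOs; markers share one pathway
    all_kos = sorted(
        {ko for gm in genomes for g in gm.genes for ko in g.ko_ids}
    )
    non_marker = [k for k in all_kos if k not in markers]
    for i, ko in enumerate(non_marker):
        ko_to_pathways[ko] = {
            f"map{(i + j) % spec.n_pathways:03d}" for j in range(spec.pathways_per_ko)
        }
    for ko in markers:
        ko_to_pathways[ko] = {"map_marker"}

    catalog = build_catalog(genomes, ko_to_pathways)
    return Community(genomes, catalog, ko_to_pathways, markers, spec, family_of)


@dataclass
class OracleSpec:
    """Declared alignment outcome for reads of a synthetic community.

    E-values must be nested: self <= strain <= species <= genus <= remote <=
    decoy range.  ``corruption_rate`` makes a gene read unmappable (its self
    and family hits are all dropped); ``decoy_rate`` adds a hit to a random
    unrelated gene with an E-value in ``decoy_evalue_range``.
    """

    self_evalue: float = 1e-40
    homolog_evalue_by_level: dict[str, float] = field(
        default_factory=lambda: {"strain": 1e-35, "species": 1e-20, "genus": 1e-10}
    )
    remote_evalue: float | None = None
    decoy_rate: float = 0.0
    decoy_evalue_range: tuple[float, float] = (0.01, 0.9)
    corruption_rate: float = 0.0
    multi_gene_hits: bool = False
    multi_min_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        levels = [self.homolog_evalue_by_level.get(l) for l in _LEVEL_ORDER]
        chain = [self.self_evalue] + [e for e in levels if e is not None]
        if self.remote_evalue is not None:
            chain.append(self.remote_evalue)
        chain.append(self.decoy_evalue_range[0])
        if any(a > b for a, b in zip(chain, chain[1:])):
            raise ValidationError("oracle E-values must be nested self <= ... <= decoy")
        for r in (self.decoy_rate, self.corruption_rate):
            if not 0 <= r <= 1:
                raise ValidationError("rates must lie in [0, 1]")


def _relationship(read_taxon: Taxon, subject_taxon: Taxon) -> str:
    if read_taxon.strain_id == subject_taxon.strain_id:
        return "strain"
    if read_taxon.species_id == subject_taxon.species_id:
        return "species"
    if read_taxon.genus_id == subject_taxon.genus_id:
        return "genus"
    return "remote"


def _make_hit(read: ReadRecord, gene_id: str, evalue: float, pident: float) -> AlignmentHit:
    aa_len = max(read.length // 3, 1)
    return AlignmentHit(
        read_id=read.read_id,
        gene_id=gene_id,
        pident=pident,
        length=aa_len,
        mismatch=0,
        gapopen=0,
        qstart=1,
        qend=read.length,
        sstart=1,
        send=aa_len,
        evalue=evalue,
        bitscore=max(10.0, -10.0 * np.log10(evalue + 1e-300)),
    )


def oracle_align(
    reads: Sequence[ReadRecord],
    community: Community,
    spec: OracleSpec,
) -> dict[str, list[AlignmentHit]]:
    """Emit per-read hit lists realizing the declared homology structure.

    Deterministic under ``spec.seed``.  Hits are returned sorted in the
    canonical order used by :func:`annobench.alignio.parse_hits`.
    """
    rng = np.random.default_rng(spec.seed)
    cat = community.catalog
    all_genes = sorted(cat.gene_to_length)
    # family index: (genus, slot) -> member gene ids
    members: dict[tuple[int, int], list[str]] = {}
    for gene_id, fam in community.family_of.items():
        members.setdefault(fam, []).append(gene_id)
    for fam in members:
        members[fam].sort()
    # remote partners: same slot, another genus
    taxon_of_genome = {g.genome_id: g.taxon for g in community.genomes}

    hits_by_read: dict[str, list[AlignmentHit]] = {}
    for read in reads:
        hits: list[AlignmentHit] = []
        source_gene = _dominant_gene(read, community, spec)
        if source_gene is not None:
            read_taxon = taxon_of_genome[read.genome_id]
            genus, slot = community.family_of[source_gene]
            corrupted = rng.random() < spec.corruption_rate
            if not corrupted:
                for gene_id in members[(genus, slot)]:
                    if gene_id == source_gene:
                        hits.append(_make_hit(read, gene_id, spec.self_evalue, 100.0))
                        continue
                    level = _relationship(read_taxon, cat.gene_to_taxon[gene_id])
                    evalue = spec.homolog_evalue_by_level.get(level)
                    if evalue is not None:
                        hits.append(_make_hit(read, gene_id, evalue, 90.0))
            if not corrupted and spec.remote_evalue is not None:
                remote_members = [
                    gid
                    for (gn, sl), gids in members.items()
                    if sl == slot and gn != genus
                    for gid in gids
                ]
                if remote_members:
                    pick = remote_members[int(rng.integers(0, len(remote_members)))]
                    hits.append(_make_hit(read, pick, spec.remote_evalue, 40.0))
        if rng.random() < spec.decoy_rate:
            family = (
                set(members[community.family_of[source_gene]])
                if source_gene is not None
                else set()
            )
            candidates = [g for g in all_genes if g not in family]
            pick = candidates[int(rng.integers(0, len(candidates)))]
            lo, hi = spec.decoy_evalue_range
            evalue = float(lo + (hi - lo) * rng.random())
            hits.append(_make_hit(read, pick, evalue, 30.0))
        if hits:
            hits_by_read[read.read_id] = sort_hits(hits)
    return hits_by_read


def _dominant_gene(read: ReadRecord, community: Community, spec: OracleSpec) -> str | None:
    """The gene whose hit structure this read inherits, if any."""
    if read.origin in (Origin.KO_GENE, Origin.NON_KO_GENE):
        # fully inside >=1 gene; pick the lexicographically first (they overlap)
        return sorted(read.gene_ids)[0]
    if read.origin is Origin.MULTI and spec.multi_gene_hits and read.gene_ids:
        gene_frac = sum(
            read.overlap_fractions.get(o, 0.0)
            for o in (Origin.KO_GENE, Origin.NON_KO_GENE)
        )
        if gene_frac >= spec.multi_min_overlap:
            return sorted(read.gene_ids)[0]
    return None


# ---------------------------------------------------------------------------
# Hand-worked fixtures
# ---------------------------------------------------------------------------


@dataclass
class WorkedFixtureF1:
    """Three-read evaluation case with hand-computed expectations.

    Genome layout (1-based): intergenic 1..100, gA 101..400 (KO K1),
    intergenic 401..500, gB 501..800 (no KO), intergenic 801..1000,
    gC 1001..1300 (KO K2), intergenic 1301..1400.

    Reads (101 bp): rA inside gA with one hit to gA (E 1e-30); rB inside gB
    with hits to gB (E 1e-20, no KO) and gC (E 0.5, K2); rI intergenic with
    one hit to gC (E 0.1).

    top_gene: rA -> K1 correct; rB -> no_result (best hit carries no KO);
    rI -> K2 assigned.  recall_ko = 1/1, precision_ko = 1/2.
    top_ko: rB's KO-bearing hit now assigned (incorrect) -> precision 1/3.
    """

    genomes: list[GenomeRecord]
    catalog: KOCatalog
    reads: list[ReadRecord]
    hits_by_read: dict[str, list[AlignmentHit]]
    expected: dict[str, float]


def fixture_f1() -> WorkedFixtureF1:
    rng = np.random.default_rng(11)
    taxon = Taxon("fx_strain", "fx_species", "fx_genus")
    genes = [
        GeneRecord("gA", "fx", 101, 400, "+", frozenset({"K1"})),
        GeneRecord("gB", "fx", 501, 800, "+", frozenset()),
        GeneRecord("gC", "fx", 1001, 1300, "+", frozenset({"K2"})),
    ]
    genome = GenomeRecord("fx", _random_seq(rng, 1400), taxon, genes)
    catalog = build_catalog([genome], {"K1": {"map001"}, "K2": {"map001"}})

    def read_at(start: int) -> ReadRecord:
        from .reference import classify_position

        origin, gene_ids, fracs = classify_position(genome, start, 101)
        return ReadRecord(
            read_id=f"fx|{start}|101",
            genome_id="fx",
            start=start,
            length=101,
            sequence=genome.sequence[start - 1 : start + 100],
            origin=origin,
            gene_ids=frozenset(gene_ids),
            overlap_fractions=fracs,
        )

    r_a, r_b, r_i = read_at(150), read_at(550), read_at(850)
    hits = {
        r_a.read_id: sort_hits([_make_hit(r_a, "gA", 1e-30, 100.0)]),
        r_b.read_id: sort_hits(
            [_make_hit(r_b, "gB", 1e-20, 100.0), _make_hit(r_b, "gC", 0.5, 35.0)]
        ),
        r_i.read_id: sort_hits([_make_hit(r_i, "gC", 0.1, 40.0)]),
    }
    expected = {
        "top_gene_precision_ko": 0.5,
        "top_gene_recall_ko": 1.0,
        "top_ko_precision_ko": 1.0 / 3.0,
        "top_ko_recall_ko": 1.0,
    }
    return WorkedFixtureF1([genome], catalog, [r_a, r_b, r_i], hits, expected)


@dataclass
class WorkedFixtureF2:
    """Equal-length copy-number case: one genome whose KO genes all have the
    same length, one KO duplicated to two copies, two single-copy markers.

    With step-1 sliding-window reads and a perfect oracle, each gene copy
    yields exactly (l − L + 1) unit-weight reads, so the equal lengths cancel
    and the duplicated KO's marker-normalized copy number is exactly 2.0.
    """

    community: Community
    duplicated_ko: str
    expected_copy_number: float


def fixture_f2() -> WorkedFixtureF2:
    dup_ko = "K00005"
    spec = CommunitySpec(
        n_genera=1,
        species_per_genus=1,
        strains_per_species=1,
        genes_per_genome=6,
        gene_length=300,
        intergenic_length=150,
        fraction_ko_genes=1.0,
        n_markers=2,
        duplicated_kos={dup_ko: 2},
        seed=22,
    )
    return WorkedFixtureF2(build_community(spec), dup_ko, 2.0)


def worked_fixtures() -> tuple[WorkedFixtureF1, WorkedFixtureF2]:
    """The bundled hand-worked fixtures used across the test-suite."""
    return fixture_f1(), fixture_f2()
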