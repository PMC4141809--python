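"""Translated-search tabular alignments (BLAST outfmt-6 dialect) and
database-exclusion filters.

Phylogenetic exclusion removes alignments to the read's own strain, species,
genus, or to genomes within a 16S-distance cutoff — equivalent to replacing
those database sequences with non-matching sequences of identical lengths,
so every surviving hit keeps its E-value unchanged.

E-value ties are defined by equality of the *printed* decimal string, not of
the parsed float: aligners print coarse precision and a float round-trip
would split printed ties.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .reference import KOCatalog, Taxon, ValidationError

OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column translated-search result."""

    read_id: str
    gene_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    evalue_str: str = ""
    known_subject: bool = True

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"negative E-value for {self.read_id} vs {self.gene_id}")
        if not self.evalue_str:
            object.__setattr__(self, "evalue_str", format_evalue(self.evalue))


def format_evalue(e: float) -> str:
    """Canonical E-value text used when none came from a file."""
    return f"{e:.3e}"


def sort_hits(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Canonical order: E ascending, bitscore descending, gene_id lexicographic."""
    return sorted(hits, key=lambda h: (h.evalue, -h.bitscore, h.gene_id))


def parse_hits(
    path: str | Path,
    catalog: KOCatalog | None = None,
    evalue_cutoff: float = 1.0,
    on_unknown_subject: str = "flag",
) -> dict[str, list[AlignmentHit]]:
    """Parse an outfmt-6 table into per-read hit lists, sorted canonically.

    Hits with E >= ``evalue_cutoff`` are discarded (strict <, the standard
    permissive threshold).  Unknown subject genes are retained but flagged
    (``on_unknown_subject='flag'``), dropped (``'drop'``) or fatal
    (``'error'``).  Reads absent from the file simply have no entry; callers
    treat them as no-hit.
    """
    if on_unknown_subject not in {"flag", "drop", "error"}:
        raise ValidationError(f"bad on_unknown_subject: {on_unknown_subject!r}")
    hits_by_read: dict[str, list[AlignmentHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValidationError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                hit = AlignmentHit(
                    read_id=parts[0],
                    gene_id=parts[1],
                    pident=float(parts[2]),
                    length=int(parts[3]),
                    mismatch=int(parts[4]),
                    gapopen=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    evalue_str=parts[10],
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: unparseable row ({exc})") from exc
            if hit.evalue >= evalue_cutoff:
                continue
            if catalog is not None and hit.gene_id not in catalog.gene_to_length:
                if on_unknown_subject == "error":
                    raise ValidationError(
                        f"{path}:{lineno}: unknown subject gene {hit.gene_id}"
                    )
                if on_unknown_subject == "drop":
                    continue
                hit = replace(hit, known_subject=False)
            hits_by_read.setdefault(hit.read_id, []).append(hit)
    return {rid: sort_hits(hits) for rid, hits in hits_by_read.items()}


def write_hits(
    hits_by_read: Mapping[str, Sequence[AlignmentHit]], path: str | Path
) -> None:
    """Write hit lists back to outfmt-6, preserving E-value text."""
    with open(path, "w") as fh:
        for read_id in hits_by_read:
            for h in hits_by_read[read_id]:
                fh.write(
                    "\t".join(
                        [
                            h.read_id,
                            h.gene_id,
                            f"{h.pident:.2f}",
                            str(h.length),
                            str(h.mismatch),
                            str(h.gapopen),
                            str(h.qstart),
                            str(h.qend),
                            str(h.sstart),
                            str(h.send),
                            h.evalue_str,
                            f"{h.bitscore:.1f}",
                        ]
                    )
                    + "\n"
                )


@dataclass
class ExclusionSpec:
    """How to thin the database seen by a read set.

    mode 'strain'/'species'/'genus' removes hits to subjects sharing the
    focal taxon's id at that rank; 'distance' removes hits to genomes whose
    precomputed distance to the focal genome is strictly below the cutoff;
    'none' is the identity.
    """

    mode: str = "none"
    focal_taxon: Taxon | None = None
    distance_cutoff: float = 0.0
    distance_table: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"none", "strain", "species", "genus", "distance"}:
            raise ValidationError(f"unknown exclusion mode {self.mode!r}")
        if self.mode in {"strain", "species", "genus"} and self.focal_taxon is None:
            raise ValidationError(f"mode={self.mode} requires a focal taxon")
        if self.mode == "distance":
            if self.distance_table is None:
                raise ValidationError("mode=distance requires a distance table")
            if self.distance_cutoff < 0:
                raise ValidationError("distance cutoff must be >= 0")


def _excluded(hit: AlignmentHit, spec: ExclusionSpec, catalog: KOCatalog,
              on_unknown: str) -> bool:
    if spec.mode == "none":
        return False
    if spec.mode == "distance":
        genome = catalog.gene_to_genome.get(hit.gene_id)
        if genome is None or genome not in spec.distance_table:
            if on_unknown == "error":
                raise ValidationError(f"no distance for subject {hit.gene_id}")
            return True  # flagged-drop
        return spec.distance_table[genome] < spec.distance_cutoff
    taxon = catalog.gene_to_taxon.get(hit.gene_id)
    if taxon is None:
        if on_unknown == "error":
            raise ValidationError(f"unknown taxon for subject gene {hit.gene_id}")
        return True  # flagged-drop
    focal = spec.focal_taxon
    if spec.mode == "strain":
        return taxon.strain_id == focal.strain_id
    if spec.mode == "species":
        return taxon.species_id == focal.species_id
    return taxon.genus_id == focal.genus_id


def apply_exclusion(
    hits_by_read: Mapping[str, Sequence[AlignmentHit]],
    spec: ExclusionSpec,
    catalog: KOCatalog,
    on_unknown_taxon: str = "error",
) -> dict[str, list[AlignmentHit]]:
    """Remove excluded alignments; surviving hits keep fields and order."""
    out: dict[str, list[AlignmentHit]] = {}
    for read_id, hits in hits_by_read.items():
        kept = [h for h in hits if not _excluded(h, spec, catalog, on_unknown_taxon)]
        out[read_id] = kept
    return out


def truncate_top(hits: Sequence[AlignmentHit], n: int) -> list[AlignmentHit]:
    """First ``n`` hits in canonical order, extended through printed-E ties.

    Short lists pass through ("up-to N alignments"); hits whose E-value text
    equals the N-th hit's are included even beyond N so that equally scoring
    alignments are treated jointly.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if len(hits) <= n:
        return list(hits)
    boundary = hits[n - 1].evalue_str
    out = list(hits[:n])
    for h in hits[n:]:
        if h.evalue_str == boundary:
            out.append(h)
        else:
            break
    return out


def top_tie_group(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """The leading hits tied (by printed E-value) with the best hit."""
    if not hits:
        return []
    best = hits[0].evalue_str
    out = []
    for h in hits:
        if h.evalue_str == best:
            out.append(h)
        else:
            break
    return out


def read_distance_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV (genome_id, distance) -> mapping."""
    out: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.strip()
            if not line:
                continue
            genome_id, dist = line.split("\t")
            out[genome_id] = float(dist)
    return out
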