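"""Strided sliding-window read simulation with optional substitution errors.

Reads of a fixed length L are cut from a genome at every ``step``-th start
position; each read records its provenance (genome, 1-based start, origin
category, overlapping genes).  Sequencing error is modeled as independent
per-position substitutions drawn from a position-dependent error profile
that can be uniformly rescaled to a target aggregate rate — emulating an
empirically trained Illumina profile without modeling indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .reference import GenomeRecord, Origin, ValidationError, classify_position

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class ReadRecord:
    """A simulated read with full provenance."""

    read_id: str
    genome_id: str
    start: int  # 1-based on the source genome
    length: int
    sequence: str
    origin: Origin
    gene_ids: frozenset[str] = frozenset()
    overlap_fractions: dict[Origin, float] = field(default_factory=dict)
    errored_positions: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ko_fraction(self) -> float:
        """Fraction of the read overlapping KO-gene territory."""
        return self.overlap_fractions.get(Origin.KO_GENE, 0.0)


def n_reads(genome_length: int, read_length: int, step: int, topology: str = "linear") -> int:
    """Closed-form read count for a strided sliding window."""
    if step < 1:
        raise ValidationError("step must be >= 1")
    if topology == "circular":
        return (genome_length - 1) // step + 1
    if read_length > genome_length:
        raise ValidationError(
            f"read length {read_length} exceeds linear genome length {genome_length}"
        )
    return (genome_length - read_length) // step + 1


def generate_reads(genome: GenomeRecord, read_length: int, step: int = 1) -> Iterator[ReadRecord]:
    """Yield every ``step``-th window of ``read_length`` bp over the genome.

    Linear genomes emit floor((G − L)/step) + 1 reads; circular genomes use
    every start position once, wrapping across the origin.  Reads come from
    the forward strand; read ids encode genome, start, and length.
    """
    count = n_reads(genome.length, read_length, step, genome.topology)
    seq = genome.sequence
    for i in range(count):
        start0 = i * step
        if genome.topology == "circular" and start0 + read_length > genome.length:
            read_seq = seq[start0:] + seq[: start0 + read_length - genome.length]
        else:
            read_seq = seq[start0 : start0 + read_length]
        origin, gene_ids, fractions = classify_position(genome, start0 + 1, read_length)
        yield ReadRecord(
            read_id=f"{genome.genome_id}|{start0 + 1}|{read_length}",
            genome_id=genome.genome_id,
            start=start0 + 1,
            length=read_length,
            sequence=read_seq,
            origin=origin,
            gene_ids=frozenset(gene_ids),
            overlap_fractions=fractions,
        )


@dataclass
class ErrorProfile:
    """Position-dependent substitution rates, optionally with a 4x4 substitution matrix.

    ``substitution_matrix[i, j]`` is P(new base j | original base i, error);
    rows sum to 1 with a zero diagonal.  Without a matrix, the replacement
    base is uniform over the three alternatives.
    """

    per_position_rate: np.ndarray
    substitution_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.per_position_rate = np.asarray(self.per_position_rate, dtype=float)
        if np.any(self.per_position_rate < 0) or np.any(self.per_position_rate > 1):
            raise ValidationError("per-position rates must lie in [0, 1]")
        m = self.substitution_matrix
        if m is not None:
            m = np.asarray(m, dtype=float)
            if m.shape != (4, 4) or np.any(m < 0):
                raise ValidationError("substitution matrix must be 4x4 and non-negative")
            if not np.allclose(np.diag(m), 0) or not np.allclose(m.sum(axis=1), 1):
                raise ValidationError("substitution matrix rows must sum to 1 with zero diagonal")
            self.substitution_matrix = m

    def base_rate(self, read_length: int | None = None) -> float:
        """Mean per-position rate over the first ``read_length`` positions."""
        rates = self.per_position_rate
        if read_length is not None:
            if read_length > len(rates):
                raise ValidationError("profile shorter than read length")
            rates = rates[:read_length]
        return float(rates.mean())


def uniform_profile(rate: float, length: int) -> ErrorProfile:
    return ErrorProfile(np.full(length, float(rate)))


def scale_profile(profile: ErrorProfile, target_rate: float, read_length: int | None = None) -> ErrorProfile:
    """Uniformly magnify the profile so its mean rate equals ``target_rate``.

    Preserves the relative shape; refuses to push any position above
    probability 1.
    """
    if not 0 <= target_rate <= 1:
        raise ValidationError("target_rate must lie in [0, 1]")
    base = profile.base_rate(read_length)
    if base == 0:
        if target_rate == 0:
            return ErrorProfile(profile.per_position_rate.copy(), profile.substitution_matrix)
        raise ValidationError("cannot scale an all-zero profile to a positive rate")
    factor = target_rate / base
    scaled = profile.per_position_rate * factor
    over = np.nonzero(scaled > 1 + 1e-12)[0]
    if over.size:
        raise ValidationError(
            f"scaling by {factor:.4g} exceeds probability 1 at position {int(over[0])}"
        )
    return ErrorProfile(np.minimum(scaled, 1.0), profile.substitution_matrix)


def read_profile(path: str | Path) -> ErrorProfile:
    """Load a profile from TSV: columns (position, rate), optional matrix block.

    A line starting with ``#matrix`` introduces 16 whitespace-separated
    row-major entries of the substitution matrix.
    """
    rates: list[tuple[int, float]] = []
    matrix_vals: list[float] = []
    with open(path) as fh:
        in_matrix = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#matrix"):
                in_matrix = True
                continue
            if line.startswith("#"):
                continue
            if in_matrix:
                matrix_vals.extend(float(x) for x in line.split())
            else:
                pos, rate = line.split("\t")
                rates.append((int(pos), float(rate)))
    rates.sort()
    arr = np.array([r for _, r in rates])
    matrix = np.array(matrix_vals).reshape(4, 4) if matrix_vals else None
    return ErrorProfile(arr, matrix)


def write_profile(profile: ErrorProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(profile.per_position_rate):
            fh.write(f"{i}\t{r:.10g}\n")
        if profile.substitution_matrix is not None:
            fh.write("#matrix\n")
            for row in profile.substitution_matrix:
                fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def inject_errors(
    reads: Iterable[ReadRecord], profile: ErrorProfile, seed: int
) -> Iterator[ReadRecord]:
    """Apply substitution-only errors; deterministic for (reads, profile, seed).

    Each position errs independently with its profile rate; the replacement
    base follows the substitution matrix if present, else is uniform over the
    three alternatives.  Non-ACGT positions are never substituted.  Injected
    changes are recorded in ``errored_positions``.
    """
    rng = np.random.default_rng(seed)
    matrix = profile.substitution_matrix
    for read in reads:
        rates = profile.per_position_rate
        if read.length > len(rates):
            raise ValidationError("profile shorter than read length")
        rates = rates[: read.length]
        hit = rng.random(read.length) < rates
        seq = np.frombuffer(read.sequence.encode(), dtype="S1").copy()
        events: list[tuple[int, str, str]] = []
        for off in np.nonzero(hit)[0]:
            orig = seq[off].decode()
            if orig not in _BASE_INDEX:
                continue  # ambiguous base: event suppressed
            i = _BASE_INDEX[orig]
            if matrix is not None:
                j = rng.choice(4, p=matrix[i])
            else:
                j = rng.choice([k for k in range(4) if k != i])
            seq[off] = _BASES[j]
            events.append((int(off), orig, _BASES[j].decode()))
        yield replace(
            read, sequence=seq.tobytes().decode(), errored_positions=events
        )


def write_fasta(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def write_fastq(reads: Iterable[ReadRecord], path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality_char * r.length}\n")


PROVENANCE_COLUMNS = [
    "read_id",
    "genome_id",
    "start",
    "length",
    "origin",
    "gene_ids",
    "overlap_fractions",
]


def write_provenance(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Sidecar TSV recording each read's origin for later evaluation."""
    rows = []
    for r in reads:
        fracs = ";".join(
            f"{o.value}:{f:.6g}" for o, f in sorted(r.overlap_fractions.items(), key=lambda x: x[0].value)
        )
        rows.append(
            {
                "read_id": r.read_id,
                "genome_id": r.genome_id,
                "start": r.start,
                "length": r.length,
                "origin": r.origin.value,
                "gene_ids": ",".join(sorted(r.gene_ids)),
                "overlap_fractions": fracs,
            }
        )
    pd.DataFrame(rows, columns=PROVENANCE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_provenance(path: str | Path) -> list[ReadRecord]:
    """Load provenance rows back into (sequence-less) :class:`ReadRecord` objects."""
    tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    reads = []
    for _, row in tab.iterrows():
        fracs: dict[Origin, float] = {}
        if row["overlap_fractions"]:
            for part in row["overlap_fractions"].split(";"):
                k, v = part.split(":")
                fracs[Origin(k)] = float(v)
        reads.append(
            ReadRecord(
                read_id=row["read_id"],
                genome_id=row["genome_id"],
                start=int(row["start"]),
                length=int(row["length"]),
                sequence="",
                origin=Origin(row["origin"]),
                gene_ids=frozenset(g for g in row["gene_ids"].split(",") if g),
                overlap_fractions=fracs,
            )
        )
    return reads
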