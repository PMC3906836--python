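"""Sequence/alignment data model and FASTA/FASTQ readers and writers.

Conventions used throughout the package:

* coordinates are 0-based, half-open; human-readable reports convert to
  1-based only at print time;
* residues are uppercased on read, and ``U`` is mapped to ``T`` in DNA;
* ``-`` is the gap character and is treated as missing data by every
  downstream statistic.

Parsing is delegated to :mod:`Bio.SeqIO`; the classes here are thin,
validated containers that the rest of the pipeline computes on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .alphabets import GAP, PROTEIN_RESIDUES, looks_protein
from .errors import AlignmentError, AlphabetError, FormatError


@dataclass(frozen=True)
class GeneRecord:
    """One identified protein or coding sequence of one species."""

    id: str
    species: str
    seq: str
    kind: str = "protein"  # "protein" | "dna"

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.kind not in ("protein", "dna"):
            raise FormatError(f"record {self.id!r}: unknown kind {self.kind!r}")
        bad = _alphabet_violations(self.seq, self.kind)
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters {sorted(bad)} not valid for {self.kind}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _alphabet_violations(seq: str, kind: str) -> set[str]:
    if kind == "dna":
        return {c for c in seq if c not in "ACGTN-"}
    return {c for c in seq if c not in PROTEIN_RESIDUES and c != GAP}


@dataclass
class Proteome:
    """Ordered collection of gene records for one species."""

    species: str
    records: list[GeneRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError(f"proteome {self.species!r}: no records")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"proteome {self.species!r}: duplicate ids {dup}")
        for r in self.records:
            if r.species != self.species:
                raise FormatError(
                    f"record {r.id!r} labelled {r.species!r} inside proteome "
                    f"{self.species!r}"
                )
        self._index = {r.id: r for r in self.records}

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index


@dataclass
class Alignment:
    """Equal-length gapped sequence matrix, column addressable."""

    names: list[str]
    rows: list[str]
    kind: str = "dna"  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        if len(self.names) != len(self.rows):
            raise AlignmentError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate row names")
        length = len(self.rows[0])
        if length == 0:
            raise AlignmentError("alignment of length 0")
        for name, row in zip(self.names, self.rows):
            if len(row) != length:
                raise AlignmentError(
                    f"row {name!r} has length {len(row)}, expected {length}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(row[j] for row in self.rows)

    def columns(self) -> Iterator[tuple[str, ...]]:
        for j in range(self.length):
            yield self.column(j)

    def ungapped(self, name: str) -> str:
        """Row sequence with gaps removed (template coordinates)."""
        return self.rows[self.names.index(name)].replace(GAP, "")

    def matrix(self) -> np.ndarray:
        """Rows as a 2-D array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")


@dataclass
class QualityMask:
    """Per-row, per-column trusted flags derived from Phred qualities.

    ``trusted[i][j]`` is True iff base j of row i has quality >= the
    threshold the mask was built with; untrusted bases are treated as
    missing data everywhere downstream.
    """

    names: list[str]
    trusted: list[np.ndarray]
    qmin: int = 40

    def __post_init__(self) -> None:
        if len(self.names) != len(self.trusted):
            raise AlignmentError("mask names/rows length mismatch")
        self.trusted = [np.asarray(t, dtype=bool) for t in self.trusted]

    def matches(self, aln: Alignment) -> bool:
        return self.names == aln.names and all(
            len(t) == aln.length for t in self.trusted
        )

    def n_trusted(self) -> int:
        return int(sum(int(t.sum()) for t in self.trusted))


def _normalise(seq: str, kind: str) -> str:
    seq = seq.upper()
    if kind == "dna":
        seq = seq.replace("U", "T")
    return seq


def sniff_kind(seqs: Iterable[str]) -> str:
    return "protein" if any(looks_protein(s.upper()) for s in seqs) else "dna"


def _parse_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    pairs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        pairs.append((rec.id, seq))
    if not pairs:
        raise FormatError(f"{path}: no FASTA records")
    ids = [i for i, _ in pairs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate record ids {dup}")
    return pairs


def read_fasta_proteome(
    path: str | Path, species: str | None = None, kind: str | None = None
) -> Proteome:
    """Read an (unaligned) FASTA file as the proteome of one species.

    The species label defaults to the file stem.  Residues are
    uppercased; kind is sniffed from the alphabet unless given.
    """
    pairs = _parse_fasta(path)
    if kind is None:
        kind = sniff_kind(s for _, s in pairs)
    species = species if species is not None else Path(path).stem
    records = [
        GeneRecord(id=i, species=species, seq=_normalise(s, kind), kind=kind)
        for i, s in pairs
    ]
    return Proteome(species=species, records=records)


def read_fasta_alignment(path: str | Path, kind: str | None = None) -> Alignment:
    """Read an aligned FASTA file; rows must be equal length."""
    pairs = _parse_fasta(path)
    if kind is None:
        kind = sniff_kind(s for _, s in pairs)
    names = [i for i, _ in pairs]
    rows = [_normalise(s, kind) for _, s in pairs]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    return Alignment(names=names, rows=rows, kind=kind)


def read_fasta(path: str | Path, kind: str | None = None) -> Proteome | Alignment:
    """Read FASTA, returning an Alignment when all rows align.

    A file whose sequences are equal length and contain at least one
    gap, or that parses as equal-length rows of more than one record,
    is returned as an :class:`Alignment`; otherwise a :class:`Proteome`.
    Use the explicit readers when the intent is known.
    """
    pairs = _parse_fasta(path)
    lengths = {len(s) for _, s in pairs}
    if len(pairs) > 1 and len(lengths) == 1:
        return read_fasta_alignment(path, kind=kind)
    return read_fasta_proteome(path, kind=kind)


def write_fasta(path: str | Path, obj: Proteome | Alignment, width: int = 70) -> None:
    path = Path(path)
    if isinstance(obj, Proteome):
        items: Sequence[tuple[str, str]] = [(r.id, r.seq) for r in obj.records]
    else:
        items = list(zip(obj.names, obj.rows))
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


DEFAULT_QMIN = 40


def read_fastq_mask(
    path: str | Path, qmin: int = DEFAULT_QMIN
) -> tuple[list[tuple[str, str]], QualityMask]:
    """Read Sanger FASTQ and derive a trusted-base mask.

    A base is trusted iff its Phred quality is >= ``qmin`` (default
    Q40, expected error rate 1e-4); everything below the threshold is
    missing data.  Returns the (id, sequence) pairs in file order plus
    the mask.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    names: list[str] = []
    seqs: list[tuple[str, str]] = []
    trusted: list[np.ndarray] = []
    try:
        records = list(SeqIO.parse(str(path), "fastq"))
    except ValueError as exc:  # Bio raises ValueError on seq/qual mismatch
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTQ records")
    for rec in records:
        seq = _normalise(str(rec.seq), "dna")
        quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=int)
        if len(quals) != len(seq):
            raise FormatError(f"{path}: record {rec.id!r} seq/quality length mismatch")
        names.append(rec.id)
        seqs.append((rec.id, seq))
        trusted.append(quals >= qmin)
    return seqs, QualityMask(names=names, trusted=trusted, qmin=qmin)


def write_fastq(
    path: str | Path,
    items: Iterable[tuple[str, str, Sequence[int]]],
) -> None:
    """Write Sanger FASTQ (Phred+33) from (id, seq, qualities) triples."""
    with open(path, "w") as fh:
        for name, seq, quals in items:
            if len(seq) != len(quals):
                raise FormatError(f"record {name!r}: seq/quality length mismatch")
            qstr = "".join(chr(min(int(q), 93) + 33) for q in quals)
            fh.write(f"@{name}\n{seq}\n+\n{qstr}\n")


def strain_panel_from_fastq(
    path: str | Path, qmin: int = DEFAULT_QMIN
) -> tuple[Alignment, QualityMask]:
    """Read an aligned strain panel stored as FASTQ (equal-length reads)."""
    seqs, mask = read_fastq_mask(path, qmin=qmin)
    aln = Alignment(
        names=[n for n, _ in seqs], rows=[s for _, s in seqs], kind="dna"
    )
    if not mask.matches(aln):
        raise AlignmentError(f"{path}: rows are not equal length")
    return aln, mask
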