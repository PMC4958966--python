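"""Sequence containers, FASTA I/O, translation, and six-frame ORF scanning.

Coordinates are 0-based half-open everywhere inside the package; writers
convert to 1-based inclusive for human-facing reports.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import AlphabetError, FormatError

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PEPTIDE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
FRAMES = (1, 2, 3, -1, -2, -3)
STOP_CODONS = frozenset(CodonTable.unambiguous_dna_by_id[1].stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CODON_TO_AA = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
for _stop in STOP_CODONS:
    _CODON_TO_AA[_stop] = "*"


def _check_nucleotide(seq: str) -> None:
    bad = set(seq) - NUCLEOTIDE_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)!r} in sequence")


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase sequence; the universal carrier of the package.

    ``alphabet`` is ``"nucleotide"`` (A, C, G, T, N) or ``"peptide"``
    (the 20 amino acids plus X and ``*``).
    """

    id: str
    sequence: str
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise FormatError("sequence record requires a non-empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} is empty")
        if self.alphabet == "nucleotide":
            _check_nucleotide(self.sequence)
        elif self.alphabet == "peptide":
            bad = set(self.sequence) - PEPTIDE_ALPHABET
            if bad:
                raise AlphabetError(f"non-peptide characters {sorted(bad)!r} in {self.id!r}")
        else:
            raise AlphabetError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal stop-free translated stretch in one of the six frames.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand of the transcript, regardless of frame sign.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    peptide: str
    length_aa: int

    def __post_init__(self) -> None:
        if self.length_aa != (self.end - self.start) // 3:
            raise ValueError("length_aa inconsistent with coordinates")
        if "*" in self.peptide:
            raise ValueError("ORF peptide must be stop-free")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    _check_nucleotide(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 1) -> str:
    """Translate ``seq`` in the given frame with the standard genetic code.

    Frames follow the usual six-frame convention: +1/+2/+3 read the forward
    strand at offsets 0/1/2, -1/-2/-3 read the reverse complement likewise.
    The trailing incomplete codon is dropped, stops render as ``*`` and any
    codon containing N renders as ``X``.
    """
    _check_nucleotide(seq)
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    strand = seq if frame > 0 else reverse_complement(seq)
    region = strand[abs(frame) - 1:]
    usable = len(region) - len(region) % 3
    return "".join(
        _CODON_TO_AA.get(region[i:i + 3], "X") for i in range(0, usable, 3)
    )


def _stop_free_runs(peptide: str) -> Iterable[tuple[int, int]]:
    """Yield (start, end) peptide index ranges of maximal stop-free runs."""
    start = None
    for i, aa in enumerate(peptide):
        if aa == "*":
            if start is not None:
                yield start, i
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, len(peptide)


def find_orfs(record: SequenceRecord, min_aa: int = 100) -> list[OrfCandidate]:
    """All maximal stop-free stretches across six frames longer than ``min_aa``.

    The length filter is strictly greater-than: a 100-aa stretch is dropped
    at ``min_aa=100``, a 101-aa stretch is kept.  No start codon is required;
    the screen downstream targets homology, not gene models.
    """
    if record.alphabet != "nucleotide":
        raise AlphabetError("ORF scanning requires a nucleotide record")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(record.sequence)
    out: list[OrfCandidate] = []
    for frame in FRAMES:
        peptide = translate(record.sequence, frame)
        offset = abs(frame) - 1
        for p0, p1 in _stop_free_runs(peptide):
            if p1 - p0 <= min_aa:
                continue
            lo, hi = offset + 3 * p0, offset + 3 * p1
            if frame < 0:
                lo, hi = n - hi, n - lo
            out.append(
                OrfCandidate(record.id, frame, lo, hi, peptide[p0:p1], p1 - p0)
            )
    out.sort(key=lambda o: (o.start, o.frame))
    return out


def extract_orf_nucleotides(record: SequenceRecord, orf: OrfCandidate) -> str:
    """Forward-strand slice of an ORF, oriented to read in its frame."""
    piece = record.sequence[orf.start:orf.end]
    return piece if orf.frame > 0 else reverse_complement(piece)


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a (multi-line) FASTA file; ids are the first whitespace token."""
    records = [
        SequenceRecord(rec.id, str(rec.seq), alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def write_orf_report(orfs: Sequence[OrfCandidate], path: str | Path) -> None:
    """TSV report with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tframe\tstart_1based\tend_1based\tlength_aa\tpeptide\n")
        for o in orfs:
            frame = f"+{o.frame}" if o.frame > 0 else str(o.frame)
            fh.write(
                f"{o.transcript_id}\t{frame}\t{o.start + 1}\t{o.end}\t{o.length_aa}\t{o.peptide}\n"
            )
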