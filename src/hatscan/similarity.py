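"""Similarity evidence: 12-column hit tables and a built-in local aligner.

External homology searches (BLAST-style) enter the pipeline as tabular hit
files.  For self-contained runs on synthetic data, ``local_align`` computes
affine-gap Smith-Waterman alignments and converts raw scores to bits with
the Karlin-Altschul transform  bits = (lambda * raw - ln K) / ln 2.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlphabetError, FormatError
from .sequence_core import SequenceRecord

HIT_TABLE_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class AlignmentHit:
    """One local-similarity hit; coordinates are 1-based inclusive."""

    query_id: str
    subject_id: str
    subject_taxon: str
    percent_identity: float
    alignment_length: int
    bitscore: float
    evalue: Optional[float] = None
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise FormatError("alignment length must be >= 1")
        if not math.isfinite(self.bitscore):
            raise FormatError("bitscore must be finite")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring for the built-in aligner.

    Gap convention: a gap of length L scores ``gap_open + (L-1) * gap_extend``
    (the opening position itself costs ``gap_open``).  ``lambda_`` and ``K``
    are the Karlin-Altschul constants for the raw-to-bit conversion.
    """

    mode: str  # "nucleotide" | "protein"
    match: int = 1
    mismatch: int = -2
    matrix_name: str = "BLOSUM62"
    gap_open: int = -5
    gap_extend: int = -2
    lambda_: float = 0.625
    K: float = 0.41

    def __post_init__(self) -> None:
        if self.mode not in ("nucleotide", "protein"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be nonpositive")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda_ and K must be positive")

    @classmethod
    def nucleotide(cls, match: int = 1, mismatch: int = -2,
                   gap_open: int = -5, gap_extend: int = -2,
                   lambda_: float = 0.625, K: float = 0.41) -> "ScoringScheme":
        """Defaults mirror the common +1/-2 nucleotide scoring."""
        return cls("nucleotide", match=match, mismatch=mismatch,
                   gap_open=gap_open, gap_extend=gap_extend,
                   lambda_=lambda_, K=K)

    @classmethod
    def protein(cls, matrix_name: str = "BLOSUM62",
                gap_open: int = -12, gap_extend: int = -1,
                lambda_: float = 0.267, K: float = 0.041) -> "ScoringScheme":
        """Standard gapped BLOSUM62 constants."""
        return cls("protein", matrix_name=matrix_name,
                   gap_open=gap_open, gap_extend=gap_extend,
                   lambda_=lambda_, K=K)

    def bits(self, raw_score: float) -> float:
        return (self.lambda_ * raw_score - math.log(self.K)) / math.log(2)


def _make_aligner(scheme: ScoringScheme, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if scheme.mode == "protein":
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    else:
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def local_align(a: SequenceRecord, b: SequenceRecord,
                scheme: ScoringScheme) -> Optional[AlignmentHit]:
    """Best local alignment of ``a`` (query) against ``b`` (subject).

    Returns None when the best local score is not positive ("no hit").
    Percent identity counts identical aligned columns over all alignment
    columns, gap columns included.
    """
    if a.alphabet != b.alphabet:
        raise AlphabetError(
            f"alphabet mismatch: {a.alphabet!r} vs {b.alphabet!r}"
        )
    expected = "nucleotide" if scheme.mode == "nucleotide" else "peptide"
    if a.alphabet != expected:
        raise AlphabetError(
            f"{scheme.mode} scoring scheme cannot align {a.alphabet} records"
        )
    aligner = _make_aligner(scheme)
    raw = aligner.score(a.sequence, b.sequence)
    if raw <= 0:
        return None
    aln = next(iter(aligner.align(a.sequence, b.sequence)))
    qcols, scols = str(aln[0]), str(aln[1])
    columns = len(qcols)
    identical = sum(1 for x, y in zip(qcols, scols) if x == y and x != "-")
    blocks = aln.aligned
    q_start, q_end = int(blocks[0][0][0]), int(blocks[0][-1][1])
    s_start, s_end = int(blocks[1][0][0]), int(blocks[1][-1][1])
    return AlignmentHit(
        query_id=a.id,
        subject_id=b.id,
        subject_taxon="",
        percent_identity=100.0 * identical / columns,
        alignment_length=columns,
        bitscore=scheme.bits(raw),
        evalue=None,
        q_start=q_start + 1,
        q_end=q_end,
        s_start=s_start + 1,
        s_end=s_end,
    )


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping subject-id prefixes to taxon labels."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"taxon map row {lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def resolve_taxon(subject_id: str, taxon_map: Mapping[str, str],
                  on_unmapped: str = "error") -> str:
    """Longest-prefix lookup of a subject id in the taxon map."""
    best = None
    for prefix, taxon in taxon_map.items():
        if subject_id.startswith(prefix):
            if best is None or len(prefix) > len(best[0]):
                best = (prefix, taxon)
    if best is not None:
        return best[1]
    if on_unmapped == "unknown":
        return "unknown"
    raise FormatError(f"subject id {subject_id!r} matches no taxon-map prefix")


def read_hit_table(path: str | Path, taxon_map: Mapping[str, str],
                   on_unmapped: str = "error") -> list[AlignmentHit]:
    """Parse a 12-column tab-separated hit table (BLAST tabular format 6).

    Column order: query, subject, pident, length, mismatch, gapopen,
    qstart, qend, sstart, send, evalue, bitscore.  Malformed rows raise
    :class:`FormatError` naming the row number.  Comment lines (``#``) and
    blank lines are skipped.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) != 12:
                raise FormatError(
                    f"hit table row {lineno}: expected 12 columns, got {len(row)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=row[0],
                    subject_id=row[1],
                    subject_taxon=resolve_taxon(row[1], taxon_map, on_unmapped),
                    percent_identity=float(row[2]),
                    alignment_length=int(row[3]),
                    bitscore=float(row[11]),
                    evalue=float(row[10]),
                    q_start=int(row[6]),
                    q_end=int(row[7]),
                    s_start=int(row[8]),
                    s_end=int(row[9]),
                )
            except ValueError as exc:
                raise FormatError(f"hit table row {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular layout (mismatch/gapopen as 0)."""
    with open(path, "w") as fh:
        for h in hits:
            evalue = h.evalue if h.evalue is not None else 0.0
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t0\t0\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{evalue:.3g}\t{h.bitscore:.2f}\n"
            )


def best_hit(hits: Sequence[AlignmentHit],
             restrict_to: Optional[set[str]] = None) -> Optional[AlignmentHit]:
    """Highest-bitscore hit, optionally restricted to a taxon set.

    Ties break by lower e-value (absent e-values sort last), then by
    lexicographic subject id, making the choice order-independent.
    """
    pool = [
        h for h in hits
        if restrict_to is None or h.subject_taxon in restrict_to
    ]
    if not pool:
        return None
    return min(
        pool,
        key=lambda h: (
            -h.bitscore,
            h.evalue if h.evalue is not None else math.inf,
            h.subject_id,
        ),
    )
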