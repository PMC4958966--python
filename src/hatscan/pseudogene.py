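"""Classify candidate coding sequences as intact or pseudogenized.

A candidate is compared with a well-annotated in-frame reference CDS by
semi-global nucleotide alignment (free end gaps, so partial candidates are
not penalized at their ends).  Two lesion kinds are called:

* premature_stop — a stop codon read in the reference frame strictly
  before the reference's final codon.  Codons are read through the
  alignment: for each reference codon whose three positions all pair with
  candidate bases, the candidate bases are translated.  Reading the frame
  off the reference keeps downstream codons in register even after a
  frameshift, so only genuine stop substitutions are called.
* frameshift_indel — any contiguous internal alignment gap whose length is
  not a multiple of three.  Each such gap is one lesion: two separate 1-nt
  and 2-nt gaps disrupt coding locally even though they restore the global
  frame downstream.  Clean in-frame indels are not lesions.

Candidates covering less than half the reference (configurable) are called
undetermined rather than trusted either way.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align

from .errors import ReferenceCdsError
from .sequence_core import SequenceRecord, translate, STOP_CODONS
from .similarity import ScoringScheme


@dataclass(frozen=True)
class CodingLesion:
    """kind 'premature_stop': position is a 0-based reference codon index.
    kind 'frameshift_indel': position is the 1-based nucleotide offset in
    the candidate where the gap opens; indel_len is the gap length."""

    kind: str
    position: int
    indel_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("premature_stop", "frameshift_indel"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.kind == "frameshift_indel":
            if self.indel_len is None or self.indel_len % 3 == 0:
                raise ValueError("frameshift indel length must be nonzero mod 3")
        elif self.indel_len is not None:
            raise ValueError("premature_stop lesions carry no indel length")


@dataclass
class CodingAssessment:
    gene_id: str
    status: str  # intact | pseudogene | undetermined
    lesions: list[CodingLesion]
    aligned_fraction: float


def _semiglobal_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scheme.mode != "nucleotide":
        raise ValueError("pseudogene assessment aligns nucleotide sequences")
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def assess_coding(candidate: SequenceRecord,
                  reference_cds: SequenceRecord,
                  min_aligned_fraction: float = 0.5,
                  scheme: Optional[ScoringScheme] = None) -> CodingAssessment:
    """Assess one candidate against an in-frame reference CDS.

    The reference must be a codon multiple with no internal stop; its final
    codon may be a stop.  A candidate stop aligned to the reference's own
    terminator is not a lesion.
    """
    ref = reference_cds.sequence
    if len(ref) % 3 != 0:
        raise ReferenceCdsError(
            f"reference {reference_cds.id!r} length {len(ref)} is not a codon multiple"
        )
    ref_pep = translate(ref)
    if "*" in ref_pep[:-1]:
        raise ReferenceCdsError(
            f"reference {reference_cds.id!r} carries an internal stop codon"
        )
    if scheme is None:
        # gaps cost more than a fully substituted codon, so point mutations
        # are never re-explained as compensating indel pairs
        scheme = ScoringScheme.nucleotide(match=2, mismatch=-3,
                                          gap_open=-10, gap_extend=-3)
    aligner = _semiglobal_aligner(scheme)
    aln = next(iter(aligner.align(ref, candidate.sequence)))
    ref_cols, cand_cols = str(aln[0]), str(aln[1])

    pair_cols = [
        c for c, (r, q) in enumerate(zip(ref_cols, cand_cols))
        if r != "-" and q != "-"
    ]
    n_codons = len(ref) // 3
    if not pair_cols:
        return CodingAssessment(candidate.id, "undetermined", [], 0.0)
    first_pair, last_pair = pair_cols[0], pair_cols[-1]

    cand_base_at_ref: dict[int, str] = {}
    anchored: list[tuple[int, CodingLesion]] = []  # (ref anchor, lesion)
    ref_pos = cand_pos = 0
    col = 0
    ncols = len(ref_cols)
    while col < ncols:
        r, q = ref_cols[col], cand_cols[col]
        if r != "-" and q != "-":
            cand_base_at_ref[ref_pos] = q
            ref_pos += 1
            cand_pos += 1
            col += 1
            continue
        # maximal gap run (all-in-ref or all-in-candidate by construction)
        run_start_col = col
        run_ref_anchor = ref_pos
        run_cand_anchor = cand_pos
        deletion = q == "-"  # gap in candidate
        while col < ncols and (
            (cand_cols[col] == "-") if deletion else (ref_cols[col] == "-")
        ):
            if deletion:
                ref_pos += 1
            else:
                cand_pos += 1
            col += 1
        run_len = col - run_start_col
        internal = run_start_col > first_pair and run_start_col < last_pair
        if internal and run_len % 3 != 0:
            anchored.append((
                run_ref_anchor,
                CodingLesion("frameshift_indel", run_cand_anchor + 1, run_len),
            ))

    for codon_idx in range(n_codons - 1):  # final reference codon excluded
        bases = [cand_base_at_ref.get(3 * codon_idx + k) for k in range(3)]
        if None in bases:
            continue
        if "".join(bases) in STOP_CODONS:
            anchored.append((
                3 * codon_idx,
                CodingLesion("premature_stop", codon_idx),
            ))

    anchored.sort(key=lambda pair: (pair[0], pair[1].kind))
    lesions = [lesion for _, lesion in anchored]
    aligned_fraction = len(cand_base_at_ref) / len(ref)

    if aligned_fraction < min_aligned_fraction:
        # coverage too low to trust any call, including the lesion list
        return CodingAssessment(candidate.id, "undetermined", [], aligned_fraction)
    status = "pseudogene" if lesions else "intact"
    return CodingAssessment(candidate.id, status, lesions, aligned_fraction)


def write_assessments(assessments: Sequence[CodingAssessment],
                      path: str | Path) -> None:
    """TSV report; lesions serialize as kind:pos[:len] joined by semicolons."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstatus\tlesions\taligned_fraction\n")
        for a in assessments:
            parts = []
            for lesion in a.lesions:
                token = f"{lesion.kind}:{lesion.position}"
                if lesion.indel_len is not None:
                    token += f":{lesion.indel_len}"
                parts.append(token)
            fh.write(
                f"{a.gene_id}\t{a.status}\t{';'.join(parts) or '-'}\t"
                f"{a.aligned_fraction:.3f}\n"
            )
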