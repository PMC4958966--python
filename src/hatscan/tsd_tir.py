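"""Search for TSD-TIR-(interior)-TIR-TSD border structures in genomic windows.

A cut-and-paste (class II) hAT transposon insertion leaves an 8-bp target
site duplication (TSD) on both sides of the element, whose ends carry short
terminal inverted repeats (TIRs, here 8-23 bp).  The finder reports every
coordinate tuple

    left TSD | left TIR | interior | right TIR | right TSD

where the two TSD copies match exactly, the left TIR equals the reverse
complement of the right TIR at every position except (optionally) the
outermost base, and the TIR is not a two-letter simple repeat.  An 8-bp TSD
is additionally annotated for the degenerate hAT consensus (T/C)A(A/G)NG.

``brute_force_oracle`` re-derives the same result set by exhaustive
enumeration and exists purely to cross-check the indexed finder.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .sequence_core import SequenceRecord, reverse_complement

log = logging.getLogger(__name__)

TSD_CONSENSUS = ({"C", "T"}, {"A"}, {"A", "G"}, {"A", "C", "G", "T"}, {"G"})


@dataclass(frozen=True)
class SearchWindow:
    """A genomic window to scan; ``origin`` is free-text provenance."""

    id: str
    sequence: str
    origin: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError("search window must be non-empty")


@dataclass(frozen=True)
class TsdTirStructure:
    """One detected border structure; positions are 0-based window offsets."""

    window_id: str
    tsd_seq: str
    left_tsd_start: int
    left_tir_start: int
    right_tir_start: int
    right_tsd_start: int
    tir_len: int
    imperfect_first_base: bool
    consensus_match: bool
    interior_len: int

    @property
    def interior_start(self) -> int:
        return self.left_tir_start + self.tir_len

    def key(self) -> tuple:
        return (self.left_tsd_start, self.tir_len, self.right_tir_start)


def composition_ok(tir: str) -> bool:
    """False for TIRs built from fewer than three nucleotide types.

    Two-letter TIRs are indistinguishable from simple repeats and are
    excluded; N does not count toward the distinct-letter tally.
    """
    if not tir:
        raise ValueError("empty TIR")
    return len(set(tir) - {"N"}) >= 3


def tsd_consensus_match(tsd: str) -> bool:
    """True iff the degenerate 5-mer (T/C)A(A/G)NG occurs within the 8-mer.

    The 5-nt pattern cannot anchor an 8-nt TSD uniquely, so all four
    offsets are scanned.  This is an annotation, never a filter.
    """
    if len(tsd) != 8:
        raise ValueError(f"TSD consensus check requires an 8-mer, got {len(tsd)} nt")
    return any(
        all(tsd[off + k] in allowed for k, allowed in enumerate(TSD_CONSENSUS))
        for off in range(4)
    )


def extract_windows(genome: SequenceRecord,
                    gene_coords: Sequence[tuple[int, int]],
                    flank: int = 5000) -> list[SearchWindow]:
    """Per-gene windows of +-``flank`` bp, clamped to the sequence, plus the
    intergenic segment between each pair of consecutive genes."""
    n = len(genome.sequence)
    coords = sorted((int(s), int(e)) for s, e in gene_coords)
    windows: list[SearchWindow] = []
    for idx, (s, e) in enumerate(coords, 1):
        lo, hi = max(0, s - flank), min(n, e + flank)
        windows.append(SearchWindow(
            id=f"{genome.id}:gene{idx}",
            sequence=genome.sequence[lo:hi],
            origin=f"gene [{s},{e}) +-{flank} bp -> [{lo},{hi})",
        ))
    for idx in range(len(coords) - 1):
        gap_lo, gap_hi = coords[idx][1], coords[idx + 1][0]
        if gap_hi > gap_lo:
            windows.append(SearchWindow(
                id=f"{genome.id}:intergenic{idx + 1}-{idx + 2}",
                sequence=genome.sequence[gap_lo:gap_hi],
                origin=f"intergenic segment [{gap_lo},{gap_hi})",
            ))
    return windows


def _tir_mismatch_positions(left: str, right_rc: str) -> list[int]:
    """Positions where the left TIR disagrees with revcomp(right TIR).

    Position 0 is the outermost base (adjacent to the TSD) on both copies.
    N never matches anything, including another N.
    """
    return [
        p for p, (x, y) in enumerate(zip(left, right_rc))
        if x != y or x == "N" or y == "N"
    ]


def _structure_at(window: SearchWindow, i: int, j: int, tir_len: int,
                  tsd_len: int, allow_first_base_mismatch: bool,
                  min_interior: int) -> Optional[TsdTirStructure]:
    """Validate the tuple (left TSD at i, right TSD at j, this TIR length)."""
    seq = window.sequence
    left_tir_start = i + tsd_len
    right_tir_start = j - tir_len
    interior = right_tir_start - (left_tir_start + tir_len)
    if interior < 0 or interior < min_interior:
        return None
    left = seq[left_tir_start:left_tir_start + tir_len]
    right_rc = reverse_complement(seq[right_tir_start:j])
    mism = _tir_mismatch_positions(left, right_rc)
    if mism and not (allow_first_base_mismatch and mism == [0]):
        return None
    # composition rule on both copies keeps the search strand-symmetric
    if not (composition_ok(left) and composition_ok(right_rc)):
        return None
    tsd = seq[i:i + tsd_len]
    return TsdTirStructure(
        window_id=window.id,
        tsd_seq=tsd,
        left_tsd_start=i,
        left_tir_start=left_tir_start,
        right_tir_start=right_tir_start,
        right_tsd_start=j,
        tir_len=tir_len,
        imperfect_first_base=bool(mism),
        consensus_match=tsd_consensus_match(tsd) if tsd_len == 8 else False,
        interior_len=interior,
    )


def find_tsd_tir(window: SearchWindow, tsd_len: int = 8,
                 tir_min: int = 8, tir_max: int = 23,
                 allow_first_base_mismatch: bool = True,
                 min_interior: int = 0) -> list[TsdTirStructure]:
    """All border structures in a window, sorted by (left TSD, TIR length).

    TSD copies must match exactly (the duplication is created verbatim at
    insertion); a single mismatch is tolerated only at the outermost TIR
    base, mirroring the published search settings.  Overlapping and nested
    structures are all reported; no maximality pruning is applied.

    Candidate TSD pairs are located through an exact k-mer position index,
    then each pair is validated across the allowed TIR lengths.
    """
    seq = window.sequence
    n = len(seq)
    if n < 2 * tsd_len + 2 * tir_min + min_interior:
        log.debug("window %s shorter than the minimal structure", window.id)
        return []
    positions_by_kmer: dict[str, list[int]] = {}
    for i in range(n - tsd_len + 1):
        kmer = seq[i:i + tsd_len]
        if "N" in kmer:
            continue
        positions_by_kmer.setdefault(kmer, []).append(i)
    found: list[TsdTirStructure] = []
    seen: set[tuple] = set()
    for positions in positions_by_kmer.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                if j + tsd_len > n:
                    continue
                for tir_len in range(tir_min, tir_max + 1):
                    st = _structure_at(window, i, j, tir_len, tsd_len,
                                       allow_first_base_mismatch, min_interior)
                    if st is not None and st.key() not in seen:
                        seen.add(st.key())
                        found.append(st)
    found.sort(key=TsdTirStructure.key)
    return found


def brute_force_oracle(window: SearchWindow, tsd_len: int = 8,
                       tir_min: int = 8, tir_max: int = 23,
                       allow_first_base_mismatch: bool = True,
                       min_interior: int = 0,
                       max_window: int = 500) -> list[TsdTirStructure]:
    """Exhaustive enumeration over all coordinate tuples; verification only.

    Same output contract as :func:`find_tsd_tir`; guarded to small windows.
    """
    seq = window.sequence
    n = len(seq)
    if n > max_window:
        raise ValueError(
            f"oracle guard: window of {n} nt exceeds the {max_window} nt limit"
        )
    found: list[TsdTirStructure] = []
    for i in range(n - tsd_len + 1):
        tsd = seq[i:i + tsd_len]
        if "N" in tsd:
            continue
        for j in range(i + tsd_len, n - tsd_len + 1):
            if seq[j:j + tsd_len] != tsd:
                continue
            for tir_len in range(tir_min, tir_max + 1):
                left_start = i + tsd_len
                right_start = j - tir_len
                interior = right_start - (left_start + tir_len)
                if interior < 0 or interior < min_interior:
                    continue
                left = seq[left_start:left_start + tir_len]
                right_rc = reverse_complement(seq[right_start:j])
                mism = [
                    p for p in range(tir_len)
                    if left[p] != right_rc[p] or left[p] == "N" or right_rc[p] == "N"
                ]
                if mism and not (allow_first_base_mismatch and mism == [0]):
                    continue
                if not (composition_ok(left) and composition_ok(right_rc)):
                    continue
                found.append(TsdTirStructure(
                    window_id=window.id,
                    tsd_seq=tsd,
                    left_tsd_start=i,
                    left_tir_start=left_start,
                    right_tir_start=right_start,
                    right_tsd_start=j,
                    tir_len=tir_len,
                    imperfect_first_base=bool(mism),
                    consensus_match=tsd_consensus_match(tsd) if tsd_len == 8 else False,
                    interior_len=interior,
                ))
    found.sort(key=TsdTirStructure.key)
    return found


def read_gene_coords(path: str | Path) -> dict[str, list[tuple[int, int, str, str]]]:
    """Gene coordinate TSV: seq_id, start_1based, end_1based, gene_id, strand.

    Returns 0-based half-open intervals grouped by sequence id.
    """
    out: dict[str, list[tuple[int, int, str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("seq_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"gene coordinate row {lineno}: expected 5 columns")
            seq_id, s1, e1, gene_id, strand = parts
            out.setdefault(seq_id, []).append(
                (int(s1) - 1, int(e1), gene_id, strand)
            )
    return out


def write_structures(structures: Sequence[TsdTirStructure],
                     path: str | Path) -> None:
    """TSV report of structures with 1-based start coordinates."""
    with open(path, "w") as fh:
        fh.write(
            "window_id\tleft_tsd_start\tleft_tir_start\tinterior_start\t"
            "right_tir_start\tright_tsd_start\ttsd_seq\ttir_len\t"
            "interior_len\timperfect_first_base\tconsensus_match\n"
        )
        for s in structures:
            fh.write(
                f"{s.window_id}\t{s.left_tsd_start + 1}\t{s.left_tir_start + 1}\t"
                f"{s.interior_start + 1}\t{s.right_tir_start + 1}\t"
                f"{s.right_tsd_start + 1}\t{s.tsd_seq}\t{s.tir_len}\t"
                f"{s.interior_len}\t{str(s.imperfect_first_base).lower()}\t"
                f"{str(s.consensus_match).lower()}\n"
            )
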