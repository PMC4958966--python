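"""Collinearity of anchor genes flanking tandem transposase (BO) loci.

The reference arrangement carries two upstream anchors (labels ``a``, ``b``),
the transposase genes (``BO1``, ``BO2a``, ``BO2b``) and four downstream
anchors (``1``-``4``).  Per species, the analysis reports which anchors
survive, whether the surviving anchors keep their reference order (a whole
block inversion is tolerated and flagged), which entries flipped strand
after normalizing for such an inversion, and whether the BO genes remain a
tandem block between anchors ``b`` and ``1``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .errors import ConfigurationError
from .similarity import AlignmentHit, best_hit

log = logging.getLogger(__name__)

ANCHORS = ("a", "b", "1", "2", "3", "4")
UPSTREAM_ANCHORS = frozenset({"a", "b"})
DOWNSTREAM_ANCHORS = frozenset({"1", "2", "3", "4"})
BO_LABELS = ("BO1", "BO2a", "BO2b")


def is_bo_label(label: Optional[str]) -> bool:
    return label is not None and label.startswith("BO")


@dataclass(frozen=True)
class GeneOrderEntry:
    locus_id: str
    anchor: Optional[str]  # one of ANCHORS, a BO label, or None
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"strand must be + or -, got {self.strand!r}")
        if self.anchor is not None and self.anchor not in ANCHORS \
                and not is_bo_label(self.anchor):
            raise ConfigurationError(f"unknown anchor label {self.anchor!r}")


@dataclass(frozen=True)
class GeneOrderTable:
    """Loci of one species ordered by chromosomal position."""

    species: str
    entries: tuple[GeneOrderEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))


@dataclass
class SyntenyReport:
    species: str
    anchors_present: frozenset
    anchors_lost: frozenset
    order_conserved: bool
    block_reversed: bool
    orientation_flips: tuple[str, ...]
    bo_gene_count: int
    tandem_bo: bool


def reference_gene_order(species: str = "Arabidopsis_thaliana") -> GeneOrderTable:
    """The reference anchor/BO arrangement on the A. thaliana chromosome 3
    segment: a, b upstream; BO1, BO2a tandem; 1-4 downstream.  Strands are a
    synthetic stand-in (all '+'): the analysis only uses them relatively."""
    labels = [
        ("AT3G17205", "a"), ("AT3G17240", "b"),
        ("AT3G17260", "BO1"), ("AT3G17290", "BO2a"),
        ("AT3G17300", "1"), ("AT3G17310", "2"),
        ("AT3G17320", "3"), ("AT3G17340", "4"),
    ]
    return GeneOrderTable(
        species,
        tuple(GeneOrderEntry(locus, anchor, "+") for locus, anchor in labels),
    )


def assign_anchors(hits: Sequence[AlignmentHit],
                   anchor_refs: Sequence[str],
                   min_bitscore: float = 50.0) -> dict[str, str]:
    """Map species loci to anchors by best hit.

    ``hits`` carry the anchor reference as query and the species locus as
    subject.  Each anchor takes its best-scoring locus at or above
    ``min_bitscore``; if two anchors claim one locus, the higher bitscore
    keeps it and the conflict is logged.  Returns locus -> anchor; anchors
    missing from the result are lost.
    """
    claimed: dict[str, tuple[str, float]] = {}  # locus -> (anchor, bitscore)
    for anchor in anchor_refs:
        pool = [h for h in hits
                if h.query_id == anchor and h.bitscore >= min_bitscore]
        top = best_hit(pool)
        if top is None:
            continue
        locus = top.subject_id
        if locus in claimed:
            other_anchor, other_score = claimed[locus]
            winner = anchor if top.bitscore > other_score else other_anchor
            log.warning(
                "anchors %r and %r both best-hit locus %r; keeping %r",
                anchor, other_anchor, locus, winner,
            )
            if winner == anchor:
                claimed[locus] = (anchor, top.bitscore)
        else:
            claimed[locus] = (anchor, top.bitscore)
    return {locus: anchor for locus, (anchor, _) in claimed.items()}


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def compare_to_reference(table: GeneOrderTable,
                         reference: GeneOrderTable) -> SyntenyReport:
    """Synteny report of one species table against the reference arrangement.

    Order conservation is judged over the anchors present in the species
    (losses do not break order); insertion of non-anchor loci anywhere is
    ignored.  Orientation flips are evaluated after normalizing for a
    whole-block inversion, for anchors and BO labels alike.
    """
    ref_anchor_order = [e.anchor for e in reference.entries if e.anchor in ANCHORS]
    if set(ref_anchor_order) != set(ANCHORS):
        missing = set(ANCHORS) - set(ref_anchor_order)
        raise ConfigurationError(f"reference is missing anchors {sorted(missing)}")

    present_order = [e.anchor for e in table.entries if e.anchor in ANCHORS]
    present = frozenset(present_order)
    lost = frozenset(ANCHORS) - present
    ref_present = [a for a in ref_anchor_order if a in present]
    forward = present_order == ref_present
    order_conserved = forward or present_order == ref_present[::-1]
    block_reversed = order_conserved and not forward and len(present_order) > 1

    ref_strand: dict[str, str] = {}
    for e in reference.entries:
        if e.anchor is not None and e.anchor not in ref_strand:
            ref_strand[e.anchor] = e.strand
    flips: list[str] = []
    for e in table.entries:
        if e.anchor is None or e.anchor not in ref_strand:
            continue
        expected = _flip(ref_strand[e.anchor]) if block_reversed else ref_strand[e.anchor]
        if e.strand != expected:
            flips.append(e.anchor)

    bo_indices = [i for i, e in enumerate(table.entries) if is_bo_label(e.anchor)]
    bo_gene_count = len(bo_indices)
    tandem_bo = False
    if bo_indices:
        lo, hi = bo_indices[0], bo_indices[-1]
        # only non-anchor loci may sit inside the BO block
        tandem_bo = all(
            table.entries[i].anchor not in ANCHORS
            for i in range(lo, hi + 1)
        )
        anchor_index = {
            e.anchor: i for i, e in enumerate(table.entries) if e.anchor in ANCHORS
        }
        before, after = ("1", "b") if block_reversed else ("b", "1")
        if before in anchor_index:
            tandem_bo = tandem_bo and anchor_index[before] < lo
        if after in anchor_index:
            tandem_bo = tandem_bo and anchor_index[after] > hi

    return SyntenyReport(
        species=table.species,
        anchors_present=present,
        anchors_lost=lost,
        order_conserved=order_conserved,
        block_reversed=block_reversed,
        orientation_flips=tuple(flips),
        bo_gene_count=bo_gene_count,
        tandem_bo=tandem_bo,
    )


def read_gene_order(path: str | Path) -> list[GeneOrderTable]:
    """Gene-order TSV: species, position_rank, locus_id, anchor_or_none ('-'),
    strand.  Rows are grouped per species and ordered by rank."""
    rows: dict[str, list[tuple[int, GeneOrderEntry]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("species\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ConfigurationError(
                    f"gene order row {lineno}: expected 5 columns"
                )
            species, rank, locus, anchor, strand = parts
            entry = GeneOrderEntry(locus, None if anchor == "-" else anchor, strand)
            rows.setdefault(species, []).append((int(rank), entry))
    tables = []
    for species in sorted(rows):
        ordered = [e for _, e in sorted(rows[species], key=lambda t: t[0])]
        tables.append(GeneOrderTable(species, tuple(ordered)))
    return tables


def write_gene_order(tables: Sequence[GeneOrderTable], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tposition_rank\tlocus_id\tanchor\tstrand\n")
        for table in tables:
            for rank, e in enumerate(table.entries, 1):
                fh.write(
                    f"{table.species}\t{rank}\t{e.locus_id}\t"
                    f"{e.anchor or '-'}\t{e.strand}\n"
                )


def write_reports(reports: Sequence[SyntenyReport], path: str | Path) -> None:
    """One species per row, mirroring a presence/orientation matrix."""
    with open(path, "w") as fh:
        fh.write(
            "species\t" + "\t".join(f"anchor_{a}" for a in ANCHORS)
            + "\torder_conserved\tblock_reversed\torientation_flips"
            "\tbo_gene_count\ttandem_bo\n"
        )
        for r in reports:
            cells = [
                "present" if a in r.anchors_present else "lost" for a in ANCHORS
            ]
            fh.write(
                f"{r.species}\t" + "\t".join(cells)
                + f"\t{str(r.order_conserved).lower()}"
                + f"\t{str(r.block_reversed).lower()}"
                + f"\t{';'.join(r.orientation_flips) or '-'}"
                + f"\t{r.bo_gene_count}\t{str(r.tandem_bo).lower()}\n"
            )
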