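"""The foreign-gene (HGT) transcriptome screen.

The screen runs four stages in a fixed order:

1. host-contamination exclusion — keep only transcripts expressed in
   developmental stages sampled before attachment to the host;
2. coding-length filter — at least one stop-free ORF strictly longer than
   100 aa in any of the six frames;
3. alien score ratio — best outgroup bitscore over best ingroup bitscore
   must strictly exceed a threshold (default 1.2); the ingroup is the
   recipient's own clade (e.g. Lamiales), the outgroup everything else;
4. closest-relative nucleotide filter — transcripts whose best
   nucleotide-level hit is the designated closest ingroup relative
   (e.g. Mimulus guttatus) are dropped as vertically inherited.

Every transcript receives a verdict carrying all failing flags, so the
filters stay auditable even for early rejects.  The ratio is scale-free in
the bitscores, so the choice of score type cannot change a verdict.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError
from .sequence_core import SequenceRecord, find_orfs
from .similarity import AlignmentHit, best_hit

FILTER_FLAGS = frozenset({"stage_filtered", "length_filtered", "nt_relative_filtered"})
INFO_FLAGS = frozenset({"no_ingroup_hit", "no_outgroup_hit"})


@dataclass(frozen=True)
class TaxonomyPartition:
    """Maps each taxon label to self / ingroup / outgroup.

    ``closest_relative`` names the designated closest ingroup relative used
    by the nucleotide-level filter.  Self hits (the screened species itself)
    never enter scoring.
    """

    classes: Mapping[str, str]
    closest_relative: str

    def __post_init__(self) -> None:
        for taxon, role in self.classes.items():
            if role not in ("self", "ingroup", "outgroup"):
                raise ConfigurationError(
                    f"taxon {taxon!r} has unknown role {role!r}"
                )
        if self.classes.get(self.closest_relative) != "ingroup":
            raise ConfigurationError(
                f"closest relative {self.closest_relative!r} must be an ingroup taxon"
            )

    def role(self, taxon: str) -> str:
        try:
            return self.classes[taxon]
        except KeyError:
            raise ConfigurationError(
                f"taxon {taxon!r} present in evidence but absent from the partition"
            ) from None

    def taxa(self, role: str) -> set[str]:
        return {t for t, r in self.classes.items() if r == role}


class StageExpressionTable:
    """Transcript-by-stage abundance matrix with a pre-attachment stage set."""

    def __init__(self, values: pd.DataFrame, pre_attachment: Sequence[str]):
        if (values.to_numpy() < 0).any():
            raise FormatError("stage expression abundances must be nonnegative")
        self.values = values
        self.pre_attachment = frozenset(pre_attachment)
        if not self.pre_attachment:
            raise ConfigurationError("pre-attachment stage set must be non-empty")
        unknown = self.pre_attachment - set(values.columns)
        if unknown:
            raise ConfigurationError(
                f"pre-attachment stages {sorted(unknown)} absent from the table"
            )

    @classmethod
    def from_tsv(cls, path: str | Path,
                 pre_attachment: Sequence[str]) -> "StageExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(df, pre_attachment)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.values.to_csv(fh, sep="\t")


@dataclass
class AlienVerdict:
    """Per-transcript outcome of the screen."""

    transcript_id: str
    best_ingroup_bitscore: Optional[float] = None
    best_outgroup_bitscore: Optional[float] = None
    ratio: Optional[float] = None  # math.inf when outgroup-only
    flags: frozenset = frozenset()
    candidate: bool = False
    putative_donor: Optional[str] = None
    donor_tie: bool = False


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable screen parameters; defaults are the published pipeline's."""

    threshold: float = 1.2
    min_aa: int = 100
    min_abundance: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("ratio threshold must be positive")
        if self.min_abundance < 0:
            raise ConfigurationError("min_abundance must be >= 0")


def filter_pre_attachment(table: StageExpressionTable,
                          min_abundance: float = 0.0) -> set[str]:
    """Transcript ids expressed (> min_abundance) in any pre-attachment stage.

    Transcripts silent before host attachment are treated as potential host
    contamination and excluded from the screen.
    """
    cols = sorted(table.pre_attachment)
    sub = table.values[cols]
    mask = (sub > min_abundance).any(axis=1)
    return set(table.values.index[mask])


def _checked_query(hits: Sequence[AlignmentHit],
                   transcript_id: Optional[str]) -> str:
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise FormatError(f"hits mix query ids: {sorted(queries)}")
    if queries:
        qid = queries.pop()
        if transcript_id is not None and qid != transcript_id:
            raise FormatError(
                f"hits belong to {qid!r}, expected {transcript_id!r}"
            )
        return qid
    if transcript_id is None:
        raise FormatError("cannot build a verdict without a transcript id")
    return transcript_id


def compute_alien_ratio(hits: Sequence[AlignmentHit],
                        partition: TaxonomyPartition,
                        threshold: float = 1.2,
                        transcript_id: Optional[str] = None) -> AlienVerdict:
    """Alien score ratio verdict for one transcript.

    ratio = best outgroup bitscore / best ingroup bitscore.  Strictly
    greater than ``threshold`` makes a candidate.  A transcript with
    outgroup evidence but no ingroup hit at all is a candidate with an
    infinite ratio and the ``no_ingroup_hit`` flag — absent ingroup homology
    is stronger evidence of foreign origin than any finite ratio.
    """
    qid = _checked_query(hits, transcript_id)
    scored = [h for h in hits if partition.role(h.subject_taxon) != "self"]
    ing = best_hit(scored, partition.taxa("ingroup"))
    out = best_hit(scored, partition.taxa("outgroup"))
    flags: set[str] = set()
    if ing is None:
        flags.add("no_ingroup_hit")
    if out is None:
        flags.add("no_outgroup_hit")
    if out is None:
        return AlienVerdict(qid, ing.bitscore if ing else None, None,
                            None, frozenset(flags), False)
    if ing is None:
        return AlienVerdict(qid, None, out.bitscore, math.inf,
                            frozenset(flags), True)
    ratio = out.bitscore / ing.bitscore
    return AlienVerdict(qid, ing.bitscore, out.bitscore, ratio,
                        frozenset(flags), ratio > threshold)


def nt_relative_filter(nt_hits: Sequence[AlignmentHit],
                       partition: TaxonomyPartition) -> bool:
    """True (filter out) iff the best nucleotide hit is the closest relative.

    Transcripts with no nucleotide hits pass: lack of nucleotide-level
    similarity to the relative is consistent with foreign origin.
    """
    if not nt_hits:
        return False
    scored = [h for h in nt_hits if partition.role(h.subject_taxon) != "self"]
    top = best_hit(scored)
    return top is not None and top.subject_taxon == partition.closest_relative


def assign_putative_donor(hits: Sequence[AlignmentHit],
                          partition: TaxonomyPartition) -> Optional[str]:
    """Taxon of the best outgroup hit, or None without outgroup evidence."""
    donor, _ = _donor_with_tie(hits, partition)
    return donor


def _donor_with_tie(hits: Sequence[AlignmentHit],
                    partition: TaxonomyPartition) -> tuple[Optional[str], bool]:
    scored = [h for h in hits if partition.role(h.subject_taxon) == "outgroup"]
    top = best_hit(scored)
    if top is None:
        return None, False
    tie = any(
        h.subject_taxon != top.subject_taxon
        and h.bitscore == top.bitscore
        and h.evalue == top.evalue
        for h in scored
    )
    return top.subject_taxon, tie


def _group_by_query(hits: Sequence[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return grouped


def run_screen(transcripts: Sequence[SequenceRecord],
               stage_table: StageExpressionTable,
               protein_hits: Sequence[AlignmentHit],
               nt_hits: Sequence[AlignmentHit],
               partition: TaxonomyPartition,
               config: Optional[ScreenConfig] = None) -> list[AlienVerdict]:
    """Run the full screen and return one verdict per transcript.

    Stage order: expression filter, ORF length filter, alien ratio,
    nucleotide closest-relative filter.  All stages annotate every
    transcript; a candidate must clear all of them.
    """
    if config is None:
        config = ScreenConfig()
    for name, table in (("stage expression table", stage_table),
                        ("protein hit table", protein_hits),
                        ("nucleotide hit table", nt_hits)):
        if table is None:
            raise ConfigurationError(f"missing evidence: {name}")
    expressed = filter_pre_attachment(stage_table, config.min_abundance)
    phits = _group_by_query(list(protein_hits))
    nhits = _group_by_query(list(nt_hits))
    verdicts: list[AlienVerdict] = []
    for rec in sorted(transcripts, key=lambda r: r.id):
        flags: set[str] = set()
        if rec.id not in expressed:
            flags.add("stage_filtered")
        if not find_orfs(rec, config.min_aa):
            flags.add("length_filtered")
        base = compute_alien_ratio(
            phits.get(rec.id, []), partition, config.threshold, rec.id
        )
        flags |= base.flags
        if nt_relative_filter(nhits.get(rec.id, []), partition):
            flags.add("nt_relative_filtered")
        donor, tie = _donor_with_tie(phits.get(rec.id, []), partition)
        candidate = base.candidate and not (flags & FILTER_FLAGS)
        verdicts.append(AlienVerdict(
            transcript_id=rec.id,
            best_ingroup_bitscore=base.best_ingroup_bitscore,
            best_outgroup_bitscore=base.best_outgroup_bitscore,
            ratio=base.ratio,
            flags=frozenset(flags),
            candidate=candidate,
            putative_donor=donor,
            donor_tie=tie,
        ))
    return verdicts


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return "NA"
    if value == math.inf:
        return "inf"
    return f"{value:.4f}"


def write_verdicts(verdicts: Sequence[AlienVerdict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tbest_ingroup_bitscore\tbest_outgroup_bitscore\t"
            "ratio\tflags\tcandidate\tputative_donor\tdonor_tie\n"
        )
        for v in verdicts:
            flags = ";".join(sorted(v.flags)) or "-"
            donor = v.putative_donor or "NA"
            fh.write(
                f"{v.transcript_id}\t{_fmt(v.best_ingroup_bitscore)}\t"
                f"{_fmt(v.best_outgroup_bitscore)}\t{_fmt(v.ratio)}\t"
                f"{flags}\t{str(v.candidate).lower()}\t{donor}\t"
                f"{str(v.donor_tie).lower()}\n"
            )


def write_run_summary(path: str | Path, config: ScreenConfig,
                      n_transcripts: int, n_candidates: int,
                      seed: Optional[int] = None,
                      extra: Optional[dict] = None) -> None:
    summary = {
        "config": asdict(config),
        "score_type": "bitscore",
        "n_transcripts": n_transcripts,
        "n_candidates": n_candidates,
        "seed": seed,
    }
    if extra:
        summary.update(extra)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
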