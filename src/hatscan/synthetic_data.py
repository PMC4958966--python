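"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure the screen assumes:

* native transcripts descend from "ingroup" ancestral coding sequences and
  stay close to the designated relative taxon;
* foreign (horizontally transferred) transcripts descend from "donor"
  ancestors, themselves diverged copies of the ingroup ancestors, so the
  alien ratio separates the two classes;
* host-contaminant transcripts look like donor-taxon genes but are only
  expressed after attachment to the host;
* genomic windows receive planted TSD-TIR border structures at recorded
  coordinates, optionally lesioned;
* coding candidates receive planted premature stops and frameshift indels
  at recorded positions;
* per-species gene-order tables receive planted anchor losses, strand
  flips, and block inversions.

Substitutions follow a uniform model with no transition/transversion bias
— sufficient for separability testing, deliberately non-biological.  Every
generator is deterministic under a fixed seed, and the similarity tables
are produced by the built-in aligner, so no external search tool is ever
needed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .hgt_screen import StageExpressionTable, TaxonomyPartition
from .sequence_core import (
    SequenceRecord, STOP_CODONS, reverse_complement, translate, write_fasta,
)
from .similarity import (
    AlignmentHit, ScoringScheme, _make_aligner, local_align, write_hit_table,
)
from .synteny import GeneOrderEntry, GeneOrderTable
from .tsd_tir import composition_ok

import pandas as pd

BASES = "ACGT"
SENSE_CODONS = tuple(sorted(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
))
STAGE_LABELS = ("0G", "2G", "3G", "4.1G", "4.2G", "5.1G", "5.2G", "6.1G", "6.2G")


@dataclass(frozen=True)
class TeParams:
    """Parameters of a planted transposon border structure.

    ``lesion`` is one of None, "outer_tir_base" (mutate the outermost base
    of the left TIR; still detectable as an imperfect-first-base structure)
    or "tsd_mismatch" (mutate one base of the right TSD copy; undetectable
    by design since TSD copies must match exactly).
    """

    tsd: Optional[str] = None
    tir: Optional[str] = None
    tsd_len: int = 8
    tir_len: int = 12
    interior_len: int = 120
    lesion: Optional[str] = None

    def __post_init__(self) -> None:
        if not 8 <= self.tir_len <= 23:
            raise ConfigurationError("TIR length must lie in [8, 23]")
        if self.lesion not in (None, "outer_tir_base", "tsd_mismatch"):
            raise ConfigurationError(f"unknown TE lesion {self.lesion!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the screen dataset generator."""

    seed: int = 1
    n_native: int = 20
    n_foreign: int = 5
    n_contaminant: int = 3
    gene_len_range: tuple[int, int] = (360, 600)  # nt, codon-rounded
    sub_prob_ingroup: float = 0.05
    sub_prob_donor: float = 0.35
    sub_prob_foreign_vs_donor: float = 0.05
    sub_prob_host: float = 0.02
    sub_prob_second_outgroup: float = 0.15
    indel_prob: float = 0.0
    min_report_bits: float = 40.0
    stage_labels: tuple[str, ...] = STAGE_LABELS
    pre_attachment: tuple[str, ...] = ("0G", "2G")
    te_params: TeParams = field(default_factory=TeParams)

    def __post_init__(self) -> None:
        for name in ("sub_prob_ingroup", "sub_prob_donor",
                     "sub_prob_foreign_vs_donor", "sub_prob_host",
                     "sub_prob_second_outgroup", "indel_prob"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if min(self.n_native, self.n_foreign, self.n_contaminant) < 0:
            raise ConfigurationError("transcript counts must be >= 0")
        if not set(self.pre_attachment) <= set(self.stage_labels):
            raise ConfigurationError(
                "pre-attachment stages must be a subset of the stage labels"
            )


def config_hash(config) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _rng(seed: Optional[int], rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def random_nucleotides(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[k] for k in rng.integers(0, 4, size=length))


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """A stop-free CDS of ``n_codons`` codons starting with ATG."""
    body = [SENSE_CODONS[k] for k in rng.integers(0, len(SENSE_CODONS),
                                                  size=n_codons - 1)]
    return "ATG" + "".join(body)


def mutate(seq: str, sub_prob: float, indel_prob: float = 0.0,
           seed: Optional[int] = None,
           rng: Optional[np.random.Generator] = None) -> str:
    """Uniform per-site substitutions plus geometric-length (mean 2) indels.

    Each site is substituted to a uniformly chosen different base with
    probability ``sub_prob``; after each emitted base, with probability
    ``indel_prob`` an insertion or deletion (50/50) of geometric length is
    applied.  Deterministic under a fixed seed.
    """
    gen = _rng(seed, rng)
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        ch = seq[i]
        if sub_prob and ch in BASES and gen.random() < sub_prob:
            alternatives = BASES.replace(ch, "")
            ch = alternatives[gen.integers(0, 3)]
        out.append(ch)
        i += 1
        if indel_prob and gen.random() < indel_prob:
            length = int(gen.geometric(0.5))
            if gen.random() < 0.5:
                out.extend(BASES[k] for k in gen.integers(0, 4, size=length))
            else:
                i += length
    return "".join(out)


def mutate_coding(seq: str, sub_prob: float,
                  rng: np.random.Generator) -> str:
    """Per-site substitutions that never create an in-frame stop codon.

    Substitutions landing on a stop codon are redirected to another base;
    if every alternative creates a stop the site is left unchanged.  Used
    for transcripts that must keep an intact reading frame.
    """
    usable = len(seq) - len(seq) % 3
    out: list[str] = []
    for start in range(0, usable, 3):
        codon = list(seq[start:start + 3])
        for k in range(3):
            if codon[k] in BASES and rng.random() < sub_prob:
                alternatives = [b for b in BASES if b != codon[k]]
                order = rng.permutation(3)
                for t in order:
                    trial = codon.copy()
                    trial[k] = alternatives[int(t)]
                    if "".join(trial) not in STOP_CODONS:
                        codon = trial
                        break
        out.append("".join(codon))
    return "".join(out) + seq[usable:]


# ---------------------------------------------------------------------------
# screen dataset
# ---------------------------------------------------------------------------

SELF_TAXON = "Phelipanche_aegyptiaca"
INGROUP_TAXON = "Mimulus_guttatus"
DONOR_TAXON = "Sisymbrium_irio"
SECOND_OUTGROUP_TAXON = "Arabidopsis_thaliana"
TAXON_PREFIXES = {
    "Mgu|": INGROUP_TAXON,
    "Sir|": DONOR_TAXON,
    "Ath|": SECOND_OUTGROUP_TAXON,
}


def default_partition() -> TaxonomyPartition:
    return TaxonomyPartition(
        classes={
            SELF_TAXON: "self",
            INGROUP_TAXON: "ingroup",
            DONOR_TAXON: "outgroup",
            SECOND_OUTGROUP_TAXON: "outgroup",
        },
        closest_relative=INGROUP_TAXON,
    )


@dataclass
class ScreenDataset:
    """In-memory screen inputs plus the ground-truth manifest."""

    transcripts: list[SequenceRecord]
    stage_table: StageExpressionTable
    protein_hits: list[AlignmentHit]
    nt_hits: list[AlignmentHit]
    taxon_map: dict[str, str]
    partition: TaxonomyPartition
    manifest: dict


def make_screen_dataset(config: SimulationConfig) -> ScreenDataset:
    """Generate transcripts, expression, similarity evidence and manifest.

    Each transcript belongs to its own gene family.  Per family an ingroup
    reference CDS is drawn; a donor reference is the ingroup reference
    mutated at ``sub_prob_donor``, and a second-outgroup reference at
    ``sub_prob_second_outgroup``.  Hit tables come from the built-in
    aligner at both protein and nucleotide level, reported above
    ``min_report_bits``.
    """
    rng = np.random.default_rng(config.seed)
    classes = (
        ["native"] * config.n_native
        + ["foreign"] * config.n_foreign
        + ["contaminant"] * config.n_contaminant
    )
    order = rng.permutation(len(classes))
    assigned = [classes[int(k)] for k in order]

    lo, hi = config.gene_len_range
    prot_scheme = ScoringScheme.protein()
    nt_scheme = ScoringScheme.nucleotide()

    transcripts: list[SequenceRecord] = []
    protein_refs: list[SequenceRecord] = []
    nt_refs: list[SequenceRecord] = []
    manifest_transcripts: dict[str, dict] = {}

    for fam, cls in enumerate(assigned):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        ingroup_ref = random_coding_sequence(n_codons, rng)
        donor_ref = mutate_coding(ingroup_ref, config.sub_prob_donor, rng)
        second_ref = mutate_coding(donor_ref, config.sub_prob_second_outgroup, rng)
        if cls == "native":
            seq = mutate_coding(ingroup_ref, config.sub_prob_ingroup, rng)
        elif cls == "foreign":
            seq = mutate_coding(donor_ref, config.sub_prob_foreign_vs_donor, rng)
        else:  # contaminant: essentially the host's (donor-like) transcript
            seq = mutate_coding(donor_ref, config.sub_prob_host, rng)
        tid = f"contig_{fam + 1:04d}"
        transcripts.append(SequenceRecord(tid, seq))
        manifest_transcripts[tid] = {"class": cls, "family": fam}
        for prefix, ref in (("Mgu|", ingroup_ref), ("Sir|", donor_ref),
                            ("Ath|", second_ref)):
            sid = f"{prefix}fam{fam:03d}"
            nt_refs.append(SequenceRecord(sid, ref))
            protein_refs.append(SequenceRecord(sid, translate(ref), "peptide"))

    # score-only prefilter: retrieve full alignments only for reportable hits
    prot_aligner = _make_aligner(prot_scheme)
    nt_aligner = _make_aligner(nt_scheme)
    protein_hits: list[AlignmentHit] = []
    nt_hits: list[AlignmentHit] = []
    for rec in transcripts:
        query_pep = SequenceRecord(rec.id, translate(rec.sequence), "peptide")
        for ref in protein_refs:
            raw = prot_aligner.score(query_pep.sequence, ref.sequence)
            if raw <= 0 or prot_scheme.bits(raw) < config.min_report_bits:
                continue
            hit = local_align(query_pep, ref, prot_scheme)
            protein_hits.append(dataclasses.replace(
                hit, subject_taxon=TAXON_PREFIXES[ref.id[:4]],
            ))
        for ref in nt_refs:
            raw = nt_aligner.score(rec.sequence, ref.sequence)
            if raw <= 0 or nt_scheme.bits(raw) < config.min_report_bits:
                continue
            hit = local_align(rec, ref, nt_scheme)
            nt_hits.append(dataclasses.replace(
                hit, subject_taxon=TAXON_PREFIXES[ref.id[:4]],
            ))

    stages = list(config.stage_labels)
    pre = set(config.pre_attachment)
    post = [s for s in stages if s not in pre]
    rows = {}
    for rec in transcripts:
        cls = manifest_transcripts[rec.id]["class"]
        if cls == "contaminant":
            row = {s: 0.0 for s in pre}
            row.update({s: float(np.round(rng.uniform(5, 50), 3)) for s in post})
        else:
            row = {s: float(np.round(rng.uniform(1, 20), 3)) for s in stages}
        rows[rec.id] = [row[s] for s in stages]
    stage_df = pd.DataFrame.from_dict(rows, orient="index", columns=stages)
    stage_df.index.name = "transcript_id"
    stage_table = StageExpressionTable(stage_df, config.pre_attachment)

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "pre_attachment": sorted(pre),
        "transcripts": manifest_transcripts,
        "foreign_ids": sorted(
            t for t, info in manifest_transcripts.items()
            if info["class"] == "foreign"
        ),
        "partition": {
            "classes": dict(default_partition().classes),
            "closest_relative": INGROUP_TAXON,
        },
    }
    return ScreenDataset(
        transcripts=transcripts,
        stage_table=stage_table,
        protein_hits=protein_hits,
        nt_hits=nt_hits,
        taxon_map=dict(TAXON_PREFIXES),
        partition=default_partition(),
        manifest=manifest,
    )


def write_screen_dataset(dataset: ScreenDataset, outdir: str | Path) -> None:
    """Write the dataset in the same formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = dataset.manifest["config_hash"]
    write_fasta(dataset.transcripts, outdir / "transcripts.fasta")
    dataset.stage_table.to_tsv(outdir / "stages.tsv",
                               header_comment=f"config_hash={chash}")
    write_hit_table(dataset.protein_hits, outdir / "protein_hits.tsv")
    write_hit_table(dataset.nt_hits, outdir / "nt_hits.tsv")
    with open(outdir / "taxon_map.tsv", "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        for prefix in sorted(dataset.taxon_map):
            fh.write(f"{prefix}\t{dataset.taxon_map[prefix]}\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(dataset.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# planted TE structures
# ---------------------------------------------------------------------------

def _random_tir(tir_len: int, rng: np.random.Generator) -> str:
    while True:
        tir = random_nucleotides(tir_len, rng)
        if composition_ok(tir):
            return tir


def plant_te(background: str, te_params: TeParams, position: int,
             seed: Optional[int] = None,
             rng: Optional[np.random.Generator] = None) -> tuple[str, dict]:
    """Insert a TSD-TIR-interior-TIR-TSD structure into a background.

    Returns the modified sequence and a manifest entry with the exact
    0-based coordinates of all five segments plus any applied lesion.
    """
    gen = _rng(seed, rng)
    if not 0 <= position <= len(background):
        raise ConfigurationError("insertion position outside the background")
    tsd = te_params.tsd or random_nucleotides(te_params.tsd_len, gen)
    if "N" in tsd:
        raise ConfigurationError("TSD must be N-free to be detectable")
    tir = te_params.tir or _random_tir(te_params.tir_len, gen)
    if len(tir) != te_params.tir_len:
        raise ConfigurationError("tir and tir_len disagree")
    if not composition_ok(tir):
        raise ConfigurationError(
            "planted TIR fails the two-nucleotide composition filter and "
            "would be undetectable by design"
        )
    interior = random_nucleotides(te_params.interior_len, gen)

    left_tir = tir
    right_tsd = tsd
    if te_params.lesion == "outer_tir_base":
        alternatives = [b for b in BASES if b != tir[0]]
        gen.shuffle(alternatives)
        for alt in alternatives:
            mutated = alt + tir[1:]
            if composition_ok(mutated):
                left_tir = mutated
                break
    elif te_params.lesion == "tsd_mismatch":
        pos = int(gen.integers(0, len(tsd)))
        alternatives = [b for b in BASES if b != tsd[pos]]
        right_tsd = tsd[:pos] + alternatives[int(gen.integers(0, 3))] + tsd[pos + 1:]

    insert = tsd + left_tir + interior + reverse_complement(tir) + right_tsd
    seq = background[:position] + insert + background[position:]
    L = te_params.tir_len
    entry = {
        "tsd_seq": tsd,
        "tir_seq": tir,
        "lesion": te_params.lesion,
        "tir_len": L,
        "interior_len": te_params.interior_len,
        "left_tsd_start": position,
        "left_tir_start": position + len(tsd),
        "interior_start": position + len(tsd) + L,
        "right_tir_start": position + len(tsd) + L + te_params.interior_len,
        "right_tsd_start": position + len(tsd) + 2 * L + te_params.interior_len,
    }
    return seq, entry


# ---------------------------------------------------------------------------
# planted coding lesions
# ---------------------------------------------------------------------------

def plant_lesions(reference_cds: str,
                  n_stops: int,
                  n_frameshifts: int,
                  rng: np.random.Generator,
                  min_spacing_nt: int = 18) -> tuple[str, list[dict]]:
    """Plant premature stops and frameshift indels into a copy of a CDS.

    Returns the lesioned candidate and manifest entries carrying the
    positions the assessment is expected to report (0-based reference codon
    index for stops; 1-based candidate nucleotide offset for frameshifts).
    Lesion sites are spaced apart and placed in locally non-repetitive
    context so the alignment-reported coordinates are unambiguous.
    """
    n_codons = len(reference_cds) // 3
    if len(reference_cds) % 3:
        raise ConfigurationError("reference CDS must be a codon multiple")
    # keep lesions clear of the ends: an indel within a few codons of a free
    # end would be absorbed into the end gap instead of scored internally
    span = range(4, n_codons - 4)
    needed = n_stops + n_frameshifts
    if needed * (min_spacing_nt // 3 + 1) > len(span):
        raise ConfigurationError("CDS too short for the requested lesions")

    sites: list[int] = []  # codon indices
    attempts = 0
    while len(sites) < needed:
        attempts += 1
        if attempts > 10000:
            raise ConfigurationError("could not place lesions with spacing")
        c = int(rng.integers(span.start, span.stop))
        if all(abs(3 * c - 3 * s) >= min_spacing_nt for s in sites):
            sites.append(c)
    sites.sort()
    kinds = ["premature_stop"] * n_stops + ["frameshift_indel"] * n_frameshifts
    kinds = [kinds[int(k)] for k in rng.permutation(needed)]

    stops = sorted(s for s, k in zip(sites, kinds) if k == "premature_stop")
    shifts = sorted(s for s, k in zip(sites, kinds) if k == "frameshift_indel")

    seq = list(reference_cds)
    stop_choices = sorted(STOP_CODONS)
    for c in stops:
        original = reference_cds[3 * c:3 * c + 3]
        # nearest stop codon: fewest substitutions, rng tie-break
        distances = [
            sum(a != b for a, b in zip(original, stop)) for stop in stop_choices
        ]
        best = min(distances)
        options = [s for s, d in zip(stop_choices, distances) if d == best]
        seq[3 * c:3 * c + 3] = list(options[int(rng.integers(0, len(options)))])
    mutated = "".join(seq)

    # apply indels left to right, tracking the candidate coordinate
    out: list[str] = []
    expected: list[dict] = []
    cursor = 0  # reference position consumed so far
    for c in stops:
        expected.append({"kind": "premature_stop", "position": c})
    for c in shifts:
        base = 3 * c  # reference nt position of the edit window
        length = int([1, 2, 4][int(rng.integers(0, 3))])
        deletion = bool(rng.integers(0, 2))
        if deletion:
            # place the deletion where repetitive context cannot slide the
            # alignment gap; scan nearby offsets and alternative lengths
            placed = None
            for trial_len in (length, 1, 2, 4):
                for off in range(0, 9):
                    p = base + off
                    if (
                        p >= 1 and p + trial_len < len(mutated)
                        and mutated[p - 1] != mutated[p + trial_len - 1]
                        and mutated[p] != mutated[p + trial_len]
                    ):
                        placed = (p, trial_len)
                        break
                if placed:
                    break
            if placed is None:
                raise ConfigurationError(
                    "could not place an unambiguous deletion"
                )
            p, length = placed
            out.append(mutated[cursor:p])
            cand_pos = sum(len(s) for s in out)
            expected.append({
                "kind": "frameshift_indel",
                "position": cand_pos + 1,
                "indel_len": length,
            })
            cursor = p + length
        else:
            p = base
            ins = None
            for _ in range(100):
                trial = random_nucleotides(length, rng)
                if trial[0] != mutated[p] and trial[-1] != mutated[p - 1]:
                    ins = trial
                    break
            if ins is None:
                raise ConfigurationError("could not draw unambiguous insertion")
            out.append(mutated[cursor:p])
            cand_pos = sum(len(s) for s in out)
            expected.append({
                "kind": "frameshift_indel",
                "position": cand_pos + 1,
                "indel_len": length,
            })
            out.append(ins)
            cursor = p
    out.append(mutated[cursor:])
    candidate = "".join(out)
    expected.sort(key=lambda e: (
        e["position"] * 3 if e["kind"] == "premature_stop" else e["position"]
    ))
    return candidate, expected


# ---------------------------------------------------------------------------
# synteny tables
# ---------------------------------------------------------------------------

def make_synteny_tables(reference: GeneOrderTable,
                        edits: Mapping[str, Sequence[tuple]],
                        seed: Optional[int] = None) -> tuple[list[GeneOrderTable], dict]:
    """Derive per-species gene-order tables from a reference by edit lists.

    Edit ops: ("delete", label), ("flip", label), ("reverse_block",).
    Labels must exist in the reference.  Returns the tables (sorted by
    species) and a manifest of the applied edits.
    """
    labels = {e.anchor for e in reference.entries if e.anchor is not None}
    tables: list[GeneOrderTable] = []
    manifest: dict = {"reference": reference.species, "edits": {}}
    for species in sorted(edits):
        entries = [
            GeneOrderEntry(f"{species}:{e.locus_id}", e.anchor, e.strand)
            for e in reference.entries
        ]
        for op in edits[species]:
            kind = op[0]
            if kind in ("delete", "flip"):
                label = op[1]
                if label not in labels:
                    raise ConfigurationError(
                        f"edit for {species!r} names absent anchor {label!r}"
                    )
                idx = next(
                    (i for i, e in enumerate(entries) if e.anchor == label), None
                )
                if idx is None:
                    raise ConfigurationError(
                        f"edit for {species!r}: label {label!r} already removed"
                    )
                if kind == "delete":
                    del entries[idx]
                else:
                    e = entries[idx]
                    entries[idx] = GeneOrderEntry(
                        e.locus_id, e.anchor, "-" if e.strand == "+" else "+"
                    )
            elif kind == "reverse_block":
                entries = [
                    GeneOrderEntry(e.locus_id, e.anchor,
                                   "-" if e.strand == "+" else "+")
                    for e in reversed(entries)
                ]
            else:
                raise ConfigurationError(f"unknown synteny edit {kind!r}")
        tables.append(GeneOrderTable(species, tuple(entries)))
        manifest["edits"][species] = [list(op) for op in edits[species]]
    return tables, manifest
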