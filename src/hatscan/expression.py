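"""Expression summarization: FPKM, reference normalization, comparative Ct.

FPKM (fragments per kilobase of transcript per million mapped fragments) is
computed from raw fragment counts.  For RNA-seq the reference level is the
sum of the usable reference-gene isoforms (e.g. the actin isoforms that
carry the qPCR primer sites); relative expression is the plain FPKM ratio.
For qPCR the comparative Ct method is applied on Ct means within a
condition: expression relative to the reference gene is 2^-(Ct_target -
Ct_reference).  No calibrator condition is baked in; cross-condition ratios
are computed by dividing within-condition values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError, UndefinedRatioError


@dataclass(frozen=True)
class ExpressionMeasurement:
    gene_id: str
    condition: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError("FPKM must be nonnegative")


@dataclass(frozen=True)
class QpcrRecord:
    gene_id: str
    condition: str
    ct_mean: float
    ct_se: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.ct_mean <= 0:
            raise ValueError("Ct mean must be positive")
        if self.ct_se < 0 or self.n_replicates < 1:
            raise ValueError("invalid qPCR record")


def fpkm(fragments: float, effective_length_bp: int,
         total_mapped_fragments: int) -> float:
    """fragments * 1e9 / (length * library size).

    Effective length defaults to the annotated transcript length upstream;
    no fragment-length correction is applied here.
    """
    if effective_length_bp < 1:
        raise UndefinedRatioError("effective length must be >= 1 bp")
    if total_mapped_fragments < 1:
        raise UndefinedRatioError("library size must be >= 1 fragment")
    return fragments * 1e9 / (effective_length_bp * total_mapped_fragments)


def reference_level(isoform_fpkms: Sequence[float],
                    usable: Sequence[bool]) -> float:
    """Sum of the usable reference-gene isoform FPKMs."""
    if len(isoform_fpkms) != len(usable):
        raise ConfigurationError("usable mask length must match the isoform list")
    if not any(usable):
        raise ConfigurationError("no usable reference isoform")
    total = sum(f for f, ok in zip(isoform_fpkms, usable) if ok)
    if total == 0.0:
        warnings.warn(
            "usable reference isoforms sum to zero FPKM; downstream ratios "
            "are undefined",
            stacklevel=2,
        )
    return total


def relative_level(gene_fpkm: float, reference_fpkm: float) -> float:
    """Expression of a gene relative to the reference, as an FPKM ratio."""
    if reference_fpkm <= 0:
        raise UndefinedRatioError("reference FPKM must be positive")
    return gene_fpkm / reference_fpkm


def comparative_ct(ct_target: float, ct_reference: float) -> float:
    """Comparative Ct relative expression: 2^-(Ct_target - Ct_reference)."""
    return 2.0 ** (-(ct_target - ct_reference))


def fpkm_table(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Tidy FPKM table from a count table.

    ``counts`` columns: gene_id, condition, fragments, length_bp.
    ``library_sizes`` maps condition -> total mapped fragments.
    """
    required = {"gene_id", "condition", "fragments", "length_bp"}
    missing = required - set(counts.columns)
    if missing:
        raise ConfigurationError(f"count table is missing columns {sorted(missing)}")
    rows = []
    for rec in counts.itertuples(index=False):
        if rec.condition not in library_sizes.index:
            raise ConfigurationError(
                f"no library size for condition {rec.condition!r}"
            )
        rows.append({
            "gene_id": rec.gene_id,
            "condition": rec.condition,
            "fpkm": fpkm(rec.fragments, int(rec.length_bp),
                         int(library_sizes[rec.condition])),
        })
    return pd.DataFrame(rows, columns=["gene_id", "condition", "fpkm"])


def read_qpcr_table(path: str | Path) -> list[QpcrRecord]:
    """qPCR TSV: gene_id, condition, ct_mean, ct_se, n_replicates."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        QpcrRecord(r.gene_id, r.condition, float(r.ct_mean),
                   float(r.ct_se), int(r.n_replicates))
        for r in df.itertuples(index=False)
    ]


def qpcr_relative_table(records: Sequence[QpcrRecord],
                        reference_gene: str) -> pd.DataFrame:
    """Within-condition relative expression of every gene vs the reference.

    Ct standard errors are passed through unchanged (no error propagation).
    """
    ref_ct = {
        r.condition: r.ct_mean for r in records if r.gene_id == reference_gene
    }
    rows = []
    for r in records:
        if r.gene_id == reference_gene:
            continue
        if r.condition not in ref_ct:
            raise ConfigurationError(
                f"reference gene {reference_gene!r} has no Ct in condition "
                f"{r.condition!r}"
            )
        rows.append({
            "gene_id": r.gene_id,
            "condition": r.condition,
            "relative_expression": comparative_ct(r.ct_mean, ref_ct[r.condition]),
            "ct_mean": r.ct_mean,
            "ct_se": r.ct_se,
            "n_replicates": r.n_replicates,
        })
    return pd.DataFrame(rows)
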