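"""The foreign-gene screen: filters, alien ratio, donor call, recovery."""
import math
import random

import numpy as np
import pandas as pd
import pytest

from hatscan.errors import ConfigurationError, FormatError
from hatscan.hgt_screen import (
    ScreenConfig, StageExpressionTable, TaxonomyPartition,
    assign_putative_donor, compute_alien_ratio, filter_pre_attachment,
    nt_relative_filter, run_screen,
)
from hatscan.similarity import AlignmentHit

STAGES = ["0G", "2G", "3G", "4.1G"]
PARTITION = TaxonomyPartition(
    classes={
        "Phelipanche_aegyptiaca": "self",
        "Mimulus_guttatus": "ingroup",
        "Sisymbrium_irio": "outgroup",
        "Brassica_rapa": "outgroup",
        "Arabidopsis_thaliana": "outgroup",
    },
    closest_relative="Mimulus_guttatus",
)


def _table(rows):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=STAGES)
    return StageExpressionTable(df, ["0G", "2G"])


def _hit(taxon, bits, query="t1", subject=None, evalue=None):
    return AlignmentHit(query, subject or f"{taxon}|x", taxon, 80.0, 100,
                        bits, evalue, 1, 100, 1, 100)


class TestStageFilter:
    def test_pre_attachment_expression_is_retained(self):
        table = _table({"t1": [5.0, 0, 0, 0]})
        assert filter_pre_attachment(table) == {"t1"}

    def test_post_attachment_only_is_excluded_as_contamination(self):
        table = _table({"t1": [0, 0, 0, 30.0]})
        assert filter_pre_attachment(table) == set()

    def test_all_zero_is_excluded(self):
        table = _table({"t1": [0, 0, 0, 0]})
        assert filter_pre_attachment(table) == set()

    def test_min_abundance_is_strict(self):
        table = _table({"t1": [1.0, 0, 0, 0]})
        assert filter_pre_attachment(table, min_abundance=1.0) == set()

    def test_unknown_pre_attachment_stage_is_configuration_error(self):
        df = pd.DataFrame.from_dict({"t1": [1.0]}, orient="index",
                                    columns=["0G"])
        with pytest.raises(ConfigurationError):
            StageExpressionTable(df, ["0G", "9G"])


class TestAlienRatio:
    def test_ratio_above_threshold_is_candidate(self):
        v = compute_alien_ratio(
            [_hit("Sisymbrium_irio", 240), _hit("Mimulus_guttatus", 180)],
            PARTITION,
        )
        assert v.ratio == pytest.approx(240 / 180)
        assert v.candidate

    def test_ratio_exactly_at_threshold_is_not_candidate(self):
        v = compute_alien_ratio(
            [_hit("Sisymbrium_irio", 120), _hit("Mimulus_guttatus", 100)],
            PARTITION,
        )
        assert v.ratio == pytest.approx(1.2)
        assert not v.candidate

    def test_outgroup_only_is_flagged_candidate_with_infinite_ratio(self):
        v = compute_alien_ratio([_hit("Sisymbrium_irio", 50)], PARTITION)
        assert v.ratio == math.inf
        assert v.candidate
        assert "no_ingroup_hit" in v.flags

    def test_no_outgroup_hit_is_never_candidate(self):
        v = compute_alien_ratio([_hit("Mimulus_guttatus", 500)], PARTITION)
        assert not v.candidate
        assert "no_outgroup_hit" in v.flags

    def test_self_hits_never_enter_scoring(self):
        v = compute_alien_ratio(
            [_hit("Phelipanche_aegyptiaca", 9000),
             _hit("Sisymbrium_irio", 150), _hit("Mimulus_guttatus", 100)],
            PARTITION,
        )
        assert v.ratio == pytest.approx(1.5)
        assert v.candidate

    def test_mixed_query_ids_raise(self):
        with pytest.raises(FormatError):
            compute_alien_ratio(
                [_hit("Sisymbrium_irio", 100, query="a"),
                 _hit("Mimulus_guttatus", 100, query="b")],
                PARTITION,
            )

    def test_unmapped_taxon_raises(self):
        with pytest.raises(ConfigurationError):
            compute_alien_ratio([_hit("Unknownia", 100)], PARTITION)


class TestNtRelativeFilter:
    def test_best_nt_hit_to_relative_filters(self):
        hits = [_hit("Mimulus_guttatus", 300), _hit("Arabidopsis_thaliana", 200)]
        assert nt_relative_filter(hits, PARTITION) is True

    def test_best_nt_hit_elsewhere_passes(self):
        hits = [_hit("Arabidopsis_thaliana", 300), _hit("Mimulus_guttatus", 200)]
        assert nt_relative_filter(hits, PARTITION) is False

    def test_no_nt_hits_passes(self):
        assert nt_relative_filter([], PARTITION) is False


class TestDonorAssignment:
    def test_best_outgroup_taxon_wins(self):
        hits = [_hit("Sisymbrium_irio", 850), _hit("Brassica_rapa", 800)]
        assert assign_putative_donor(hits, PARTITION) == "Sisymbrium_irio"

    def test_ingroup_only_gives_none(self):
        assert assign_putative_donor([_hit("Mimulus_guttatus", 900)],
                                     PARTITION) is None

    def test_equal_scores_break_by_evalue_then_taxon(self):
        hits = [_hit("Sisymbrium_irio", 800, evalue=1e-40),
                _hit("Brassica_rapa", 800, evalue=1e-50)]
        assert assign_putative_donor(hits, PARTITION) == "Brassica_rapa"
        tied = [_hit("Sisymbrium_irio", 800, subject="A", evalue=1e-40),
                _hit("Brassica_rapa", 800, subject="B", evalue=1e-40)]
        assert assign_putative_donor(tied, PARTITION) == "Sisymbrium_irio"


class TestRunScreen:
    def test_exact_recovery_of_planted_foreign_genes(self, screen_dataset):
        ds = screen_dataset
        verdicts = run_screen(ds.transcripts, ds.stage_table,
                              ds.protein_hits, ds.nt_hits, ds.partition)
        candidates = {v.transcript_id for v in verdicts if v.candidate}
        assert candidates == set(ds.manifest["foreign_ids"])

    def test_contaminants_are_stage_filtered(self, screen_dataset):
        ds = screen_dataset
        verdicts = {
            v.transcript_id: v
            for v in run_screen(ds.transcripts, ds.stage_table,
                                ds.protein_hits, ds.nt_hits, ds.partition)
        }
        for tid, info in ds.manifest["transcripts"].items():
            if info["class"] == "contaminant":
                assert "stage_filtered" in verdicts[tid].flags

    def test_foreign_donor_is_the_simulated_donor_taxon(self, screen_dataset):
        ds = screen_dataset
        verdicts = {
            v.transcript_id: v
            for v in run_screen(ds.transcripts, ds.stage_table,
                                ds.protein_hits, ds.nt_hits, ds.partition)
        }
        for tid in ds.manifest["foreign_ids"]:
            assert verdicts[tid].putative_donor == "Sisymbrium_irio"

    def test_raising_threshold_never_adds_candidates(self, screen_dataset):
        ds = screen_dataset
        previous = None
        for threshold in (1.0, 1.2, 1.5, 2.0):
            verdicts = run_screen(ds.transcripts, ds.stage_table,
                                  ds.protein_hits, ds.nt_hits, ds.partition,
                                  ScreenConfig(threshold=threshold))
            current = {v.transcript_id for v in verdicts if v.candidate}
            if previous is not None:
                assert current <= previous
            previous = current

    def test_permutation_invariance(self, screen_dataset):
        ds = screen_dataset
        baseline = run_screen(ds.transcripts, ds.stage_table,
                              ds.protein_hits, ds.nt_hits, ds.partition)
        gen = random.Random(1)
        transcripts = list(ds.transcripts)
        protein = list(ds.protein_hits)
        nt = list(ds.nt_hits)
        gen.shuffle(transcripts)
        gen.shuffle(protein)
        gen.shuffle(nt)
        shuffled = run_screen(transcripts, ds.stage_table, protein, nt,
                              ds.partition)
        assert shuffled == baseline

    def test_bitscore_scaling_leaves_verdicts_unchanged(self, screen_dataset):
        import dataclasses

        ds = screen_dataset
        factor = 3.7
        scale = lambda hits: [
            dataclasses.replace(h, bitscore=h.bitscore * factor) for h in hits
        ]
        baseline = run_screen(ds.transcripts, ds.stage_table,
                              ds.protein_hits, ds.nt_hits, ds.partition)
        scaled = run_screen(ds.transcripts, ds.stage_table,
                            scale(ds.protein_hits), scale(ds.nt_hits),
                            ds.partition)
        for b, s in zip(baseline, scaled):
            assert (b.transcript_id, b.candidate, b.flags) == (
                s.transcript_id, s.candidate, s.flags
            )
            if b.ratio not in (None, math.inf):
                assert s.ratio == pytest.approx(b.ratio)

    def test_short_orf_transcript_is_length_filtered(self):
        # 90-aa stop-free gene: passes expression, fails the >100 aa filter
        from hatscan.synthetic_data import random_coding_sequence
        from hatscan.sequence_core import SequenceRecord

        gen = np.random.default_rng(8)
        rec = SequenceRecord("t1", random_coding_sequence(90, gen))
        table = _table({"t1": [5.0, 0, 0, 0]})
        hits = [_hit("Sisymbrium_irio", 500), _hit("Mimulus_guttatus", 100)]
        verdicts = run_screen([rec], table, hits, [], PARTITION)
        assert not verdicts[0].candidate
        assert "length_filtered" in verdicts[0].flags
        assert verdicts[0].ratio == pytest.approx(5.0)  # still annotated

    def test_post_attachment_contaminant_is_stage_filtered_despite_ratio(self):
        from hatscan.synthetic_data import random_coding_sequence
        from hatscan.sequence_core import SequenceRecord

        gen = np.random.default_rng(9)
        rec = SequenceRecord("t1", random_coding_sequence(150, gen))
        table = _table({"t1": [0, 0, 0, 30.0]})
        hits = [_hit("Sisymbrium_irio", 500), _hit("Mimulus_guttatus", 100)]
        verdicts = run_screen([rec], table, hits, [], PARTITION)
        assert not verdicts[0].candidate
        assert "stage_filtered" in verdicts[0].flags

    def test_missing_evidence_table_raises_with_name(self, screen_dataset):
        ds = screen_dataset
        with pytest.raises(ConfigurationError, match="protein hit table"):
            run_screen(ds.transcripts, ds.stage_table, None, ds.nt_hits,
                       ds.partition)
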