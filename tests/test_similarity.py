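"""Built-in aligner vs an independent Gotoh DP oracle; hit-table parsing."""
import math
import random

import numpy as np
import pytest

from hatscan.errors import AlphabetError, FormatError
from hatscan.sequence_core import SequenceRecord
from hatscan.similarity import (
    AlignmentHit, ScoringScheme, best_hit, local_align, read_hit_table,
    read_taxon_map, write_hit_table,
)

from conftest import random_dna


def gotoh_local_score(s, t, match, mismatch, gap_open, gap_extend):
    """Independent affine-gap Smith-Waterman score (full DP, no shortcuts).

    Gap convention: opening position costs gap_open, each further position
    gap_extend.
    """
    NEG = float("-inf")
    n, m = len(s), len(t)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s (consumes t)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in t (consumes s)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            sub = match if s[i - 1] == t[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def test_worked_example_raw_score_13():
    scheme = ScoringScheme.nucleotide(match=3, mismatch=-3,
                                      gap_open=-2, gap_extend=-2)
    assert gotoh_local_score("TGTTACGG", "GGTTGACTA", 3, -3, -2, -2) == 13
    hit = local_align(SequenceRecord("a", "TGTTACGG"),
                      SequenceRecord("b", "GGTTGACTA"), scheme)
    assert hit.bitscore == pytest.approx(scheme.bits(13))


@pytest.mark.parametrize("seed", range(15))
def test_local_align_matches_dp_oracle_on_short_pairs(seed):
    gen = np.random.default_rng(seed)
    scheme = ScoringScheme.nucleotide(match=2, mismatch=-3,
                                      gap_open=-4, gap_extend=-1)
    for _ in range(8):
        a = random_dna(int(gen.integers(1, 13)), gen)
        b = random_dna(int(gen.integers(1, 13)), gen)
        expected = gotoh_local_score(a, b, 2, -3, -4, -1)
        hit = local_align(SequenceRecord("a", a), SequenceRecord("b", b), scheme)
        got = 0.0 if hit is None else (hit.bitscore * math.log(2)
                                       + math.log(scheme.K)) / scheme.lambda_
        assert got == pytest.approx(expected, abs=1e-9)


def test_self_alignment_is_fully_identical():
    gen = np.random.default_rng(99)
    seq = random_dna(100, gen)
    scheme = ScoringScheme.nucleotide(match=1, mismatch=-1,
                                      gap_open=-2, gap_extend=-2)
    hit = local_align(SequenceRecord("a", seq), SequenceRecord("b", seq), scheme)
    assert hit.percent_identity == 100.0
    assert hit.alignment_length == 100
    assert hit.bitscore == pytest.approx(scheme.bits(100))


def test_disjoint_alphabets_yield_no_hit():
    scheme = ScoringScheme.nucleotide()
    assert local_align(SequenceRecord("a", "A" * 30),
                       SequenceRecord("b", "C" * 30), scheme) is None


def test_percent_identity_is_symmetric_for_substituted_pairs():
    gen = np.random.default_rng(5)
    scheme = ScoringScheme.nucleotide()
    for _ in range(5):
        a = random_dna(60, gen)
        b = "".join(
            ("ACGT".replace(c, "")[gen.integers(0, 3)]
             if gen.random() < 0.1 else c)
            for c in a
        )
        h1 = local_align(SequenceRecord("a", a), SequenceRecord("b", b), scheme)
        h2 = local_align(SequenceRecord("b", b), SequenceRecord("a", a), scheme)
        assert h1.percent_identity == pytest.approx(h2.percent_identity)


def test_alphabet_mismatch_raises():
    scheme = ScoringScheme.protein()
    with pytest.raises(AlphabetError):
        local_align(SequenceRecord("a", "ACGT"),
                    SequenceRecord("b", "MKV", "peptide"), scheme)
    with pytest.raises(AlphabetError):
        local_align(SequenceRecord("a", "ACGT"),
                    SequenceRecord("b", "ACGT"), scheme)


def test_read_hit_table_parses_and_maps_taxa(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "q1\tATH|AT3G17260\t83.0\t373\t60\t2\t1\t373\t5\t377\t1e-150\t240\n"
    )
    hits = read_hit_table(path, {"ATH": "Arabidopsis_thaliana"})
    assert len(hits) == 1
    hit = hits[0]
    assert hit.subject_taxon == "Arabidopsis_thaliana"
    assert hit.bitscore == 240.0
    assert hit.percent_identity == 83.0
    assert hit.evalue == 1e-150


def test_read_hit_table_empty_file(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    assert read_hit_table(path, {}) == []


def test_read_hit_table_rejects_malformed_row_with_number(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "q1\ts1\t90\t100\t10\t0\t1\t100\t1\t100\t1e-5\t200\n"
        "q2\ts1\t90\t100\t10\t0\t1\t100\t1\t100\t1e-5\n"  # 11 columns
    )
    with pytest.raises(FormatError, match="row 2"):
        read_hit_table(path, {"s": "x"})


def test_unmapped_subject_behavior(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("q1\tZZZ|1\t90\t100\t10\t0\t1\t100\t1\t100\t1e-5\t200\n")
    with pytest.raises(FormatError):
        read_hit_table(path, {"ATH": "x"})
    hits = read_hit_table(path, {"ATH": "x"}, on_unmapped="unknown")
    assert hits[0].subject_taxon == "unknown"


def test_hit_table_roundtrip(tmp_path):
    hits = [
        AlignmentHit("q", "Mgu|1", "M", 91.5, 120, 222.5, 1e-60, 1, 120, 3, 122),
        AlignmentHit("q", "Sir|1", "S", 75.0, 110, 180.0, 1e-40, 1, 110, 1, 110),
    ]
    path = tmp_path / "x.tsv"
    write_hit_table(hits, path)
    back = read_hit_table(path, {"Mgu": "M", "Sir": "S"})
    assert [(h.subject_id, h.bitscore) for h in back] == [
        ("Mgu|1", 222.5), ("Sir|1", 180.0)
    ]


def _hit(subject, taxon, bits, evalue=None):
    return AlignmentHit("q", subject, taxon, 90.0, 100, bits, evalue,
                        1, 100, 1, 100)


def test_best_hit_max_bitscore_and_restriction():
    hits = [_hit("s1", "A", 240.0), _hit("s2", "B", 180.0)]
    assert best_hit(hits, {"A", "B"}).subject_id == "s1"
    assert best_hit(hits, {"B"}).subject_id == "s2"
    assert best_hit(hits, {"C"}) is None
    assert best_hit([]) is None


def test_best_hit_tie_breaks_on_evalue_then_subject_id():
    hits = [_hit("s2", "A", 200.0, 1e-40), _hit("s1", "A", 200.0, 1e-50)]
    assert best_hit(hits).subject_id == "s1"
    tied = [_hit("s2", "A", 200.0, 1e-40), _hit("s1", "A", 200.0, 1e-40)]
    assert best_hit(tied).subject_id == "s1"


def test_best_hit_is_permutation_invariant():
    gen = random.Random(0)
    hits = [_hit(f"s{i}", "A", 100.0 + (i % 7), 10.0 ** -i) for i in range(12)]
    reference = best_hit(hits)
    for _ in range(10):
        gen.shuffle(hits)
        assert best_hit(hits) == reference


def test_taxon_map_reader(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text("# comment\nMgu|\tMimulus_guttatus\nSir|\tSisymbrium_irio\n")
    assert read_taxon_map(path) == {
        "Mgu|": "Mimulus_guttatus", "Sir|": "Sisymbrium_irio",
    }
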