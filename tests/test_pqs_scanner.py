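"""Scanner unit and property tests: G-runs, enumeration vs brute force,
scoring monotonicity, best-parse tie-breaks, non-overlap selection and
window streaming."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4lnc.core_io import TranscriptRecord
from g4lnc.pqs_scanner import (
    QgrsCandidate,
    ScanParams,
    best_parse,
    canonical_motif_check,
    enumerate_qgrs,
    find_g_runs,
    scan_transcript,
    score_qgrs,
)
from g4lnc.reference import REFERENCE_OLIGOS

from _oracle import oracle_best, oracle_candidates, oracle_select
from conftest import random_sequence

TERRA = "GGGTTAGGGTTAGGGTTAGGG"


class TestGRuns:
    @pytest.mark.parametrize("seq,expected", [
        ("GGG", [(0, 3)]),
        ("AAAA", []),
        (TERRA, [(0, 3), (6, 3), (12, 3), (18, 3)]),
        ("GGGGG", [(0, 5)]),
        ("AGGGA" + "G" * 4, [(1, 3), (5, 4)]),
    ])
    def test_maximal_runs(self, seq, expected):
        assert [(r.start, r.length) for r in find_g_runs(seq, 3)] == expected


class TestEnumeration:
    def test_single_candidate_geometry(self, paper_params):
        cands = enumerate_qgrs("GGGAGGGAGGGAGGG", paper_params)
        assert len(cands) == 1
        c = cands[0]
        assert c.tetrad_size == 3 and c.loops == (1, 1, 1)
        assert c.span_length == 15

    def test_two_runs_only_is_empty(self, paper_params):
        assert enumerate_qgrs("GGGTTAGGG", paper_params) == []

    def test_terra_matches_brute_force(self, paper_params):
        got = {(c.group_starts, c.tetrad_size) for c in
               enumerate_qgrs(TERRA, paper_params)}
        want = {(starts, t) for starts, t, *_ in
                oracle_candidates(TERRA, paper_params)}
        assert got == want

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), length=st.integers(12, 60))
    def test_enumeration_matches_brute_force(self, seed, length,
                                             paper_params):
        """The candidate set equals an independent exhaustive search."""
        seq = random_sequence(np.random.default_rng(seed), length)
        got = {(c.group_starts, c.tetrad_size, c.loops, c.span_length,
                c.g_score) for c in enumerate_qgrs(seq, paper_params)}
        assert got == set(oracle_candidates(seq, paper_params))


class TestScoring:
    def test_terra_best_score_is_published_value(self, paper_params):
        assert best_parse(TERRA, paper_params).g_score == 72

    def test_score_is_pure(self, paper_params):
        c = best_parse(TERRA, paper_params)
        assert all(score_qgrs(c, paper_params) == c.g_score
                   for _ in range(5))

    def test_extending_a_longest_loop_never_scores_higher(self,
                                                          paper_params):
        """Lengthening a loop that is already (one of) the longest can only
        hurt — checked exhaustively over all loop triples <= 14."""
        lo, hi = paper_params.loop_min, paper_params.loop_max
        for l1 in range(lo, hi + 1):
            for l2 in range(lo, hi + 1):
                for l3 in range(lo, hi):
                    if l3 < max(l1, l2):
                        continue  # extending a non-longest loop may equalize
                    c0 = _candidate(3, (l1, l2, l3))
                    c1 = _candidate(3, (l1, l2, l3 + 1))
                    assert score_qgrs(c1, paper_params) <= \
                        score_qgrs(c0, paper_params)

    def test_more_tetrads_dominate_loop_penalty(self, paper_params):
        worst = _candidate(4, (1, 14, 1))
        best3 = _candidate(3, (1, 1, 1))
        assert score_qgrs(worst, paper_params) > \
            score_qgrs(best3, paper_params)


def _candidate(t: int, loops: tuple[int, int, int]) -> QgrsCandidate:
    s1 = 0
    s2 = s1 + t + loops[0]
    s3 = s2 + t + loops[1]
    s4 = s3 + t + loops[2]
    from g4lnc.pqs_scanner import _score
    return QgrsCandidate((s1, s2, s3, s4), t, loops, s4 + t - s1,
                         _score(t, loops))


class TestBestParse:
    def test_no_parse_is_none(self, paper_params):
        assert best_parse("ACGTACGT", paper_params) is None

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), length=st.integers(15, 60))
    def test_best_parse_matches_oracle(self, seed, length, paper_params):
        seq = random_sequence(np.random.default_rng(seed), length)
        mine = best_parse(seq, paper_params)
        ref = oracle_best(seq, paper_params)
        if ref is None:
            assert mine is None
        else:
            assert (mine.group_starts, mine.tetrad_size) == (ref[0], ref[1])
            assert mine.g_score == ref[4]


class TestCanonicalMotifCheck:
    def test_terra_passes(self):
        assert canonical_motif_check(TERRA)

    def test_twelve_nt_loop_fails(self):
        # scanner-admissible (loops 1-14) but outside the stricter 1-7 band
        motif = "GGG" + "A" * 12 + "GGGAGGGAGGG"
        assert not canonical_motif_check(motif)

    def test_reference_oligos(self):
        """Five of the six benchmark oligos contain the strict canonical
        pattern; the MEG3 oligo's first inter-tract gap is 12 nt, which
        the 1-7 nt loop bound rejects."""
        verdicts = {name: canonical_motif_check(seq)
                    for name, (seq, _) in REFERENCE_OLIGOS.items()}
        assert verdicts == {"TERRA": True, "SNHG20": True, "MEG3": False,
                            "LINP1": True, "CRNDE R1": True,
                            "CRNDE R2": True}


class TestScanTranscript:
    def _scan(self, seq, params, tid="T1"):
        return scan_transcript(TranscriptRecord(tid, "GENE", seq), params)

    def test_poly_a_transcript_is_empty(self, paper_params):
        assert self._scan("A" * 2000, paper_params) == []

    def test_hits_are_disjoint_and_above_threshold(self, paper_params):
        rng = np.random.default_rng(7)
        seq = random_sequence(rng, 400, g_weight=0.45)
        hits = self._scan(seq, paper_params)
        for h in hits:
            assert h.g_score > paper_params.score_threshold
            assert h.motif == seq[h.start - 1:h.end]
        for a, b in zip(hits, hits[1:]):
            assert a.end < b.start

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), length=st.integers(20, 60))
    def test_selection_matches_oracle(self, seed, length, paper_params):
        seq = random_sequence(np.random.default_rng(seed), length)
        hits = self._scan(seq, paper_params)
        ref = oracle_select(seq, paper_params)
        assert [(h.start - 1, h.end, h.g_score) for h in hits] == \
            [(c[0][0], c[0][3] + c[1], c[4]) for c in ref]

    def test_two_planted_motifs_recovered(self, paper_params):
        seq = TERRA + "A" * 100 + TERRA
        hits = self._scan(seq, paper_params)
        assert [(h.start, h.g_score) for h in hits] == \
            [(1, 72), (122, 72)]

    def test_window_streaming_equals_split_scan(self, paper_params):
        """Scanning a long transcript equals scanning its parts split at a
        hit-free gap >= max_length."""
        left = TERRA + "C" * 30 + "GGGAGGGAGGGAGGG"
        gap = "A" * 60
        right = "GGGCTAGGGCCTGGGCCTCGGG"
        whole = self._scan(left + gap + right, paper_params)
        parts = self._scan(left, paper_params)
        shifted = [(h.start + len(left + gap), h.end + len(left + gap),
                    h.g_score)
                   for h in self._scan(right, paper_params)]
        assert [(h.start, h.end, h.g_score) for h in whole] == \
            [(h.start, h.end, h.g_score) for h in parts] + shifted
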