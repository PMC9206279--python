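"""Scanner: G-run finding, canonical scanning, equal-stem topology parsing."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gquadfold.scanner import (
    G4Motif,
    InvalidSequenceError,
    TopologyParse,
    canonical_loop_lengths,
    dedupe_motifs,
    find_g_runs,
    parse_topology,
    reverse_complement,
    scan_canonical,
)
from conftest import WORKED_EXAMPLE
from topology_oracle import oracle_parse


class TestFindGRuns:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGGAGGGAGGGAGGG", [(0, 3), (4, 3), (8, 3), (12, 3)]),
            ("ACGT", [(2, 1)]),
            ("acgt", [(2, 1)]),
            ("AAAA", []),
            ("", []),
            (WORKED_EXAMPLE, [(0, 3), (10, 5), (22, 3), (28, 3)]),
        ],
    )
    def test_maximal_runs(self, seq, expected):
        assert [(r.start, r.length) for r in find_g_runs(seq)] == expected

    def test_rejects_non_iupac(self):
        with pytest.raises(InvalidSequenceError):
            find_g_runs("ACGXG")

    def test_worked_example_second_run_has_five_guanines(self):
        lengths = [r.length for r in find_g_runs(WORKED_EXAMPLE)]
        assert lengths == [3, 5, 3, 3]


class TestParseTopology:
    def test_worked_example_surplus_goes_to_loops(self):
        topo = parse_topology(WORKED_EXAMPLE)
        assert topo.q == 3
        assert topo.n_loops == 3
        assert topo.loop_min == 3
        assert topo.loop_max == 9

    def test_forced_parse_without_surplus(self):
        topo = parse_topology("GGGAGGGAGGGAGGG")
        assert (topo.q, topo.n_loops, topo.loop_min, topo.loop_max) == (3, 3, 1, 1)
        assert topo.span == (0, 15)

    def test_three_runs_is_not_a_quadruplex(self):
        assert parse_topology("GGAGGAGG") is None

    def test_single_quartet_motif(self):
        # four single Gs with 1-nt loops: one quartet, the refined lower bound
        topo = parse_topology("GAGAGAG")
        assert (topo.q, topo.n_loops) == (1, 3)

    def test_q_capped_at_eight(self):
        seq = ("G" * 10 + "TT") * 3 + "G" * 10
        topo = parse_topology(seq)
        assert topo.q == 8

    def test_loop_longer_than_twelve_blocks_window(self):
        # a 13-nt gap cannot serve as a loop: the first run is unusable and
        # the window shifts to the four runs right of the gap
        seq = "GGG" + "T" * 13 + "GGGTTGGGTTGGGTTGGG"
        topo = parse_topology(seq)
        assert topo is not None
        assert topo.span[0] == 16
        # with only three runs right of the gap no window remains at all
        assert parse_topology("GGG" + "T" * 13 + "GGGTTGGGTTGGG") is None

    def test_ties_prefer_fewer_stems_then_leftmost(self):
        # five equal runs: the leftmost four-run window must win
        seq = "GGGTTGGGTTGGGTTGGGTTGGG"
        topo = parse_topology(seq)
        assert topo.n_loops == 3
        assert topo.span[0] == 0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="GACT", min_size=0, max_size=60))
    def test_matches_bruteforce_oracle(self, seq):
        expected = oracle_parse(seq)
        topo = parse_topology(seq)
        if expected is None:
            assert topo is None
        else:
            assert topo is not None
            got = (topo.q, topo.n_loops + 1, topo.span[0], topo.loop_min, topo.loop_max)
            assert got == expected

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="GACT", min_size=10, max_size=60))
    def test_bounds_invariants(self, seq):
        topo = parse_topology(seq)
        if topo is None:
            return
        runs = {(r.start, r.length) for r in find_g_runs(seq)}
        assert 1 <= topo.q <= 8
        assert 1 <= topo.loop_min <= topo.loop_max <= 12
        for a, b in topo.stems:
            assert b - a == topo.q
            assert set(seq[a:b].upper()) == {"G"}
            # each stem lies within one maximal G-run
            assert any(s <= a and b <= s + l for s, l in runs)


class TestScanCanonical:
    def test_canonical_exemplar_plus_strand(self):
        hits = scan_canonical("GGGAGGGAGGGAGGG", both_strands=False)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (0, 15, "+")

    def test_minus_strand_reported_as_reverse_complement(self):
        hits = scan_canonical("CCCTCCCTCCCTCCC")
        assert len(hits) == 1
        hit = hits[0]
        assert hit.strand == "-"
        assert hit.motif_seq == "GGGAGGGAGGGAGGG"
        assert (hit.start, hit.end) == (0, 15)

    def test_worked_example_greedy_match_covers_31_nt(self):
        hits = scan_canonical(WORKED_EXAMPLE, both_strands=False)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (0, 31)
        # under the greedy canonical parse the first two loops are 7 nt
        assert canonical_loop_lengths(hits[0].motif_seq) == [7, 7, 3]

    def test_no_match_returns_empty(self):
        assert scan_canonical("ACACACACAC") == []

    def test_motif_embedded_in_flanks(self):
        seq = "ATAT" + "GGGAGGGAGGGAGGG" + "CACA"
        hits = scan_canonical(seq, both_strands=False)
        assert [(h.start, h.end) for h in hits] == [(4, 19)]
        assert hits[0].topology.q == 3

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="GACT", min_size=0, max_size=80))
    def test_strand_symmetry(self, seq):
        rc = reverse_complement(seq)
        minus = [h for h in scan_canonical(seq) if h.strand == "-"]
        plus_on_rc = [h for h in scan_canonical(rc) if h.strand == "+"]
        L = len(seq)
        reflected = sorted((L - h.end, L - h.start, h.motif_seq) for h in plus_on_rc)
        assert sorted((h.start, h.end, h.motif_seq) for h in minus) == reflected


class TestDedupeMotifs:
    def _motif(self, seq: str) -> G4Motif:
        return G4Motif(query_id="q", start=0, end=len(seq), strand="+", motif_seq=seq)

    def test_case_insensitive_identity(self):
        motifs = [self._motif("GGGAGGGAGGGAGGG"), self._motif("gggagggagggaggg")]
        assert len(dedupe_motifs(motifs)) == 1

    def test_empty(self):
        assert dedupe_motifs([]) == []

    def test_two_identical_one_distinct(self):
        a = self._motif("GGGAGGGAGGGAGGG")
        b = self._motif("GGGTGGGTGGGTGGG")
        out = dedupe_motifs([a, self._motif(a.motif_seq), b])
        assert [m.motif_seq for m in out] == [a.motif_seq, b.motif_seq]

    def test_idempotent(self):
        random.seed(0)
        motifs = [
            self._motif("GGG" + random.choice("AT") + "GGGAGGGAGGG") for _ in range(20)
        ]
        once = dedupe_motifs(motifs)
        assert dedupe_motifs(once) == once
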