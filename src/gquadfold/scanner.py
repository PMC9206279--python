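"""Canonical G-quadruplex motif scanning and refined equal-stem topology parsing.

A G-quadruplex (G4) motif is a succession of at least four runs of guanines
(G-stems) separated by short loops.  The canonical definition requires stems
of three or more Gs and loops of 1-7 nt.  That pattern can match spans whose
G-runs are unequal in length (e.g. a second run of five Gs between runs of
three), leaving it ambiguous which guanines stack into G-quartets.  The
refined parse implemented here forces every stem to contribute the same
number of Gs (the quartet count ``q``) and pushes any surplus guanines of a
run into the adjacent loop, so that a motif is described by the maximal
number of stackable G-quartets plus the loop-length extrema over all
admissible surplus placements.  Refined bounds: 1-8 quartets, 4-12 stems,
loops 1-12 nt.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "GRun",
    "TopologyParse",
    "G4Motif",
    "find_g_runs",
    "parse_topology",
    "scan_canonical",
    "dedupe_motifs",
    "reverse_complement",
]

#: Characters accepted in input sequences (case-insensitive; U treated as T).
VALID_BASES = frozenset("ACGTUN")

_G_RUN_RE = re.compile(r"[gG]+")
_INVALID_RE = re.compile(r"[^ACGTUNacgtun]")

# Refined motif bounds: (G_1-8 L_1-12)_3-11 G_1-8
Q_MAX = 8
LOOP_MIN = 1
LOOP_MAX = 12
STEMS_MIN = 4
STEMS_MAX = 12


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,U,N}."""


def _check_sequence(seq: str) -> str:
    m = _INVALID_RE.search(seq)
    if m:
        raise InvalidSequenceError(
            f"non-IUPAC character {m.group()!r} at position {m.start()}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case; U is complemented like T."""
    _check_sequence(seq)
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GRun:
    """A maximal run of consecutive guanines.

    ``start`` is a 0-based offset; ``length`` >= 1.  Bases flanking the run
    are never G (maximality).
    """

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class TopologyParse:
    """Equal-stem assignment of G-runs to G-quartet stems.

    ``q`` is the number of stacked G-quartets (each stem contributes exactly
    ``q`` guanines).  ``stems`` are 0-based half-open intervals, one per
    selected G-run, for the representative placement (terminal stems anchored
    at the outermost run edges, internal stems left-aligned).  Loop-length
    extrema are taken over *all* admissible placements of surplus guanines.
    """

    q: int
    stems: tuple[tuple[int, int], ...]
    n_loops: int
    loop_min: int
    loop_max: int
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if not (1 <= self.q <= Q_MAX):
            raise ValueError(f"q={self.q} outside [1, {Q_MAX}]")
        if len(self.stems) != self.n_loops + 1:
            raise ValueError("n_stems must equal n_loops + 1")
        if not (STEMS_MIN <= len(self.stems) <= STEMS_MAX):
            raise ValueError(f"{len(self.stems)} stems outside [{STEMS_MIN}, {STEMS_MAX}]")
        if not (LOOP_MIN <= self.loop_min <= self.loop_max <= LOOP_MAX):
            raise ValueError("loop extrema outside refined bounds")


@dataclass(frozen=True)
class G4Motif:
    """A located motif with strand, forward-strand coordinates and topology.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    query.  ``motif_seq`` is strand-oriented: for a minus-strand hit it is
    the reverse complement of the forward-strand slice.
    """

    query_id: str
    start: int
    end: int
    strand: str
    motif_seq: str
    topology: Optional[TopologyParse] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.motif_seq):
            raise ValueError("coordinates inconsistent with motif_seq length")


def find_g_runs(seq: str) -> list[GRun]:
    """All maximal G-runs of *seq*, left to right.

    Case-insensitive; rejects non-IUPAC characters.
    """
    _check_sequence(seq)
    return [GRun(m.start(), m.end() - m.start()) for m in _G_RUN_RE.finditer(seq)]


def _feasible_offsets(
    win: Sequence[GRun], q: int, loop_max: int
) -> Optional[list[list[int]]]:
    """Arc-consistent per-stem offset domains for a window of G-runs.

    A stem occupies ``q`` consecutive Gs within its run at offset ``o`` from
    the run start.  Terminal stems are anchored (first at offset 0, last
    flush right) so surplus guanines of terminal runs fall into loops.  The
    loop between stems i and i+1 must be 1..loop_max nt.  Returns per-stem
    offset lists containing exactly the offsets that occur in at least one
    fully admissible placement, or None if no placement is admissible.
    Forward/backward reachability suffices because the constraints form a
    chain.
    """
    k = len(win)
    domains: list[list[int]] = []
    for i, run in enumerate(win):
        if i == 0:
            domains.append([0])
        elif i == k - 1:
            domains.append([run.length - q])
        else:
            domains.append(list(range(run.length - q + 1)))

    def loop_len(i: int, o_i: int, o_next: int) -> int:
        stem_end = win[i].start + o_i + q
        next_start = win[i + 1].start + o_next
        return next_start - stem_end

    # forward pass
    fwd: list[set[int]] = [set(domains[0])]
    for i in range(1, k):
        reach = {
            o
            for o in domains[i]
            if any(LOOP_MIN <= loop_len(i - 1, p, o) <= loop_max for p in fwd[i - 1])
        }
        if not reach:
            return None
        fwd.append(reach)
    # backward pass
    bwd: list[set[int]] = [set()] * k
    bwd[k - 1] = fwd[k - 1]
    for i in range(k - 2, -1, -1):
        bwd[i] = {
            o
            for o in fwd[i]
            if any(LOOP_MIN <= loop_len(i, o, n) <= loop_max for n in bwd[i + 1])
        }
        if not bwd[i]:
            return None
    return [sorted(s) for s in bwd]


def _loop_extrema(
    win: Sequence[GRun], q: int, feas: list[list[int]], loop_max: int
) -> tuple[int, int]:
    """Min/max loop length over all loops of all admissible placements."""
    lo, hi = LOOP_MAX + 1, 0
    for i in range(len(win) - 1):
        for o in feas[i]:
            stem_end = win[i].start + o + q
            for n in feas[i + 1]:
                length = win[i + 1].start + n - stem_end
                if LOOP_MIN <= length <= loop_max:
                    lo = min(lo, length)
                    hi = max(hi, length)
    return lo, hi


def parse_topology(
    seq: str,
    *,
    q_max: int = Q_MAX,
    loop_max: int = LOOP_MAX,
    stems_min: int = STEMS_MIN,
    stems_max: int = STEMS_MAX,
) -> Optional[TopologyParse]:
    """Refined equal-stem parse of *seq*; None when no admissible window exists.

    Algorithm: enumerate contiguous windows of k consecutive maximal G-runs
    (stems_min <= k <= stems_max); for each window the quartet count is
    q = min(q_max, shortest run in the window); a window is admissible iff
    some placement of the equal-length stems keeps every loop within
    [1, loop_max].  The admissible window maximizing q wins; ties prefer
    fewer stems, then the leftmost window.  Loop-length extrema are reported
    over all admissible placements of the winning window.
    """
    runs = find_g_runs(seq)
    n = len(runs)
    best: Optional[tuple[int, int, int]] = None  # (q, -k, -start) maximized
    best_payload = None
    for k in range(stems_min, min(stems_max, n) + 1):
        for i in range(n - k + 1):
            win = runs[i : i + k]
            q = min(q_max, min(r.length for r in win))
            key = (q, -k, -win[0].start)
            if best is not None and key <= best:
                continue
            feas = _feasible_offsets(win, q, loop_max)
            if feas is None:
                continue
            best = key
            best_payload = (win, q, feas)
    if best_payload is None:
        return None
    win, q, feas = best_payload
    lo, hi = _loop_extrema(win, q, feas, loop_max)
    # representative placement: terminal stems anchored, internal stems at
    # their smallest admissible offset
    stems = []
    for run, offs in zip(win, feas):
        o = offs[0]
        stems.append((run.start + o, run.start + o + q))
    stems[-1] = (win[-1].end - q, win[-1].end)
    return TopologyParse(
        q=q,
        stems=tuple(stems),
        n_loops=len(win) - 1,
        loop_min=lo,
        loop_max=hi,
        span=(win[0].start, win[-1].end),
    )


def canonical_regex(min_stem: int = 3, max_loop: int = 7) -> re.Pattern:
    """Compiled canonical motif pattern (G{m,}N{1,l}){3,}G{m,}."""
    if min_stem < 1 or max_loop < 1:
        raise ValueError("min_stem and max_loop must be >= 1")
    return re.compile(
        r"(?:[gG]{%d,}[A-Za-z]{1,%d}){3,}[gG]{%d,}" % (min_stem, max_loop, min_stem)
    )


def canonical_loop_lengths(motif_seq: str) -> list[int]:
    """Loop lengths of the greedy canonical parse (maximal G-runs as stems)."""
    runs = find_g_runs(motif_seq)
    return [runs[i + 1].start - runs[i].end for i in range(len(runs) - 1)]


def scan_canonical(
    seq: str,
    *,
    query_id: str = "query",
    min_stem: int = 3,
    max_loop: int = 7,
    both_strands: bool = True,
) -> list[G4Motif]:
    """Greedy non-overlapping canonical motif scan on one or both strands.

    Minus-strand hits are found on the reverse complement and reported with
    forward-strand coordinates; their ``motif_seq`` is the reverse
    complement (the strand that actually carries the G-runs).  Every hit
    carries the refined equal-stem :class:`TopologyParse` of its span.
    """
    _check_sequence(seq)
    pat = canonical_regex(min_stem, max_loop)
    hits: list[G4Motif] = []
    for m in pat.finditer(seq):
        hits.append(
            G4Motif(
                query_id=query_id,
                start=m.start(),
                end=m.end(),
                strand="+",
                motif_seq=m.group(),
                topology=parse_topology(m.group()),
            )
        )
    if both_strands:
        rc = reverse_complement(seq)
        L = len(seq)
        for m in pat.finditer(rc):
            hits.append(
                G4Motif(
                    query_id=query_id,
                    start=L - m.end(),
                    end=L - m.start(),
                    strand="-",
                    motif_seq=m.group(),
                    topology=parse_topology(m.group()),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def dedupe_motifs(motifs: Iterable[G4Motif]) -> list[G4Motif]:
    """Keep the first occurrence per case-insensitive motif sequence."""
    seen: set[str] = set()
    out: list[G4Motif] = []
    for m in motifs:
        key = m.motif_seq.upper().replace("U", "T")
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out
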