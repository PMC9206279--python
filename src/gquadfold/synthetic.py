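"""Seeded generator of G4-like and non-G4 sequences with known topology.

Positive records are built stem-by-stem: ``k`` G-runs of equal length ``q``
joined by loops of controlled length and composition, wrapped in guanine-free
flanks.  Optionally one internal run carries surplus guanines, so the
equal-stem parser must push them into an adjacent loop — the situation the
refined motif definition exists for.  Loops and flanks never contain G, so
the intended topology is recoverable by construction and the emitted truth
table can be checked against the scanner without circularity.

Negatives come in three schemes: ``c_rich_interference`` keeps the G4 shape
but fills loops with cytosines (which compete for the stem guanines via
Watson-Crick pairing and suppress quadruplex folding), ``shuffled_matched``
permutes a positive's letters (exact mononucleotide counts preserved), and
``at_random`` draws an unconstrained low-G background sequence.  Folding
labels are never asserted by the generator; they come from the thermo
engine downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["CorpusSpec", "generate_corpus", "join_multimolecular"]

TRUTH_COLUMNS = [
    "record_id",
    "positive",
    "scheme",
    "q",
    "n_runs",
    "n_loops",
    "loop_min",
    "loop_max",
    "motif_start",
    "motif_end",
    "sequence",
]


def _default_stem_weights() -> dict[int, float]:
    # mostly canonical three-quartet motifs, tails to 1 and 6
    return {1: 0.05, 2: 0.15, 3: 0.50, 4: 0.18, 5: 0.08, 6: 0.04}


def _default_run_count_weights() -> dict[int, float]:
    return {4: 0.70, 5: 0.18, 6: 0.08, 7: 0.03, 8: 0.01}


def _default_loop_weights() -> dict[int, float]:
    # short loops dominate; the refined definition admits up to 12 nt
    w = {1: 0.22, 2: 0.18, 3: 0.16, 4: 0.12, 5: 0.09, 6: 0.07, 7: 0.06}
    w.update({8: 0.035, 9: 0.025, 10: 0.02, 11: 0.01, 12: 0.01})
    return w


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus; the seed is mandatory.

    ``loop_c_weight`` is the sampling weight of C relative to A and T (each
    weight 1) inside loops; flanks use ``flank_c_weight`` the same way.
    ``surplus_prob`` is the chance that one internal G-run of a positive
    carries 1-2 surplus guanines beyond the quartet count.
    """

    n_sequences: int
    seed: int
    stem_weights: dict[int, float] = field(default_factory=_default_stem_weights)
    run_count_weights: dict[int, float] = field(
        default_factory=_default_run_count_weights
    )
    loop_weights: dict[int, float] = field(default_factory=_default_loop_weights)
    loop_c_weight: float = 0.7
    flank_length: int = 10
    flank_c_weight: float = 0.7
    surplus_prob: float = 0.15
    negative_fraction: float = 0.3
    negative_scheme: str = "c_rich_interference"
    negative_c_weight: float = 5.0
    rna: bool = False

    def __post_init__(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")
        if not all(1 <= q <= 8 for q in self.stem_weights):
            raise ValueError("stem lengths must lie in [1, 8]")
        if not all(4 <= k <= 12 for k in self.run_count_weights):
            raise ValueError("run counts must lie in [4, 12]")
        if not all(1 <= l <= 12 for l in self.loop_weights):
            raise ValueError("loop lengths must lie in [1, 12]")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise ValueError("negative_fraction must lie in [0, 1]")
        if self.negative_scheme not in (
            "c_rich_interference",
            "shuffled_matched",
            "at_random",
        ):
            raise ValueError(f"unknown negative scheme {self.negative_scheme!r}")
        if self.flank_length < 0:
            raise ValueError("flank_length must be >= 0")


def _weighted_choice(rng: np.random.Generator, weights: dict[int, float]) -> int:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


def _loop_alphabet(rna: bool) -> list[str]:
    return ["A", "C", "U" if rna else "T"]


def _random_gfree(
    rng: np.random.Generator, length: int, c_weight: float, rna: bool
) -> str:
    if length == 0:
        return ""
    bases = _loop_alphabet(rna)
    p = np.array([1.0, c_weight, 1.0])
    return "".join(rng.choice(bases, size=length, p=p / p.sum()))


def _build_motif(
    rng: np.random.Generator, spec: CorpusSpec, c_weight: float
) -> tuple[str, dict]:
    """One G4-shaped motif plus its analytically-known refined parse.

    The parser maximizes the quartet count and, among equal counts, prefers
    fewer stems and the leftmost window, so a clean equal-stem motif always
    parses as its leftmost four runs; the truth entries account for that,
    including the loop-extrema widening caused by a surplus-carrying run.
    """
    q = _weighted_choice(rng, spec.stem_weights)
    k = _weighted_choice(rng, spec.run_count_weights)
    loops = [_weighted_choice(rng, spec.loop_weights) for _ in range(k - 1)]

    surplus_at: Optional[int] = None
    surplus = 0
    if spec.surplus_prob > 0 and rng.random() < spec.surplus_prob and q < 8:
        # one run at window position 1 or 2 so the parse window is affected;
        # keep adjacent loops + surplus within the 12-nt bound
        cand = int(rng.integers(1, 3))
        s = int(rng.integers(1, 3))
        if loops[cand - 1] + s <= 12 and loops[cand] + s <= 12 and q + s <= 8:
            surplus_at, surplus = cand, s

    g = "G"
    parts = []
    for i in range(k):
        run_len = q + (surplus if i == surplus_at else 0)
        parts.append(g * run_len)
        if i < k - 1:
            parts.append(_random_gfree(rng, loops[i], c_weight, spec.rna))
    motif = "".join(parts)

    window_loops = loops[:3]
    if surplus_at is not None:
        lo = min(window_loops)
        hi = max(
            max(window_loops),
            window_loops[surplus_at - 1] + surplus,
            window_loops[surplus_at] + surplus,
        )
    else:
        lo, hi = min(window_loops), max(window_loops)
    truth = {
        "q": q,
        "n_runs": k,
        "n_loops": 3,
        "loop_min": lo,
        "loop_max": hi,
    }
    return motif, truth


def _negative_sequence(
    rng: np.random.Generator, spec: CorpusSpec, positive_pool: list[str]
) -> tuple[str, Optional[dict]]:
    if spec.negative_scheme == "c_rich_interference":
        motif, truth = _build_motif(rng, spec, spec.negative_c_weight)
        return motif, truth
    if spec.negative_scheme == "shuffled_matched":
        template = positive_pool[int(rng.integers(len(positive_pool)))]
        letters = list(template)
        rng.shuffle(letters)
        return "".join(letters), None
    # at_random: low-G background, same length scale as positives
    length = int(rng.integers(25, 61))
    bases = ["A", "C", "G", "U" if spec.rna else "T"]
    p = np.array([0.3, 0.25, 0.15, 0.3])
    return "".join(rng.choice(bases, size=length, p=p)), None


def generate_corpus(spec: CorpusSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """FASTA-ready records plus a truth table of intended topology.

    Returns ``(records, truth)`` where records are ``(id, sequence)`` pairs
    in emission order and truth has one row per record (topology columns are
    NA for negatives without an intended motif).  Reproducible: the same
    spec, seed included, yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n_neg = int(round(spec.n_sequences * spec.negative_fraction))
    n_pos = spec.n_sequences - n_neg

    records: list[tuple[str, str]] = []
    rows: list[dict] = []
    positive_pool: list[str] = []

    for i in range(n_pos):
        motif, truth = _build_motif(rng, spec, spec.loop_c_weight)
        left = _random_gfree(rng, spec.flank_length, spec.flank_c_weight, spec.rna)
        right = _random_gfree(rng, spec.flank_length, spec.flank_c_weight, spec.rna)
        seq = left + motif + right
        rid = f"pos_{i:05d}"
        records.append((rid, seq))
        positive_pool.append(motif)
        rows.append(
            {
                "record_id": rid,
                "positive": True,
                "scheme": "positive",
                **truth,
                "motif_start": len(left),
                "motif_end": len(left) + len(motif),
                "sequence": seq,
            }
        )

    if n_neg and not positive_pool and spec.negative_scheme == "shuffled_matched":
        raise ValueError("shuffled_matched negatives need at least one positive")

    for i in range(n_neg):
        seq, truth = _negative_sequence(rng, spec, positive_pool)
        if truth is not None:
            left = _random_gfree(rng, spec.flank_length, spec.flank_c_weight, spec.rna)
            right = _random_gfree(rng, spec.flank_length, spec.flank_c_weight, spec.rna)
            motif_start, motif_end = len(left), len(left) + len(seq)
            seq = left + seq + right
        else:
            motif_start = motif_end = None
        rid = f"neg_{i:05d}"
        records.append((rid, seq))
        rows.append(
            {
                "record_id": rid,
                "positive": False,
                "scheme": spec.negative_scheme,
                **(truth or {}),
                "motif_start": motif_start,
                "motif_end": motif_end,
                "sequence": seq,
            }
        )

    truth_table = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return records, truth_table


def join_multimolecular(strands: list[str], linker_length=3) -> str:
    """Join 2 or 4 quadruplex strands with poly-T linkers.

    Bi- and tetramolecular quadruplexes are turned into a single-strand
    surrogate by inserting an artificial all-T loop between consecutive
    strands; *linker_length* is one int for all linkers or a list with one
    length per junction.
    """
    if len(strands) not in (2, 4):
        raise ValueError("expected 2 or 4 strands")
    n_junctions = len(strands) - 1
    if isinstance(linker_length, int):
        lengths = [linker_length] * n_junctions
    else:
        lengths = list(linker_length)
        if len(lengths) != n_junctions:
            raise ValueError(f"expected {n_junctions} linker lengths")
    if any(l < 1 for l in lengths):
        raise ValueError("linker lengths must be >= 1")
    out = [strands[0]]
    for strand, l in zip(strands[1:], lengths):
        out.append("T" * l)
        out.append(strand)
    return "".join(out)
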