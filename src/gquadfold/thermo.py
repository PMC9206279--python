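"""Folding-state and free-energy labels from a quadruplex-aware MFE engine.

A motif is *folded* when the minimum-free-energy secondary structure
contains quadruplex pairing (``+`` positions in dot-plus notation) and
*unfolded* otherwise — a motif whose MFE structure is an ordinary hairpin
counts as unfolded even though its energy may be low.  The default engine
is ViennaRNA with G-quadruplex support enabled; DNA is folded with RNA
parameters after a T→U mapping, which reconstructs DNA secondary structure
with acceptable accuracy.  A deterministic rule-based mock engine lets the
rest of the pipeline run and be tested without ViennaRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Protocol, runtime_checkable

import pandas as pd

from .features import FEATURE_NAMES, extract_features
from .scanner import G4Motif, _check_sequence, dedupe_motifs, parse_topology

__all__ = [
    "FoldResult",
    "Engine",
    "ViennaRNAEngine",
    "MockEngine",
    "default_engine",
    "fold",
    "classify_fold",
    "build_training_table",
    "EngineUnavailableError",
]

logger = logging.getLogger(__name__)

_STRUCTURE_CHARS = frozenset(".()+")

import re as _re

_GG_RUN_RE = _re.compile(r"GG+")


class EngineUnavailableError(RuntimeError):
    """The configured folding engine cannot be loaded."""


@runtime_checkable
class Engine(Protocol):
    """Contract for a quadruplex-aware MFE engine.

    ``fold_structure`` must be deterministic for a fixed sequence and engine
    version and return a dot-plus string of the same length as the input
    plus an energy in kcal/mol.
    """

    engine_name: str
    engine_version: str

    def fold_structure(self, seq: str) -> tuple[str, float]: ...


@dataclass(frozen=True)
class FoldResult:
    """Engine output: dot-plus structure, MFE energy (kcal/mol), folded flag."""

    structure: str
    energy: float
    folded: bool


def classify_fold(structure: str) -> bool:
    """True iff the dot-plus structure contains quadruplex pairing.

    Hairpins and unstructured strings are 'unfolded' regardless of energy.
    """
    bad = set(structure) - _STRUCTURE_CHARS
    if bad:
        raise ValueError(f"invalid structure characters: {sorted(bad)!r}")
    return "+" in structure


class ViennaRNAEngine:
    """ViennaRNA MFE folding with G-quadruplex prediction enabled.

    DNA input is mapped T→U and folded with RNA energy parameters; the
    adapter records this in ``metadata``.  ViennaRNA >= 2.7 marks the
    3'-most quadruplex position with ``~``; it is normalized to ``+`` so
    the dot-plus alphabet is exactly {., (, ), +}.
    """

    engine_name = "viennarna"

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - environment-dependent
            raise EngineUnavailableError(
                "ViennaRNA python bindings (module 'RNA') are not installed"
            ) from exc
        self._RNA = RNA
        self.engine_version = RNA.__version__
        md = RNA.md()
        md.gquad = 1
        self._md = md
        self._md_plain = RNA.md()
        self.metadata = {
            "engine": self.engine_name,
            "version": self.engine_version,
            "gquad": True,
            "dna_handling": "T mapped to U; RNA energy parameters",
        }

    def fold_structure(self, seq: str) -> tuple[str, float]:
        _check_sequence(seq)
        rna = seq.upper().replace("T", "U")
        # A quadruplex needs at least four G-runs of two or more guanines.
        # When none is possible the gquad terms cannot contribute, so they
        # are switched off; the MFE structure is identical and ViennaRNA's
        # quadruplex scan — very slow on short sequences — is avoided.
        md = self._md if len(_GG_RUN_RE.findall(rna)) >= 4 else self._md_plain
        fc = self._RNA.fold_compound(rna, md)
        structure, energy = fc.mfe()
        structure = structure.replace("~", "+")
        return structure, float(energy)


class MockEngine:
    """Deterministic rule-based stand-in for the MFE engine.

    Purely a function of the sequence: a motif with an admissible equal-stem
    parse of >= 2 quartets and cytosine content below ``c_threshold`` is
    assigned a quadruplex structure ('+' over the representative stems) with
    an energy decreasing in quartet count; a C-rich sequence gets a hairpin;
    anything else is unstructured at 0.0 kcal/mol.  The rules caricature the
    real engine's behaviour (C interferes with quartet formation) and are
    not thermodynamic.
    """

    engine_name = "mock"
    engine_version = "1"

    def __init__(self, c_threshold: float = 0.20) -> None:
        self.c_threshold = c_threshold
        self.metadata = {"engine": self.engine_name, "version": self.engine_version}

    def fold_structure(self, seq: str) -> tuple[str, float]:
        _check_sequence(seq)
        s = seq.upper().replace("U", "T")
        L = len(s)
        c_frac = s.count("C") / L if L else 0.0
        topo = parse_topology(s)
        if topo is not None and topo.q >= 2 and c_frac < self.c_threshold:
            chars = ["."] * L
            for a, b in topo.stems:
                for i in range(a, b):
                    chars[i] = "+"
            # deeper stacks and shorter loops are more stable
            energy = -4.2 * topo.q * (topo.n_loops + 1) / 4.0 + 0.3 * (
                topo.loop_max + topo.loop_min
            )
            return "".join(chars), round(min(energy, -0.1), 2)
        n_pairs = min(s.count("G"), s.count("C"), (L - 3) // 2)
        if n_pairs >= 3:
            structure = "(" * n_pairs + "." * (L - 2 * n_pairs) + ")" * n_pairs
            return structure, round(-1.8 * n_pairs, 2)
        return "." * L, 0.0


def default_engine() -> Engine:
    """The ViennaRNA engine, or an explicit error when unavailable."""
    return ViennaRNAEngine()


def fold(seq: str, engine: Optional[Engine] = None) -> FoldResult:
    """Fold *seq* with a quadruplex-aware engine and label its state."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    if engine is None:
        engine = default_engine()
    structure, energy = engine.fold_structure(seq)
    if len(structure) != len(seq):
        raise RuntimeError(
            f"engine returned structure of length {len(structure)} "
            f"for sequence of length {len(seq)}"
        )
    return FoldResult(structure=structure, energy=energy, folded=classify_fold(structure))


def build_training_table(
    motifs: Iterable[G4Motif],
    engine: Optional[Engine] = None,
    *,
    query_seqs: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Labeled training table: one row per unique motif.

    Columns: the 26 features, then ``folded`` (bool) and ``energy``
    (kcal/mol).  Features are computed on the query sequence when
    *query_seqs* maps the motif's ``query_id`` to its record, otherwise on
    the motif sequence itself.  Energies are recorded for folded and
    unfolded motifs alike.  Engine failures skip the row with a logged
    warning, never silently.
    """
    if engine is None:
        engine = default_engine()
    rows = []
    for motif in dedupe_motifs(motifs):
        query = (
            query_seqs[motif.query_id]
            if query_seqs and motif.query_id in query_seqs
            else motif.motif_seq
        )
        try:
            result = fold(motif.motif_seq, engine)
        except Exception as exc:  # engine failure must be visible, not fatal
            logger.warning(
                "folding engine failed on motif %s[%d:%d]: %s",
                motif.query_id,
                motif.start,
                motif.end,
                exc,
            )
            continue
        row = extract_features(query, motif)
        row["folded"] = result.folded
        row["energy"] = result.energy
        rows.append(row)
    table = pd.DataFrame(rows, columns=FEATURE_NAMES + ["folded", "energy"])
    if len(table):
        n_folded = int(table["folded"].sum())
        logger.info(
            "training table: %d motifs, %d folded / %d unfolded",
            len(table),
            n_folded,
            len(table) - n_folded,
        )
    return table
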