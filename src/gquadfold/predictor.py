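"""Three-layer prediction over FASTA: topology → fold probability → energy.

Given a query sequence and nothing else, layer one annotates the refined
equal-stem topology (scan mode finds canonical motifs first; annotate mode
parses each whole record), layer two scores the quadruplex folding
probability with the trained classifier, and layer three predicts the
folding free energy with the trained regressor.  The decision threshold is
an argument, not a constant, so callers can trade precision against recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .features import extract_features, features_frame
from .io import read_fasta
from .models import ModelBundle
from .scanner import G4Motif, parse_topology, reverse_complement, scan_canonical

__all__ = ["PredictionRecord", "predict", "batch_report", "records_to_frame"]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "query_id",
    "start",
    "end",
    "strand",
    "q",
    "n_loops",
    "loop_min",
    "loop_max",
    "fold_probability",
    "fold_call",
    "predicted_energy",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One motif (or no-G4 record) with the three prediction layers filled."""

    query_id: str
    start: Optional[int]
    end: Optional[int]
    strand: Optional[str]
    q: Optional[int]
    n_loops: Optional[int]
    loop_min: Optional[int]
    loop_max: Optional[int]
    fold_probability: Optional[float]
    fold_call: Optional[bool]
    predicted_energy: Optional[float]

    @property
    def no_g4(self) -> bool:
        return self.q is None


def _annotate_motif(query_id: str, seq: str) -> Optional[G4Motif]:
    topo = parse_topology(seq)
    if topo is None:
        return None
    a, b = topo.span
    return G4Motif(
        query_id=query_id,
        start=a,
        end=b,
        strand="+",
        motif_seq=seq[a:b],
        topology=topo,
    )


def predict(
    fasta: Union[str, Path, Sequence[tuple[str, str]]],
    classifier_bundle: ModelBundle,
    regressor_bundle: ModelBundle,
    *,
    threshold: Optional[float] = None,
    mode: str = "scan",
    flank: int = 0,
    min_stem: int = 3,
    max_loop: int = 7,
    both_strands: bool = True,
) -> list[PredictionRecord]:
    """Predict topology, folding probability and folding energy per motif.

    ``mode="scan"`` reports one record per canonical motif hit, with the
    feature query being the matched span extended by *flank* nt each side
    (strand-oriented).  ``mode="annotate"`` reports one record per input
    sequence, parsed as a whole under the refined definition — this also
    covers motifs below the canonical stem bound (down to a single quartet);
    records with no admissible parse come back flagged as no-G4 with the
    probability omitted.
    """
    if mode not in ("scan", "annotate"):
        raise ValueError(f"unknown mode {mode!r}")
    if threshold is None:
        threshold = classifier_bundle.threshold
    if classifier_bundle.task != "classification":
        raise ValueError("classifier_bundle is not a classification bundle")
    if regressor_bundle.task != "regression":
        raise ValueError("regressor_bundle is not a regression bundle")

    if isinstance(fasta, (str, Path)):
        records = read_fasta(fasta)
    else:
        records = list(fasta)
    if not records:
        logger.warning("empty FASTA input: no records to predict")
        return []

    slots: list[tuple] = []  # (query_id, motif | None, feature_row | None)
    for rid, seq in records:
        if mode == "annotate":
            motif = _annotate_motif(rid, seq)
            if motif is None:
                slots.append((rid, None, None))
            else:
                slots.append((rid, motif, extract_features(seq, motif)))
        else:
            for motif in scan_canonical(
                seq,
                query_id=rid,
                min_stem=min_stem,
                max_loop=max_loop,
                both_strands=both_strands,
            ):
                a = max(0, motif.start - flank)
                b = min(len(seq), motif.end + flank)
                query = seq[a:b]
                if motif.strand == "-":
                    query = reverse_complement(query)
                slots.append((rid, motif, extract_features(query, motif)))

    feature_rows = [row for _, _, row in slots if row is not None]
    out: list[PredictionRecord] = []
    if feature_rows:
        table = features_frame(feature_rows)
        probs = classifier_bundle.predict_proba(table)
        energies = regressor_bundle.predict(table)
    idx = 0
    for rid, motif, row in slots:
        if row is None:
            out.append(
                PredictionRecord(rid, None, None, None, None, None, None, None, None, None, None)
            )
            continue
        topo = motif.topology
        p = float(probs[idx])
        out.append(
            PredictionRecord(
                query_id=rid,
                start=motif.start,
                end=motif.end,
                strand=motif.strand,
                q=topo.q,
                n_loops=topo.n_loops,
                loop_min=topo.loop_min,
                loop_max=topo.loop_max,
                fold_probability=p,
                fold_call=bool(p >= threshold),
                predicted_energy=float(energies[idx]),
            )
        )
        idx += 1
    return out


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Records as a DataFrame with fixed column order and float formatting."""
    rows = []
    for r in records:
        rows.append(
            {
                "query_id": r.query_id,
                "start": r.start,
                "end": r.end,
                "strand": r.strand if r.strand else "no-G4",
                "q": r.q,
                "n_loops": r.n_loops,
                "loop_min": r.loop_min,
                "loop_max": r.loop_max,
                "fold_probability": (
                    None if r.fold_probability is None else round(r.fold_probability, 4)
                ),
                "fold_call": r.fold_call,
                "predicted_energy": (
                    None if r.predicted_energy is None else round(r.predicted_energy, 2)
                ),
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def batch_report(records: Sequence[PredictionRecord]) -> dict:
    """Deterministic summary: counts, class balance, energy distribution."""
    motif_records = [r for r in records if not r.no_g4]
    folded = [r for r in motif_records if r.fold_call]
    energies = sorted(
        r.predicted_energy for r in motif_records if r.predicted_energy is not None
    )
    strands: dict[str, int] = {}
    for r in motif_records:
        strands[r.strand] = strands.get(r.strand, 0) + 1
    report = {
        "n_records": len(records),
        "n_motifs": len(motif_records),
        "n_no_g4": len(records) - len(motif_records),
        "folded_count": len(folded),
        "unfolded_count": len(motif_records) - len(folded),
        "per_strand": dict(sorted(strands.items())),
        "energy": {},
    }
    if energies:
        n = len(energies)
        report["energy"] = {
            "min": round(energies[0], 2),
            "median": round(energies[n // 2], 2),
            "max": round(energies[-1], 2),
            "mean": round(sum(energies) / n, 2),
        }
    return report
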