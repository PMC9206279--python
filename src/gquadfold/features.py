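"""Sequence-intrinsic feature extraction for G-quadruplex prediction.

26 features per (query sequence, motif) pair: five topology descriptors
(quartet count, loop count, loop-length extrema, motif length), the query
length, four mononucleotide frequencies and sixteen overlapping dinucleotide
frequencies.  Composition is computed over the full query sequence, since
cytosines *around* the motif compete for its guanines via Watson-Crick
pairing and carry signal about folding.  A 10-feature subset (topology +
lengths + G/C monomers + GG/CC dimers) is the default model input.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .scanner import G4Motif, TopologyParse, _check_sequence

__all__ = [
    "MONO_FEATURES",
    "DI_FEATURES",
    "FEATURE_NAMES",
    "SELECTED_FEATURES",
    "extract_features",
    "features_frame",
    "rank_features",
]

_BASES = "ACGT"
MONO_FEATURES = [f"freq_{b}" for b in _BASES]
DI_FEATURES = [f"di_{a}{b}" for a in _BASES for b in _BASES]

#: Stable order of the full 26-feature schema.
FEATURE_NAMES = (
    ["n_tetrads", "n_loops", "loop_min", "loop_max", "seq_length", "motif_length"]
    + MONO_FEATURES
    + DI_FEATURES
)

#: The selected 10-feature subset used by the shipped models.
SELECTED_FEATURES = [
    "n_tetrads",
    "n_loops",
    "loop_max",
    "loop_min",
    "seq_length",
    "motif_length",
    "freq_G",
    "freq_C",
    "di_GG",
    "di_CC",
]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def extract_features(
    query_seq: str, motif: Optional[G4Motif] = None
) -> dict[str, float]:
    """26-feature vector for *query_seq*, with topology taken from *motif*.

    Mononucleotide frequencies are counts / len(query); dinucleotide
    frequencies are overlapping-window counts / (len - 1), with N-containing
    windows skipped and the denominator reduced accordingly.  Without a
    motif (feature-only mode) the topology fields are zero.

    Raises ValueError for queries shorter than 2 nt.
    """
    _check_sequence(query_seq)
    seq = _normalize(query_seq)
    L = len(seq)
    if L < 2:
        raise ValueError("query sequence must be at least 2 nt")

    feats: dict[str, float] = {}
    if motif is not None and motif.topology is not None:
        topo: TopologyParse = motif.topology
        feats["n_tetrads"] = float(topo.q)
        feats["n_loops"] = float(topo.n_loops)
        feats["loop_min"] = float(topo.loop_min)
        feats["loop_max"] = float(topo.loop_max)
        feats["motif_length"] = float(len(motif.motif_seq))
    else:
        for name in ("n_tetrads", "n_loops", "loop_min", "loop_max", "motif_length"):
            feats[name] = 0.0
    feats["seq_length"] = float(L)

    for b in _BASES:
        feats[f"freq_{b}"] = seq.count(b) / L
    dimer_counts = {name: 0 for name in DI_FEATURES}
    valid_windows = 0
    for i in range(L - 1):
        d = seq[i : i + 2]
        if "N" in d:
            continue
        valid_windows += 1
        dimer_counts[f"di_{d}"] += 1
    denom = valid_windows if valid_windows else 1
    for name in DI_FEATURES:
        feats[name] = dimer_counts[name] / denom
    return {name: feats[name] for name in FEATURE_NAMES}


def features_frame(rows: list[dict[str, float]]) -> pd.DataFrame:
    """Assemble feature dicts into a DataFrame with the stable column order."""
    return pd.DataFrame(rows, columns=FEATURE_NAMES)


def rank_features(
    X: pd.DataFrame,
    y,
    method: str = "importance",
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Total order over feature columns by predictive contribution.

    method "importance": total-gain importance of a small gradient-boosted
    ensemble (classification if y is binary, else regression).
    method "rfe": recursive feature elimination with the same estimator;
    scores are inverted elimination ranks.

    Returns a DataFrame with columns ``feature`` and ``score``, sorted by
    decreasing score (ties broken by schema order, so constant columns with
    zero score sort last among equals deterministically).
    """
    from xgboost import XGBClassifier, XGBRegressor

    y = np.asarray(y)
    if np.unique(y).size < 2:
        # no signal to rank against
        return pd.DataFrame({"feature": list(X.columns), "score": 0.0})
    is_classif = y.dtype == bool or np.unique(y).size <= 2
    est_cls = XGBClassifier if is_classif else XGBRegressor
    est = est_cls(
        n_estimators=100,
        max_depth=4,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    if is_classif:
        y = y.astype(int)

    if method == "importance":
        est.fit(X, y)
        booster = est.get_booster()
        gain = booster.get_score(importance_type="total_gain")
        scores = np.array([gain.get(c, 0.0) for c in X.columns], dtype=float)
    elif method == "rfe":
        from sklearn.feature_selection import RFE

        rfe = RFE(est, n_features_to_select=1)
        rfe.fit(X, y)
        scores = (len(X.columns) - rfe.ranking_ + 1).astype(float)
    else:
        raise ValueError(f"unknown ranking method {method!r}")

    order = np.lexsort((np.arange(len(X.columns)), -scores))
    return pd.DataFrame(
        {
            "feature": np.asarray(X.columns)[order],
            "score": scores[order],
        }
    ).reset_index(drop=True)
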