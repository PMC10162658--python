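"""Permutation feature importance over peptide positions, and activation
heatmaps of the fusion layer.

The importance procedure follows three steps: shuffle the residues at one
peptide position across all records of a length stratum (other positions
untouched), rescore the shuffled peptides with the trained model, and
report the distance between the baseline AUC and the mean shuffled AUC.
A positive score marks a position the model relies on; scores are signed,
so a shuffle that accidentally helps shows up as negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import metrics as M
from .model import CapsNetMHC, records_to_Xy
from .network import ConfigurationError
from .records import BindingRecord


@dataclass(frozen=True)
class ImportanceScore:
    peptide_length: int
    position: int  # 1-based
    score: float  # baseline AUC - mean shuffled AUC
    n_repeats: int
    dispersion: float  # std of the shuffled-AUC distances over repeats


@dataclass(frozen=True)
class CapsuleHeatmap:
    allele: str
    peptide: str
    values: np.ndarray
    mode: str  # "capsule" | "concat" | "conv"


def permutation_importance(
    model: CapsNetMHC,
    records: Sequence[BindingRecord],
    position: int,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceScore:
    """Importance of one peptide position within a single-length stratum."""
    lengths = {len(r.peptide) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"records must share one peptide length, got {sorted(lengths)}")
    k = lengths.pop()
    if not 1 <= position <= k:
        raise ValueError(f"position must be in 1..{k}, got {position}")
    pairs, _, labels = records_to_Xy(records)
    if len(set(labels)) < 2:
        return ImportanceScore(k, position, float("nan"), n_repeats, float("nan"))
    baseline = M.auc(model.predict(pairs), labels)
    rng = np.random.default_rng(seed)
    column = [p[position - 1] for p, _ in pairs]
    distances = np.empty(n_repeats)
    for rep in range(n_repeats):
        perm = rng.permutation(len(pairs))
        shuffled_pairs = []
        for i, (pep, allele) in enumerate(pairs):
            residues = list(pep)
            residues[position - 1] = column[perm[i]]
            shuffled_pairs.append(("".join(residues), allele))
        distances[rep] = baseline - M.auc(model.predict(shuffled_pairs), labels)
    return ImportanceScore(
        peptide_length=k,
        position=position,
        score=float(distances.mean()),
        n_repeats=n_repeats,
        dispersion=float(distances.std()),
    )


def importance_profile(
    model: CapsNetMHC,
    records: Sequence[BindingRecord],
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(length, position) importance table in heatmap-ready long format.

    Columns: ``length``, ``position``, ``importance``, ``dispersion``,
    ``n_repeats``, ``n_records``; one row per position of every peptide
    length present in ``records``.
    """
    by_length: Dict[int, List[BindingRecord]] = {}
    for r in records:
        by_length.setdefault(len(r.peptide), []).append(r)
    rows = []
    for k in sorted(by_length):
        stratum = by_length[k]
        for pos in range(1, k + 1):
            sc = permutation_importance(
                model, stratum, pos, n_repeats=n_repeats, seed=seed + 1000 * k + pos
            )
            rows.append(
                {
                    "length": k,
                    "position": pos,
                    "importance": sc.score,
                    "dispersion": sc.dispersion,
                    "n_repeats": sc.n_repeats,
                    "n_records": len(stratum),
                }
            )
    return pd.DataFrame(rows)


def top_positions(profile: pd.DataFrame, length: int, n: int = 2) -> List[int]:
    """The n positions with the largest importance for one peptide length."""
    sub = profile[profile["length"] == length].sort_values(
        ["importance", "position"], ascending=[False, True]
    )
    return sub["position"].head(n).tolist()


def capture_heatmap(
    model: CapsNetMHC, peptide: str, allele: str, mode: str = "capsule"
) -> CapsuleHeatmap:
    """Fusion-layer activations for one peptide-allele complex.

    ``capsule``: the J x D matrix of output-capsule components v_j.
    ``concat``: the two flattened branch latents stacked to 40 x 11.
    ``conv``: the final convolutional feature map of the conv-fusion
    baseline.  The model must have been built with the matching fusion
    mode.
    """
    if mode not in ("capsule", "concat", "conv"):
        raise ConfigurationError(f"unknown heatmap mode {mode!r}")
    if model.fusion != mode:
        raise ConfigurationError(
            f"model fusion mode is {model.fusion!r}; cannot capture {mode!r} heatmap"
        )
    peps, mhcs = model._encode_pairs([(peptide, allele)])
    _, captured = model.core_.forward(peps, mhcs, capture=True)
    if mode == "capsule":
        values = captured["routing_state"].v[0]
    elif mode == "concat":
        values = captured["concat_latent"][0].reshape(
            2 * captured["peptide_latent"].shape[1], -1
        )
    else:
        values = captured["conv_feature_map"][0]
    return CapsuleHeatmap(allele=allele, peptide=peptide, values=values, mode=mode)


def routing_state_of(model: CapsNetMHC, peptide: str, allele: str):
    """Full routing internals (u, W, u_hat, b, c, s, v) for one complex."""
    if model.fusion != "capsule":
        raise ConfigurationError("routing state requires capsule fusion")
    peps, mhcs = model._encode_pairs([(peptide, allele)])
    _, captured = model.core_.forward(peps, mhcs, capture=True)
    return captured["routing_state"]
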