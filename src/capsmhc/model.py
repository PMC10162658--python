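"""Scikit-learn-style estimator wrapping the capsule network, plus the
five-fold cross-validation training protocol.

``CapsNetMHC`` follows the sklearn estimator contract: constructor
parameters stored verbatim, ``fit``/``predict``/``score``, fitted
attributes with a trailing underscore, and ``get_params``/``set_params``
inherited from :class:`sklearn.base.BaseEstimator`, so the model composes
with sklearn model selection.  ``X`` is a sequence of ``(peptide, allele)``
pairs (or a DataFrame with ``peptide``/``allele`` columns); ``y`` holds
regression targets in [0, 1] (transformed affinities) or binary labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from . import metrics as M
from ._autodiff import Adam, Tensor
from .encoding import (
    AlleleTable,
    encode_mhc,
    encode_peptide,
    load_substitution_matrix,
    normalize_allele_name,
)
from .network import (
    CapsNetCore,
    CapsuleConfig,
    ConfigurationError,
    NetworkConfig,
    PredictorConfig,
)
from .records import BindingRecord


def _pairs_from_X(X) -> List[Tuple[str, str]]:
    if isinstance(X, pd.DataFrame):
        return list(zip(X["peptide"].astype(str), X["allele"].astype(str)))
    return [(str(p), str(a)) for p, a in X]


class CapsNetMHC(BaseEstimator):
    """Pan-specific peptide-MHC class I binding predictor.

    Parameters
    ----------
    allele_table
        :class:`~capsmhc.encoding.AlleleTable` (or plain dict of allele ->
        MHC sequence) resolving every allele seen in ``X``.
    encoding
        ``"blosum62"`` (default), ``"blosum80"``, or either with a
        ``"-normalized"`` suffix for the min-max-scaled variant.
    fusion
        ``"capsule"`` (dynamic-routing fusion, default), ``"concat"``
        (flat concatenation baseline) or ``"conv"`` (convolutional fusion
        baseline).
    routing
        If False the capsule layer uses uniform couplings throughout (the
        routing-ablated model); ignored for non-capsule fusion.
    loss
        ``"auto"`` picks binary cross-entropy when ``y`` is {0,1} and mean
        squared error otherwise; or force ``"mse"``/``"bce"``.
    """

    def __init__(
        self,
        allele_table=None,
        encoding: str = "blosum62",
        fusion: str = "capsule",
        routing: bool = True,
        routing_iters: int = 3,
        n_capsules: int = 16,
        capsule_dim: int = 16,
        hidden_layers: Tuple[int, int, int] = (128, 64, 32),
        activation: str = "sigmoid",
        loss: str = "auto",
        lr: float = 1e-3,
        epochs: int = 60,
        batch_size: int = 100,
        validation_fraction: float = 0.0,
        patience: int = 20,
        random_state: int = 0,
        verbose: bool = False,
    ):
        self.allele_table = allele_table
        self.encoding = encoding
        self.fusion = fusion
        self.routing = routing
        self.routing_iters = routing_iters
        self.n_capsules = n_capsules
        self.capsule_dim = capsule_dim
        self.hidden_layers = hidden_layers
        self.activation = activation
        self.loss = loss
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ----------------------------------------------------------
    def _table(self) -> AlleleTable:
        if isinstance(self.allele_table, AlleleTable):
            return self.allele_table
        if isinstance(self.allele_table, dict):
            return AlleleTable(self.allele_table)
        raise ConfigurationError("allele_table must be an AlleleTable or dict")

    def _matrix(self):
        name = self.encoding.lower()
        normalized = name.endswith("-normalized")
        if normalized:
            name = name[: -len("-normalized")]
        return load_substitution_matrix(name, normalized=normalized)

    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            capsule=CapsuleConfig(
                n_output_capsules=self.n_capsules,
                output_dim=self.capsule_dim,
                routing_iterations=self.routing_iters,
            ),
            predictor=PredictorConfig(
                hidden_layers=tuple(self.hidden_layers),
                output_activation=self.activation,
            ),
            fusion=self.fusion,
            routing=self.routing,
            seed=self.random_state,
        )

    def _encode_pairs(
        self, pairs: Sequence[Tuple[str, str]]
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Encode peptides per record and MHCs via a per-allele cache.

        Returns (B x 23 x 15 peptide array, B-vector of indices) along with
        the unique-allele MHC array stored on the instance for the call.
        """
        table, matrix = self._table(), self._matrix()
        peps = np.stack([encode_peptide(p, matrix).matrix for p, _ in pairs])
        alleles = [normalize_allele_name(a) for _, a in pairs]
        uniq = sorted(set(alleles))
        mhc_enc = np.stack([encode_mhc(a, table, matrix).matrix for a in uniq])
        idx = np.array([uniq.index(a) for a in alleles])
        return peps, mhc_enc[idx]

    def _resolve_loss(self, y: np.ndarray) -> str:
        if self.loss != "auto":
            return self.loss
        return "bce" if set(np.unique(y)) <= {0.0, 1.0} else "mse"

    @staticmethod
    def _loss_tensor(scores: Tensor, y: np.ndarray, kind: str) -> Tensor:
        if kind == "mse":
            diff = scores - Tensor(y)
            return (diff * diff).mean()
        if kind == "bce":
            eps = 1e-7
            p = scores * (1 - 2 * eps) + eps  # clamp away from {0, 1}
            yt = Tensor(y)
            return -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).mean()
        raise ConfigurationError(f"unknown loss {kind!r}")

    # -- sklearn surface --------------------------------------------------
    def fit(self, X, y):
        pairs = _pairs_from_X(X)
        y = np.asarray(y, dtype=float)
        if len(pairs) != len(y):
            raise ValueError("X and y length mismatch")
        peps, mhcs = self._encode_pairs(pairs)
        loss_kind = self._resolve_loss(y)

        self.core_ = CapsNetCore(self._network_config())
        self.loss_kind_ = loss_kind
        opt = Adam(self.core_.params(), lr=self.lr)
        rng = np.random.default_rng(self.random_state)

        n = len(pairs)
        val_idx = np.array([], dtype=int)
        train_idx = np.arange(n)
        if self.validation_fraction > 0:
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, train_idx = perm[:n_val], perm[n_val:]

        history: List[Dict[str, float]] = []
        best_val = np.inf
        best_state = None
        stall = 0
        for epoch in range(self.epochs):
            order = rng.permutation(train_idx)
            total, count = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                sel = order[start : start + self.batch_size]
                scores, _ = self.core_.forward(peps[sel], mhcs[sel])
                loss = self._loss_tensor(scores, y[sel], loss_kind)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}: {loss.data}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * len(sel)
                count += len(sel)
            entry = {"epoch": epoch, "train_loss": total / max(count, 1)}
            if len(val_idx):
                vs = self._scores_for(peps[val_idx], mhcs[val_idx])
                vloss = float(
                    self._loss_tensor(Tensor(vs), y[val_idx], loss_kind).data
                )
                entry["val_loss"] = vloss
                if vloss < best_val - 1e-6:
                    best_val, stall = vloss, 0
                    best_state = {
                        k: v.copy() for k, v in self.core_.state_arrays().items()
                    }
                else:
                    stall += 1
            history.append(entry)
            if self.verbose:
                print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.5f}" for k, v in entry.items() if k != "epoch"))
            if len(val_idx) and stall >= self.patience:
                break
        if best_state is not None:
            self.core_.load_state_arrays(best_state)
        self.history_ = history
        self.n_features_in_ = 2
        return self

    def _scores_for(self, peps: np.ndarray, mhcs: np.ndarray) -> np.ndarray:
        out = np.empty(len(peps))
        for start in range(0, len(peps), self.batch_size):
            sl = slice(start, start + self.batch_size)
            out[sl] = self.core_.predict_scores(peps[sl], mhcs[sl])
        return out

    def predict(self, X) -> np.ndarray:
        """Binding scores in [0, 1], one per (peptide, allele) pair."""
        if not hasattr(self, "core_"):
            raise RuntimeError("CapsNetMHC instance is not fitted yet")
        pairs = _pairs_from_X(X)
        peps, mhcs = self._encode_pairs(pairs)
        return self._scores_for(peps, mhcs)

    def score(self, X, y) -> float:
        """AUC against binary labels; SRCC against continuous targets."""
        y = np.asarray(y, dtype=float)
        s = self.predict(X)
        if set(np.unique(y)) <= {0.0, 1.0}:
            return M.auc(s, y.astype(int))
        return M.srcc(s, y)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive checkpoint: parameters + full config + seed."""
        if not hasattr(self, "core_"):
            raise RuntimeError("cannot save an unfitted model")
        arrays = self.core_.state_arrays()
        params = {k: v for k, v in self.get_params().items() if k != "allele_table"}
        table = self._table()
        meta = {
            "params": params,
            "alleles": {name: table.sequence(name) for name in table.names()},
            "loss_kind": self.loss_kind_,
        }
        np.savez(path, __config__=np.frombuffer(
            yaml.safe_dump(meta).encode(), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path) -> "CapsNetMHC":
        with np.load(path) as data:
            meta = yaml.safe_load(bytes(data["__config__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__config__"}
        params = meta["params"]
        params["hidden_layers"] = tuple(params["hidden_layers"])
        est = cls(allele_table=AlleleTable(meta["alleles"]), **params)
        est.core_ = CapsNetCore(est._network_config())
        est.core_.load_state_arrays(arrays)
        est.loss_kind_ = meta["loss_kind"]
        est.history_ = []
        return est


# ---------------------------------------------------------------------------
# cross-validation protocol


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (1..k) per record under a seeded shuffle-and-split."""

    fold_index: np.ndarray
    k: int
    seed: int


def make_folds(n_records: int, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Partition record indices into k nearly equal folds (sizes differ <= 1)."""
    if n_records < k:
        raise ConfigurationError(f"need at least {k} records for {k} folds, got {n_records}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_records)
    folds = np.empty(n_records, dtype=int)
    for fold, chunk in enumerate(np.array_split(order, k), start=1):
        folds[chunk] = fold
    return FoldAssignment(fold_index=folds, k=k, seed=seed)


def records_to_Xy(records: Sequence[BindingRecord]) -> Tuple[List[Tuple[str, str]], np.ndarray, np.ndarray]:
    """(peptide, allele) pairs, training targets, and binary labels.

    IC50 measurements are transformed with :func:`~capsmhc.metrics.ic50_to_target`
    and binarized at the 500 nM convention; binary records pass through.
    """
    pairs = [(r.peptide, r.allele) for r in records]
    y = np.empty(len(records))
    labels = np.empty(len(records), dtype=int)
    for i, r in enumerate(records):
        if r.measurement_kind == "ic50":
            y[i] = M.ic50_to_target(r.value)
            labels[i] = M.binarize(r.value)
        else:
            y[i] = float(r.value)
            labels[i] = int(r.value)
    return pairs, y, labels


def _evaluate(scores: np.ndarray, y: np.ndarray, labels: np.ndarray) -> Dict[str, float]:
    counts = M.ConfusionCounts.from_scores(scores, labels, threshold=0.5)
    return {
        "auc": M.auc(scores, labels),
        "srcc": M.srcc(scores, y),
        "accuracy": M.accuracy(counts),
        "sensitivity": M.sensitivity(counts),
        "specificity": M.specificity(counts),
        "precision": M.precision(counts),
        "f1": M.f1(counts),
        "mcc": M.mcc(counts),
    }


def train_with_cv(
    records: Sequence[BindingRecord],
    allele_table,
    estimator_params: Optional[dict] = None,
    k: int = 5,
    seed: int = 0,
    test_records: Optional[Sequence[BindingRecord]] = None,
):
    """Five-fold cross-validation, then a final fit on all training records.

    For each fold the model is fitted on the other k-1 folds and evaluated
    on the held-out fold; the headline numbers are the arithmetic means of
    the per-fold metrics.  If ``test_records`` is given, the final model is
    additionally evaluated on that independent set.

    Returns a dict with ``folds`` (per-fold metric dicts), ``mean``
    (mean-of-folds), ``model`` (the final estimator) and optionally
    ``independent_test``.
    """
    params = dict(estimator_params or {})
    pairs, y, labels = records_to_Xy(records)
    assignment = make_folds(len(records), k=k, seed=seed)
    fold_metrics: List[Dict[str, float]] = []
    for fold in range(1, k + 1):
        held = assignment.fold_index == fold
        est = CapsNetMHC(allele_table=allele_table, random_state=seed + fold, **params)
        est.fit([p for p, h in zip(pairs, held) if not h], y[~held])
        scores = est.predict([p for p, h in zip(pairs, held) if h])
        fold_metrics.append(_evaluate(scores, y[held], labels[held]))
    mean = {
        key: float(np.nanmean([m[key] for m in fold_metrics]))
        for key in fold_metrics[0]
    }
    final = CapsNetMHC(allele_table=allele_table, random_state=seed, **params)
    final.fit(pairs, y)
    result = {"folds": fold_metrics, "mean": mean, "model": final}
    if test_records is not None:
        tp, ty, tl = records_to_Xy(test_records)
        result["independent_test"] = _evaluate(final.predict(tp), ty, tl)
    return result


def evaluate_by_stratum(
    model: CapsNetMHC, records: Sequence[BindingRecord]
) -> pd.DataFrame:
    """Tidy per-(allele, peptide-length) metric table (one row per metric)."""
    pairs, y, labels = records_to_Xy(records)
    scores = model.predict(pairs)
    rows = []
    df = pd.DataFrame(
        {
            "allele": [normalize_allele_name(r.allele) for r in records],
            "length": [len(r.peptide) for r in records],
        }
    )
    for (allele, length), idx in df.groupby(["allele", "length"]).groups.items():
        idx = np.asarray(idx)
        for name, value in _evaluate(scores[idx], y[idx], labels[idx]).items():
            rows.append(
                {
                    "allele": allele,
                    "length": length,
                    "metric": name,
                    "value": value,
                    "n": len(idx),
                }
            )
    return pd.DataFrame(rows)
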