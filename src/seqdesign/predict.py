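"""Sequence design from trained parameters, and the evaluation metrics.

A designed sequence is the per-position argmax of the eval-mode class
probabilities (ties, which are measure-zero in practice, go to the lowest
class index, i.e. alphabetically first amino acid). Evaluation pools a 20×20
confusion matrix over all labelled residues; recall is the diagonal over row
sums, precision the diagonal over column sums, and sequence recovery the
trace over the total. UNKNOWN-labelled residues receive predictions but are
excluded from every metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .featurise import FeatureSet, FEATURE_LAYOUT_VERSION
from .model import ModelParams, forward
from .structure_io import AA1, UNKNOWN

logger = logging.getLogger(__name__)

N_CLASSES = len(AA1)


class IncompatibleFeaturesError(ValueError):
    """Feature layout/width does not match the model's expectations."""


class NothingToEvaluateError(ValueError):
    """No labelled residues available for metric computation."""


@dataclass
class PredictionResult:
    """Per-chain design output: probabilities, sequences and recovery."""

    chain_id: str
    probabilities: np.ndarray  # (L, 20)
    designed_sequence: str
    true_labels: np.ndarray  # (L,) int, 0–19 or UNKNOWN
    residue_ids: list[str]

    @property
    def true_sequence(self) -> str:
        return "".join(
            AA1[lab] if lab != UNKNOWN else "X" for lab in self.true_labels
        )

    @property
    def recovery(self) -> float | None:
        """Fraction of labelled positions designed identically; None if no labels."""
        known = self.true_labels != UNKNOWN
        if not known.any():
            return None
        designed = np.array([AA1.index(ch) for ch in self.designed_sequence])
        return float(np.mean(designed[known] == self.true_labels[known]))


def predict_sequence(params: ModelParams, features: FeatureSet) -> PredictionResult:
    """Design a sequence for one featurised chain.

    Raises :class:`IncompatibleFeaturesError` if the feature width or layout
    version does not match the model config.
    """
    if features.matrix.shape[1] != params.config.input_dim:
        raise IncompatibleFeaturesError(
            f"incompatible features: width {features.matrix.shape[1]} != "
            f"model input_dim {params.config.input_dim}"
        )
    if features.meta.get("layout_version") != FEATURE_LAYOUT_VERSION:
        raise IncompatibleFeaturesError("incompatible features: layout version")
    probs = forward(params, features.matrix, train_mode=False)
    designed = "".join(AA1[i] for i in probs.argmax(axis=1))  # argmax → lowest index
    return PredictionResult(
        chain_id=features.chain_id,
        probabilities=probs,
        designed_sequence=designed,
        true_labels=features.labels.copy(),
        residue_ids=list(features.residue_ids),
    )


def evaluate(predictions: list[PredictionResult]) -> dict:
    """Pooled metrics over a collection of designed chains.

    Returns a dict with the pooled 20×20 ``confusion`` matrix (rows = true
    class, columns = predicted), its row-normalised form ``confusion_rownorm``
    (the empirical probability of each prediction given the true residue),
    per-class ``recall`` and ``precision`` (0 where the denominator is 0),
    pooled ``recovery`` (trace/total) and the ``per_chain_recovery`` mapping.
    """
    trues, preds = [], []
    per_chain = {}
    for result in predictions:
        known = result.true_labels != UNKNOWN
        if known.any():
            designed = np.array([AA1.index(ch) for ch in result.designed_sequence])
            trues.append(result.true_labels[known])
            preds.append(designed[known])
            per_chain[result.chain_id] = result.recovery
    if not trues:
        raise NothingToEvaluateError("nothing to evaluate: no labelled residues")
    y_true = np.concatenate(trues)
    y_pred = np.concatenate(preds)
    confusion = _sk_confusion(y_true, y_pred, labels=np.arange(N_CLASSES))
    row_sums = confusion.sum(axis=1)
    col_sums = confusion.sum(axis=0)
    diag = np.diag(confusion)
    recall = np.divide(diag, row_sums, out=np.zeros(N_CLASSES), where=row_sums > 0)
    precision = np.divide(diag, col_sums, out=np.zeros(N_CLASSES), where=col_sums > 0)
    rownorm = np.divide(
        confusion,
        row_sums[:, None],
        out=np.zeros_like(confusion, dtype=np.float64),
        where=row_sums[:, None] > 0,
    )
    return {
        "confusion": confusion,
        "confusion_rownorm": rownorm,
        "recall": recall,
        "precision": precision,
        "recovery": float(diag.sum() / confusion.sum()),
        "per_chain_recovery": per_chain,
        "n_residues": int(confusion.sum()),
    }


def write_fasta(results: list[PredictionResult], path, model_version: str = "0.1.0") -> None:
    """Write designed sequences as FASTA, 60-column wrapped.

    Header: ``>chainID | model-version | recovery=<x or NA>``.
    """
    if not results:
        logger.warning("write_fasta: empty prediction collection, writing empty file")
    with open(path, "w") as fh:
        for result in results:
            rec = result.recovery
            rec_str = f"{rec:.4f}" if rec is not None else "NA"
            fh.write(f">{result.chain_id} | {model_version} | recovery={rec_str}\n")
            seq = result.designed_sequence
            for start in range(0, len(seq), 60):
                fh.write(seq[start : start + 60] + "\n")
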