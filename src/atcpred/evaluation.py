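"""Metrics and experiment runners.

AUROC is computed as the Mann-Whitney statistic — the probability that a
random positive outscores a random negative, ties counted one half — via
average ranks.  AUPRC is the area under the precision-recall *step* curve
(equivalently, average precision): no trapezoidal interpolation between
operating points, which would be optimistic for precision-recall.

Cross-validation composes the pipeline: balanced negative sampling once,
stratified folds, leakage-masked feature assembly, per-fold training, and
per-fold metrics summarised as mean +/- standard deviation (sample sd,
ddof=1) across folds.  Runner variants cover the feature-combination
ablation, the ATC-similarity-measure comparison and the label-noise
robustness protocol.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import AssociationTable, LabeledPair, make_folds, negative_sample
from .drug_similarity import SimilarityMatrix
from .errors import ValidationError
from .model import FoldResult, ModelConfig, TrainConfig, train

__all__ = [
    "EvalResult",
    "auroc",
    "auprc",
    "cross_validate",
    "feature_combination_study",
    "robustness_study",
    "curve_points",
    "write_results",
]


def _validate_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError(f"scores {scores.shape} and labels {labels.shape} must be equal-length 1-D")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary")
    return scores, labels


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUROC: P(score+ > score-) with ties counted 1/2."""
    scores, labels = _validate_scores(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC needs both classes present")
    ranks = rankdata(scores)  # average ranks resolve ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall step curve (average precision)."""
    scores, labels = _validate_scores(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValidationError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tp = np.cumsum(labels[order] == 1)
    fp = np.cumsum(labels[order] == 0)
    # operating points only where the threshold can actually sit: at the last
    # element of each tied-score run
    boundary = np.nonzero(np.diff(np.append(sorted_scores, -np.inf)))[0]
    precision = tp[boundary] / (tp[boundary] + fp[boundary])
    recall = tp[boundary] / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


@dataclass
class EvalResult:
    """Per-fold AUROC/AUPRC for one experiment, with mean +/- sd summaries."""

    level: int
    tag: str
    fold_auroc: list[float]
    fold_auprc: list[float]
    fold_labels: list[list[int]] = field(default_factory=list, repr=False)
    fold_scores: list[list[float]] = field(default_factory=list, repr=False)

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))

    @property
    def sd_auroc(self) -> float:
        return float(np.std(self.fold_auroc, ddof=1)) if len(self.fold_auroc) > 1 else 0.0

    @property
    def mean_auprc(self) -> float:
        return float(np.mean(self.fold_auprc))

    @property
    def sd_auprc(self) -> float:
        return float(np.std(self.fold_auprc, ddof=1)) if len(self.fold_auprc) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "level": self.level,
            "tag": self.tag,
            "n_folds": len(self.fold_auroc),
            "auroc_mean": self.mean_auroc,
            "auroc_sd": self.sd_auroc,
            "auprc_mean": self.mean_auprc,
            "auprc_sd": self.sd_auprc,
        }


def _score_folds(results: Sequence[FoldResult], level: int, tag: str) -> EvalResult:
    out = EvalResult(level=level, tag=tag, fold_auroc=[], fold_auprc=[])
    for fr in results:
        labels = [p.label for p in fr.test_pairs]
        scores = list(map(float, fr.test_scores))
        out.fold_auroc.append(auroc(scores, labels))
        out.fold_auprc.append(auprc(scores, labels))
        out.fold_labels.append(labels)
        out.fold_scores.append(scores)
    return out


def _permute_labels(pairs: list[LabeledPair], seed: int) -> list[LabeledPair]:
    rng = np.random.default_rng(seed)
    labels = np.array([p.label for p in pairs])
    rng.shuffle(labels)
    return [p._replace(label=int(l)) for p, l in zip(pairs, labels)]


def cross_validate(
    table: AssociationTable,
    drug_sims: Mapping[str, SimilarityMatrix],
    atc_sim: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    n_folds: int = 10,
    seed: int = 0,
    channels: Sequence[str] | None = None,
    tag: str = "cv",
    permute_labels: bool = False,
    perturbation: tuple[float, str] | None = None,
) -> EvalResult:
    """Balanced sampling + stratified k-fold training + per-fold metrics.

    ``permute_labels=True`` shuffles the pair labels once before fold
    splitting — a null control whose AUROC should hover around 0.5.
    ``perturbation=(fraction, mode)`` corrupts training labels per fold (see
    :func:`atcpred.dataset.inject_label_noise`); test labels are never touched.
    """
    pairs = negative_sample(table, seed=seed)
    if permute_labels:
        pairs = _permute_labels(pairs, seed=seed + 1)
    folds = make_folds(pairs, n_folds=n_folds, seed=seed)
    results = train(
        folds, table, drug_sims, atc_sim, model_cfg, train_cfg,
        channels=channels, perturbation=perturbation,
    )
    return _score_folds(results, table.level, tag)


def feature_combination_study(
    subsets: Sequence[Sequence[str]],
    table: AssociationTable,
    drug_sims: Mapping[str, SimilarityMatrix],
    atc_sim: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    n_folds: int = 10,
    seed: int = 0,
) -> list[EvalResult]:
    """One cross-validation per channel subset; the head width adapts."""
    out = []
    for subset in subsets:
        subset = tuple(subset)
        if not subset:
            raise ValidationError("channel subset must be non-empty")
        missing = [ch for ch in subset if ch not in drug_sims]
        if missing:
            raise ValidationError(f"no similarity matrix for channels {missing}")
        out.append(
            cross_validate(
                table, drug_sims, atc_sim, model_cfg, train_cfg,
                n_folds=n_folds, seed=seed, channels=subset, tag="+".join(subset),
            )
        )
    return out


def robustness_study(
    fractions: Sequence[float],
    table: AssociationTable,
    drug_sims: Mapping[str, SimilarityMatrix],
    atc_sim: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    n_folds: int = 10,
    seed: int = 0,
    channels: Sequence[str] | None = None,
) -> list[EvalResult]:
    """Training-label perturbation sweep.

    Negative fractions hide known positives in the negative training set
    (false negatives); positive fractions inject unverified positives (false
    positives); 0 is the unperturbed baseline.  Evaluation labels are never
    perturbed.
    """
    out = []
    for fraction in fractions:
        if abs(fraction) > 0.5:
            raise ValidationError(f"fraction {fraction} outside +/-0.5")
        if fraction == 0:
            perturbation = None
        elif fraction < 0:
            perturbation = (abs(fraction), "false_negative")
        else:
            perturbation = (fraction, "false_positive")
        out.append(
            cross_validate(
                table, drug_sims, atc_sim, model_cfg, train_cfg,
                n_folds=n_folds, seed=seed, channels=channels,
                tag=f"{fraction:+.0%}" if fraction else "baseline",
                perturbation=perturbation,
            )
        )
    return out


def curve_points(labels: Sequence[int], scores: Sequence[float]) -> dict[str, pd.DataFrame]:
    """ROC and PR operating points for plotting, one row per threshold."""
    scores, labels = _validate_scores(scores, labels)
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(labels[order] == 1)
    fp = np.cumsum(labels[order] == 0)
    n_pos, n_neg = int(labels.sum()), int((labels == 0).sum())
    sorted_scores = scores[order]
    boundary = np.nonzero(np.diff(np.append(sorted_scores, -np.inf)))[0]
    roc = pd.DataFrame({
        "threshold": sorted_scores[boundary],
        "fpr": fp[boundary] / max(n_neg, 1),
        "tpr": tp[boundary] / max(n_pos, 1),
    })
    pr = pd.DataFrame({
        "threshold": sorted_scores[boundary],
        "recall": tp[boundary] / max(n_pos, 1),
        "precision": tp[boundary] / (tp[boundary] + fp[boundary]),
    })
    return {"roc": roc, "pr": pr}


def write_results(results: Sequence[EvalResult], json_path, csv_path=None) -> None:
    """Persist results as JSON (per-fold detail) and optionally a flat CSV."""
    payload = [
        {**r.summary(), "fold_auroc": r.fold_auroc, "fold_auprc": r.fold_auprc}
        for r in results
    ]
    Path(json_path).write_text(json.dumps(payload, indent=2))
    if csv_path is not None:
        rows = []
        for r in results:
            for metric, mean, sd in (
                ("auroc", r.mean_auroc, r.sd_auroc),
                ("auprc", r.mean_auprc, r.sd_auprc),
            ):
                rows.append({
                    "experiment": r.tag, "level": r.level, "metric": metric,
                    "mean": mean, "sd": sd,
                })
        pd.DataFrame(rows).to_csv(csv_path, index=False)
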