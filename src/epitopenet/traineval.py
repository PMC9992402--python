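"""Training, evaluation and experiment protocols.

Evaluation uses the four standard binary-classification indices computed
from the confusion matrix:

    Sn  = TP / (TP + FN)                      (sensitivity / recall)
    Sp  = TN / (TN + FP)                      (specificity)
    ACC = (TP + TN) / (TP + FP + TN + FN)     (accuracy)
    MCC = (TP*TN - FP*FN) /
          sqrt((TP+FN)(TN+FN)(TP+FP)(TN+FP))  (Matthews corr. coefficient)

A metric whose denominator is zero is reported as 0 and flagged as
degenerate rather than raising, so fold aggregation stays total.

Protocols: a stratified 80/20 holdout, stratified k-fold cross-validation
(each sample tests the model exactly once), an exhaustive grid over
unordered triples of CNN kernel widths, and per-stage activation export
for t-SNE inspection.  All randomness (weight init, batch order, dropout,
splits, t-SNE) derives from the seed in the model configuration, so every
run is reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace, asdict
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .autograd import Adam, bce_with_logits
from .model import EpitopeClassifier, ModelConfig, forward_with_taps
from .seqio import EncodedBatch, EpitopeRecord, encode_batch

logger = logging.getLogger("epitopenet")

METRIC_COLUMNS = ("Sn", "Sp", "ACC", "MCC")


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN of one evaluation; totals must match sample count."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Sensitivity, specificity, accuracy and MCC, with degeneracy flags."""

    Sn: float
    Sp: float
    ACC: float
    MCC: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive Sn, Sp, ACC and MCC from confusion counts.

    Raises on an empty confusion table; an individual metric with a zero
    denominator is reported as 0 and listed in ``degenerate``.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from an empty confusion table")
    degenerate: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sn = ratio(c.TP, c.TP + c.FN, "Sn")
    sp = ratio(c.TN, c.TN + c.FP, "Sp")
    acc = (c.TP + c.TN) / c.total
    denom = math.sqrt(
        float(c.TP + c.FN) * (c.TN + c.FN) * (c.TP + c.FP) * (c.TN + c.FP)
    )
    if denom == 0:
        degenerate.append("MCC")
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / denom
    return MetricsReport(Sn=sn, Sp=sp, ACC=acc, MCC=mcc, degenerate=tuple(degenerate))


def confusion_from_predictions(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Threshold probabilities (ties go positive) and count the confusion."""
    labels = np.asarray(labels).astype(int)
    calls = (np.asarray(probabilities) >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(((calls == 1) & (labels == 1)).sum()),
        TN=int(((calls == 0) & (labels == 0)).sum()),
        FP=int(((calls == 1) & (labels == 0)).sum()),
        FN=int(((calls == 0) & (labels == 1)).sum()),
    )


def evaluate(
    network: EpitopeClassifier,
    batch: EncodedBatch,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> MetricsReport:
    probs = network.predict_proba(batch)
    return compute_metrics(confusion_from_predictions(labels, probs, threshold))


# -- training --------------------------------------------------------------


class TrainingError(RuntimeError):
    """Training could not proceed (single-class data, diverging loss)."""


def train(
    config: ModelConfig,
    train_batch: EncodedBatch,
    train_labels: np.ndarray,
    valid_batch: Optional[EncodedBatch] = None,
    valid_labels: Optional[np.ndarray] = None,
) -> tuple[EpitopeClassifier, list[dict]]:
    """Train a fresh network by minimizing binary cross-entropy with Adam.

    The per-epoch history records training loss (plus validation loss and
    metrics when a validation set is supplied).  With a validation set,
    training stops early after ``config.patience`` epochs without
    validation-loss improvement and the best-validation weights are
    restored.  Fully reproducible given ``config.seed``.
    """
    labels = np.asarray(train_labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise TrainingError("training labels must contain both classes")
    if (valid_batch is None) != (valid_labels is None):
        raise ValueError("valid_batch and valid_labels must be given together")

    net = EpitopeClassifier(config)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    # independent, seed-derived streams for batch order and dropout
    ss = np.random.SeedSequence(config.seed)
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    n = train_batch.n
    history: list[dict] = []
    best_valid = np.inf
    best_weights = None
    since_best = 0

    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            taps = net.forward(train_batch.codes[idx], train=True, rng=dropout_rng)
            loss = bce_with_logits(taps["logits"], labels[idx])
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry: dict = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if valid_batch is not None:
            vtaps = net.forward(valid_batch.codes)
            vloss = float(
                bce_with_logits(vtaps["logits"], np.asarray(valid_labels)).data
            )
            entry["valid_loss"] = vloss
            entry["valid_metrics"] = evaluate(net, valid_batch, valid_labels)
            if vloss < best_valid - 1e-12:
                best_valid = vloss
                best_weights = net.get_weights()
                since_best = 0
            else:
                since_best += 1
        history.append(entry)
        logger.debug("epoch %d: %s", epoch, entry)
        if valid_batch is not None and since_best >= config.patience:
            logger.info("early stopping at epoch %d", epoch)
            break
    if best_weights is not None:
        net.set_weights(best_weights)
    return net, history


# -- protocols -------------------------------------------------------------


def _split_records(
    records: Sequence[EpitopeRecord], train_fraction: float, seed: int
) -> tuple[list[EpitopeRecord], list[EpitopeRecord]]:
    labels = [rec.label for rec in records]
    if any(l is None for l in labels):
        raise ValueError("all records must be labelled")
    if len(set(labels)) < 2:
        raise TrainingError("records must contain both classes")
    idx = np.arange(len(records))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


def holdout_eval(
    records: Sequence[EpitopeRecord],
    config: ModelConfig,
    train_fraction: float = 0.8,
) -> MetricsReport:
    """Stratified holdout: train on ``train_fraction``, test on the rest."""
    train_recs, test_recs = _split_records(records, train_fraction, config.seed)
    tr_batch, tr_labels = encode_batch(train_recs, config.L)
    te_batch, te_labels = encode_batch(test_recs, config.L)
    net, _ = train(config, tr_batch, tr_labels)
    return evaluate(net, te_batch, te_labels)


@dataclass
class CVReport:
    """Result of one stratified k-fold cross-validation run."""

    k: int
    fold_metrics: list[MetricsReport]
    mean_metrics: MetricsReport
    fold_assignment: dict[str, int]
    config: ModelConfig
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Rows: fold 1..k plus a Mean row; columns Sn, Sp, ACC, MCC."""
        rows = [
            {"fold": str(i + 1), **m.as_dict()}
            for i, m in enumerate(self.fold_metrics)
        ]
        rows.append({"fold": "Mean", **self.mean_metrics.as_dict()})
        return pd.DataFrame(rows)


def _mean_metrics(reports: Sequence[MetricsReport]) -> MetricsReport:
    return MetricsReport(
        **{
            col: float(np.mean([getattr(r, col) for r in reports]))
            for col in METRIC_COLUMNS
        }
    )


def stratified_folds(
    records: Sequence[EpitopeRecord], k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Label-stratified partition into k near-equal folds.

    Returns (train_idx, test_idx) pairs; the test sets are pairwise
    disjoint and cover the dataset.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError("need at least k records")
    labels = np.array([rec.label for rec in records])
    if any(l is None for l in labels):
        raise ValueError("all records must be labelled")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(labels, labels))


def kfold_cv(
    records: Sequence[EpitopeRecord], config: ModelConfig, k: int = 10
) -> CVReport:
    """Stratified k-fold cross-validation with one fresh model per fold.

    The dataset is partitioned into k near-equal, label-stratified folds;
    each fold is tested by a model trained on the other k-1, so every
    sample is used exactly once for testing.  The Mean row is the
    arithmetic mean of the fold metrics.
    """
    folds = stratified_folds(records, k, config.seed)
    fold_metrics: list[MetricsReport] = []
    assignment: dict[str, int] = {}
    for fold, (train_idx, test_idx) in enumerate(folds):
        for i in test_idx:
            assignment[records[i].id] = fold
        tr_batch, tr_labels = encode_batch([records[i] for i in train_idx], config.L)
        te_batch, te_labels = encode_batch([records[i] for i in test_idx], config.L)
        fold_config = replace(config, seed=config.seed + fold + 1)
        net, _ = train(fold_config, tr_batch, tr_labels)
        m = evaluate(net, te_batch, te_labels)
        fold_metrics.append(m)
        logger.info("fold %d/%d: %s", fold + 1, k, m.as_dict())
    return CVReport(
        k=k,
        fold_metrics=fold_metrics,
        mean_metrics=_mean_metrics(fold_metrics),
        fold_assignment=assignment,
        config=config,
        seed=config.seed,
    )


def scale_search(
    records: Sequence[EpitopeRecord],
    config: ModelConfig,
    candidate_widths: Sequence[int] = (7, 9, 11, 13, 15),
) -> tuple[pd.DataFrame, tuple[int, ...]]:
    """Grid-search all unordered triples of CNN kernel widths by holdout.

    Every C(len(candidates), 3) triple of distinct widths is evaluated with
    a stratified 80/20 holdout; the best row maximizes ACC, with ties
    broken by MCC and then by smaller kernels.  Returns the full table and
    the winning triple.
    """
    widths = sorted(set(int(w) for w in candidate_widths))
    if len(widths) < 3:
        raise ValueError("need at least 3 candidate widths")
    if any(w > config.L for w in widths):
        raise ValueError("every candidate width must be <= L")
    rows = []
    for triple in combinations(widths, 3):
        cfg = replace(config, cnn_scales=triple, active_scales=triple)
        m = holdout_eval(records, cfg)
        rows.append(
            {"scale1": triple[0], "scale2": triple[1], "scale3": triple[2],
             **m.as_dict()}
        )
        logger.info("scales %s: %s", triple, m.as_dict())
    table = pd.DataFrame(rows)
    ranked = sorted(
        rows,
        key=lambda r: (-r["ACC"], -r["MCC"], r["scale1"], r["scale2"], r["scale3"]),
    )
    best = (ranked[0]["scale1"], ranked[0]["scale2"], ranked[0]["scale3"])
    return table, best


def export_activations(
    network: EpitopeClassifier,
    batch: EncodedBatch,
    stage: str,
    path: str | Path,
    tsne: bool = False,
    labels: Optional[np.ndarray] = None,
    seed: int = 0,
) -> Optional[pd.DataFrame]:
    """Write per-sample activations at a stage; optionally add 2-D t-SNE.

    The activation table has one row per sample (id + flattened
    activations).  With ``tsne=True`` a second table ``<path>.tsne.tsv``
    holds (id, x, y, label); the t-SNE embedding is seeded and thus
    reproducible.
    """
    act = forward_with_taps(network, batch, stage)
    frame = pd.DataFrame(act, columns=[f"a{i}" for i in range(act.shape[1])])
    frame.insert(0, "id", batch.ids)
    frame.to_csv(path, sep="\t", index=False)
    if not tsne:
        return None
    from sklearn.manifold import TSNE

    perplexity = min(30.0, max(2.0, (act.shape[0] - 1) / 3))
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(act)
    tsne_frame = pd.DataFrame(
        {
            "id": batch.ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "label": labels if labels is not None else [""] * batch.n,
        }
    )
    tsne_frame.to_csv(f"{path}.tsne.tsv", sep="\t", index=False)
    return tsne_frame


def write_report(
    frame: pd.DataFrame, path: str | Path, metadata: Optional[dict] = None
) -> None:
    """Write a TSV report plus a JSON sidecar with run metadata."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
    if metadata is not None:
        sidecar = Path(str(path) + ".meta.json")
        def default(o):
            if isinstance(o, ModelConfig):
                return asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            return str(o)
        sidecar.write_text(json.dumps(metadata, indent=2, default=default))
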