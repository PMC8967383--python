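"""Linear decoding of scene information and trial-wise reactivation scoring.

A linear support vector machine is trained per ROI to distinguish
localizer block patterns of intact versus morphed aversive scenes,
validated with leave-one-block-out cross-validation, and its weight
vector is converted to a forward-model activation pattern (the
covariance-times-weights transformation). Scene evidence for a trial is
the dot product of that pattern with the trial's t-map, a scalar index
of how strongly the trial reactivates scene information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .glm import TrialPatternSet
from .synthetic import ROIMask

logger = logging.getLogger(__name__)

#: class whose decision values are positive by convention
POSITIVE_CLASS = "intact"


@dataclass
class LinearDecoder:
    """Trained linear decoder for one ROI.

    ``w``/``b`` define the decision function d(x) = <w, x> + b with
    d > 0 for the intact-scene class; ``pattern`` is the forward-model
    activation pattern (sample covariance of the training patterns times
    ``w``, unnormalised — every downstream use is a scale-invariant
    contrast). ``valid_voxels`` marks ROI voxels that were finite across
    all training patterns; the rest are dropped from the fit.
    """

    roi: str
    w: np.ndarray
    b: float
    C: float
    classes: tuple[str, str]
    valid_voxels: np.ndarray
    pattern: np.ndarray | None = None
    cv_accuracy: float | None = None
    folds: pd.DataFrame | None = None


def _roi_matrix(patterns: TrialPatternSet, roi: ROIMask) -> np.ndarray:
    roi.validate(patterns.n_voxels)
    return patterns.patterns[:, roi.indices]


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Fit a soft-margin linear SVM; returns (w, b) with d>0 => intact."""
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    # sklearn orients the decision function toward classes_[1]
    if clf.classes_[1] != POSITIVE_CLASS:
        w, b = -w, -b
    return w, b


def train_decoder(
    block_patterns: TrialPatternSet,
    labels: np.ndarray | list,
    roi: ROIMask,
    C: float = 1.0,
    zscore: bool = False,
) -> LinearDecoder:
    """Train a linear SVM on ROI-restricted block patterns.

    Parameters
    ----------
    labels : array of str
        One class per pattern; exactly the two localizer classes.
    C : float
        Soft-margin penalty (default 1, exposed for users).
    zscore : bool
        Optional per-voxel standardisation before fitting (off by
        default; the decoder is trained on raw t-patterns).
    """
    labels = np.asarray(labels)
    if len(labels) != block_patterns.n_trials:
        raise ValueError("one label per pattern required")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError(f"training requires two classes, got only {uniq.tolist()}")
    X = _roi_matrix(block_patterns, roi)
    valid = np.all(np.isfinite(X), axis=0)
    if valid.sum() == 0:
        raise ValueError("no ROI voxel is finite across all training patterns")
    if not valid.all():
        logger.info("train_decoder[%s]: dropping %d undefined voxels", roi.name, (~valid).sum())
    Xv = X[:, valid]
    if zscore:
        mu, sd = Xv.mean(axis=0), Xv.std(axis=0, ddof=0)
        Xv = (Xv - mu) / np.maximum(sd, 1e-12)
    w_v, b = _fit_svm(Xv, labels, C)
    w = np.zeros(X.shape[1])
    w[valid] = w_v
    return LinearDecoder(
        roi=roi.name,
        w=w,
        b=b,
        C=C,
        classes=tuple(sorted(uniq.tolist())),
        valid_voxels=valid,
    )


def cross_validate(
    block_patterns: TrialPatternSet,
    labels: np.ndarray | list,
    roi: ROIMask,
    C: float = 1.0,
    blocks: np.ndarray | None = None,
    scheme: str = "paired",
) -> tuple[float, pd.DataFrame]:
    """Leave-block-out cross-validation accuracy.

    Every block's pattern is scored 0/1 exactly once while held out, so
    the accuracy is a multiple of 1/n_blocks.

    scheme='paired' (default) holds out one block of each class per
    fold (the k-th block of one class with the k-th of the other, in
    presentation order), keeping the training set class-balanced: an
    imbalanced training fold biases a margin classifier against the
    held-out class, which pushes null-data accuracy visibly below
    chance at localizer-sized samples. scheme='loo' is the classical
    leave-one-block-out variant that trains on all blocks but one.
    """
    labels = np.asarray(labels)
    if blocks is None:
        blocks = block_patterns.meta["block"].to_numpy()
    blocks = np.asarray(blocks)
    uniq_blocks = np.unique(blocks)
    if uniq_blocks.size < 3:
        raise ValueError("leave-block-out requires at least 3 blocks")
    classes = np.unique(labels)
    block_class = {b: labels[blocks == b][0] for b in uniq_blocks}
    for cls in classes:
        if np.unique(blocks[labels == cls]).size < 2:
            raise ValueError(f"need at least 2 blocks of class '{cls}'")
    if scheme == "loo":
        fold_sets = [[b] for b in uniq_blocks]
    elif scheme == "paired":
        per_class = {c: [b for b in uniq_blocks if block_class[b] == c] for c in classes}
        n_pairs = min(len(v) for v in per_class.values())
        fold_sets = [
            [per_class[c][k] for c in classes] for k in range(n_pairs)
        ]
        # leftover blocks of the larger class fall back to singleton folds
        for c in classes:
            fold_sets.extend([[b] for b in per_class[c][n_pairs:]])
    else:
        raise ValueError(f"unknown cv scheme: {scheme}")
    X_full = _roi_matrix(block_patterns, roi)
    records = []
    for held_set in fold_sets:
        train = ~np.isin(blocks, held_set)
        X_tr, y_tr = X_full[train], labels[train]
        if np.unique(y_tr).size < 2:
            raise ValueError("a training fold contains a single class")
        valid = np.all(np.isfinite(X_tr), axis=0)
        w, b = _fit_svm(X_tr[:, valid], y_tr, C)
        for i in np.flatnonzero(~train):
            x = X_full[i, valid]
            d = float(np.nansum(w * x) + b)
            pred = POSITIVE_CLASS if d > 0 else next(
                c for c in classes if c != POSITIVE_CLASS
            )
            records.append({"block": blocks[i], "true": labels[i], "pred": pred,
                            "correct": int(pred == labels[i])})
    folds = pd.DataFrame.from_records(records)
    acc = float(folds["correct"].mean())
    return acc, folds


def haufe_transform(decoder: LinearDecoder, training_patterns: TrialPatternSet, roi: ROIMask) -> np.ndarray:
    """Forward-model activation pattern A = Cov(X) @ w.

    Cov(X) is the sample covariance (ddof 1) of the ROI-restricted
    training patterns; the global scale of A is unconstrained and
    irrelevant to the condition contrasts computed downstream. Undefined
    voxels keep NaN in A and are excluded pairwise when scoring.
    """
    X = _roi_matrix(training_patterns, roi)
    if X.shape[0] < 2:
        raise ValueError("covariance requires at least 2 training patterns")
    valid = decoder.valid_voxels
    Xv = X[:, valid]
    cov = np.cov(Xv, rowvar=False, ddof=1)
    A = np.full(X.shape[1], np.nan)
    A[valid] = np.atleast_2d(cov) @ decoder.w[valid]
    decoder.pattern = A
    return A


def score_reactivation(
    template: np.ndarray,
    patterns: TrialPatternSet,
    roi: ROIMask,
    roi_name: str | None = None,
) -> pd.DataFrame:
    """Trial-wise scene evidence: dot product of template and ROI pattern.

    Voxels undefined in either the template or a trial pattern are
    excluded pairwise (count logged per trial); a trial with no finite
    voxel gets NaN evidence and is reported.
    """
    template = np.asarray(template, dtype=float)
    X = _roi_matrix(patterns, roi)
    if template.size != X.shape[1]:
        raise ValueError("template length must match the ROI voxel count")
    prod = X * template[None, :]
    finite = np.isfinite(prod)
    n_used = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        evid = np.where(n_used > 0, np.nansum(np.where(finite, prod, 0.0), axis=1), np.nan)
    n_excluded = X.shape[1] - n_used
    if (n_excluded > 0).any():
        logger.info(
            "score_reactivation[%s]: %d voxel values excluded pairwise",
            roi_name or roi.name, int(n_excluded.sum()),
        )
    if (n_used == 0).any():
        logger.warning(
            "score_reactivation[%s]: %d trials have undefined evidence",
            roi_name or roi.name, int((n_used == 0).sum()),
        )
    out = patterns.meta.copy()
    out["roi"] = roi_name or roi.name
    out["evidence"] = evid
    out["n_voxels_excluded"] = n_excluded
    return out
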