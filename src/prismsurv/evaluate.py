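"""Predictive-performance evaluation by Harrell's C over repeated
censoring-stratified holdouts.

Predictions here are log survival times, so *larger predicted value means
longer survival*: a pair is concordant when the record with the higher
prediction also survives longer. (Risk-score conventions are the mirror
image; compare with care.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines.utils import concordance_index

from .data_model import Dataset
from .stute import FitError
from .tree import TreeConfig, grow

log = logging.getLogger(__name__)

__all__ = ["EvaluationResult", "harrell_c", "stratified_split", "repeated_holdout"]


@dataclass
class EvaluationResult:
    per_repeat_c: np.ndarray
    mean_c: float
    se_c: float
    repeats: int
    train_fraction: float
    skipped: int = 0


def harrell_c(predicted, y, delta) -> float:
    """Harrell's concordance over censoring-usable pairs.

    A pair (i, j) is usable when the smaller observed y belongs to an event;
    prediction ties count 1/2; pairs with tied observed times are excluded
    unless exactly one is an event. Raises ValueError when no pair is usable.
    """
    predicted = np.asarray(predicted, float)
    y = np.asarray(y, float)
    delta = np.asarray(delta)
    if predicted.shape != y.shape or y.shape != delta.shape:
        raise ValueError("harrell_c: length mismatch")
    try:
        return float(concordance_index(y, predicted, event_observed=delta))
    except ZeroDivisionError as e:
        raise ValueError("harrell_c: no usable (comparable) pairs") from e


def stratified_split(delta, train_fraction, rng):
    """Indices for one censoring-stratified train/test split; preserves the
    event/censored mix of each stratum up to integer rounding."""
    delta = np.asarray(delta)
    train, test = [], []
    for val in (0, 1):
        idx = np.flatnonzero(delta == val)
        idx = rng.permutation(idx)
        k = int(round(train_fraction * idx.size))
        train.append(idx[:k])
        test.append(idx[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def repeated_holdout(ds: Dataset, cfg: TreeConfig, repeats: int = 100,
                     train_fraction: float = 0.8, seed: int | None = None
                     ) -> EvaluationResult:
    """Repeat: stratify by censoring status, split 80/20, grow on the training
    set, predict the test set, score with Harrell's C; report the mean and its
    standard error over repeats. Repeats whose training set cannot support a
    root model are skipped (with a warning) and counted."""
    rng = np.random.default_rng(seed)
    cs = []
    skipped = 0
    for rep in range(repeats):
        tr, te = stratified_split(ds.delta, train_fraction, rng)
        try:
            tree = grow(ds.subset(tr), cfg)
        except FitError as e:
            log.warning("repeat %d skipped: %s", rep, e)
            skipped += 1
            continue
        test = ds.subset(te)
        cs.append(harrell_c(tree.predict(test), test.y, test.delta))
    cs = np.asarray(cs)
    if cs.size == 0:
        raise FitError("every holdout repeat failed to fit a root model")
    se = float(cs.std(ddof=1) / np.sqrt(cs.size)) if cs.size > 1 else float("nan")
    return EvaluationResult(per_repeat_c=cs, mean_c=float(cs.mean()), se_c=se,
                            repeats=repeats, train_fraction=train_fraction,
                            skipped=skipped)
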