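"""Classifier scoring with an even random train/test split.

The non-informative class is the positive (detection) class throughout.
Because the term "specificity" is used in more than one way in the blur
detection literature, :func:`metrics` reports both readings explicitly:
``precision_as_paper_specificity`` = tp/(tp+fp) and ``specificity_standard``
= tn/(tn+fp).  Metrics with a zero denominator are reported as ``None``
(undefined) with a warning rather than being coerced to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, TypeVar

import numpy as np

from .dct_detector import INFORMATIVE, NON_INFORMATIVE

__all__ = [
    "ConfusionMatrix",
    "BenchmarkReport",
    "confusion",
    "metrics",
    "split_even_random",
    "run_benchmark",
]

T = TypeVar("T")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for the two-class task with non-informative as positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(predicted: Sequence[str], true: Sequence[str]) -> ConfusionMatrix:
    """Tally a confusion matrix (positive class = non-informative)."""
    if len(predicted) != len(true):
        raise ValueError(
            f"predicted ({len(predicted)}) and true ({len(true)}) labels "
            "must have equal length"
        )
    valid = {INFORMATIVE, NON_INFORMATIVE}
    bad = (set(predicted) | set(true)) - valid
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    tp = fp = fn = tn = 0
    for p, t in zip(predicted, true):
        if p == NON_INFORMATIVE:
            if t == NON_INFORMATIVE:
                tp += 1
            else:
                fp += 1
        else:
            if t == NON_INFORMATIVE:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator)", stacklevel=3)
        return None
    return num / den


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, both specificity readings, accuracy and F-measure.

    ``precision_as_paper_specificity`` is tp/(tp+fp), the quantity some
    reports print under the heading "specificity"; ``specificity_standard``
    is tn/(tn+fp).  ``f_measure`` is the standard F1, the harmonic mean of
    precision and sensitivity.
    """
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    accuracy = _ratio(cm.tp + cm.tn, cm.total, "accuracy")
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f_measure = None
        if precision is not None and sensitivity is not None:
            warnings.warn("f_measure is undefined (zero denominator)", stacklevel=2)
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "sensitivity": sensitivity,
        "precision_as_paper_specificity": precision,
        "specificity_standard": specificity,
        "accuracy": accuracy,
        "f_measure": f_measure,
    }


def split_even_random(items: Sequence[T], seed: int) -> tuple[list[T], list[T]]:
    """Evenly (but randomly) split items into train and test halves.

    A uniformly random permutation under ``seed``; the first half is the
    training set (the extra item goes to train when the count is odd).  The
    halves are disjoint and exhaustive.
    """
    if len(items) < 2:
        raise ValueError("need at least 2 items to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    cut = (len(items) + 1) // 2
    train = [items[i] for i in order[:cut]]
    test = [items[i] for i in order[cut:]]
    return train, test


@dataclass
class BenchmarkReport:
    """Full record of a synthetic benchmark run."""

    n_per_class: int
    seed: int
    n_train: int
    n_test: int
    decision_threshold: float
    train_metrics: dict
    test_metrics: dict
    train_confusion: ConfusionMatrix | None = None
    test_confusion: ConfusionMatrix | None = None
    model: "object | None" = field(default=None, repr=False)

    def to_dict(self) -> dict:
        def cm_dict(cm):
            return None if cm is None else {
                "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
            }

        return {
            "n_per_class": self.n_per_class,
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "decision_threshold": self.decision_threshold,
            "train_metrics": self.train_metrics,
            "test_metrics": self.test_metrics,
            "train_confusion": cm_dict(self.train_confusion),
            "test_confusion": cm_dict(self.test_confusion),
        }


def run_benchmark(
    n_per_class: int,
    seed: int,
    sigma_range: tuple[float, float] = (6.0, 12.0),
    frame_size: int = 256,
    model: "object | None" = None,
) -> BenchmarkReport:
    """Score the DCT detector on a synthetic sharp/blurred frame set.

    Generates ``n_per_class`` sharp endoscopy-like frames and ``n_per_class``
    Gaussian-blurred counterparts (sigma uniform in ``sigma_range``), splits
    the pooled set evenly at random, fits the decision threshold on the
    training half by maximizing F-measure, and reports all metrics on both
    halves (non-informative = positive).
    """
    from .dct_detector import (
        DctDetectorModel,
        classify_frame,
        dct_nonzero_fraction,
        train_decision_threshold,
    )
    from .synthetic import make_informative_frame, make_noninformative_frame

    if n_per_class < 10:
        raise ValueError("n_per_class must be at least 10")
    base = model or DctDetectorModel()
    rng = np.random.default_rng(seed)
    frame_seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    sigmas = rng.uniform(*sigma_range, size=n_per_class)

    fractions: list[float] = []
    labels: list[str] = []
    for i in range(n_per_class):
        sharp, _ = make_informative_frame(
            int(frame_seeds[i]), size=frame_size, n_lumina=1 + i % 3
        )
        fractions.append(dct_nonzero_fraction(sharp, base))
        labels.append(INFORMATIVE)
    for i in range(n_per_class):
        sharp, _ = make_informative_frame(
            int(frame_seeds[n_per_class + i]), size=frame_size, n_lumina=1 + i % 3
        )
        blurred = make_noninformative_frame(sharp, float(sigmas[i]))
        fractions.append(dct_nonzero_fraction(blurred, base))
        labels.append(NON_INFORMATIVE)

    fitted, fit_report = train_decision_threshold(
        fractions, labels, split_seed=seed, base_model=base
    )

    train_idx, test_idx = split_even_random(list(range(len(labels))), seed)
    cms = {}
    for name, idx in (("train", train_idx), ("test", test_idx)):
        pred = [classify_frame(fractions[i], fitted) for i in idx]
        true = [labels[i] for i in idx]
        cms[name] = confusion(pred, true)

    return BenchmarkReport(
        n_per_class=n_per_class,
        seed=seed,
        n_train=fit_report.n_train,
        n_test=fit_report.n_test,
        decision_threshold=fitted.decision_threshold,
        train_metrics=fit_report.train_metrics,
        test_metrics=fit_report.test_metrics or {},
        train_confusion=cms["train"],
        test_confusion=cms["test"],
        model=fitted,
    )
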