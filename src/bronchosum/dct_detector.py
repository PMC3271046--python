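"""Non-informative frame detection via DCT spectral sparsity.

Blurred (non-informative) endoscopy frames have few edges, so their energy
concentrates in the low-order harmonics of the 2-D discrete cosine transform;
sharp (informative) frames spread energy across the spectrum.  A frame is
scored by the fraction of DCT coefficients whose magnitude survives a fixed
cutoff (default 20), and classified informative when that fraction reaches a
trainable decision threshold.

Convention: a single full-image orthonormal (``norm='ortho'``) 2-D DCT-II is
taken on the 0-255 luminance after bilinear resize to a fixed square working
size, so the magnitude cutoff and the fractional count are both independent
of the camera resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.fft
from skimage.transform import resize

from .frame_io import Frame

__all__ = [
    "INFORMATIVE",
    "NON_INFORMATIVE",
    "DctDetectorModel",
    "ThresholdTrainingReport",
    "dct_nonzero_fraction",
    "classify_frame",
    "train_decision_threshold",
]

INFORMATIVE = "informative"
NON_INFORMATIVE = "non_informative"


@dataclass(frozen=True)
class DctDetectorModel:
    """Parameters of the DCT sparsity classifier.

    magnitude_threshold
        Coefficient-magnitude cutoff below which DCT coefficients are zeroed
        (default 20, selected experimentally for precision/recall and easily
        re-tuned for custom sensitivity demands).
    decision_threshold
        Fraction of surviving coefficients at or above which a frame is
        called informative.  Trained with :func:`train_decision_threshold`.
    working_size
        Square side length frames are resized to before the transform.
    """

    magnitude_threshold: float = 20.0
    decision_threshold: float = 0.5
    working_size: int = 256

    def __post_init__(self) -> None:
        if self.magnitude_threshold <= 0:
            raise ValueError("magnitude_threshold must be positive")
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must lie in [0, 1]")
        if self.working_size < 8:
            raise ValueError("working_size must be at least 8")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "magnitude_threshold": self.magnitude_threshold,
                    "decision_threshold": self.decision_threshold,
                    "working_size": self.working_size,
                },
                fh,
                indent=1,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DctDetectorModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            magnitude_threshold=float(doc["magnitude_threshold"]),
            decision_threshold=float(doc["decision_threshold"]),
            working_size=int(doc["working_size"]),
        )


def dct_nonzero_fraction(frame: Frame, model: DctDetectorModel) -> float:
    """Fraction of DCT coefficients surviving the magnitude cutoff.

    The luminance is bilinearly resized to ``working_size`` square, the
    orthonormal 2-D DCT-II is computed, coefficients with magnitude below
    ``magnitude_threshold`` are set to zero, and the count of non-zero
    elements divided by ``working_size**2`` is returned.
    """
    px = frame.pixels
    n = model.working_size
    if px.shape != (n, n):
        px = resize(
            px, (n, n), order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    coeffs = scipy.fft.dctn(px, type=2, norm="ortho")
    nonzero = int(np.count_nonzero(np.abs(coeffs) >= model.magnitude_threshold))
    return nonzero / (n * n)


def classify_frame(fraction: float, model: DctDetectorModel) -> str:
    """Label a frame from its non-zero-DCT fraction.

    Informative iff ``fraction >= decision_threshold`` (a fraction exactly at
    the threshold counts as informative).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    return INFORMATIVE if fraction >= model.decision_threshold else NON_INFORMATIVE


@dataclass
class ThresholdTrainingReport:
    """Outcome of a decision-threshold fit."""

    decision_threshold: float
    n_train: int
    n_test: int
    train_metrics: dict
    test_metrics: dict | None = None
    candidates_evaluated: int = 0


def _f_measure_at(threshold: float, fractions: np.ndarray, positive: np.ndarray) -> float:
    # positive class = non-informative = fraction below threshold
    pred_pos = fractions < threshold
    tp = int(np.sum(pred_pos & positive))
    fp = int(np.sum(pred_pos & ~positive))
    fn = int(np.sum(~pred_pos & positive))
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def train_decision_threshold(
    fractions: Sequence[float],
    labels: Sequence[str],
    split_seed: int | None = None,
    base_model: DctDetectorModel | None = None,
) -> tuple[DctDetectorModel, ThresholdTrainingReport]:
    """Fit the decision threshold by maximizing F-measure.

    Candidate thresholds are 0, 1, and the midpoints between consecutive
    distinct sorted fractions; the candidate maximizing F-measure with
    non-informative as the positive class is chosen, ties broken toward the
    larger threshold.

    When ``split_seed`` is given the data are first evenly (but randomly)
    split; the fit uses the training half and the report additionally carries
    held-out test metrics.  When ``split_seed`` is None all provided examples
    form the training set.
    """
    from .evaluation import confusion, metrics, split_even_random

    fractions = np.asarray(fractions, dtype=np.float64)
    labels = list(labels)
    if len(fractions) != len(labels):
        raise ValueError("fractions and labels must have equal length")
    bad = set(labels) - {INFORMATIVE, NON_INFORMATIVE}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")

    if split_seed is not None:
        train_idx, test_idx = split_even_random(list(range(len(labels))), split_seed)
    else:
        train_idx, test_idx = list(range(len(labels))), []

    train_frac = fractions[train_idx]
    train_pos = np.array([labels[i] == NON_INFORMATIVE for i in train_idx])
    for cls, present in ((NON_INFORMATIVE, train_pos.any()),
                         (INFORMATIVE, (~train_pos).any())):
        if not present:
            raise ValueError(f"training data contains no {cls} examples")

    distinct = np.unique(train_frac)
    candidates = [0.0] + list((distinct[:-1] + distinct[1:]) / 2.0) + [1.0]
    best_t, best_f = 0.0, -1.0
    for t in candidates:
        f = _f_measure_at(t, train_frac, train_pos)
        if f >= best_f:  # >= breaks ties toward the larger threshold
            best_t, best_f = t, f

    base = base_model or DctDetectorModel()
    model = DctDetectorModel(
        magnitude_threshold=base.magnitude_threshold,
        decision_threshold=best_t,
        working_size=base.working_size,
    )

    def _metrics(idx: list[int]) -> dict:
        pred = [classify_frame(fractions[i], model) for i in idx]
        true = [labels[i] for i in idx]
        return metrics(confusion(pred, true))

    report = ThresholdTrainingReport(
        decision_threshold=best_t,
        n_train=len(train_idx),
        n_test=len(test_idx),
        train_metrics=_metrics(train_idx),
        test_metrics=_metrics(test_idx) if test_idx else None,
        candidates_evaluated=len(candidates),
    )
    return model, report
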