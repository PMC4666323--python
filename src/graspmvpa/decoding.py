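"""Leave-pair-out cross-validated linear SVM decoding.

Each cross-validation fold holds out one sample per class (a "modified
leave-one-out"); the classifier is a soft-margin linear SVM with C = 1 and
no internal feature scaling.  Accuracy is the proportion of correct test
predictions across the whole loop.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .sampling import ClassificationSpec, MiniblockSamples, SampleSet, select_classification

logger = logging.getLogger(__name__)


class LinearDecision:
    """Fitted linear decision function f(x) = w . x + b; sign predicts the class.

    A decision value of exactly 0 predicts the positive class (documented
    tie-break; a measure-zero event for continuous data).
    """

    def __init__(self, svc: SVC):
        self._svc = svc

    @property
    def weights(self) -> np.ndarray:
        return self._svc.coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self._svc.intercept_[0])

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(np.atleast_2d(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) >= 0, 1, -1)


def train_linear_svm(X: np.ndarray, T: Sequence[int], C: float = 1.0) -> LinearDecision:
    """Fit the standard C-SVM with a linear kernel (C = 1 by default)."""
    T = np.asarray(T, dtype=int)
    if len(np.unique(T)) < 2:
        raise ValueError("training labels contain a single class")
    svc = SVC(kernel="linear", C=C)
    svc.fit(np.atleast_2d(X), T)
    return LinearDecision(svc)


@dataclass(frozen=True)
class DecodingResult:
    subject: str
    roi: str
    hemisphere: str
    classification: str
    accuracy: float
    n_folds: int
    n_samples: int


def leave_pair_out_cv(
    samples: SampleSet,
    C: float = 1.0,
    pairing: str = "chronological",
    rng: np.random.Generator | int | None = None,
) -> DecodingResult:
    """Hold out one sample per class per fold; accuracy over all held-out pairs.

    ``pairing="chronological"`` pairs the k-th positive with the k-th
    negative sample in (run, miniblock) order; ``"random"`` permutes the
    negative order with the supplied seed.  Classes must be balanced.
    """
    n_pos, n_neg = samples.class_counts
    if n_pos != n_neg:
        raise ValueError(
            f"leave-pair-out requires balanced classes (got {n_pos} vs {n_neg})"
        )
    order = np.lexsort(
        (samples.meta["miniblock_id"].to_numpy(), samples.meta["run"].to_numpy())
    )
    pos_idx = [i for i in order if samples.T[i] == 1]
    neg_idx = [i for i in order if samples.T[i] == -1]
    if pairing == "random":
        g = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        neg_idx = list(g.permutation(neg_idx))
    elif pairing != "chronological":
        raise ValueError(f"unknown pairing strategy {pairing!r}")

    n = samples.n_samples
    correct = 0
    for p, q in zip(pos_idx, neg_idx):
        train = np.setdiff1d(np.arange(n), [p, q])
        clf = train_linear_svm(samples.X[train], samples.T[train], C=C)
        pred = clf.predict(samples.X[[p, q]])
        correct += int(pred[0] == samples.T[p]) + int(pred[1] == samples.T[q])
    return DecodingResult(
        subject=samples.subject,
        roi=samples.roi,
        hemisphere=samples.hemisphere,
        classification=samples.classification,
        accuracy=correct / (2 * n_pos),
        n_folds=n_pos,
        n_samples=n,
    )


def decode_all(
    samplesets: Mapping[tuple[str, str, str], MiniblockSamples],
    classifications: Iterable[ClassificationSpec],
    C: float = 1.0,
    pairing: str = "chronological",
) -> tuple[pd.DataFrame, list[dict]]:
    """Decode every (subject, ROI, hemisphere, classification) cell.

    ``samplesets`` maps (subject, roi, hemisphere) to mini-block samples.
    Cells missing from the full subject x ROI grid, or failing (e.g. on an
    absent condition), are logged and returned in the gap report instead of
    aborting the table.
    """
    classifications = list(classifications)
    subjects = sorted({k[0] for k in samplesets})
    roi_cells = sorted({(k[1], k[2]) for k in samplesets})
    rows = []
    gaps: list[dict] = []
    for subject in subjects:
        for roi, hemi in roi_cells:
            key = (subject, roi, hemi)
            if key not in samplesets:
                gaps.append({"subject": subject, "roi": roi, "hemisphere": hemi,
                             "classification": "*", "reason": "missing sampleset"})
                logger.warning("missing sampleset for %s / %s / %s", *key)
                continue
            for cspec in classifications:
                try:
                    sset = select_classification(samplesets[key], cspec)
                    res = leave_pair_out_cv(sset, C=C, pairing=pairing)
                except ValueError as exc:
                    gaps.append({"subject": subject, "roi": roi, "hemisphere": hemi,
                                 "classification": cspec.name, "reason": str(exc)})
                    logger.warning("skipping %s/%s/%s/%s: %s",
                                   subject, roi, hemi, cspec.name, exc)
                    continue
                rows.append(res.__dict__)
    return pd.DataFrame(rows), gaps
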