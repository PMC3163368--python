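"""Train/test splitting and classifier performance metrics.

The split is a uniform random 80/20 partition with the training size
computed by round-half-up of fraction*n (216 samples -> 173 training,
43 test).  Metrics are the
standard trio — accuracy A = 100*(1 - N_e/N_b) where N_e is the number of
classification errors and N_b the number of items classified, sensitivity
Se = T_p/(T_p+F_N) and specificity Sp = T_n/(T_n+F_p) with the cancer
class as positive.  Undefined metrics (empty denominator) raise
:class:`~seldiclass.errors.UndefinedMetricError` rather than silently
returning 0 or NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, UndefinedMetricError
from .spectra import CANCER, CONTROL


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf.

    A small epsilon guards against binary representation of values such
    as 5.6 landing just below the true half point.
    """
    return int(math.floor(x + 0.5 + 1e-9))


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test sample-id partition."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float
    seed: int


def split(
    ids: Sequence[str],
    fraction: float = 0.8,
    seed: int = 0,
    stratify_labels: Mapping[str, str] | None = None,
) -> SplitPlan:
    """Uniform random train/test split without replacement.

    The training size is round-half-up(fraction * n).  With
    ``stratify_labels`` the same rounding applies within each class so
    class proportions carry over to both halves.  Reproducible under
    ``seed``; raises if either half would be empty.
    """
    ids = [str(i) for i in ids]
    n = len(ids)
    if n < 2:
        raise DataError("need at least 2 ids to split")
    if not (0.0 < fraction < 1.0):
        raise ConfigError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        n_train = round_half_up(fraction * n)
        if n_train == 0 or n_train == n:
            raise DataError(
                f"fraction {fraction} leaves an empty train or test half for n={n}"
            )
        perm = rng.permutation(n)
        train = [ids[i] for i in sorted(perm[:n_train])]
        test = [ids[i] for i in sorted(perm[n_train:])]
    else:
        train, test = [], []
        for cls in sorted({stratify_labels[i] for i in ids}):
            members = [i for i in ids if stratify_labels[i] == cls]
            k = round_half_up(fraction * len(members))
            perm = rng.permutation(len(members))
            train.extend(members[i] for i in sorted(perm[:k]))
            test.extend(members[i] for i in sorted(perm[k:]))
        if not train or not test:
            raise DataError(
                f"fraction {fraction} leaves an empty train or test half"
            )
    return SplitPlan(tuple(train), tuple(test), fraction, seed)


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts with the derived performance metrics.

    ``tp`` counts cancer samples called cancer, ``fp`` controls called
    cancer, ``fn`` cancers called control, ``tn`` controls called control.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_b(self) -> int:
        """Total items classified."""
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_e(self) -> int:
        """Total classification errors."""
        return self.fp + self.fn

    @property
    def accuracy_pct(self) -> float:
        return accuracy(self.n_e, self.n_b)

    @property
    def sensitivity(self) -> float:
        return sensitivity(self)

    @property
    def specificity(self) -> float:
        return specificity(self)

    def to_frame(self) -> pd.DataFrame:
        def metric(fn):
            try:
                return fn()
            except UndefinedMetricError:
                return float("nan")

        return pd.DataFrame(
            [
                {
                    "tp": self.tp,
                    "fp": self.fp,
                    "fn": self.fn,
                    "tn": self.tn,
                    "n_b": self.n_b,
                    "n_e": self.n_e,
                    "accuracy_pct": metric(lambda: self.accuracy_pct),
                    "sensitivity": metric(lambda: self.sensitivity),
                    "specificity": metric(lambda: self.specificity),
                }
            ]
        )


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive_class: str = CANCER,
) -> EvaluationReport:
    """Tally the confusion counts with cancer as the positive class."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise DataError(
            f"{len(true_labels)} true labels vs {len(predicted_labels)} predictions"
        )
    for lab in (*true_labels, *predicted_labels):
        if lab not in (CANCER, CONTROL):
            raise DataError(f"unknown class label {lab!r}")
    tp = fp = fn = tn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return EvaluationReport(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy(n_e: int, n_b: int) -> float:
    """Overall accuracy A = 100 * (1 - N_e/N_b), as a percentage."""
    if n_b < 1:
        raise UndefinedMetricError("accuracy undefined for N_b = 0")
    if not (0 <= n_e <= n_b):
        raise DataError(f"need 0 <= N_e <= N_b, got N_e={n_e}, N_b={n_b}")
    return 100.0 * (1.0 - n_e / n_b)


def sensitivity(report: EvaluationReport) -> float:
    """Se = T_p / (T_p + F_N): fraction of true cancers called cancer."""
    denom = report.tp + report.fn
    if denom < 1:
        raise UndefinedMetricError("sensitivity undefined: no positive-class items")
    return report.tp / denom


def specificity(report: EvaluationReport) -> float:
    """Sp = T_n / (T_n + F_p): fraction of true controls cleared."""
    denom = report.tn + report.fp
    if denom < 1:
        raise UndefinedMetricError("specificity undefined: no negative-class items")
    return report.tn / denom
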