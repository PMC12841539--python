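"""Intact/damaged kernel classification with support vector machines.

The classifier operates on the 8-dimensional shape-descriptor vectors and
supports three kernel functions:

- linear:      K(x1, x2) = x1 . x2
- RBF:         K(x1, x2) = exp(-gamma * ||x1 - x2||^2), default gamma 0.1
- polynomial:  K(x1, x2) = (gamma * x1 . x2 + r)^d, default degree 3

Features span four orders of magnitude (area ~8000 px^2 vs eccentricity
~0.5), so per-feature standardization (fit on the training set only) is on
by default; RBF distances are meaningless otherwise. The margin optimizer is
scikit-learn's SVC; the feature protocol, kernel configuration and label
conventions here are what make it a damage detector. Damaged is the positive
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FEATURE_NAMES, KernelRecord

__all__ = ["SvmConfig", "SvmModel", "kernel_value", "fit", "predict"]

INTACT, DAMAGED = "intact", "damaged"
_KERNEL_MAP = {"linear": "linear", "rbf": "rbf", "polynomial": "poly"}


@dataclass(frozen=True)
class SvmConfig:
    """Kernel choice and hyperparameters of the damage classifier."""

    kernel: str = "rbf"
    gamma: float = 0.1
    coef_r: float = 1.0  # inhomogeneous polynomial offset
    degree: int = 3
    C: float = 1.0
    standardize: bool = True

    def __post_init__(self):
        if self.kernel not in _KERNEL_MAP:
            raise ValueError(f"kernel must be one of {sorted(_KERNEL_MAP)}")
        if self.kernel in ("rbf", "polynomial") and self.gamma <= 0:
            raise ValueError("gamma must be positive for rbf/polynomial kernels")
        if self.degree < 1 or int(self.degree) != self.degree:
            raise ValueError("degree must be a positive integer")
        if self.C <= 0:
            raise ValueError("C must be positive")


def kernel_value(x1, x2, config: SvmConfig) -> float:
    """Evaluate the configured kernel function on two feature vectors."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError("vectors must have equal length")
    if config.kernel == "linear":
        return float(x1 @ x2)
    if config.kernel == "rbf":
        return float(np.exp(-config.gamma * np.sum((x1 - x2) ** 2)))
    return float((config.gamma * (x1 @ x2) + config.coef_r) ** config.degree)


def _as_matrix(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return records.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    if len(records) == 0:
        return np.empty((0, len(FEATURE_NAMES)))
    if isinstance(records[0], KernelRecord):
        return np.stack([r.vector() for r in records])
    return np.asarray(records, dtype=np.float64)


@dataclass
class SvmModel:
    """A fitted classifier: config, standardization constants and the SVC."""

    config: SvmConfig
    offset: np.ndarray
    scale: np.ndarray
    svc: SVC = field(repr=False)

    def _transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.offset) / self.scale

    def decision_function(self, records) -> np.ndarray:
        x = _as_matrix(records)
        if x.shape[0] == 0:
            return np.empty(0)
        return self.svc.decision_function(self._transform(x))

    def predict(self, records) -> list[str]:
        x = _as_matrix(records)
        if x.shape[0] == 0:
            return []
        y = self.svc.predict(self._transform(x))
        return [DAMAGED if v > 0 else INTACT for v in y]


def fit(records, config: SvmConfig | None = None, labels=None) -> SvmModel:
    """Train the damage classifier.

    ``records`` is a DataFrame with the 8 feature columns and a ``label``
    column, a list of labelled :class:`KernelRecord`, or a feature matrix
    with ``labels`` given separately. Deterministic for fixed inputs.
    """
    config = config or SvmConfig()
    x = _as_matrix(records)
    if labels is None:
        if isinstance(records, pd.DataFrame):
            labels = records["label"].tolist()
        else:
            labels = [r.label for r in records]
    y = np.array([1 if str(l) == DAMAGED else -1 for l in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    if config.standardize:
        offset = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        offset = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
    svc = SVC(
        kernel=_KERNEL_MAP[config.kernel],
        gamma=config.gamma if config.kernel != "linear" else "scale",
        coef0=config.coef_r,
        degree=config.degree,
        C=config.C,
    )
    svc.fit((x - offset) / scale, y)
    return SvmModel(config=config, offset=offset, scale=scale, svc=svc)


def predict(model: SvmModel, records) -> list[str]:
    """Label each record 'intact' or 'damaged' (decision threshold at 0)."""
    return model.predict(records)
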