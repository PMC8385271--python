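"""Reference classifiers on flattened spectrograms.

The comparison models mirror common practice: an RBF-kernel support vector
machine with penalty C = 1.0 and an L2-regularized logistic regression with
C = 1.0, both applied to spectrograms flattened to 31*56 = 1736-length
vectors (all other settings at library defaults). Both fits are
deterministic given fixed inputs.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = ["fit_baselines", "flatten_spectrograms"]


def flatten_spectrograms(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    return X.reshape(X.shape[0], -1)


def fit_baselines(X: np.ndarray, y: np.ndarray) -> dict:
    """Fit the SVM and LR baselines; returns ``{"svm": ..., "lr": ...}``."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    Xf = flatten_spectrograms(X)
    svm = SVC(C=1.0, kernel="rbf").fit(Xf, y)
    lr = LogisticRegression(C=1.0, max_iter=1000).fit(Xf, y)  # l2 default
    return {"svm": svm, "lr": lr}
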