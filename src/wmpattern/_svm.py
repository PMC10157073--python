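"""Thin fast wrapper around scikit-learn's libsvm binding.

The nested cross-validation engine fits hundreds of thousands of tiny
(n < 30) linear C-SVC problems during wrapper selection and permutation
testing. The public ``sklearn.svm.SVC`` estimator spends ~99% of its time
in per-fit validation at this problem size, so the engine calls the
low-level libsvm `fit` directly and recovers the primal weight vector as
w = dual_coef @ support_vectors.

Orientation: with ±1 targets, libsvm orients its decision function toward
its internally first class, which is the opposite of the scikit-learn
convention (decision > 0 => class +1); the wrapper therefore negates
(w, b). The equivalence with ``sklearn.svm.SVC`` is asserted by a
dedicated property test.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import _libsvm as libsvm

libsvm.set_verbosity_wrap(0)


def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float,
                   tol: float = 1e-3) -> tuple[np.ndarray, float]:
    """Fit a linear C-SVC; return (weights, bias) with +1 on the positive side.

    ``X`` must be float64; ``y`` must contain both of {+1, -1}. The fit is
    deterministic for fixed input (libsvm SMO has no random component).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes do not match")
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("training fold contains a single class")
    _, sv, _, sv_coef, intercept, *_ = libsvm.fit(
        X, y, svm_type=0, kernel="linear", C=float(C), tol=tol)
    w = -(sv_coef @ sv).ravel()
    b = -float(intercept[0])
    return w, b
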