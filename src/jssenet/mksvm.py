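"""Multi-kernel support vector machine on precomputed linear kernels.

Each feature modality m (connection weights, global metrics, nodal metrics)
contributes a linear Gram matrix K_m; the classifier kernel is the convex
combination sum_m beta_m K_m with beta on the unit simplex.  Training solves
the usual box-constrained SVM dual

    max_alpha  sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K(i, j)
    s.t.       sum_i alpha_i y_i = 0,   0 <= alpha_i <= C

by sequential minimal optimization with maximal-violating-pair working-set
selection; the bias b comes from the KKT conditions averaged over free
support vectors.  The decision value for a test point is
sum_i y_i alpha_i sum_m beta_m k_m(x_i, x) + b, and the predicted label its
sign (ties toward +1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-12


def linear_kernel(X_a: np.ndarray, X_b: np.ndarray | None = None) -> np.ndarray:
    """Gram matrix of inner products between rows of X_a and X_b."""
    X_a = np.atleast_2d(np.asarray(X_a, dtype=np.float64))
    X_b = X_a if X_b is None else np.atleast_2d(np.asarray(X_b, dtype=np.float64))
    if X_a.shape[1] != X_b.shape[1]:
        raise ValueError(f"feature dimension mismatch: {X_a.shape[1]} vs {X_b.shape[1]}")
    return X_a @ X_b.T


@dataclass(frozen=True)
class KernelSet:
    """Per-modality Gram matrices over a common sample ordering."""

    grams: tuple[np.ndarray, ...]
    sample_ids: tuple = ()

    def __post_init__(self) -> None:
        for g in self.grams:
            if g.ndim != 2 or g.shape[0] != g.shape[1]:
                raise ValueError("each Gram matrix must be square")
            if np.max(np.abs(g - g.T)) > 1e-9 * max(1.0, np.max(np.abs(g))):
                raise ValueError("Gram matrix is not symmetric")

    @property
    def n_modalities(self) -> int:
        return len(self.grams)


def combine_kernels(grams, beta) -> np.ndarray:
    """Convex combination sum_m beta_m K_m of per-modality Grams."""
    beta = np.asarray(beta, dtype=np.float64)
    grams = list(grams.grams) if isinstance(grams, KernelSet) else list(grams)
    if beta.ndim != 1 or beta.size != len(grams):
        raise ValueError("one weight per kernel required")
    if np.any(beta < 0):
        raise ValueError("kernel weights must be nonnegative")
    if abs(beta.sum() - 1.0) > 1e-8:
        raise ValueError("kernel weights must sum to 1")
    out = np.zeros_like(np.asarray(grams[0], dtype=np.float64))
    for w, g in zip(beta, grams):
        if w:
            out += w * np.asarray(g, dtype=np.float64)
    return out


def simplex_grid(m: int, step: float = 0.1) -> list[tuple[float, ...]]:
    """All weight vectors on the unit simplex with coordinates in step multiples."""
    k = round(1.0 / step)
    if abs(k * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    out = []
    for combo in product(range(k + 1), repeat=m - 1):
        if sum(combo) <= k:
            rest = k - sum(combo)
            out.append(tuple(c / k for c in combo) + (rest / k,))
    return sorted(out)


@dataclass
class MKSVMModel:
    alpha: np.ndarray
    b: float
    beta: np.ndarray
    C: float
    y: np.ndarray
    support_ids: np.ndarray
    sample_ids: tuple = ()

    def check_invariants(self, tol: float = 1e-8) -> None:
        if np.any(self.alpha < -tol) or np.any(self.alpha > self.C + tol):
            raise AssertionError("dual coefficients escape the box [0, C]")
        if abs(float(self.alpha @ self.y)) > max(tol, 1e-8 * self.C * len(self.y)):
            raise AssertionError("equality constraint sum alpha_i y_i = 0 violated")
        if np.any(self.beta < 0) or abs(self.beta.sum() - 1.0) > 1e-8:
            raise AssertionError("kernel weights must be a point on the simplex")

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha.tolist(),
            "b": self.b,
            "beta": self.beta.tolist(),
            "C": self.C,
            "y": self.y.tolist(),
            "support_ids": self.support_ids.tolist(),
            "sample_ids": list(self.sample_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "MKSVMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            alpha=np.asarray(d["alpha"], dtype=np.float64),
            b=float(d["b"]),
            beta=np.asarray(d["beta"], dtype=np.float64),
            C=float(d["C"]),
            y=np.asarray(d["y"], dtype=np.float64),
            support_ids=np.asarray(d["support_ids"], dtype=np.int64),
            sample_ids=tuple(d["sample_ids"]),
        )


def _smo_core(K, y, C, tol, max_iter):  # pragma: no cover - numba replaces this
    """Maximal-violating-pair SMO on a precomputed kernel.

    Minimizes f(alpha) = 1/2 alpha' Q alpha - 1' alpha with Q = (y y') * K
    under the box and equality constraints.  Returns (alpha, grad).
    """
    n = y.size
    alpha = np.zeros(n)
    grad = -np.ones(n)  # d/dalpha of 1/2 a'Qa - 1'a at a = 0
    Qi = np.empty(n)
    Qj = np.empty(n)
    for _ in range(max_iter):
        # second-order working-set selection: i maximizes the KKT violation,
        # j maximizes the guaranteed objective decrease along the pair
        m_up = -np.inf
        m_low = np.inf
        i = -1
        for t in range(n):
            v = -y[t] * grad[t]
            if (y[t] > 0 and alpha[t] < C - _EPS) or (y[t] < 0 and alpha[t] > _EPS):
                if v > m_up:
                    m_up = v
                    i = t
            if (y[t] > 0 and alpha[t] > _EPS) or (y[t] < 0 and alpha[t] < C - _EPS):
                if v < m_low:
                    m_low = v
        if i < 0 or m_up - m_low < tol:
            break
        j = -1
        best_gain = 0.0
        for t in range(n):
            if (y[t] > 0 and alpha[t] > _EPS) or (y[t] < 0 and alpha[t] < C - _EPS):
                diff = m_up + y[t] * grad[t]  # m_up - (-y_t grad_t)
                if diff > 0:
                    a_it = K[i, i] + K[t, t] - 2.0 * K[i, t]
                    if a_it <= _EPS:
                        a_it = _EPS
                    gain = diff * diff / a_it
                    if gain > best_gain:
                        best_gain = gain
                        j = t
        if j < 0:
            break
        s = y[i] * y[j]
        ai = alpha[i]
        aj = alpha[j]
        if s < 0:
            L = max(0.0, aj - ai)
            H = min(C, C + aj - ai)
        else:
            L = max(0.0, ai + aj - C)
            H = min(C, ai + aj)
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta <= _EPS:
            eta = _EPS
        # E_i - E_j in terms of the maintained gradient
        e_i = y[i] * (grad[i] + 1.0) - y[i]
        e_j = y[j] * (grad[j] + 1.0) - y[j]
        aj_new = aj + y[j] * (e_i - e_j) / eta
        if aj_new < L:
            aj_new = L
        elif aj_new > H:
            aj_new = H
        ai_new = ai + s * (aj - aj_new)
        d_i = ai_new - ai
        d_j = aj_new - aj
        if abs(d_i) < _EPS and abs(d_j) < _EPS:
            break
        alpha[i] = ai_new
        alpha[j] = aj_new
        for t in range(n):
            Qi[t] = y[t] * y[i] * K[t, i]
            Qj[t] = y[t] * y[j] * K[t, j]
            grad[t] += Qi[t] * d_i + Qj[t] * d_j
    return alpha, grad


try:  # JIT-compile the hot loop when numba is available
    from numba import njit

    _smo_core = njit(cache=True)(_smo_core)
except ImportError:  # pragma: no cover
    pass


def _smo(K: np.ndarray, y: np.ndarray, C: float, tol: float, max_iter: int):
    """Run the SMO core and derive the bias and KKT gap. Returns (alpha, b, gap)."""
    alpha, grad = _smo_core(
        np.ascontiguousarray(K, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        float(C),
        float(tol),
        int(max_iter),
    )
    up = ((y > 0) & (alpha < C - _EPS)) | ((y < 0) & (alpha > _EPS))
    low = ((y > 0) & (alpha > _EPS)) | ((y < 0) & (alpha < C - _EPS))
    vals = -y * grad
    m_up = np.max(np.where(up, vals, -np.inf))
    m_low = np.min(np.where(low, vals, np.inf))
    free = (alpha > _EPS) & (alpha < C - _EPS)
    if free.any():
        b = float(np.mean(vals[free]))
    else:
        b = float((m_up + m_low) / 2.0)
    return alpha, b, float(m_up - m_low)


def train(
    K_combined: np.ndarray,
    y: np.ndarray,
    C: float,
    beta: np.ndarray | None = None,
    sample_ids: tuple = (),
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> MKSVMModel:
    """Fit the SVM dual on an already-combined kernel.

    ``beta`` is stored on the model for bookkeeping and prediction-time
    kernel combination; it does not alter the (already combined) training
    kernel.
    """
    y = np.asarray(y, dtype=np.float64)
    K = np.asarray(K_combined, dtype=np.float64)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be in {+1, -1}")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if C <= 0:
        raise ValueError("C must be positive")
    if K.shape != (y.size, y.size):
        raise ValueError("kernel/label size mismatch")
    alpha, b, gap = _smo(K, y, C, tol=tol, max_iter=max_iter)
    # On rank-deficient kernels SMO converges sublinearly near the optimum;
    # accept a residual KKT gap that is tiny relative to the kernel scale
    # (the induced objective error is O(gap * n * C)), fail otherwise.
    scale = max(1.0, float(np.max(np.diag(K))))
    if gap > max(100.0 * tol, 1e-3 * scale):
        raise RuntimeError(f"SMO failed to converge: KKT gap {gap:.3g}")
    if gap > 10.0 * tol:
        logger.debug("SMO stopped with residual KKT gap %.3g (tol %.3g)", gap, tol)
    model = MKSVMModel(
        alpha=alpha,
        b=b,
        beta=np.asarray(beta, dtype=np.float64) if beta is not None else np.array([1.0]),
        C=float(C),
        y=y,
        support_ids=np.flatnonzero(alpha > _EPS),
        sample_ids=tuple(sample_ids),
    )
    model.check_invariants()
    return model


def dual_objective(alpha: np.ndarray, K: np.ndarray, y: np.ndarray) -> float:
    """Value of the dual objective sum alpha - 1/2 alpha' (yy' * K) alpha."""
    alpha = np.asarray(alpha, dtype=np.float64)
    Q = (y[:, None] * y[None, :]) * K
    return float(alpha.sum() - 0.5 * alpha @ Q @ alpha)


def decision_value(model: MKSVMModel, k_test) -> float:
    """Pre-sign decision value for one test sample.

    ``k_test`` is a list of per-modality kernel columns (length n_train
    each, aligned to training order) which are combined with the model's
    beta; a single already-combined column is also accepted.
    """
    k_test = [np.asarray(k, dtype=np.float64) for k in np.atleast_2d(k_test)]
    if len(k_test) == model.beta.size:
        col = np.zeros_like(k_test[0])
        for w, k in zip(model.beta, k_test):
            col += w * k
    elif len(k_test) == 1:
        col = k_test[0]
    else:
        raise ValueError("kernel columns do not match the model's modalities")
    if col.size != model.y.size:
        raise ValueError("kernel column misaligned with training samples")
    return float((model.alpha * model.y) @ col + model.b)


def predict(model: MKSVMModel, k_test) -> int:
    """Predicted label: sign of the decision value, ties toward +1."""
    return 1 if decision_value(model, k_test) >= 0 else -1
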