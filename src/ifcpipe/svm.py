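"""Soft-margin linear SVM trained by sequential minimal optimization.

This is a self-contained Platt-style SMO solver for the dual problem

    max  sum(alpha) - 1/2 sum_ij alpha_i alpha_j y_i y_j <x_i, x_j>
    s.t. 0 <= alpha_i <= C,  sum_i alpha_i y_i = 0

with a linear kernel. It is the classifier used everywhere in the
pipeline; off-the-shelf SVMs appear only as independent oracles in the
test suite. Problems here are small (tens of subjects), so the solver
favours clarity and exact KKT bookkeeping over large-scale tricks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SvmConfig:
    """Hyperparameters; defaults mirror a stock linear SMO setup."""

    C: float = 1.0
    tol: float = 1e-3  # KKT violation tolerance
    eps: float = 1e-12  # minimal alpha step
    max_sweeps: int = 10_000
    standardize_in_fold: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class LinearSvmModel:
    w: np.ndarray
    b: float
    alpha: np.ndarray
    support_: np.ndarray  # indices with alpha > 0
    objective: float  # dual objective at the solution
    converged: bool
    n_sweeps: int

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, float)) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {-1, +1}; the boundary itself (f == 0) goes to -1."""
        return np.where(self.decision_function(X) > 0, 1, -1)


class _Smo:
    def __init__(self, X: np.ndarray, y: np.ndarray, cfg: SvmConfig):
        self.X = X
        self.y = y.astype(float)
        self.C = float(cfg.C)
        self.tol = float(cfg.tol)
        self.eps = float(cfg.eps)
        self.K = X @ X.T
        n = len(y)
        self.alpha = np.zeros(n)
        self.b = 0.0
        # error cache: E_i = f(x_i) - y_i; with alpha = 0, f = 0
        self.E = -self.y.copy()
        self.rng = np.random.default_rng(cfg.seed)

    def _f(self, i: int) -> float:
        return float((self.alpha * self.y) @ self.K[:, i] + self.b)

    def _take_step(self, i1: int, i2: int) -> bool:
        if i1 == i2:
            return False
        a1, a2 = self.alpha[i1], self.alpha[i2]
        y1, y2 = self.y[i1], self.y[i2]
        E1, E2 = self.E[i1], self.E[i2]
        s = y1 * y2
        if s > 0:
            L, H = max(0.0, a1 + a2 - self.C), min(self.C, a1 + a2)
        else:
            L, H = max(0.0, a2 - a1), min(self.C, self.C + a2 - a1)
        if L >= H:
            return False
        k11, k12, k22 = self.K[i1, i1], self.K[i1, i2], self.K[i2, i2]
        eta = k11 + k22 - 2.0 * k12
        if eta > 0:
            a2_new = a2 + y2 * (E1 - E2) / eta
            a2_new = min(H, max(L, a2_new))
        else:
            # flat curvature (duplicate points under a linear kernel): the
            # dual objective is linear in a2, so move to the bound the
            # derivative points at
            slope = y2 * (E1 - E2)
            if slope > self.eps:
                a2_new = H
            elif slope < -self.eps:
                a2_new = L
            else:
                return False
        if abs(a2_new - a2) < self.eps * (a2_new + a2 + self.eps):
            return False
        a1_new = a1 + s * (a2 - a2_new)

        d1 = y1 * (a1_new - a1)
        d2 = y2 * (a2_new - a2)
        b_old = self.b
        b1 = b_old - (E1 + d1 * k11 + d2 * k12)
        b2 = b_old - (E2 + d1 * k12 + d2 * k22)
        if 0 < a1_new < self.C:
            self.b = b1
        elif 0 < a2_new < self.C:
            self.b = b2
        else:
            self.b = 0.5 * (b1 + b2)
        self.alpha[i1], self.alpha[i2] = a1_new, a2_new
        self.E += d1 * self.K[i1] + d2 * self.K[i2] + (self.b - b_old)
        return True

    def _examine(self, i2: int) -> int:
        y2, a2, E2 = self.y[i2], self.alpha[i2], self.E[i2]
        r2 = E2 * y2
        if (r2 < -self.tol and a2 < self.C) or (r2 > self.tol and a2 > 0):
            non_bound = np.flatnonzero((self.alpha > 0) & (self.alpha < self.C))
            if non_bound.size > 1:
                i1 = int(non_bound[np.argmax(np.abs(self.E[non_bound] - E2))])
                if self._take_step(i1, i2):
                    return 1
            for pool in (non_bound, np.arange(len(self.y))):
                if pool.size == 0:
                    continue
                start = int(self.rng.integers(pool.size))
                for k in range(pool.size):
                    i1 = int(pool[(start + k) % pool.size])
                    if self._take_step(i1, i2):
                        return 1
        return 0

    def solve(self, max_sweeps: int) -> tuple[bool, int]:
        examine_all = True
        sweeps = 0
        while sweeps < max_sweeps:
            sweeps += 1
            changed = 0
            idx = (
                np.arange(len(self.y))
                if examine_all
                else np.flatnonzero((self.alpha > 0) & (self.alpha < self.C))
            )
            for i in idx:
                changed += self._examine(int(i))
            if examine_all:
                if changed == 0:
                    return True, sweeps
                examine_all = False
            elif changed == 0:
                examine_all = True
        return False, sweeps


def _canonical_threshold(
    X: np.ndarray, y: np.ndarray, alpha: np.ndarray, C: float, fallback: float
) -> float:
    """Canonical bias: mean over free support vectors, else the midpoint of
    the KKT-feasible interval (the solution only pins b to an interval when
    every multiplier sits at a bound)."""
    wx = X @ (X.T @ (alpha * y))
    tol = 1e-8 * max(1.0, C)
    free = (alpha > tol) & (alpha < C - tol)
    if free.any():
        return float(np.mean(y[free] - wx[free]))
    lo, hi = -np.inf, np.inf
    for i in range(len(y)):
        bound = y[i] - wx[i]
        if y[i] > 0:
            if alpha[i] < C - tol:
                lo = max(lo, bound)  # y_i f_i >= 1
            if alpha[i] > tol:
                hi = min(hi, bound)  # y_i f_i <= 1
        else:
            if alpha[i] < C - tol:
                hi = min(hi, bound)
            if alpha[i] > tol:
                lo = max(lo, bound)
    if np.isfinite(lo) and np.isfinite(hi):
        return 0.5 * (lo + hi)
    return fallback


def train_linear_svm(X: np.ndarray, y: np.ndarray, cfg: SvmConfig | None = None) -> LinearSvmModel:
    """Fit the soft-margin linear SVM by SMO.

    ``y`` must contain both classes, coded as -1/+1 (any two distinct
    labels are mapped onto -1/+1 by sorted order). Deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or SvmConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_instances, n_features) matching y")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    yy = np.where(y == classes[1], 1.0, -1.0)

    smo = _Smo(X, yy, cfg)
    converged, sweeps = smo.solve(cfg.max_sweeps)
    alpha = smo.alpha
    w = X.T @ (alpha * yy)
    b = _canonical_threshold(X, yy, alpha, cfg.C, smo.b)
    obj = alpha.sum() - 0.5 * float((alpha * yy) @ smo.K @ (alpha * yy))
    return LinearSvmModel(
        w=w,
        b=b,
        alpha=alpha,
        support_=np.flatnonzero(alpha > 0),
        objective=obj,
        converged=converged,
        n_sweeps=sweeps,
    )
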