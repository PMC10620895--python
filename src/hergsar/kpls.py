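"""Kernel partial least squares (KPLS) regression on molecular fingerprints.

PLS regression is carried out in the feature space induced by a kernel over
fingerprints, using the dual (kernel) form of the NIPALS sequence: the
centred training Gram matrix is deflated component by component, and
predictions are expansions in kernel evaluations against the training set.
With a linear kernel and the full number of components this reproduces
ordinary least squares on the fingerprint features; with a Tanimoto or
minmax kernel it is a similarity-based nonlinear regression, the standard
setting for activity modelling on sparse substructure fingerprints.

Model quality is reported as R² on the training set and external Q² on a
held-out test set (1 - PRESS/SS with the *training* mean as reference), and
models can be ordered by a composite score that rewards accuracy on both
sets and penalises train/test gaps.

An atom-level attribution is provided: the contribution of an atom is the
drop in prediction when every fingerprint feature whose substructure
contains that atom is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator, RegressorMixin

from .chem import CompoundRecord
from .fingerprints import Fingerprint, FingerprintFeaturizer, fold

__all__ = [
    "KernelSpec",
    "kernel_matrix",
    "train_test_split_records",
    "KernelPLSRegressor",
    "r2_q2",
    "model_rank_score",
    "atomic_contribution",
]

KernelKind = Literal["tanimoto", "minmax", "gaussian", "linear", "precomputed"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice for fingerprint Gram matrices."""

    kind: KernelKind = "tanimoto"
    bandwidth: float = 1.0  # gaussian only

    def __post_init__(self):
        if self.kind == "gaussian" and not self.bandwidth > 0:
            raise ValueError("gaussian bandwidth must be positive")


def _tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    sa, sb = a.support, b.support
    union = len(sa | sb)
    if union == 0:
        return 1.0  # both empty: identical
    return len(sa & sb) / union


def _minmax(a: Fingerprint, b: Fingerprint) -> float:
    keys = set(a.features) | set(b.features)
    if not keys:
        return 1.0
    num = sum(min(a.features.get(k, 0), b.features.get(k, 0)) for k in keys)
    den = sum(max(a.features.get(k, 0), b.features.get(k, 0)) for k in keys)
    return num / den


def kernel_matrix(
    fps_a: Sequence[Fingerprint] | np.ndarray,
    fps_b: Sequence[Fingerprint] | np.ndarray,
    spec: KernelSpec = KernelSpec(),
) -> np.ndarray:
    """Gram matrix K[i, j] = k(fps_a[i], fps_b[j]).

    Tanimoto operates on binary supports (|A∩B| / |A∪B|, defined as 1 when
    both are empty); minmax on counts; gaussian and linear on dense arrays
    (or fingerprints folded to 2048 counts).
    """
    if spec.kind == "precomputed":
        return np.asarray(fps_a, dtype=float)

    if spec.kind in ("gaussian", "linear"):
        xa = _as_dense(fps_a)
        xb = _as_dense(fps_b)
        if spec.kind == "linear":
            return xa @ xb.T
        sq = (
            (xa**2).sum(axis=1)[:, None]
            + (xb**2).sum(axis=1)[None, :]
            - 2 * xa @ xb.T
        )
        return np.exp(-np.maximum(sq, 0.0) / (2.0 * spec.bandwidth**2))

    _check_schemes(fps_a, fps_b)
    fn = _tanimoto if spec.kind == "tanimoto" else _minmax
    out = np.empty((len(fps_a), len(fps_b)))
    for i, fa in enumerate(fps_a):
        for j, fb in enumerate(fps_b):
            out[i, j] = fn(fa, fb)
    return out


def _as_dense(x) -> np.ndarray:
    if len(x) and isinstance(x[0], Fingerprint):
        return np.vstack([fold(fp, 2048) for fp in x])
    return np.atleast_2d(np.asarray(x, dtype=float))


def _check_schemes(fps_a, fps_b):
    schemes = {fp.scheme for fp in fps_a} | {fp.scheme for fp in fps_b}
    if len(schemes) > 1:
        raise ValueError(f"fingerprint scheme mismatch: {sorted(schemes)}")


def train_test_split_records(
    records: Sequence, ratio: float = 0.85, seed: int = 0
) -> tuple[list, list]:
    """Seeded shuffle split into train (round(n*ratio)) and test (rest)."""
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(n * ratio))
    n_train = min(max(n_train, 1), n - 1)
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


class KernelPLSRegressor(BaseEstimator, RegressorMixin):
    """Kernel PLS regression (dual NIPALS with sequential deflation).

    Parameters
    ----------
    n_components : int or "auto"
        Number of latent components.  "auto" picks the count (1..max_components)
        maximising 5-fold internal Q² on the training set.
    kernel : {"tanimoto", "minmax", "gaussian", "linear", "precomputed"}
        Kernel over the inputs.  X may be a list of :class:`Fingerprint`
        (tanimoto/minmax, or folded for gaussian/linear), a dense feature
        array (gaussian/linear), or the training Gram matrix (precomputed).
    bandwidth : float
        Gaussian kernel bandwidth.
    max_components : int
        Cap for the "auto" search.
    tol : float
        Deflation stops when the candidate score variance falls below this.

    Attributes
    ----------
    n_components_ : int
        Components actually extracted (may be fewer than requested when the
        deflated kernel degenerates).
    dual_coef_ : ndarray (n_train,)
        Expansion coefficients over centred training-kernel columns.
    r2_train_ : float
        R² of the fitted values on the training responses.
    """

    def __init__(
        self,
        n_components: int | str = "auto",
        kernel: KernelKind = "tanimoto",
        bandwidth: float = 1.0,
        max_components: int = 10,
        tol: float = 1e-12,
    ):
        self.n_components = n_components
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.max_components = max_components
        self.tol = tol

    # ------------------------------------------------------------------
    def _spec(self) -> KernelSpec:
        return KernelSpec(self.kernel, self.bandwidth)

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if self.kernel == "precomputed":
            K = np.asarray(X, dtype=float)
            if K.shape != (n, n):
                raise ValueError("precomputed kernel must be square (n_train, n_train)")
            self.X_fit_ = None
        else:
            self.X_fit_ = X
            K = kernel_matrix(X, X, self._spec())

        if isinstance(self.n_components, str):
            if self.n_components != "auto":
                raise ValueError(f"unknown n_components {self.n_components!r}")
            ncomp = self._select_components(K, y)
        else:
            ncomp = int(self.n_components)
        if ncomp < 0 or ncomp > n:
            raise ValueError(f"n_components must be in [0, n_train={n}]")

        self._fit_kernel(K, y, ncomp)
        return self

    def _fit_kernel(self, K: np.ndarray, y: np.ndarray, ncomp: int) -> None:
        n = len(y)
        self.n_train_ = n
        self.y_mean_ = float(y.mean())
        self.K_row_mean_ = K.mean(axis=0)
        self.K_grand_mean_ = float(K.mean())

        # double centring of the training Gram matrix
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        K0 = J @ K @ J
        yc = y - self.y_mean_

        T = np.zeros((n, ncomp))
        U = np.zeros((n, ncomp))
        Kd, yd = K0.copy(), yc.copy()
        achieved = 0
        for m in range(ncomp):
            t = Kd @ yd
            norm2 = float(t @ t)
            if norm2 < self.tol:
                warnings.warn(
                    f"deflation degenerate after {achieved} components "
                    f"({ncomp} requested)",
                    stacklevel=2,
                )
                break
            t = t / np.sqrt(norm2)
            u = yd.copy()  # univariate response: u is proportional to y residual
            T[:, m], U[:, m] = t, u
            P = np.eye(n) - np.outer(t, t)
            Kd = P @ Kd @ P
            yd = yd - t * (t @ yd)
            achieved += 1
        T, U = T[:, :achieved], U[:, :achieved]
        self.n_components_ = achieved
        self.scores_, self.loadings_ = T, U

        if achieved == 0:
            self.dual_coef_ = np.zeros(n)
        else:
            M = T.T @ K0 @ U
            self.dual_coef_ = U @ np.linalg.solve(M, T.T @ yc)
        self._K0_ = K0

        fitted = self._predict_from_centered(K0)
        ss = float(((y - y.mean()) ** 2).sum())
        self.r2_train_ = 1.0 - float(((y - fitted) ** 2).sum()) / ss if ss > 0 else 1.0

    def _select_components(self, K: np.ndarray, y: np.ndarray) -> int:
        """5-fold internal Q² over 1..max_components on the training set."""
        n = len(y)
        cap = min(self.max_components, n - max(1, n // 5) - 1)
        if cap < 1:
            return 1
        rng = np.random.default_rng(0)
        order = rng.permutation(n)
        folds = np.array_split(order, 5)
        press = np.zeros(cap)
        ss = 0.0
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            tr = np.flatnonzero(mask)
            sub = KernelPLSRegressor(kernel="precomputed", n_components=0, tol=self.tol)
            Ktr = K[np.ix_(tr, tr)]
            Kte = K[np.ix_(fold, tr)]
            ytr = y[tr]
            ss += float(((y[fold] - ytr.mean()) ** 2).sum())
            for m in range(1, cap + 1):
                sub.n_components = min(m, len(tr))
                sub.fit(Ktr, ytr)
                pred = sub.predict(Kte)
                press[m - 1] += float(((y[fold] - pred) ** 2).sum())
        q2 = 1.0 - press / ss if ss > 0 else -press
        return int(np.argmax(q2)) + 1

    # ------------------------------------------------------------------
    def _predict_from_centered(self, Ktc: np.ndarray) -> np.ndarray:
        return self.y_mean_ + Ktc @ self.dual_coef_

    def predict(self, X) -> np.ndarray:
        if self.kernel == "precomputed":
            Kt = np.asarray(X, dtype=float)
            if Kt.shape[1] != self.n_train_:
                raise ValueError("precomputed test kernel must have n_train columns")
        else:
            Kt = kernel_matrix(X, self.X_fit_, self._spec())
        # centre the test kernel with the training statistics
        Ktc = (
            Kt
            - self.K_row_mean_[None, :]
            - Kt.mean(axis=1, keepdims=True)
            + self.K_grand_mean_
        )
        return self._predict_from_centered(Ktc)

    def q2(self, X_test, y_test) -> float:
        """External Q² on held-out data (training-mean reference)."""
        return r2_q2(y_test, self.predict(X_test), ref_mean=self.y_mean_)


def r2_q2(
    observed: Sequence[float],
    predicted: Sequence[float],
    ref_mean: Optional[float] = None,
) -> float:
    """1 - Σ(y-ŷ)² / Σ(y-ȳ)².

    With ``ref_mean=None`` this is R² (ȳ = mean of ``observed``); passing the
    *training* mean gives the external Q² convention for test sets.
    """
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    if y.shape != yh.shape or y.size < 2:
        raise ValueError("observed and predicted must be equal-length, size >= 2")
    ybar = float(y.mean()) if ref_mean is None else float(ref_mean)
    den = float(((y - ybar) ** 2).sum())
    if den == 0:
        raise ValueError("zero variance around the reference mean")
    return 1.0 - float(((y - yh) ** 2).sum()) / den


def model_rank_score(r2_train: float, q2_test: float, penalty: float = 0.5) -> float:
    """Composite model-ordering score in [0, 1].

    score = min(R², Q²) − penalty·|R² − Q²|, with the inputs clipped to
    [0, 1] and the result clipped to [0, 1].  This is this package's own
    surrogate objective: it rewards models accurate on both sets and
    penalises train/test gaps; it is used only to order candidate models.
    """
    r2 = min(max(float(r2_train), 0.0), 1.0)
    q2 = min(max(float(q2_test), 0.0), 1.0)
    score = min(r2, q2) - penalty * abs(r2 - q2)
    return min(max(score, 0.0), 1.0)


def atomic_contribution(
    model: KernelPLSRegressor,
    fp: Fingerprint,
    n_atoms: Optional[int] = None,
) -> np.ndarray:
    """Per-atom prediction attributions for one molecule.

    contribution(a) = prediction(full fingerprint) − prediction(fingerprint
    with every feature occurrence whose substructure contains atom ``a``
    removed).  Requires a fingerprint computed with ``track_atoms=True``.
    """
    if fp.feature_atoms is None:
        raise ValueError("fingerprint must be computed with track_atoms=True")
    if n_atoms is None:
        n_atoms = max(
            (max(occ) + 1 for occs in fp.feature_atoms.values() for occ in occs if occ),
            default=0,
        )
    full = float(model.predict([fp])[0])
    contribs = np.zeros(n_atoms)
    for a in range(n_atoms):
        contribs[a] = full - float(model.predict([fp.without_atom(a)])[0])
    return contribs
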