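"""Spatial mode decomposition of contraction dynamics.

The detrended intensity matrix is decomposed into orthonormal spatial modes
(eigenvectors of the pixel-pixel temporal covariance) with time-dependent
coefficients:

    I(t_i) - <I> = sum_mu a_mu(t_i) phi_mu

When there are many more pixels than frames, the eigendecomposition goes
through the T x T Gram ("snapshot") matrix, which shares the nonzero
eigenvalues of the P x P covariance. The ranked relative eigenvalue
spectrum, in percent of total variance, characterizes how contraction
variance distributes over modes; its noise floor is estimated from
temporally shuffled data.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import (
    DataError,
    EigenSpectrum,
    IntensityMatrix,
    ModeBasis,
    NullSpectrum,
    ParameterError,
)

_EIG_TOL = 1e-12


def _fix_signs(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: per mode, the largest-magnitude
    component is positive; magnitude ties go to the lowest pixel index."""
    out = modes.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        k = int(np.argmax(np.abs(col)))  # argmax takes the first maximum
        if col[k] < 0:
            out[:, j] = -col
    return out


class ContractionModePCA(BaseEstimator, TransformerMixin):
    """PCA of skeleton-pixel intensity dynamics.

    Follows the scikit-learn transformer protocol with samples = time
    points and features = skeleton pixels, i.e. ``fit(X)`` expects
    ``X`` of shape (T, P).

    Parameters
    ----------
    n_modes : int or None
        Number of modes to keep; ``None`` keeps all modes with nonzero
        eigenvalue (at most min(P, T-1)).
    method : {"auto", "direct", "snapshot"}
        "direct" eigendecomposes the P x P covariance, "snapshot" the
        T x T Gram matrix; "auto" picks whichever matrix is smaller.

    Attributes
    ----------
    components_ : ndarray, (M, P)
        Orthonormal spatial modes, eigenvalue-descending, rows.
    eigenvalues_ : ndarray, (M,)
        Covariance eigenvalues (variance per mode), descending.
    mean_ : ndarray, (P,)
        Per-pixel temporal mean subtracted before decomposition.
    """

    def __init__(self, n_modes: int | None = None, method: str = "auto"):
        self.n_modes = n_modes
        self.method = method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DataError("expected a 2-D (time x pixels) matrix")
        T, P = X.shape
        if T < 3:
            raise DataError("need at least 3 time points")
        if P < 2:
            raise DataError("need at least 2 pixels")
        if not np.all(np.isfinite(X)):
            raise DataError("non-finite entries in input")
        if self.method not in ("auto", "direct", "snapshot"):
            raise ParameterError(f"unknown method {self.method!r}")

        mean = X.mean(axis=0)
        Xc = X - mean
        method = self.method
        if method == "auto":
            method = "snapshot" if P > T else "direct"

        max_rank = min(P, T - 1)
        if method == "direct":
            C = (Xc.T @ Xc) / (T - 1)
            evals, evecs = np.linalg.eigh(C)
            order = np.argsort(evals)[::-1]
            evals = np.clip(evals[order], 0.0, None)
            modes = evecs[:, order]
        else:
            G = (Xc @ Xc.T) / (T - 1)
            evals, evecs = np.linalg.eigh(G)
            order = np.argsort(evals)[::-1]
            evals = np.clip(evals[order], 0.0, None)
            evecs = evecs[:, order]
            # lift Gram eigenvectors to pixel space: phi = X^T v / sqrt((T-1) lam)
            scale = np.sqrt(np.maximum(evals * (T - 1), _EIG_TOL))
            modes = (Xc.T @ evecs) / scale

        keep = min(max_rank, int(np.sum(evals > _EIG_TOL * max(evals.max(), 1.0))))
        keep = max(keep, 1)
        if self.n_modes is not None:
            keep = min(keep, self.n_modes)
        modes = _fix_signs(modes[:, :keep])
        self.components_ = modes.T
        self.eigenvalues_ = evals[:keep]
        self.mean_ = mean
        self.n_features_in_ = P
        return self

    def transform(self, X):
        """Mode coefficients a_mu(t); shape (T, M)."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, A):
        """Reconstruct intensities from coefficients; shape (T, P)."""
        check_is_fitted(self, "components_")
        return np.asarray(A, dtype=float) @ self.components_ + self.mean_

    @property
    def explained_variance_ratio_(self):
        check_is_fitted(self, "eigenvalues_")
        return self.eigenvalues_ / self.eigenvalues_.sum()


def compute_modes(mat: IntensityMatrix, method: str = "auto") -> ModeBasis:
    """Decompose a detrended intensity matrix into a mode basis."""
    est = ContractionModePCA(method=method).fit(mat.values.T)
    coefficients = est.transform(mat.values.T).T
    return ModeBasis(
        modes=est.components_.T,
        eigenvalues=est.eigenvalues_,
        coefficients=coefficients,
        temporal_mean=est.mean_,
        dt=mat.dt,
    )


def relative_spectrum(basis: ModeBasis) -> EigenSpectrum:
    """Ranked spectrum of relative eigenvalues in percent of total variance."""
    total = basis.eigenvalues.sum()
    if total <= 0:
        raise DataError("all eigenvalues are zero: degenerate data")
    rel = basis.eigenvalues / total * 100.0
    return EigenSpectrum(relative_eigenvalues=rel, ranks=np.arange(1, len(rel) + 1))


def null_spectrum(
    mat: IntensityMatrix, n_shuffles: int = 10, seed: int = 0
) -> NullSpectrum:
    """Noise floor of the eigenvalue spectrum from temporally shuffled data.

    Each shuffle independently permutes every pixel's time series — this
    destroys temporal structure and cross-pixel alignment while preserving
    each pixel's marginal distribution (and hence the total variance). The
    relative spectra are averaged over shuffles; the cutoff is the largest
    averaged null eigenvalue, in percent.
    """
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    P, T = mat.values.shape
    M = min(P, T - 1)
    acc = np.zeros(M)
    acc_abs = np.zeros(M)
    for _ in range(n_shuffles):
        shuffled = np.empty_like(mat.values)
        for p in range(P):
            shuffled[p] = mat.values[p, rng.permutation(T)]
        est = ContractionModePCA().fit(shuffled.T)
        lam = np.zeros(M)
        lam[: len(est.eigenvalues_)] = est.eigenvalues_
        acc += lam / lam.sum() * 100.0
        acc_abs += lam
    rel = np.sort(acc / n_shuffles)[::-1]
    return NullSpectrum(
        relative_eigenvalues_null=rel,
        cutoff_eigenvalue=float(rel[0]),
        n_shuffles=n_shuffles,
        seed=seed,
        eigenvalues_null=np.sort(acc_abs / n_shuffles)[::-1],
    )


def reconstruct(basis: ModeBasis, mode_subset) -> IntensityMatrix:
    """Partial reconstruction from a subset of modes (0-based indices)."""
    idx = np.asarray(sorted(set(int(i) for i in mode_subset)), dtype=int)
    if len(idx) and (idx.min() < 0 or idx.max() >= basis.n_modes):
        raise ParameterError("mode index out of range")
    if len(idx):
        part = basis.modes[:, idx] @ basis.coefficients[idx]
    else:
        part = np.zeros((basis.modes.shape[0], basis.coefficients.shape[1]))
    values = basis.temporal_mean[:, None] + part
    return IntensityMatrix(values=values, dt=basis.dt, stage="raw")
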