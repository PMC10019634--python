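"""Kernel construction and conditioning.

Similarity matrices from information-content measures (Resnik, Lin) on
multi-parent ontologies are generally indefinite and cannot be used directly
as SVM kernels without giving up convexity. This module diagnoses
indefiniteness and applies the standard spectral corrections:

* ``clip`` — zero out negative eigenvalues (the Frobenius-nearest PSD matrix),
* ``flip`` — take absolute values of eigenvalues (eigenvalues become the
  singular values),
* ``shift`` — add |λ_min| to the whole spectrum (diagonal only), applied only
  when the matrix is actually indefinite.

It also builds the RBF kernel on numeric feature vectors and performs
feature-space kernel normalization k̂(x,z) = k(x,z)/√(k(x,x)·k(z,z)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf

from .ontology import SimilarityMatrix

__all__ = [
    "KernelMatrix",
    "FeatureTable",
    "rbf_kernel",
    "normalize_kernel",
    "nearest_psd",
    "check_psd",
    "embed_test_columns",
    "median_sigma",
]

Correction = Literal["clip", "flip", "shift"]

# relative eigenvalue tolerance: float noise near zero is expected for
# Jaccard matrices with near-duplicate rows
PSD_RTOL = 1e-8
SYM_RTOL = 1e-12


@dataclass(frozen=True)
class KernelMatrix:
    """Square symmetric sample-indexed similarity with PSD bookkeeping.

    ``psd_status`` is "verified" (PSD by construction or checked),
    "corrected:<method>", or "indefinite".
    """

    sample_ids: tuple[str, ...]
    values: np.ndarray
    psd_status: str = "verified"

    def __post_init__(self):
        v = self.values
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("kernel shape does not match sample ids")
        scale = max(1.0, float(np.abs(v).max()) if v.size else 1.0)
        if not np.allclose(v, v.T, rtol=0, atol=SYM_RTOL * scale * 10):
            raise ValueError("kernel matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, rows, cols=None) -> np.ndarray:
        cols = rows if cols is None else cols
        return self.values[np.ix_(rows, cols)]


@dataclass(frozen=True)
class FeatureTable:
    """Numeric per-sample feature matrix (samples x descriptors)."""

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("feature table shape mismatch")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        vals = df.to_numpy(dtype=float)
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.feature_names))


def median_sigma(X: FeatureTable | np.ndarray) -> float:
    """Median-heuristic RBF bandwidth: median of nonzero pairwise distances."""
    vals = X.values if isinstance(X, FeatureTable) else np.asarray(X, dtype=float)
    from scipy.spatial.distance import pdist

    d = pdist(vals)
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    return float(np.median(d))


def rbf_kernel(X: FeatureTable, sigma: float) -> KernelMatrix:
    """Gaussian kernel k(x,z) = exp(-||x-z||^2 / (2 sigma^2)); PSD by construction."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    bad = [
        X.sample_ids[i]
        for i in np.nonzero(~np.isfinite(X.values).all(axis=1))[0]
    ]
    if bad:
        raise ValueError(f"non-finite feature values for samples: {bad[:5]}")
    K = _sk_rbf(X.values, gamma=1.0 / (2.0 * sigma**2))
    np.fill_diagonal(K, 1.0)
    K = 0.5 * (K + K.T)
    return KernelMatrix(X.sample_ids, K, psd_status="verified")


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Feature-space normalization: k̂(x,z) = k(x,z)/sqrt(k(x,x) k(z,z)).

    Idempotent; maps a PSD kernel into [-1, 1] with unit diagonal.
    """
    d = np.diag(K.values).copy()
    bad = np.nonzero(d <= 0)[0]
    if bad.size:
        names = [K.sample_ids[i] for i in bad[:5]]
        raise ValueError(f"non-positive kernel diagonal for samples: {names}")
    denom = np.sqrt(np.outer(d, d))
    v = K.values / denom
    np.fill_diagonal(v, 1.0)
    v = 0.5 * (v + v.T)
    return KernelMatrix(K.sample_ids, v, psd_status=K.psd_status)


def check_psd(S: np.ndarray | KernelMatrix | SimilarityMatrix,
              tol: float = PSD_RTOL) -> tuple[bool, float]:
    """Check positive semi-definiteness: λ_min >= -tol * max(1, λ_max)."""
    v = S.values if hasattr(S, "values") else np.asarray(S, dtype=float)
    _assert_symmetric(v)
    w = np.linalg.eigvalsh(v)
    lam_min, lam_max = float(w[0]), float(w[-1])
    return lam_min >= -tol * max(1.0, lam_max), lam_min


def _assert_symmetric(v: np.ndarray) -> None:
    scale = max(1.0, float(np.abs(v).max()) if v.size else 1.0)
    if not np.allclose(v, v.T, rtol=0, atol=1e-9 * scale):
        raise ValueError("matrix is not symmetric within tolerance")


def nearest_psd(S: SimilarityMatrix | KernelMatrix | np.ndarray,
                method: Correction, sample_ids=None) -> KernelMatrix:
    """Spectral PSD correction of a symmetric similarity matrix.

    clip: S' = Σ max(λ_i, 0) v_i v_iᵀ (Frobenius-nearest PSD matrix);
    flip: S' = Σ |λ_i| v_i v_iᵀ;
    shift: S' = S + |λ_min| I, applied only when λ_min is genuinely negative
    (no-op on PSD input). shift changes only the diagonal.
    """
    if hasattr(S, "values"):
        ids = tuple(S.sample_ids)
        v = np.asarray(S.values, dtype=float)
    else:
        v = np.asarray(S, dtype=float)
        ids = tuple(sample_ids) if sample_ids is not None else tuple(
            str(i) for i in range(v.shape[0])
        )
    _assert_symmetric(v)
    v = 0.5 * (v + v.T)
    w, V = np.linalg.eigh(v)
    lam_max = float(w[-1])
    tol = PSD_RTOL * max(1.0, abs(lam_max))
    if method == "clip":
        out = (V * np.maximum(w, 0.0)) @ V.T
    elif method == "flip":
        out = (V * np.abs(w)) @ V.T
    elif method == "shift":
        lam_min = float(w[0])
        out = v + abs(lam_min) * np.eye(v.shape[0]) if lam_min < -tol else v.copy()
    else:
        raise ValueError(f"unknown correction method {method!r}")
    out = 0.5 * (out + out.T)
    return KernelMatrix(ids, out, psd_status=f"corrected:{method}")


def embed_test_columns(S_train: np.ndarray, S_test_train: np.ndarray,
                       method: Correction) -> np.ndarray:
    """Embed out-of-sample similarity rows into a spectrally corrected kernel.

    For clip/flip the training eigenbasis transform is applied to the test
    rows (row s becomes s·V g(Λ) Λ⁺ Vᵀ with g the correction of each
    eigenvalue); for shift, off-diagonal similarities are unchanged, so test
    rows pass through as-is.
    """
    S_train = np.asarray(S_train, dtype=float)
    S_test_train = np.atleast_2d(np.asarray(S_test_train, dtype=float))
    if method == "shift":
        return S_test_train.copy()
    w, V = np.linalg.eigh(0.5 * (S_train + S_train.T))
    tol = 1e-12 * max(1.0, float(np.abs(w).max()))
    if method == "clip":
        g = np.where(w > tol, 1.0, 0.0)
    elif method == "flip":
        g = np.where(np.abs(w) > tol, np.sign(w), 0.0)
    else:
        raise ValueError(f"unknown correction method {method!r}")
    P = (V * g) @ V.T
    return S_test_train @ P
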