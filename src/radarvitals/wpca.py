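"""Weighted-PCA separation of respiration and heartbeat.

The scalar thoracic phase signal is lag-embedded into a Hankel trajectory
matrix (the singular-spectrum-analysis construction), its sample covariance
is eigendecomposed, and eigencomponents are grouped by the dominant
frequency of their coefficient series: components oscillating in the
respiration band (0.1-0.5 Hz) reconstruct the respiration signal, those in
the heartbeat band (0.8-2 Hz) the heartbeat signal. Unlike plain PCA, each
retained component is weighted by its eigenvalue share

    w_i = lambda_i / sum_{j in kept} lambda_j,

so stronger components dominate the reconstruction. Rank-1 terms
``w_i * q_i * y_i(t)`` are summed and mapped back to a 1-D series by
anti-diagonal (Hankel) averaging. Setting all weights to ``1/K`` recovers
the plain-PCA reconstruction, which is exposed as a comparison baseline.

An eigenvalue-interval filter is available as an optional secondary
criterion (some practitioners select components by absolute eigenvalue
ranges calibrated on their own hardware), but the frequency-band rule is
the primary, scale-free selector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import NoPhysiologicalComponentError, ParameterError
from .preprocess import PhaseSignal

__all__ = [
    "TrajectoryMatrix",
    "EigenSystem",
    "ComponentSelection",
    "embed",
    "decompose",
    "dominant_frequency",
    "select_components",
    "reconstruct",
    "hankel_average",
    "save_eigensystem_npz",
]


@dataclass
class TrajectoryMatrix:
    """Hankel lag-embedding of a scalar series: data[i, j] = source[i + j].

    Shape is [M x L] with M the embedding window and L = len(source)-M+1
    the number of unit-hop lagged windows.
    """

    data: np.ndarray
    source_fs: float
    window: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.window:
            raise ParameterError("data must be [window x L]")

    @property
    def n_lags(self) -> int:
        return self.data.shape[1]


@dataclass
class EigenSystem:
    """Eigendecomposition of the trajectory-matrix sample covariance.

    ``eigenvalues`` are sorted descending; ``eigenvectors`` columns are the
    matching orthonormal basis with a deterministic sign (largest-magnitude
    entry positive); ``coefficients[i]`` is the i-th component's coefficient
    series y_i(t) = q_i^T (X - mean); ``mean`` is the per-row mean removed
    before forming the covariance (1/L normalisation).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    coefficients: np.ndarray
    mean: np.ndarray
    fs: float

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


@dataclass
class ComponentSelection:
    """Indices, normalised weights and the band that selected them."""

    indices: tuple
    weights: np.ndarray
    band: tuple
    label: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.indices) != self.weights.size or len(self.indices) == 0:
            raise ParameterError("indices and weights must be non-empty and matched")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ParameterError("weights must be non-negative and sum to 1")


def embed(sig: PhaseSignal, window: int) -> TrajectoryMatrix:
    """Hankel trajectory matrix with embedding window ``window``, unit hop."""
    x = sig.values
    if not 2 <= window <= x.size // 2:
        raise ParameterError(
            f"embedding window {window} outside [2, {x.size // 2}]"
        )
    n_lags = x.size - window + 1
    data = np.lib.stride_tricks.sliding_window_view(x, n_lags)[:window].copy()
    return TrajectoryMatrix(data=data, source_fs=sig.fs, window=window)


def decompose(traj: TrajectoryMatrix) -> EigenSystem:
    """Eigendecomposition of the lag covariance (1/L) * Xc Xc^T.

    Row means are removed first; eigenpairs are returned in descending
    eigenvalue order with the sign of each eigenvector fixed so its
    largest-magnitude entry is positive.
    """
    X = traj.data
    M, L = X.shape
    if L < M:
        raise ParameterError("need at least as many lagged windows as the embedding")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    if not np.any(Xc):
        warnings.warn("degenerate all-constant input", stacklevel=2)
        return EigenSystem(
            eigenvalues=np.zeros(M),
            eigenvectors=np.eye(M),
            coefficients=np.zeros_like(X),
            mean=mean[:, 0],
            fs=traj.source_fs,
        )
    cov = Xc @ Xc.T / L
    lams, Q = np.linalg.eigh(cov)
    order = np.argsort(lams)[::-1]
    lams, Q = np.maximum(lams[order], 0.0), Q[:, order]
    flip = Q[np.argmax(np.abs(Q), axis=0), np.arange(M)] < 0
    Q[:, flip] *= -1.0
    coeffs = Q.T @ Xc
    return EigenSystem(
        eigenvalues=lams, eigenvectors=Q, coefficients=coeffs,
        mean=mean[:, 0], fs=traj.source_fs,
    )


def dominant_frequency(component, fs: float) -> float:
    """Frequency of the largest non-DC magnitude-spectrum peak (4x padded)."""
    y = np.asarray(component, dtype=float)
    if y.size < 8:
        raise ParameterError("need at least 8 samples")
    y = y - y.mean()
    if not np.any(np.abs(y) > 1e-300):
        return 0.0
    nfft = 4 * y.size
    mag = np.abs(np.fft.rfft(y, nfft))
    mag[0] = 0.0
    return float(np.argmax(mag) * fs / nfft)


def select_components(
    es: EigenSystem,
    fs: float,
    band: tuple,
    max_k: int = 4,
    eigenvalue_range: tuple | None = None,
    label: str = "",
) -> ComponentSelection:
    """Pick eigencomponents whose coefficient series oscillate inside ``band``.

    Candidates are ordered by descending eigenvalue (the decomposition's
    order), optionally intersected with an absolute ``eigenvalue_range``,
    truncated to ``max_k``, and weighted by eigenvalue share.
    """
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ParameterError(f"band {band} must lie inside (0, {fs / 2})")
    if max_k < 1:
        raise ParameterError("max_k must be >= 1")
    kept = []
    for i in range(es.n_components):
        if eigenvalue_range is not None and not (
            eigenvalue_range[0] <= es.eigenvalues[i] <= eigenvalue_range[1]
        ):
            continue
        if lo <= dominant_frequency(es.coefficients[i], fs) <= hi:
            kept.append(i)
            if len(kept) == max_k:
                break
    if not kept:
        raise NoPhysiologicalComponentError(
            f"no component with dominant frequency in {band} Hz"
        )
    lams = es.eigenvalues[kept]
    total = lams.sum()
    weights = lams / total if total > 0 else np.full(len(kept), 1.0 / len(kept))
    return ComponentSelection(
        indices=tuple(kept), weights=weights, band=band, label=label
    )


def hankel_average(matrix: np.ndarray) -> np.ndarray:
    """Map an [M x L] matrix back to a length M+L-1 series by anti-diagonal means."""
    matrix = np.asarray(matrix, dtype=float)
    M, L = matrix.shape
    n = M + L - 1
    out = np.zeros(n)
    cnt = np.zeros(n)
    for i in range(M):
        out[i:i + L] += matrix[i]
        cnt[i:i + L] += 1.0
    return out / cnt


def reconstruct(
    es: EigenSystem, sel: ComponentSelection, weights=None
) -> PhaseSignal:
    """Weighted rank-1 synthesis of the selected components.

    Sums ``w_i * q_i y_i(t)`` over the selection and Hankel-averages the
    result back into a 1-D series. The removed mean is *not* re-added: the
    separated oscillatory component is zero-mean by construction. Passing
    ``weights`` overrides the selection's eigenvalue-share weights (uniform
    ``1/K`` gives the plain-PCA baseline).
    """
    if weights is None:
        weights = sel.weights
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(sel.indices):
        raise ParameterError("weights length must match selection")
    if max(sel.indices) >= es.n_components:
        raise ParameterError("selection index out of range")
    M = es.eigenvectors.shape[0]
    L = es.coefficients.shape[1]
    xhat = np.zeros((M, L))
    for w, i in zip(weights, sel.indices):
        xhat += w * np.outer(es.eigenvectors[:, i], es.coefficients[i])
    return PhaseSignal(values=hankel_average(xhat), fs=es.fs, stage="separated")


def save_eigensystem_npz(es: EigenSystem, path) -> None:
    np.savez(
        path,
        eigenvalues=es.eigenvalues,
        eigenvectors=es.eigenvectors,
        coefficients=es.coefficients,
        mean=es.mean,
        fs=np.array(es.fs),
    )
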