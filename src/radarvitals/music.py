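"""MUSIC subspace frequency estimation and BPM conversion.

The separated respiration or heartbeat series is cut into overlapping
length-N snapshots (unit hop, Hankel layout); the snapshot covariance is
eigendecomposed and split into signal and noise subspaces, the signal
dimension chosen by the MDL information criterion (AIC optional) unless
supplied. The pseudo-spectrum

    P(omega) = 1 / (a(omega)^H U_N U_N^H a(omega)),
    a(omega) = [1, e^{-j omega}, ..., e^{-j (N-1) omega}]^T,

peaks where the steering vector is orthogonal to the noise subspace, i.e.
at the signal frequencies, and is evaluated on a dense grid over the
physiological band of the branch being estimated (mapped to digital
frequency omega = 2*pi*f/fs). Restricting the search to the positive-
frequency physiological band both halves the work for real inputs and
keeps the mirrored negative-frequency peak out of the running. Because a
weak out-of-band-leaking harmonic contributes only a low-rank perturbation,
its pseudo-spectrum peak is far weaker than a genuine in-band tone's —
this is what suppresses respiration harmonics when estimating heart rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .preprocess import PhaseSignal

__all__ = [
    "SnapshotMatrix",
    "PseudoSpectrum",
    "VitalEstimate",
    "build_snapshots",
    "mdl_order",
    "aic_order",
    "subspace_split",
    "pseudo_spectrum",
    "estimate_frequency",
    "to_bpm",
    "save_spectrum_csv",
]

#: pseudo-spectrum values are capped here when the denominator underflows
PSEUDO_SPECTRUM_CAP = 1e300

#: eigenvalues below max*this are floored before the information criteria
#: (numerically-zero eigenvalues otherwise destabilise the log-likelihood)
_EIG_FLOOR_REL = 1e-12


@dataclass
class SnapshotMatrix:
    """Unit-hop length-N windows of a series, columns are snapshots."""

    data: np.ndarray
    snapshot_len: int
    fs: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.snapshot_len < 4:
            raise ParameterError("snapshot length must be >= 4")
        if self.data.shape[0] != self.snapshot_len:
            raise ParameterError("data rows must equal snapshot_len")
        if self.data.shape[1] < self.snapshot_len:
            warnings.warn(
                "fewer snapshots than the snapshot length; covariance estimate "
                "will be poor", stacklevel=2,
            )

    @property
    def n_snapshots(self) -> int:
        return self.data.shape[1]


@dataclass
class PseudoSpectrum:
    """MUSIC pseudo-spectrum sampled on a digital-frequency grid.

    ``omegas`` in rad/sample, ``frequencies = omegas*fs/(2*pi)`` in Hz,
    ``values`` strictly positive, ``capped`` flags grid points whose
    denominator underflowed (value clipped to PSEUDO_SPECTRUM_CAP).
    """

    omegas: np.ndarray
    frequencies: np.ndarray
    values: np.ndarray
    signal_dim: int
    capped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.capped is None:
            self.capped = np.zeros(len(self.values), dtype=bool)


@dataclass
class VitalEstimate:
    """Estimated respiration / heartbeat frequencies and integer rates."""

    f_resp_hat: float
    f_heart_hat: float
    rr: int
    hr: int
    spectra: dict
    details: dict = field(default_factory=dict)


def build_snapshots(sig: PhaseSignal, snapshot_len: int) -> SnapshotMatrix:
    """Hankel snapshot matrix: column j is sig.values[j : j+N]."""
    x = sig.values
    if snapshot_len > x.size:
        raise ParameterError(
            f"snapshot length {snapshot_len} exceeds series length {x.size}"
        )
    n_snap = x.size - snapshot_len + 1
    data = np.lib.stride_tricks.sliding_window_view(x, n_snap)[:snapshot_len].copy()
    return SnapshotMatrix(data=data, snapshot_len=snapshot_len, fs=sig.fs)


def _floored(eigenvalues: np.ndarray) -> np.ndarray:
    top = eigenvalues.max()
    floor = top * _EIG_FLOOR_REL if top > 0 else 1e-300
    return np.maximum(eigenvalues, floor)


def mdl_order(eigenvalues: np.ndarray, n_snapshots: int) -> int:
    """Minimum-description-length signal-dimension estimate.

    ``eigenvalues`` must be sorted descending. Returns the k minimising
    -L(N-k) log(GM/AM of the N-k smallest) + (1/2) k (2N-k) log L.
    """
    lams = _floored(np.asarray(eigenvalues, dtype=float))
    N = lams.size
    crit = np.empty(N)
    for k in range(N):
        tail = lams[k:]
        gm_log = np.mean(np.log(tail))
        am = np.mean(tail)
        crit[k] = -n_snapshots * (N - k) * (gm_log - np.log(am)) \
            + 0.5 * k * (2 * N - k) * np.log(n_snapshots)
    return int(np.argmin(crit))


def aic_order(eigenvalues: np.ndarray, n_snapshots: int) -> int:
    """Akaike-information-criterion signal-dimension estimate."""
    lams = _floored(np.asarray(eigenvalues, dtype=float))
    N = lams.size
    crit = np.empty(N)
    for k in range(N):
        tail = lams[k:]
        gm_log = np.mean(np.log(tail))
        am = np.mean(tail)
        crit[k] = -2 * n_snapshots * (N - k) * (gm_log - np.log(am)) \
            + 2 * k * (2 * N - k)
    return int(np.argmin(crit))


def subspace_split(
    snap: SnapshotMatrix,
    signal_dim: int | None = None,
    method: str = "mdl",
):
    """Split the snapshot covariance eigenspace into signal and noise bases.

    Returns ``(signal_basis, noise_basis, p)``. If ``signal_dim`` is not
    supplied, p is chosen by MDL (or AIC), clamped to [2, N-2] and rounded
    up to an even number since real tones occupy conjugate exponential
    pairs. A supplied ``signal_dim`` is honoured unchanged.
    """
    X = snap.data
    N, L = X.shape
    cov = (X @ X.conj().T) / L
    lams, V = np.linalg.eigh(cov)
    order = np.argsort(lams)[::-1]
    lams, V = lams[order], V[:, order]

    if signal_dim is None:
        pick = {"mdl": mdl_order, "aic": aic_order}
        try:
            raw = pick[method](lams, L)
        except KeyError:
            raise ParameterError(f"unknown order method '{method}'") from None
        p = min(max(raw, 2), N - 2)
        if p % 2:
            p += 1
        if raw < 2:
            warnings.warn(
                "order criterion found no clear signal subspace; using the "
                "smallest admissible dimension (low confidence)", stacklevel=2,
            )
    else:
        p = signal_dim
        if not 1 <= p <= N - 1:
            raise ParameterError(f"signal_dim {p} must leave a noise subspace")
    return V[:, :p], V[:, p:], p


def pseudo_spectrum(
    noise_basis: np.ndarray,
    snapshot_len: int,
    band: tuple,
    fs: float,
    n_grid: int = 1024,
) -> PseudoSpectrum:
    """Evaluate the MUSIC cost on ``n_grid`` points across ``band`` (Hz)."""
    if n_grid < 16:
        raise ParameterError("n_grid must be >= 16")
    lo, hi = band
    if not 0 < lo < hi <= fs / 2:
        raise ParameterError(f"band {band} must lie inside (0, fs/2]")
    freqs = np.linspace(lo, hi, n_grid)
    omegas = 2 * np.pi * freqs / fs
    steering = np.exp(-1j * np.outer(np.arange(snapshot_len), omegas))
    denom = np.sum(np.abs(noise_basis.conj().T @ steering) ** 2, axis=0)
    capped = denom < 1.0 / PSEUDO_SPECTRUM_CAP
    values = 1.0 / np.maximum(denom, 1.0 / PSEUDO_SPECTRUM_CAP)
    return PseudoSpectrum(
        omegas=omegas, frequencies=freqs, values=values,
        signal_dim=snapshot_len - noise_basis.shape[1], capped=capped,
    )


def estimate_frequency(spec: PseudoSpectrum) -> float:
    """Frequency of the pseudo-spectrum's global maximum (lowest on ties)."""
    if len(spec.values) == 0:
        raise ParameterError("empty spectrum")
    return float(spec.frequencies[int(np.argmax(spec.values))])


def to_bpm(freq_hz: float) -> int:
    """Convert a frequency in Hz to integer beats (breaths) per minute.

    Rounds half away from zero: 0.29 Hz -> 17.4 -> 17 BPM,
    1.35 Hz -> 81 BPM.
    """
    if freq_hz < 0:
        raise ParameterError("frequency must be non-negative")
    return int(math.floor(60.0 * freq_hz + 0.5))


def save_spectrum_csv(spec: PseudoSpectrum, path) -> None:
    np.savetxt(
        path,
        np.column_stack([spec.frequencies, spec.values]),
        delimiter=",", header="frequency_hz,pseudo_spectrum", comments="",
    )
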