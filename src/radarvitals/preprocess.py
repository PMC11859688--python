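"""Phase pre-processing: DC removal, range FFT, phase extraction.

Turns an IF data cube into the 1-D thoracic phase signal:

1. remove the DC / static component per range column over slow time,
2. fast-time FFT to resolve reflectors into range bins,
3. pick the subject's range bin,
4. four-quadrant arctangent of (I, Q) at that bin per frame,
5. unwrap the +-2*pi jumps,
6. first-difference to suppress residual low-frequency drift.

The arctangent is the four-quadrant ``atan2`` rather than ``arctan(Q/I)``:
the plain ratio cannot distinguish opposite quadrants and unwrapping assumes
a (-pi, pi] wrapped input. Unwrapping applies cumulative multi-wrap
correction: centimetre-scale chest excursions at a ~5 mm wavelength produce
phase swings of several multiples of 2*pi, so a single-jump correction would
not suffice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .exceptions import ParameterError
from .simulate import SPEED_OF_LIGHT, IFDataCube

__all__ = [
    "RangeProfile",
    "PhaseSignal",
    "remove_dc",
    "range_fft",
    "select_target_bin",
    "extract_phase",
    "unwrap_phase",
    "diff_phase",
    "wrap_phase",
    "save_phase_csv",
    "load_phase_csv",
]

_STAGES = ("wrapped", "unwrapped", "differenced", "separated")


@dataclass
class RangeProfile:
    """Fast-time FFT of a DC-removed cube: [n_frames x n_adc] spectra.

    ``bin_axis[k]`` is the range of bin ``k`` in metres; ``fs`` is the
    slow-time sampling rate carried through to the phase signal.
    """

    spectra: np.ndarray
    bin_axis: np.ndarray
    fs: float

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=np.complex128)
        self.bin_axis = np.asarray(self.bin_axis, dtype=float)
        if self.spectra.shape[1] != self.bin_axis.size:
            raise ParameterError("bin_axis length must match spectra width")


@dataclass
class PhaseSignal:
    """Real-valued slow-time phase series with a processing-stage tag."""

    values: np.ndarray
    fs: float
    stage: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values contain non-finite entries")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.stage not in _STAGES:
            raise ParameterError(f"stage must be one of {_STAGES}")
        if self.stage == "wrapped" and np.any(np.abs(self.values) > np.pi + 1e-12):
            raise ParameterError("wrapped phase must lie in (-pi, pi]")

    def __len__(self) -> int:
        return self.values.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


def remove_dc(cube: IFDataCube) -> IFDataCube:
    """Subtract each fast-time column's slow-time mean (DC / static clutter).

    Per-column (not global scalar) removal zeroes every static reflector's
    constant contribution in every range bin; the operation is idempotent.
    """
    if cube.samples.size == 0:
        raise ParameterError("empty cube")
    cleaned = cube.samples - cube.samples.mean(axis=0, keepdims=True)
    return IFDataCube(samples=cleaned, config=cube.config, truth=cube.truth)


def range_fft(cube: IFDataCube, window: str = "rect") -> RangeProfile:
    """Fast-time DFT per frame. No zero padding; rectangular window default."""
    samples = cube.samples
    if window not in ("rect", "rectangular", "boxcar"):
        w = get_window(window, cube.config.n_adc, fftbins=True)
        samples = samples * w[None, :]
    spectra = np.fft.fft(samples, axis=1)
    cfg = cube.config
    bin_axis = (
        np.arange(cfg.n_adc) * SPEED_OF_LIGHT * cfg.fs_adc / (2.0 * cfg.kappa * cfg.n_adc)
    )
    return RangeProfile(spectra=spectra, bin_axis=bin_axis, fs=cfg.frame_rate)


def select_target_bin(profile: RangeProfile, gate: tuple | None = None) -> int:
    """Bin with the largest mean magnitude over slow time, optionally gated.

    ``gate`` is a ``(min_range, max_range)`` interval in metres. Ties break
    to the lowest index.
    """
    mag = np.abs(profile.spectra).mean(axis=0)
    if gate is None:
        return int(np.argmax(mag))
    lo, hi = gate
    idx = np.where((profile.bin_axis >= lo) & (profile.bin_axis <= hi))[0]
    if idx.size == 0:
        raise ParameterError(f"gate {gate} contains no range bin")
    return int(idx[np.argmax(mag[idx])])


def extract_phase(profile: RangeProfile, bin_index: int) -> PhaseSignal:
    """Four-quadrant arctangent of (I, Q) at one range bin, per frame."""
    if not 0 <= bin_index < profile.spectra.shape[1]:
        raise ParameterError(f"bin {bin_index} out of range")
    z = profile.spectra[:, bin_index]
    values = np.arctan2(z.imag, z.real)
    # atan2 returns [-pi, pi]; fold the -pi edge onto +pi for (-pi, pi]
    values[values == -np.pi] = np.pi
    return PhaseSignal(values=values, fs=profile.fs, stage="wrapped")


def unwrap_phase(sig: PhaseSignal) -> PhaseSignal:
    """Cumulative 2*pi-jump correction of a wrapped phase series.

    Whenever a step between consecutive samples exceeds pi in magnitude the
    appropriate multiple of 2*pi is subtracted from all subsequent samples,
    so arbitrarily many wraps unwrap correctly. The first sample is
    unchanged.
    """
    if sig.stage != "wrapped":
        raise ParameterError("unwrap_phase expects a wrapped signal")
    if len(sig) < 2:
        warnings.warn("fewer than 2 samples; nothing to unwrap", stacklevel=2)
        return PhaseSignal(values=sig.values.copy(), fs=sig.fs, stage="unwrapped")
    return PhaseSignal(values=np.unwrap(sig.values), fs=sig.fs, stage="unwrapped")


def diff_phase(sig: PhaseSignal) -> PhaseSignal:
    """First difference of the unwrapped phase (length shrinks by one)."""
    if sig.stage != "unwrapped":
        raise ParameterError("diff_phase expects an unwrapped signal")
    if len(sig) < 2:
        raise ParameterError("need at least 2 samples to difference")
    return PhaseSignal(values=np.diff(sig.values), fs=sig.fs, stage="differenced")


def wrap_phase(x) -> np.ndarray:
    """Wrap arbitrary real values into (-pi, pi]."""
    w = np.mod(np.asarray(x, dtype=float), 2 * np.pi)
    w = np.where(w > np.pi, w - 2 * np.pi, w)
    return w


def save_phase_csv(sig: PhaseSignal, path) -> None:
    data = np.column_stack([sig.time, sig.values])
    np.savetxt(
        path, data, delimiter=",",
        header=f"time_s,value_rad  # fs={sig.fs} stage={sig.stage}", comments="",
    )


def load_phase_csv(path, fs: float, stage: str) -> PhaseSignal:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return PhaseSignal(values=data[:, 1], fs=fs, stage=stage)
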