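"""Forward model: synthetic FMCW intermediate-frequency (IF) data cubes.

An FMCW radar transmits a linear chirp of bandwidth ``B`` over duration
``T``; mixing the echo of a reflector at range ``R`` with the transmit
signal yields a beat tone at ``f_b = 2*kappa*R/c`` (``kappa = B/T``) whose
phase tracks sub-wavelength range changes as ``dphi = 4*pi*dR/lambda``.
Chest-wall motion from respiration (0.1-0.5 Hz, ~4-12 mm) and heartbeat
(0.8-2 Hz, ~0.2-0.5 mm) therefore modulates the phase of the target's
range bin across slow time.

This module synthesises that signal with known ground truth so every
downstream stage of the pipeline can be tested without hardware: a moving
chest reflector, optional static clutter reflectors, a DC offset, optional
phase noise, and additive complex Gaussian noise at a prescribed SNR.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ParameterError, UnambiguousRangeError

SPEED_OF_LIGHT = 299792458.0

RESP_BAND = (0.1, 0.5)
HEART_BAND = (0.8, 2.0)

__all__ = [
    "SPEED_OF_LIGHT",
    "RESP_BAND",
    "HEART_BAND",
    "RadarConfig",
    "VitalTruth",
    "IFDataCube",
    "chest_displacement",
    "simulate_if_cube",
    "save_cube_npz",
    "load_cube_npz",
    "save_cube_raw",
    "load_cube_raw",
    "save_cube_csv",
    "load_cube_csv",
]


@dataclass(frozen=True)
class RadarConfig:
    """FMCW waveform and sampling parameters.

    Parameters
    ----------
    fc : float
        Chirp start (carrier) frequency in Hz.
    B : float
        Sweep bandwidth in Hz.
    T : float
        Chirp duration in s.
    n_adc : int
        Fast-time ADC samples per chirp.
    fs_adc : float
        ADC sampling rate in Hz.
    frame_rate : float
        Slow-time sampling rate in frames/s. Must exceed twice the highest
        heartbeat frequency of interest (2 Hz) for the phase signal to be
        adequately sampled.
    """

    fc: float = 60.25e9
    B: float = 3.6e9
    T: float = 64e-6
    n_adc: int = 128
    fs_adc: float = 2e6
    frame_rate: float = 20.0

    def __post_init__(self):
        if self.fc <= 0 or self.B <= 0 or self.T <= 0 or self.fs_adc <= 0:
            raise ParameterError("fc, B, T and fs_adc must be positive")
        if self.n_adc < 2:
            raise ParameterError("n_adc must be >= 2")
        if self.frame_rate <= 2.0 * HEART_BAND[1]:
            raise ParameterError(
                f"frame_rate={self.frame_rate} Hz under-samples heartbeat; "
                f"need > {2.0 * HEART_BAND[1]} Hz"
            )

    @property
    def kappa(self) -> float:
        """Chirp slope B/T in Hz/s."""
        return self.B / self.T

    @property
    def wavelength(self) -> float:
        """Carrier wavelength c/fc in m (always derived, never stored)."""
        return SPEED_OF_LIGHT / self.fc

    @property
    def max_unambiguous_range(self) -> float:
        """Largest range whose beat frequency stays below fs_adc/2."""
        return SPEED_OF_LIGHT * self.fs_adc / (4.0 * self.kappa)

    def beat_frequency(self, r: float) -> float:
        """Beat frequency 2*kappa*r/c of a reflector at range ``r``."""
        return 2.0 * self.kappa * r / SPEED_OF_LIGHT

    def range_bin(self, r: float) -> int:
        """Nearest fast-time FFT bin for a reflector at range ``r``."""
        return int(round(self.beat_frequency(r) * self.n_adc / self.fs_adc))


@dataclass(frozen=True)
class VitalTruth:
    """Ground-truth chest-motion model consumed by the simulator.

    Displacement amplitudes are in metres. ``resp_harmonics`` and
    ``heart_harmonics`` are tuples of ``(order, relative_amplitude)``
    adding ``rel * a * sin(2*pi*order*f*t)`` terms to the fundamental;
    real chest motion is non-sinusoidal, and these harmonics are what
    make heart-rate estimation hard (a respiration 3rd harmonic falls in
    the heartbeat band).

    ``noise_snr_db`` sets the additive complex Gaussian noise power
    relative to the mean power of the noiseless cube; ``None`` disables
    noise. ``clutter`` is a tuple of ``(range_m, amplitude)`` static
    reflectors. ``dc_offset`` is added to every IF sample.
    """

    f_resp: float = 0.29
    a_resp: float = 5.0e-3
    f_heart: float = 1.35
    a_heart: float = 0.35e-3
    resp_harmonics: tuple = ((2, 0.15), (3, 0.05))
    heart_harmonics: tuple = ((2, 0.2),)
    target_range: float = 1.0
    clutter: tuple = ((0.5, 0.3), (1.8, 0.2))
    dc_offset: complex = 0.1 + 0.1j
    noise_snr_db: float | None = 10.0
    phase_noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.a_resp < 0 or self.a_heart < 0:
            raise ParameterError("displacement amplitudes must be non-negative")
        if any(rel < 0 for _, rel in self.resp_harmonics) or any(
            rel < 0 for _, rel in self.heart_harmonics
        ):
            raise ParameterError("harmonic amplitudes must be non-negative")
        if self.phase_noise_std < 0:
            raise ParameterError("phase_noise_std must be non-negative")
        if self.a_resp > 0 and not (RESP_BAND[0] <= self.f_resp <= RESP_BAND[1]):
            warnings.warn(
                f"f_resp={self.f_resp} Hz outside the physiological band "
                f"{RESP_BAND}", stacklevel=2,
            )
        if self.a_heart > 0 and not (HEART_BAND[0] <= self.f_heart <= HEART_BAND[1]):
            warnings.warn(
                f"f_heart={self.f_heart} Hz outside the physiological band "
                f"{HEART_BAND}", stacklevel=2,
            )


@dataclass
class IFDataCube:
    """Complex IF samples arranged slow time x fast time.

    ``samples[k, n]`` is ADC sample ``n`` of the chirp at slow-time frame
    ``k``. ``truth`` is present for simulated cubes and absent for imported
    recordings.
    """

    samples: np.ndarray
    config: RadarConfig
    truth: VitalTruth | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 2:
            raise ParameterError("samples must be a 2-D [n_frames x n_adc] array")
        if self.samples.shape[1] != self.config.n_adc:
            raise ParameterError(
                f"fast-time size {self.samples.shape[1]} != config.n_adc "
                f"{self.config.n_adc}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def slow_time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.config.frame_rate


def chest_displacement(truth: VitalTruth, t) -> np.ndarray:
    """Deterministic chest-wall displacement d(t) in metres.

    Sum of the respiration and heartbeat fundamentals and their declared
    harmonics; contains no noise terms.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or (t.size > 1 and not np.all(np.diff(t) > 0)):
        raise ParameterError("time points must be a strictly increasing 1-D sequence")
    d = truth.a_resp * np.sin(2 * np.pi * truth.f_resp * t)
    d += truth.a_heart * np.sin(2 * np.pi * truth.f_heart * t)
    for order, rel in truth.resp_harmonics:
        d += rel * truth.a_resp * np.sin(2 * np.pi * order * truth.f_resp * t)
    for order, rel in truth.heart_harmonics:
        d += rel * truth.a_heart * np.sin(2 * np.pi * order * truth.f_heart * t)
    return d


def simulate_if_cube(
    config: RadarConfig,
    truth: VitalTruth,
    duration: float,
    n_chirps_avg: int = 1,
) -> IFDataCube:
    """Simulate an IF data cube of ``duration`` seconds.

    One chirp is synthesised per slow-time frame: the pipeline consumes one
    phase sample per frame, so a frame's chirp group is represented by a
    single chirp. ``n_chirps_avg > 1`` emulates intra-frame chirp averaging
    by averaging that many independent-noise copies of each frame (the
    deterministic part is identical across a frame's chirps).

    The chest echo at frame ``k`` is
    ``exp(j*(2*pi*f_b*n/fs_adc + 4*pi*R(t_k)/lambda))`` with
    ``R(t_k) = target_range + d(t_k)`` and ``f_b`` the beat frequency of
    the nominal range (displacement is sub-mm and does not shift the range
    bin). Static clutter enters as constant-phase beat tones at its own
    ranges; then the DC offset and, last, complex Gaussian noise scaled to
    ``noise_snr_db`` relative to the mean noiseless power.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    n_frames = int(round(duration * config.frame_rate))
    if n_frames < 2:
        raise ParameterError("duration*frame_rate must be >= 2")
    if n_chirps_avg < 1:
        raise ParameterError("n_chirps_avg must be >= 1")
    r_max = config.max_unambiguous_range
    for r in [truth.target_range] + [r for r, _ in truth.clutter]:
        if not 0 < r < r_max:
            raise UnambiguousRangeError(
                f"range {r} m outside (0, {r_max:.3f}) m unambiguous span"
            )

    t_k = np.arange(n_frames) / config.frame_rate
    n = np.arange(config.n_adc)
    lam = config.wavelength
    rng = np.random.default_rng(truth.seed)

    r_t = truth.target_range + chest_displacement(truth, t_k)
    fb = config.beat_frequency(truth.target_range)
    fast = 2 * np.pi * fb * n[None, :] / config.fs_adc
    slow = (4 * np.pi / lam) * r_t[:, None]
    cube = np.exp(1j * (fast + slow))

    for r_c, amp in truth.clutter:
        fb_c = config.beat_frequency(r_c)
        cube += amp * np.exp(
            1j * (2 * np.pi * fb_c * n[None, :] / config.fs_adc + 4 * np.pi * r_c / lam)
        )
    cube += truth.dc_offset

    if truth.phase_noise_std > 0:
        cube = cube * np.exp(
            1j * truth.phase_noise_std * rng.standard_normal(cube.shape)
        )

    if truth.noise_snr_db is not None:
        p_sig = float(np.mean(np.abs(cube) ** 2))
        p_noise = p_sig * 10.0 ** (-truth.noise_snr_db / 10.0)
        sigma = np.sqrt(p_noise / 2.0)
        noise = np.zeros_like(cube)
        for _ in range(n_chirps_avg):
            noise += sigma * (
                rng.standard_normal(cube.shape) + 1j * rng.standard_normal(cube.shape)
            )
        cube = cube + noise / n_chirps_avg

    return IFDataCube(samples=cube, config=config, truth=truth)


# ---------------------------------------------------------------------------
# Serialisation


def _truth_to_jsonable(truth: VitalTruth) -> dict:
    d = asdict(truth)
    d["dc_offset"] = [truth.dc_offset.real, truth.dc_offset.imag]
    return d


def _truth_from_jsonable(d: dict) -> VitalTruth:
    d = dict(d)
    re, im = d["dc_offset"]
    d["dc_offset"] = complex(re, im)
    d["resp_harmonics"] = tuple(tuple(h) for h in d["resp_harmonics"])
    d["heart_harmonics"] = tuple(tuple(h) for h in d["heart_harmonics"])
    d["clutter"] = tuple(tuple(c) for c in d["clutter"])
    return VitalTruth(**d)


def save_cube_npz(cube: IFDataCube, path) -> None:
    """Write a cube to NPZ with config/truth as JSON string arrays."""
    meta = {"config": asdict(cube.config)}
    if cube.truth is not None:
        meta["truth"] = _truth_to_jsonable(cube.truth)
    np.savez(path, samples=cube.samples, meta=np.array(json.dumps(meta)))


def load_cube_npz(path) -> IFDataCube:
    with np.load(path, allow_pickle=False) as z:
        samples = z["samples"]
        meta = json.loads(str(z["meta"]))
    truth = _truth_from_jsonable(meta["truth"]) if "truth" in meta else None
    return IFDataCube(samples=samples, config=RadarConfig(**meta["config"]), truth=truth)


def save_cube_raw(cube: IFDataCube, path) -> None:
    """Interleaved float32 I/Q binary plus a YAML sidecar (<path>.yaml)."""
    path = Path(path)
    inter = np.empty(cube.samples.size * 2, dtype=np.float32)
    inter[0::2] = cube.samples.real.ravel()
    inter[1::2] = cube.samples.imag.ravel()
    inter.tofile(path)
    meta = {"config": asdict(cube.config), "n_frames": cube.n_frames}
    if cube.truth is not None:
        meta["truth"] = _truth_to_jsonable(cube.truth)
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def load_cube_raw(path) -> IFDataCube:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".yaml")) as fh:
        meta = yaml.safe_load(fh)
    config = RadarConfig(**meta["config"])
    inter = np.fromfile(path, dtype=np.float32)
    samples = (inter[0::2] + 1j * inter[1::2]).reshape(meta["n_frames"], config.n_adc)
    truth = _truth_from_jsonable(meta["truth"]) if "truth" in meta else None
    return IFDataCube(samples=samples, config=config, truth=truth)


def save_cube_csv(cube: IFDataCube, path) -> None:
    """One frame per row, columns I0,Q0,I1,Q1,...; for small fixtures only."""
    flat = np.empty((cube.n_frames, 2 * cube.config.n_adc))
    flat[:, 0::2] = cube.samples.real
    flat[:, 1::2] = cube.samples.imag
    header = ",".join(f"I{i},Q{i}" for i in range(cube.config.n_adc))
    np.savetxt(path, flat, delimiter=",", header=header, comments="")


def load_cube_csv(path, config: RadarConfig) -> IFDataCube:
    flat = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    samples = flat[:, 0::2] + 1j * flat[:, 1::2]
    return IFDataCube(samples=samples, config=config)
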