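"""Exception hierarchy for the radarvitals pipeline.

Stage errors raised inside :func:`radarvitals.pipeline.run_pipeline` are
re-raised wrapped in :class:`StageError` so callers can tell which stage of
the chain failed.
"""


class RadarVitalsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RadarVitalsError, ValueError):
    """A physical or configuration parameter is invalid (e.g. negative amplitude)."""


class UnambiguousRangeError(RadarVitalsError, ValueError):
    """A reflector lies beyond the radar's unambiguous range c*fs_adc/(4*kappa)."""


class NoPhysiologicalComponentError(RadarVitalsError, RuntimeError):
    """No eigencomponent has its dominant frequency inside the requested band.

    Usually means the SNR is too low, the observation too short, or the band
    does not match the signal content.
    """


class StageError(RadarVitalsError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
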