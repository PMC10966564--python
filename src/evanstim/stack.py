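"""In-memory containers for camera data and the stimulation protocol."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError

__all__ = ["OpticalStack", "StimulationProtocol"]


@dataclass
class OpticalStack:
    """A time-lapse (or single-frame) stack of camera counts with metadata.

    ``data`` has shape (frames, rows, cols) and holds non-negative counts.
    Frame *i* starts at time ``t0_s + i * frame_interval_s``; each frame is
    integrated over ``exposure_s``.  ``frame_interval_s`` may be None only
    for single-frame stacks (still images carry no time base).
    """

    data: np.ndarray
    frame_interval_s: float | None = 0.1
    exposure_s: float = 0.01
    pixel_size_um: float | None = None
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis, ...]
        if self.data.ndim != 3:
            raise ValidationError(f"data must be 2-D or 3-D (got ndim={self.data.ndim})")
        if self.data.size == 0:
            raise ValidationError("data must be non-empty")
        if np.min(self.data) < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_frames > 1:
            if self.frame_interval_s is None or self.frame_interval_s <= 0:
                raise ValidationError(
                    "frame_interval_s must be positive for multi-frame stacks"
                )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def sampling_rate_hz(self) -> float:
        if self.frame_interval_s is None:
            raise ValidationError("stack has no time base (frame_interval_s is None)")
        return 1.0 / self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        """Start time of every frame."""
        if self.n_frames > 1 and self.frame_interval_s is None:
            raise ValidationError("stack has no time base (frame_interval_s is None)")
        dt = self.frame_interval_s if self.frame_interval_s is not None else 0.0
        return self.t0_s + dt * np.arange(self.n_frames)

    @property
    def duration_s(self) -> float:
        dt = self.frame_interval_s if self.frame_interval_s is not None else 0.0
        return self.n_frames * dt

    def with_data(self, data: np.ndarray, **meta) -> "OpticalStack":
        """Copy of this stack with new pixel data and optional metadata updates."""
        return replace(self, data=data, **meta)

    def metadata(self) -> dict:
        return {
            "frame_interval_s": self.frame_interval_s,
            "exposure_s": self.exposure_s,
            "pixel_size_um": self.pixel_size_um,
            "t0_s": self.t0_s,
        }


@dataclass(frozen=True)
class StimulationProtocol:
    """Optogenetic stimulation timing: a quiet background period followed by a
    train of short light pulses at a fixed rate.

    Defaults mirror the platform's standard protocol: 20 s of background, then
    10 pulses of 60 ms at 1 Hz, within a 60 s recording sampled at 10 Hz.
    """

    background_s: float = 20.0
    n_pulses: int = 10
    pulse_rate_hz: float = 1.0
    pulse_width_s: float = 0.06
    total_s: float = 60.0

    def __post_init__(self) -> None:
        if self.background_s < 0:
            raise ValidationError("background_s must be >= 0")
        if self.n_pulses < 1:
            raise ValidationError("n_pulses must be >= 1")
        if self.pulse_rate_hz <= 0:
            raise ValidationError("pulse_rate_hz must be positive")
        if not 0 < self.pulse_width_s < 1.0 / self.pulse_rate_hz:
            raise ValidationError("pulse_width_s must lie in (0, 1/pulse_rate_hz)")
        if self.background_s + self.n_pulses / self.pulse_rate_hz > self.total_s:
            raise ValidationError("background + pulse train must fit inside total_s")

    @property
    def pulse_times_s(self) -> np.ndarray:
        """Onset time of every pulse."""
        return self.background_s + np.arange(self.n_pulses) / self.pulse_rate_hz

    @property
    def stimulation_window_s(self) -> tuple[float, float]:
        """Default analysis window: from 1 s after stimulation onset, spanning
        the pulse train (21-31 s for the default protocol)."""
        start = self.background_s + 1.0
        return (start, start + self.n_pulses / self.pulse_rate_hz)
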