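"""Per-pixel frequency-domain mapping of stimulation-locked calcium responses.

A pixel that responds to a periodic stimulus (pulse rate ``f_stim``) carries
spectral power at integer multiples of ``f_stim``.  The responder statistic is
therefore the sum of unnormalized DFT magnitudes at the harmonic bins,

    score = sum_k |X[bin(k f_stim)]|,   k in {1, ..., 5} by default,

computed over the analysis window in which the stimulation occurs (21-31 s
for the default protocol).  The DC bin is excluded, which makes the score
exactly invariant to any constant offset.  Scores are normalized to the
maximum over the field of view, so the map lives in [0, 1] and is invariant
to a global rescaling of the traces.

Harmonics must fall exactly on DFT bins (``k f_stim N / fs`` integer); with
the default protocol (10 s window at 10 Hz, N = 100) every integer harmonic
of 1 Hz does.  Off-bin harmonics are refused rather than silently leaked.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .stack import OpticalStack, StimulationProtocol

__all__ = [
    "ResponseMap",
    "DEFAULT_HARMONICS",
    "extract_window",
    "harmonic_response_score",
    "response_map",
    "roi_average_trace",
    "classify_responders",
]

DEFAULT_HARMONICS = (1, 2, 3, 4, 5)


@dataclass
class ResponseMap:
    """Per-pixel normalized harmonic response scores in [0, 1]."""

    scores: np.ndarray
    window_s: tuple[float, float]
    harmonics: tuple[int, ...]
    f_stim_hz: float
    raw_max_score: float

    def to_metadata(self) -> dict:
        return {
            "window_s": list(self.window_s),
            "harmonics": list(self.harmonics),
            "f_stim_hz": self.f_stim_hz,
            "raw_max_score": self.raw_max_score,
        }


def extract_window(movie: OpticalStack, start_s: float, end_s: float) -> OpticalStack:
    """Frames whose start time lies in the half-open interval [start, end).

    The returned stack's ``t0_s`` is the start time of its first frame.
    """
    if movie.n_frames < 2:
        raise ValidationError("windowing requires a multi-frame stack")
    t = movie.times_s
    sel = (t >= start_s) & (t < end_s)
    if not sel.any():
        raise ValidationError(
            f"window [{start_s}, {end_s}) s contains no frames of the "
            f"{movie.duration_s:.1f} s recording"
        )
    return movie.with_data(movie.data[sel], t0_s=float(t[sel][0]))


def _harmonic_bins(
    n: int, fs_hz: float, f_stim_hz: float, harmonics: tuple[int, ...]
) -> list[int]:
    if not harmonics:
        raise ValidationError("harmonics set must be non-empty")
    bins = []
    for k in sorted(set(int(h) for h in harmonics)):
        if k <= 0:
            raise ValidationError(
                f"harmonic {k} is not allowed: the DC bin (and negative orders) "
                "are excluded by construction"
            )
        b = k * f_stim_hz * n / fs_hz
        if abs(b - round(b)) > 1e-9:
            raise ValidationError(
                f"harmonic {k} ({k * f_stim_hz} Hz) does not fall on a DFT bin "
                f"for N={n}, fs={fs_hz} Hz (bin index {b:.6g} is not an integer)"
            )
        b = int(round(b))
        if b > n // 2:
            raise ValidationError(
                f"harmonic {k} ({k * f_stim_hz} Hz) exceeds the Nyquist "
                f"frequency ({fs_hz / 2} Hz)"
            )
        bins.append(b)
    return bins


def harmonic_response_score(
    trace: np.ndarray,
    fs_hz: float,
    f_stim_hz: float,
    harmonics: tuple[int, ...] = DEFAULT_HARMONICS,
) -> float:
    """Sum of raw DFT magnitudes of ``trace`` at the stimulation harmonics.

    Uses the unnormalized forward DFT of the raw trace — no taper, no
    detrending; DC is handled purely by bin exclusion.
    """
    trace = np.asarray(trace, float).ravel()
    bins = _harmonic_bins(trace.size, fs_hz, f_stim_hz, harmonics)
    spectrum = np.fft.rfft(trace)
    return float(np.sum(np.abs(spectrum[bins])))


def response_map(
    movie: OpticalStack,
    protocol: StimulationProtocol,
    window_s: tuple[float, float] | None = None,
    harmonics: tuple[int, ...] = DEFAULT_HARMONICS,
) -> ResponseMap:
    """Per-pixel harmonic response scores, normalized to the FOV maximum.

    Equivalent to mapping :func:`harmonic_response_score` over every pixel
    trace of the windowed movie (no cross-pixel coupling), then dividing by
    the maximum score in the field of view.  An all-zero movie yields an
    all-zero map (no division).
    """
    win = window_s if window_s is not None else protocol.stimulation_window_s
    sub = extract_window(movie, *win)
    fs = sub.sampling_rate_hz
    n = sub.n_frames
    f_stim = protocol.pulse_rate_hz
    win_len = n / fs
    cycles = win_len * f_stim
    if abs(cycles - round(cycles)) > 1e-9:
        warnings.warn(
            f"analysis window ({win_len:.3g} s) is not an integer number of "
            f"stimulation periods (1/f_stim = {1 / f_stim:.3g} s)",
            stacklevel=2,
        )
    bins = _harmonic_bins(n, fs, f_stim, harmonics)
    spectra = np.fft.rfft(sub.data.astype(float), axis=0)
    raw = np.abs(spectra[bins]).sum(axis=0)
    raw_max = float(raw.max())
    scores = raw / raw_max if raw_max > 0 else raw
    return ResponseMap(
        scores=scores,
        window_s=(float(win[0]), float(win[1])),
        harmonics=tuple(sorted(set(int(h) for h in harmonics))),
        f_stim_hz=float(f_stim),
        raw_max_score=raw_max,
    )


def roi_average_trace(movie: OpticalStack, roi_mask: np.ndarray) -> np.ndarray:
    """Per-frame arithmetic mean of the counts inside a boolean ROI mask."""
    roi_mask = np.asarray(roi_mask)
    if roi_mask.shape != movie.frame_shape:
        raise ValidationError(
            f"roi_mask shape {roi_mask.shape} does not match the frame shape "
            f"{movie.frame_shape}"
        )
    if not roi_mask.any():
        raise ValidationError("roi_mask is empty")
    return movie.data[:, roi_mask.astype(bool)].mean(axis=1)


def classify_responders(result: ResponseMap, threshold: float = 0.5) -> np.ndarray:
    """Boolean responder mask: pixels whose normalized score exceeds
    ``threshold``.  The threshold is a reporting convenience, not part of the
    mapping itself, and is always explicit in outputs."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    return result.scores > threshold
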