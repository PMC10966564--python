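"""Synthetic microscopy and transmission data with known ground truth.

Every generator is a deterministic function of its parameters and seed and
returns a machine-readable ground-truth record next to the data, so each
analysis stage has a recovery test that needs no external downloads.

The generators emulate the platform's operating conditions:

* bead images — a fluorophore-coated sphere on the guiding surface, excited
  by an exponentially decaying evanescent field (peak ~2.5e3 counts at the
  contact point), imaged at 0.11 um/px, optionally masked to a waveguide
  excitation stripe (which renders the excited region elliptical when the
  bead sits at the stripe edge);
* calcium movies — a 20 s background followed by 10 stimulation pulses at
  1 Hz; responder cells gain an exponentially decaying fluorescence transient
  (dF/F0 = 0.3, tau = 0.5 s by default — typical Rhod-3 scale) at every pulse
  onset, with responders either all cells (full-field stimulation) or only
  cells intersecting the waveguide stripe;
* cut-back tables — a line in device length with Gaussian measurement noise,
  spanning the platform's 1.2-8.1 cm device range.

Camera noise: Poisson shot noise on the expected counts, Gaussian read noise,
and a constant baseline offset, finally rounded to integer counts and clipped
at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beads import BeadSpec
from .exceptions import ValidationError
from .loss import CutbackDataset
from .stack import OpticalStack, StimulationProtocol

__all__ = [
    "NoiseModel",
    "demo_layout",
    "ExcitationStripe",
    "CellRegion",
    "SceneLayout",
    "generate_bead_image",
    "generate_calcium_movie",
    "generate_cutback_data",
    "DEFAULT_CUTBACK_LENGTHS_CM",
]

DEFAULT_CUTBACK_LENGTHS_CM = (1.2, 2.5, 4.0, 5.5, 7.0, 8.1)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: optional Poisson shot noise, Gaussian read noise, and a
    constant baseline offset.  Identical seeds give bit-identical output."""

    shot_noise: bool = True
    read_noise_sd_counts: float = 2.0
    offset_counts: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd_counts < 0:
            raise ValidationError("read_noise_sd_counts must be >= 0")
        if self.offset_counts < 0:
            raise ValidationError("offset_counts must be >= 0")

    def apply(self, expected: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw camera counts for an array of expected photon counts."""
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        out = rng.poisson(expected).astype(float) if self.shot_noise else expected.astype(float)
        out = out + self.offset_counts
        if self.read_noise_sd_counts > 0:
            out = out + rng.normal(0.0, self.read_noise_sd_counts, size=out.shape)
        return np.clip(np.rint(out), 0, None)

    def to_dict(self) -> dict:
        return {
            "shot_noise": self.shot_noise,
            "read_noise_sd_counts": self.read_noise_sd_counts,
            "offset_counts": self.offset_counts,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ExcitationStripe:
    """A waveguide excitation stripe across the frame.

    The stripe is the set of pixels within ``width_um / 2`` of the center
    line, which runs along ``axis`` ('x' = horizontal rows) at perpendicular
    position ``center_px`` (row index for axis 'x', column index for 'y').
    """

    center_px: float
    width_um: float = 4.5
    axis: str = "x"

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise ValidationError("width_um must be positive")
        if self.axis not in ("x", "y"):
            raise ValidationError("axis must be 'x' or 'y'")

    def mask(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        rows, cols = shape
        half_px = self.width_um / (2.0 * pixel_size_um)
        if self.axis == "x":
            dist = np.abs(np.arange(rows) - self.center_px)
            return np.broadcast_to((dist <= half_px)[:, None], shape).copy()
        dist = np.abs(np.arange(cols) - self.center_px)
        return np.broadcast_to((dist <= half_px)[None, :], shape).copy()

    def to_dict(self) -> dict:
        return {"center_px": self.center_px, "width_um": self.width_um, "axis": self.axis}


@dataclass(frozen=True)
class CellRegion:
    """An elliptical soma with optional straight neurite segments
    (each ((x0, y0), (x1, y1), width_px) in pixel coordinates)."""

    center_px: tuple[float, float]
    radii_px: tuple[float, float]
    orientation_deg: float = 0.0
    neurites: tuple[tuple[tuple[float, float], tuple[float, float], float], ...] = ()

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        th = math.radians(self.orientation_deg)
        dx, dy = xx - self.center_px[0], yy - self.center_px[1]
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        m = (u / self.radii_px[0]) ** 2 + (v / self.radii_px[1]) ** 2 <= 1.0
        for (p0, p1), width in ((seg[:2], seg[2]) for seg in self.neurites):
            vx, vy = p1[0] - p0[0], p1[1] - p0[1]
            norm2 = vx**2 + vy**2
            if norm2 == 0:
                continue
            t = np.clip(((xx - p0[0]) * vx + (yy - p0[1]) * vy) / norm2, 0.0, 1.0)
            dist = np.hypot(xx - (p0[0] + t * vx), yy - (p0[1] + t * vy))
            m |= dist <= width / 2.0
        return m


@dataclass(frozen=True)
class SceneLayout:
    """Cell geometry, optional waveguide stripe, and frame metadata for a
    synthetic calcium movie.  The default frame is a small fast test frame;
    the platform's full field of view is 1200x1200 pixels."""

    cell_regions: tuple[CellRegion, ...]
    waveguide_stripe: ExcitationStripe | None = None
    frame_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.55

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        rows, cols = self.frame_shape
        for cell in self.cell_regions:
            cx, cy = cell.center_px
            if not (0 <= cx < cols and 0 <= cy < rows):
                raise ValidationError(f"cell center {cell.center_px} lies outside the frame")

    def cell_masks(self) -> list[np.ndarray]:
        return [c.mask(self.frame_shape) for c in self.cell_regions]

    def stripe_mask(self) -> np.ndarray | None:
        if self.waveguide_stripe is None:
            return None
        return self.waveguide_stripe.mask(self.frame_shape, self.pixel_size_um)


def demo_layout(
    frame_shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.55,
    stripe_center_px: float | None = None,
    n_on_stripe: int = 3,
    n_off_stripe: int = 3,
    seed: int = 0,
    stripe_width_um: float = 4.5,
) -> SceneLayout:
    """A reproducible scene with guaranteed on-stripe and off-stripe somata.

    On-stripe cells are centered on the (horizontal) stripe line; off-stripe
    cells are placed at least three soma radii away from it, so the
    waveguide/full-field responder dichotomy is unambiguous.
    """
    rng = np.random.default_rng(seed)
    rows, cols = frame_shape
    center = stripe_center_px if stripe_center_px is not None else rows / 2.0
    stripe = ExcitationStripe(center_px=center, width_um=stripe_width_um)
    half_px = stripe_width_um / (2.0 * pixel_size_um)
    cells = []
    xs = np.linspace(15, cols - 15, max(n_on_stripe, 1))
    for i in range(n_on_stripe):
        cells.append(
            CellRegion(
                center_px=(float(xs[i]), center + rng.uniform(-half_px, half_px)),
                radii_px=(rng.uniform(6, 9), rng.uniform(5, 7)),
                orientation_deg=float(rng.uniform(0, 180)),
            )
        )
    placed = 0
    while placed < n_off_stripe:
        cy = float(rng.uniform(12, rows - 12))
        radius = rng.uniform(5, 8)
        if abs(cy - center) < half_px + 3 * radius:
            continue
        cells.append(
            CellRegion(
                center_px=(float(rng.uniform(12, cols - 12)), cy),
                radii_px=(radius, rng.uniform(4, 7)),
                orientation_deg=float(rng.uniform(0, 180)),
            )
        )
        placed += 1
    return SceneLayout(
        cell_regions=tuple(cells),
        waveguide_stripe=stripe,
        frame_shape=frame_shape,
        pixel_size_um=pixel_size_um,
    )


def generate_bead_image(
    bead: BeadSpec,
    d_p_true_nm: float,
    peak_counts: float = 2.5e3,
    pixel_size_um: float = 0.11,
    excitation_stripe: ExcitationStripe | None = None,
    noise: NoiseModel = NoiseModel(),
    frame_shape: tuple[int, int] = (128, 128),
    center_px: tuple[float, float] | None = None,
) -> tuple[OpticalStack, dict]:
    """Single-frame image of a bead excited by an evanescent field.

    Expected counts at a pixel under the bead are
    ``peak_counts * exp(-y(r) / d_p_true)`` with the sphere height map
    ``y(r) = R - sqrt(R^2 - r^2)``; pixels outside the projected disc (or
    outside the excitation stripe, if one is given) carry no signal.
    """
    if d_p_true_nm <= 0:
        raise ValidationError("d_p_true_nm must be positive")
    if peak_counts <= 0:
        raise ValidationError("peak_counts must be positive")
    rows, cols = frame_shape
    radius_px = bead.radius_um / pixel_size_um
    if 2 * radius_px > min(rows, cols):
        raise ValidationError(
            f"bead (diameter {2 * radius_px:.0f} px) does not fit in the "
            f"{rows}x{cols} frame"
        )
    if center_px is None:
        center_px = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    yy, xx = np.mgrid[0:rows, 0:cols]
    r_um = pixel_size_um * np.hypot(xx - center_px[0], yy - center_px[1])
    inside = r_um < bead.radius_um
    heights_nm = np.zeros(frame_shape)
    heights_nm[inside] = (
        bead.radius_um - np.sqrt(bead.radius_um**2 - r_um[inside] ** 2)
    ) * 1e3
    expected = np.where(inside, peak_counts * np.exp(-heights_nm / d_p_true_nm), 0.0)
    if excitation_stripe is not None:
        expected = np.where(
            excitation_stripe.mask(frame_shape, pixel_size_um), expected, 0.0
        )
    counts = noise.apply(expected)
    stack = OpticalStack(
        data=counts, frame_interval_s=None, pixel_size_um=pixel_size_um
    )
    truth = {
        "kind": "bead_image",
        "d_p_true_nm": d_p_true_nm,
        "peak_counts": peak_counts,
        "bead_diameter_um": bead.diameter_um,
        "pixel_size_um": pixel_size_um,
        "center_px": list(center_px),
        "excitation_stripe": excitation_stripe.to_dict() if excitation_stripe else None,
        "noise": noise.to_dict(),
    }
    return stack, truth


def generate_calcium_movie(
    layout: SceneLayout,
    protocol: StimulationProtocol = StimulationProtocol(),
    transient_amplitude_frac: float = 0.3,
    decay_tau_s: float = 0.5,
    baseline_counts: float = 1000.0,
    background_counts: float = 250.0,
    stimulation_mode: str = "full_field",
    noise: NoiseModel = NoiseModel(),
    frame_interval_s: float = 0.1,
    exposure_s: float = 0.01,
) -> tuple[OpticalStack, dict]:
    """Time-lapse calcium movie with stimulation-locked transients.

    Responder pixels are all cell pixels (``full_field``) or the pixels of
    cells intersecting the waveguide stripe (``waveguide``).  Every pulse at
    onset ``t_i`` adds ``baseline * amplitude * exp(-(t - t_i)/tau)`` for
    ``t > t_i`` to responder traces (zero pulse-to-fluorescence latency).

    Returns the noisy movie and a truth record whose ``responder_mask`` /
    ``cell_mask`` arrays are the ground truth for recovery tests.
    """
    if stimulation_mode not in ("full_field", "waveguide"):
        raise ValidationError("stimulation_mode must be 'full_field' or 'waveguide'")
    if transient_amplitude_frac < 0 or decay_tau_s <= 0:
        raise ValidationError("transient amplitude must be >= 0 and tau > 0")
    if stimulation_mode == "waveguide" and layout.waveguide_stripe is None:
        raise ValidationError("waveguide stimulation requires a stripe in the layout")

    cell_masks = layout.cell_masks()
    cell_mask = np.zeros(layout.frame_shape, bool)
    for m in cell_masks:
        cell_mask |= m
    if stimulation_mode == "full_field":
        responder_mask = cell_mask.copy()
    else:
        stripe = layout.stripe_mask()
        responder_mask = np.zeros(layout.frame_shape, bool)
        for m in cell_masks:
            if (m & stripe).any():
                responder_mask |= m

    n_frames = int(round(protocol.total_s / frame_interval_s))
    t = frame_interval_s * np.arange(n_frames)
    transient = np.zeros(n_frames)
    for t_i in protocol.pulse_times_s:
        active = t > t_i
        transient[active] += np.exp(-(t[active] - t_i) / decay_tau_s)
    transient *= baseline_counts * transient_amplitude_frac

    expected = np.where(cell_mask, baseline_counts, background_counts)
    movie = np.broadcast_to(expected, (n_frames, *layout.frame_shape)).copy()
    movie[:, responder_mask] += transient[:, None]
    counts = noise.apply(movie)
    stack = OpticalStack(
        data=counts,
        frame_interval_s=frame_interval_s,
        exposure_s=exposure_s,
        pixel_size_um=layout.pixel_size_um,
    )
    truth = {
        "kind": "calcium_movie",
        "stimulation_mode": stimulation_mode,
        "transient_amplitude_frac": transient_amplitude_frac,
        "decay_tau_s": decay_tau_s,
        "baseline_counts": baseline_counts,
        "background_counts": background_counts,
        "pulse_times_s": protocol.pulse_times_s.tolist(),
        "noise": noise.to_dict(),
        "responder_mask": responder_mask,
        "cell_mask": cell_mask,
        "stripe_mask": layout.stripe_mask(),
    }
    return stack, truth


def generate_cutback_data(
    slope_true: float = -0.9,
    intercept_true: float = -13.4,
    lengths_cm: tuple[float, ...] = DEFAULT_CUTBACK_LENGTHS_CM,
    noise_sd_dB: float = 0.3,
    seed: int = 0,
    wavelength_nm: float = 489.0,
) -> tuple[CutbackDataset, dict]:
    """Cut-back transmissions ``T = slope * L + intercept + N(0, sd)``."""
    if noise_sd_dB < 0:
        raise ValidationError("noise_sd_dB must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = np.asarray(lengths_cm, float)
    noise = rng.normal(0.0, noise_sd_dB, size=lengths.size) if noise_sd_dB > 0 else 0.0
    trans = slope_true * lengths + intercept_true + noise
    data = CutbackDataset(
        lengths_cm=tuple(float(v) for v in lengths),
        transmissions_dB=tuple(float(v) for v in trans),
        wavelength_nm=wavelength_nm,
    )
    truth = {
        "kind": "cutback",
        "slope_true": slope_true,
        "intercept_true": intercept_true,
        "noise_sd_dB": noise_sd_dB,
        "seed": seed,
    }
    return data, truth
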