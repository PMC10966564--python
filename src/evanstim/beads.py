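"""Fluorescent-bead calibration of the evanescent-field penetration depth.

A micrometer-sized fluorophore-coated sphere resting on the guiding surface
samples the evanescent field at a continuum of heights: a pixel at lateral
distance ``r`` from the contact point images fluorophores at height

    y(r) = R - sqrt(R^2 - r^2),        R = bead diameter / 2,

so the radial intensity profile of the bead image encodes the vertical decay
of the excitation field.  The procedure is: locate the bead center with a 2-D
Gaussian fit, map every pixel to a height via the sphere geometry, fit
``I(y) = A exp(-y/d_p) + b``, and convert the fitted depth from the immersion
medium (typically index-matched sucrose) to the water cladding the platform
operates with.

Counts are assumed proportional to the local excitation intensity (equal
collection efficiency for all fluorophores regardless of height).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .evanescent import N_WATER, convert_penetration_depth
from .exceptions import FitFailure, LocalizationFailure, ValidationError
from .stack import OpticalStack

__all__ = [
    "BeadSpec",
    "BeadCenter",
    "PenetrationFit",
    "BeadFit",
    "fit_bead_center",
    "pixel_heights",
    "fit_penetration_depth",
    "run_bead_calibration",
]

MIN_FIT_PIXELS = 30


@dataclass(frozen=True)
class BeadSpec:
    """A fluorophore-coated calibration sphere."""

    diameter_um: float = 7.38
    fluorophore_label: str = "FITC"

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValidationError("diameter_um must be positive")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0


@dataclass(frozen=True)
class BeadCenter:
    """Sub-pixel bead center from a 2-D Gaussian fit.

    ``center_xy_px`` is (x, y) = (col, row) with pixel centers at integer
    coordinates.  ``center_se_px`` is the fit-covariance standard error of
    the center coordinates.
    """

    center_xy_px: tuple[float, float]
    amplitude_counts: float
    background_counts: float
    sigma_xy_px: tuple[float, float]
    center_se_px: tuple[float, float]


@dataclass(frozen=True)
class PenetrationFit:
    """Exponential decay fit ``I(y) = A exp(-y/d_p) + b``."""

    d_p_nm: float
    d_p_se_nm: float
    amplitude_counts: float
    background_counts: float
    n_pixels_used: int
    rms_residual_counts: float
    reliable: bool  #: False when the d_p standard error exceeds 50% of d_p


@dataclass(frozen=True)
class BeadFit:
    """Full bead-calibration result: localization, medium-frame depth, and
    water-converted depth, with the indices used for the conversion."""

    center_xy_px: tuple[float, float]
    amplitude_counts: float
    background_counts: float
    d_p_measured_nm: float
    d_p_measured_se_nm: float
    d_p_water_nm: float
    medium_index: float
    water_index: float
    wavelength_nm: float
    n_pixels_used: int
    rms_residual_counts: float
    reliable: bool

    def to_dict(self) -> dict:
        return {
            "center_xy_px": list(self.center_xy_px),
            "amplitude_counts": self.amplitude_counts,
            "background_counts": self.background_counts,
            "d_p_measured_nm": self.d_p_measured_nm,
            "d_p_measured_se_nm": self.d_p_measured_se_nm,
            "d_p_water_nm": self.d_p_water_nm,
            "medium_index": self.medium_index,
            "water_index": self.water_index,
            "wavelength_nm": self.wavelength_nm,
            "n_pixels_used": self.n_pixels_used,
            "rms_residual_counts": self.rms_residual_counts,
            "reliable": self.reliable,
        }


def _gauss2d(coords, amp, x0, y0, sx, sy, b):
    x, y = coords
    return amp * np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2))) + b


def fit_bead_center(
    image: OpticalStack | np.ndarray,
    approximate_center_px: tuple[float, float] | None = None,
) -> BeadCenter:
    """Locate the bead by least-squares fitting a 2-D elliptical Gaussian.

    The Gaussian is a localization model only (the true profile is the
    exponential-on-sphere shape); its center is what matters.  Raises
    :class:`LocalizationFailure` when the fit diverges or the fitted
    amplitude is below 3x the background noise SD.
    """
    frame = image.data[0] if isinstance(image, OpticalStack) else np.asarray(image)
    if frame.ndim != 2:
        raise ValidationError("bead localization expects a single 2-D frame")
    frame = frame.astype(float)
    rows, cols = frame.shape
    yy, xx = np.mgrid[0:rows, 0:cols]

    if approximate_center_px is None:
        y0, x0 = np.unravel_index(np.argmax(frame), frame.shape)
    else:
        x0, y0 = approximate_center_px

    b0 = float(np.percentile(frame, 10))
    a0 = float(frame.max() - b0)
    s0 = max(2.0, min(rows, cols) / 10.0)
    p0 = [a0, float(x0), float(y0), s0, s0, b0]
    try:
        popt, pcov = curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            frame.ravel(),
            p0=p0,
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise LocalizationFailure(f"Gaussian center fit did not converge: {exc}") from exc

    amp, cx, cy, sx, sy, b = popt
    # noise estimate: robust SD of the fit residuals
    resid = frame.ravel() - _gauss2d((xx.ravel(), yy.ravel()), *popt)
    noise_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if not np.isfinite(popt).all() or amp < 3.0 * max(noise_sd, 1e-12):
        raise LocalizationFailure(
            f"fitted amplitude {amp:.3g} is below 3x the background noise SD "
            f"({noise_sd:.3g}): no dominant bead blob"
        )
    if not (0 <= cx < cols and 0 <= cy < rows):
        raise LocalizationFailure(f"fitted center ({cx:.1f}, {cy:.1f}) lies outside the frame")
    perr = np.sqrt(np.diag(pcov))
    return BeadCenter(
        center_xy_px=(float(cx), float(cy)),
        amplitude_counts=float(amp),
        background_counts=float(b),
        sigma_xy_px=(abs(float(sx)), abs(float(sy))),
        center_se_px=(float(perr[1]), float(perr[2])),
    )


def pixel_heights(
    center_xy_px: tuple[float, float],
    bead: BeadSpec,
    pixel_size_um: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Map every pixel to the height (nm) of the bead surface above the chip.

    Returns ``(heights_nm, valid)``; pixels at lateral distance >= the bead
    radius are masked invalid (the sphere no longer covers them).
    """
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be positive")
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    r_um = pixel_size_um * np.hypot(xx - center_xy_px[0], yy - center_xy_px[1])
    radius = bead.radius_um
    valid = r_um < radius
    heights_nm = np.full(shape, np.nan)
    heights_nm[valid] = (radius - np.sqrt(radius**2 - r_um[valid] ** 2)) * 1e3
    return heights_nm, valid


def fit_penetration_depth(
    heights_nm: np.ndarray,
    counts: np.ndarray,
    y_max_nm: float = 500.0,
) -> PenetrationFit:
    """Nonlinear least squares of ``I(y) = A exp(-y/d_p) + b`` over y <= y_max.

    Initialization: A = max count, d_p = 100 nm, b = 5th percentile of counts.
    Raises :class:`FitFailure` on non-convergence; a fit whose d_p standard
    error exceeds 50% of d_p is returned flagged unreliable.
    """
    heights_nm = np.asarray(heights_nm, float).ravel()
    counts = np.asarray(counts, float).ravel()
    if heights_nm.shape != counts.shape:
        raise ValidationError("heights and counts must have matching shapes")
    sel = np.isfinite(heights_nm) & np.isfinite(counts) & (heights_nm <= y_max_nm)
    y, c = heights_nm[sel], counts[sel]
    if y.size < MIN_FIT_PIXELS:
        raise ValidationError(
            f"need >= {MIN_FIT_PIXELS} valid (height, count) pairs, got {y.size}"
        )

    def model(yv, amp, d_p, b):
        return amp * np.exp(-yv / d_p) + b

    p0 = [float(c.max()), 100.0, float(np.percentile(c, 5))]
    try:
        popt, pcov = curve_fit(
            model,
            y,
            c,
            p0=p0,
            bounds=([0.0, 1e-3, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailure(f"exponential decay fit did not converge: {exc}") from exc
    amp, d_p, b = popt
    d_p_se = float(np.sqrt(pcov[1, 1]))
    resid = c - model(y, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    # unreliable when the SE dominates, or when no decaying component was
    # actually detected (amplitude lost in the residuals or the background)
    reliable = bool(
        np.isfinite(d_p_se)
        and d_p_se <= 0.5 * d_p
        and amp > 5.0 * rms
        and amp > 1e-3 * (amp + b)
    )
    return PenetrationFit(
        d_p_nm=float(d_p),
        d_p_se_nm=d_p_se,
        amplitude_counts=float(amp),
        background_counts=float(b),
        n_pixels_used=int(y.size),
        rms_residual_counts=rms,
        reliable=reliable,
    )


def run_bead_calibration(
    image: OpticalStack,
    bead: BeadSpec,
    medium_index: float,
    wavelength_nm: float,
    *,
    y_max_nm: float = 500.0,
    water_index: float = N_WATER,
    stripe_mask: np.ndarray | None = None,
    approximate_center_px: tuple[float, float] | None = None,
) -> BeadFit:
    """End-to-end calibration: localize, height-map, fit, convert to water.

    ``stripe_mask`` (boolean, frame-shaped) restricts the fit to pixels inside
    a waveguide excitation stripe — the bead region excited evanescently is
    elliptical when the bead sits on the waveguide edge, and pixels outside
    the stripe carry no excitation and must not enter the fit.

    The conversion step never alters the medium-frame fit; both depths are
    reported along with the indices used.
    """
    if image.pixel_size_um is None:
        raise ValidationError(
            "pixel_size_um metadata is required for bead calibration but is missing"
        )
    center = fit_bead_center(image, approximate_center_px)
    frame = image.data[0].astype(float)
    heights_nm, valid = pixel_heights(
        center.center_xy_px, bead, image.pixel_size_um, frame.shape
    )
    if stripe_mask is not None:
        if stripe_mask.shape != frame.shape:
            raise ValidationError("stripe_mask shape must match the frame")
        valid &= stripe_mask.astype(bool)
    fit = fit_penetration_depth(heights_nm[valid], frame[valid], y_max_nm=y_max_nm)
    converted = convert_penetration_depth(
        fit.d_p_nm, medium_index, water_index, wavelength_nm
    )
    return BeadFit(
        center_xy_px=center.center_xy_px,
        amplitude_counts=fit.amplitude_counts,
        background_counts=fit.background_counts,
        d_p_measured_nm=fit.d_p_nm,
        d_p_measured_se_nm=fit.d_p_se_nm,
        d_p_water_nm=converted.d_p_nm,
        medium_index=medium_index,
        water_index=water_index,
        wavelength_nm=wavelength_nm,
        n_pixels_used=fit.n_pixels_used,
        rms_residual_counts=fit.rms_residual_counts,
        reliable=fit.reliable,
    )
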