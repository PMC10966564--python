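"""Waveguide loss budget: cut-back regression, intercept decomposition, and a
Payne-Lacey roughness-scattering estimate.

Sign convention: all dB quantities are signed with losses negative (a
propagation loss of 0.9 dB/cm is stored as -0.9).

The cut-back method measures the total transmission of otherwise identical
devices whose straight-segment lengths differ; ordinary least squares of
transmission (dB) on length (cm) separates the per-length propagation loss
(slope) from the length-independent terms (intercept = facet coupling plus
bend loss).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import quad

from .exceptions import ValidationError
from .evanescent import MaterialIndices, slab_neff
from .modes import WaveguideGeometry

__all__ = [
    "CutbackDataset",
    "CutbackFit",
    "LossBudget",
    "ScatteringLossEstimate",
    "cutback_fit",
    "decompose_intercept",
    "build_loss_budget",
    "payne_lacey_loss",
]

DB_PER_NEPER = 10.0 / math.log(10.0)  # 4.3429...; dB per factor-e power ratio


@dataclass(frozen=True)
class CutbackDataset:
    """Total transmission of spiral devices versus straight-segment length."""

    lengths_cm: tuple[float, ...]
    transmissions_dB: tuple[float, ...]
    wavelength_nm: float = 489.0

    def __post_init__(self) -> None:
        if len(self.lengths_cm) != len(self.transmissions_dB):
            raise ValidationError("lengths and transmissions must have equal length")
        if len(self.lengths_cm) < 2:
            raise ValidationError("cut-back needs at least two devices")
        if any(length <= 0 for length in self.lengths_cm):
            raise ValidationError("lengths must be strictly positive")
        if len(set(self.lengths_cm)) < 2:
            raise ValidationError("lengths must not all be equal (zero length variance)")


@dataclass(frozen=True)
class CutbackFit:
    """OLS slope/intercept with standard errors from the residual variance.

    ``se_defined`` is False for the degenerate two-point case: the line is an
    exact interpolation and no residual degrees of freedom remain.
    """

    propagation_dB_per_cm: float
    propagation_se: float
    intercept_dB: float
    intercept_se: float
    r_squared: float
    n_devices: int
    se_defined: bool


@dataclass(frozen=True)
class LossBudget:
    """Decomposition of a cut-back fit into propagation, coupling, and bend
    contributions.  ``bend_total_dB = intercept - n_facets * coupling``;
    coupling uncertainty is propagated in quadrature into the bend SE."""

    propagation_dB_per_cm: float
    propagation_se: float
    intercept_dB: float
    intercept_se: float
    coupling_dB_per_facet: float
    coupling_se: float
    n_facets: int
    bend_total_dB: float
    bend_total_se: float
    bend_dB_per_turn: float | None = None
    n_turns: float | None = None

    def to_dict(self) -> dict:
        return {
            "propagation_dB_per_cm": self.propagation_dB_per_cm,
            "propagation_se": self.propagation_se,
            "intercept_dB": self.intercept_dB,
            "intercept_se": self.intercept_se,
            "coupling_dB_per_facet": self.coupling_dB_per_facet,
            "coupling_se": self.coupling_se,
            "n_facets": self.n_facets,
            "bend_total_dB": self.bend_total_dB,
            "bend_total_se": self.bend_total_se,
            "bend_dB_per_turn": self.bend_dB_per_turn,
            "n_turns": self.n_turns,
        }


def cutback_fit(data: CutbackDataset) -> CutbackFit:
    """Ordinary least squares of transmission (dB) on device length (cm).

    A positive slope (gain with length) is physically impossible for a
    passive waveguide and triggers a warning-level flag via the caller; the
    fit itself is reported as-is.
    """
    x = np.asarray(data.lengths_cm, float)
    y = np.asarray(data.transmissions_dB, float)
    if x.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        return CutbackFit(
            propagation_dB_per_cm=float(slope),
            propagation_se=math.nan,
            intercept_dB=float(intercept),
            intercept_se=math.nan,
            r_squared=1.0,
            n_devices=2,
            se_defined=False,
        )
    res = stats.linregress(x, y)
    return CutbackFit(
        propagation_dB_per_cm=float(res.slope),
        propagation_se=float(res.stderr),
        intercept_dB=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2),
        n_devices=int(x.size),
        se_defined=True,
    )


def decompose_intercept(
    intercept_dB: float, coupling_dB_per_facet: float, n_facets: int = 2
) -> float:
    """Bend loss left in the intercept after removing the facet coupling:
    ``bend_total = intercept - n_facets * coupling`` (exact arithmetic)."""
    if n_facets < 1:
        raise ValidationError("n_facets must be >= 1")
    return intercept_dB - n_facets * coupling_dB_per_facet


def build_loss_budget(
    fit: CutbackFit,
    coupling_dB_per_facet: float,
    coupling_se: float = 0.0,
    n_facets: int = 2,
    n_turns: float | None = None,
) -> LossBudget:
    """Assemble the full loss budget from a cut-back fit and the measured
    facet coupling.  ``n_turns`` (number of full 360-degree turns in the
    spiral) is required to quote a per-turn bend loss."""
    bend = decompose_intercept(fit.intercept_dB, coupling_dB_per_facet, n_facets)
    intercept_se = fit.intercept_se if fit.se_defined else 0.0
    bend_se = math.hypot(intercept_se, n_facets * coupling_se)
    per_turn = None
    if n_turns is not None:
        if n_turns <= 0:
            raise ValidationError("n_turns must be positive")
        per_turn = bend / n_turns
    return LossBudget(
        propagation_dB_per_cm=fit.propagation_dB_per_cm,
        propagation_se=fit.propagation_se,
        intercept_dB=fit.intercept_dB,
        intercept_se=fit.intercept_se,
        coupling_dB_per_facet=coupling_dB_per_facet,
        coupling_se=coupling_se,
        n_facets=n_facets,
        bend_total_dB=bend,
        bend_total_se=bend_se,
        bend_dB_per_turn=per_turn,
        n_turns=n_turns,
    )


@dataclass(frozen=True)
class ScatteringLossEstimate:
    """Order-of-magnitude surface-roughness scattering loss (signed dB/cm,
    negative).  ``upper_bound_dB_per_cm`` is the worst-case bound over all
    correlation lengths."""

    loss_dB_per_cm: float
    upper_bound_dB_per_cm: float
    rms_roughness_nm: float
    correlation_length_nm: float
    n_eff: float
    order_of_magnitude: bool = True


def payne_lacey_loss(
    rms_roughness_nm: float,
    geometry: WaveguideGeometry,
    wavelength_nm: float | None = None,
    correlation_length_nm: float = 50.0,
) -> ScatteringLossEstimate:
    """Roughness-scattering loss of a slab of the rib's total core thickness.

    Implements the planar radiation model: for the TE0 slab mode with
    normalized surface field ``phi2 = phi^2(surface)/int phi^2``,

        alpha = phi2 (n1^2 - n2^2) k0^3 / (4 pi n1)
                * int_0^pi S(beta - n2 k0 cos(theta)) d(theta)

    with an exponential roughness autocorrelation, whose 1-D power spectrum
    is ``S(Omega) = 2 sigma^2 Lc / (1 + Omega^2 Lc^2)``.  Only the top
    (cladding-side) surface is included — the AFM roughness the estimate is
    based on is measured there.  The closed-form worst case
    ``alpha_max = 0.76 sigma^2 / (k0 d^4 n1)`` (d = half-thickness) is
    reported alongside as a ceiling.

    The result is an order-of-magnitude estimate and is tagged as such; it is
    quadratic in the RMS roughness and vanishes with it.
    """
    if rms_roughness_nm < 0:
        raise ValidationError("rms_roughness_nm must be >= 0")
    if correlation_length_nm <= 0:
        raise ValidationError("correlation_length_nm must be positive")
    idx = geometry.indices
    lam = wavelength_nm if wavelength_nm is not None else idx.wavelength_nm
    thickness = geometry.total_height_nm
    n1, n2, n_sub = idx.n_core, idx.n_cladding, idx.n_substrate

    indices = MaterialIndices(n1, n_sub, n2, lam)
    n_eff = slab_neff(indices, thickness, "TE", 0)
    if n_eff is None:
        raise ValidationError("slab of this thickness is below cutoff; no guided mode")

    k0 = 2.0 * math.pi / lam  # rad/nm
    kappa = k0 * math.sqrt(n1**2 - n_eff**2)
    g_sub = k0 * math.sqrt(n_eff**2 - n_sub**2)
    g_clad = k0 * math.sqrt(n_eff**2 - n2**2)
    # analytic TE0 mode: phi = cos(kappa y + phase), exponential tails; the
    # normalized surface intensity is phi^2(top) / int phi^2 dy
    phase = math.atan2(g_sub, kappa)  # bottom-interface phase
    phi_bot = math.cos(phase)
    phi_top = math.cos(kappa * thickness - phase)
    # integral of phi^2 through the core plus both tails
    core_int = 0.5 * thickness + (
        math.sin(2 * (kappa * thickness - phase)) + math.sin(2 * phase)
    ) / (4.0 * kappa)
    total_int = core_int + phi_bot**2 / (2.0 * g_sub) + phi_top**2 / (2.0 * g_clad)
    phi2_surface = phi_top**2 / total_int  # 1/nm

    sigma2 = rms_roughness_nm**2
    lc = correlation_length_nm
    beta = k0 * n_eff

    def spectrum(omega: float) -> float:
        return 2.0 * sigma2 * lc / (1.0 + (omega * lc) ** 2)

    integral, _ = quad(lambda th: spectrum(beta - n2 * k0 * math.cos(th)), 0.0, math.pi)
    alpha_per_nm = phi2_surface * (n1**2 - n2**2) * k0**3 / (4.0 * math.pi * n1) * integral
    loss_db_cm = DB_PER_NEPER * alpha_per_nm * 1e7  # nm^-1 -> cm^-1, nepers -> dB

    d_half = thickness / 2.0
    alpha_max_per_nm = 0.76 * sigma2 / (k0 * d_half**4 * n1)
    bound_db_cm = DB_PER_NEPER * alpha_max_per_nm * 1e7

    return ScatteringLossEstimate(
        loss_dB_per_cm=-loss_db_cm,
        upper_bound_dB_per_cm=-bound_db_cm,
        rms_roughness_nm=rms_roughness_nm,
        correlation_length_nm=correlation_length_nm,
        n_eff=n_eff,
        order_of_magnitude=True,
    )
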