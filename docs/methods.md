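# Methods

This note documents the models behind `evanstim`, the defaults and why they
were chosen, the numerical choices, and what the synthetic-data tests do and
do not demonstrate about real data.

## Evanescent-field model

All penetration depths use the intensity convention: the evanescent power
density above a guiding interface decays as `I(y) = I_surf exp(-y/d_p)` with

    d_p = λ / (4π √(β² − n_clad²)),

where β is the tangential wavevector in index units — the effective index
`n_eff` of a guided mode, or `n sin θ` for a totally internally reflected
beam. The factor 4π (rather than 2π) is the intensity, not field, decay.

Cladding-medium conversion holds β fixed: the guided or incident wave that
creates the field does not change when the probed medium does, so a depth
measured in medium A maps to medium B via
`β = √((λ/4πd_p)² + n_A²)`, `d_p' = λ/(4π√(β² − n_B²))`. The conversion is
an exact involution wherever both sides are evanescent; it fails (and the
package raises a no-evanescent-regime error) when β does not exceed the
target index. One practical consequence: a depth measured in an
index-matched sucrose bath (n = 1.45) always converts to a *smaller* depth
in water, and a water-frame depth above ~70 nm at 491 nm cannot have come
from a sucrose-immersed total-internal-reflection measurement at all. The
calibration tests therefore model the waveguide case as a sucrose
measurement (96.8 nm in the bath ↔ 57 nm in water) and the objective-TIRF
reference as measured directly in the aqueous chamber (80 nm).

The threshold-crossing height `h = d_p ln(I_surf/I_th)` is linear in
`ln I_surf`; with the platform's computed `I_surf ≈ 3.3×10⁵ mW/mm²` per mW
and the ~5 mW/mm² channelrhodopsin-2 irradiance threshold it evaluates to
≈620 nm (the platform's quoted 610 nm comes from unrounded inputs; the
package asserts agreement within 5%). Linear scaling of `I_surf` with
guided power puts the minimum power for threshold-at-surface at ≈15 nW.

Default indices at 491 nm: OrmoClear 1.566, OrmoComp 1.527, water 1.340
(platform values); fused silica / thermal oxide 1.463 (Malitson dispersion) and
sucrose solution 1.450 (matched to silica beads) are package defaults for
values that vary between setups — both configurable, and every conversion
reports the indices it used.

## Mode solver

The rib cross-section is solved with a scalar (semi-vectorial)
finite-difference Helmholtz eigenproblem, Dirichlet boundaries, shift-invert
Lanczos for the largest `β²`. For index contrasts ≤ 0.15 the scalar field
approximates the dominant lateral E component of the TE-like family well;
vectorial corrections to `n_eff` are far below the tolerances of every
quantity derived here. Full-vectorial solving is out of scope by design.

Grid: 50 nm × 20 nm (x × y) cells over a 9 µm × 4 µm window, permittivity
volume-averaged over 4×4 sub-samples per cell so that interfaces not aligned
with cell boundaries do not staircase. Convergence at the default grid:
halving the vertical step moves the TE00 effective index by ~1×10⁻⁴ and the
derived penetration depth by 0.02 nm — two orders below the ±3 nm reporting
tolerance. Eigenvectors are normalized so the cross-sectional intensity
integral equals 1 mW; the surface density is the maximum of the intensity
linearly interpolated onto the rib top surface (the line maximum, which for
this geometry coincides with the value above the rib center to <1%).

Mode labels (TE00/TE10/TE20) count lateral sign changes at mid-core height.
`mode_penetration_depth` fits `ln I` against height over 400 nm above the
surface and cross-checks the closed form from `n_eff`; disagreement beyond
10% or a non-exponential tail (R² < 0.99) attaches a warning.

### Fiber coupling

Coupling efficiency is the normalized overlap integral between the solved
mode field and a Gaussian beam, `10 log₁₀ |⟨E_g|E_m⟩|²/(⟨E_g|E_g⟩⟨E_m|E_m⟩)`,
with the beam waist at the fiber facet and free-space propagation (beam
expansion plus wavefront curvature) across the gap; Fresnel reflections are
excluded and the transverse alignment is optimized, matching how facet
coupling is measured. Two modeling decisions matter and are the package's
own:

* **Facet context.** Coupling is characterized on dry chips — OrmoComp
  waveguides stamped on the thermal oxide of a silicon substrate, air
  cladding (`facet_geometry()`), not the water-clad stimulation chip. The
  air-clad mode near cutoff extends deeper into the substrate and couples
  measurably better than the water-clad chip mode (−5.8 dB for the latter
  with the same beam).
* **Fiber MFD default 3.5 µm.** Single-mode fiber for 488 nm (460HP /
  S405-XP class) has a mode-field diameter of 3.3–3.6 µm at 491 nm; the
  waveguide width of 4.5 µm "matches" it only nominally. With MFD 3.5 µm
  the computed efficiencies are −3.5 dB at contact and −3.9 dB at a 10 µm
  gap, consistent with the platform's calculated −3.6/−4.2 dB and its measured
  −5.5 ± 0.3 dB/facet (which additionally absorbs misalignment and facet
  quality). With a literal 4.5 µm MFD the overlap is −4.5 dB at contact and
  nearly gap-independent out to 10 µm (Rayleigh range 32 µm), which
  reproduces neither printed value; the narrower beam also explains the
  observed near-linear decrease with gap distance. The MFD is a parameter
  of `FiberBeam`, not a constant.

## Bead calibration

The sphere of known diameter (default 7.38 µm) converts lateral distance to
height exactly: `y(r) = R − √(R² − r²)`. The center comes from a 2-D
elliptical Gaussian least-squares fit — a localization model only; its
residuals estimate the noise floor, and a fitted amplitude below 3× that
floor raises a localization failure rather than returning a bogus center.
Pixel centers sit at integer coordinates; sub-pixel results are real-valued.

The decay fit `I(y) = A e^(−y/d_p) + b` uses nonlinear least squares with
A initialized at the maximum count, `d_p` at 100 nm, and b at the 5th
percentile of counts, restricted to `y ≤ 500 nm` (≈6–9× the expected depth;
near the bead equator the height error diverges, and the exponential has
decayed to numerical background long before). Counts are assumed
proportional to excitation intensity — equal collection efficiency for all
fluorophore heights; no depth-dependent correction is applied. A fit is
flagged unreliable when the depth's standard error exceeds half its value or
when no decaying component is detectable above the residuals (the
constant-profile degenerate case). At least 30 (height, count) pairs are
required.

When the bead sits on the waveguide edge, only the stripe-covered sector is
excited and the visible spot is elliptical; an optional stripe mask excludes
unexcited pixels before fitting. On synthetic ground truth this restriction
leaves the fitted depth unbiased, because the height map is rotationally
symmetric — any angular sector samples the same height-intensity relation.

## Response mapping

Responder statistic: over the analysis window (default 21–31 s, half-open,
frames assigned by start timestamp) the per-pixel trace is transformed with
an unnormalized DFT — no taper, no detrending — and the magnitudes at
harmonics {1..5} of the 1 Hz stimulation rate are summed. Requested
harmonics must land exactly on DFT bins (`k·f_stim·N/fs` integer); off-bin
requests are refused naming the offending harmonic, because spectral leakage
would silently corrupt the statistic. The DC bin is excluded, making the
score exactly offset-invariant; normalizing to the field-of-view maximum
makes the map scale-invariant and also makes the one-sided-versus-raw
amplitude convention irrelevant (raw magnitudes are used and documented).
Ties at the maximum all map to 1.0. An all-zero window yields an all-zero
map. Photobleaching is not removed by default.

The classification threshold (0.5 of the normalized score) is a reporting
convenience exposed as a parameter, never hard-coded into the map.

## Loss characterization

Cut-back: ordinary least squares of transmission (dB, losses negative) on
straight-segment length (cm); standard errors from residual variance. The
two-point case is an exact interpolation with undefined SEs and is returned
flagged rather than rejected. A nominal 95% CI built with the t quantile at
n−2 degrees of freedom covers the true slope at 94–95% over 1000 synthetic
replicates (6 devices, 0.3 dB noise); with only 4 residual degrees of
freedom a ±2·SE band would cover at only ~88%, which is why the package and
its tests use the t-based interval.

Intercept decomposition is exact arithmetic
(`bend = intercept − n_facets × coupling`), with the coupling uncertainty
propagated in quadrature. The per-360° bend loss requires the user to supply
the turn count (4 for the platform's spiral layout, giving −0.6 dB/turn from
−2.4 dB total).

Payne–Lacey scattering: the planar radiation model for the TE0 slab mode of
the rib's total thickness, top surface only, exponential roughness
autocorrelation (`S(Ω) = 2σ²L_c/(1+Ω²L_c²)`), integrated over radiation
angles; the closed-form worst case `0.76 σ²/(k₀ d⁴ n₁)` is reported
alongside as a ceiling. The correlation length is not published for this
platform; the default 50 nm yields an estimate roughly an order of magnitude
above the measured propagation loss, and the result is returned explicitly
tagged order-of-magnitude — it scales as σ² and is meant to bound, not
predict, the roughness contribution.

## Synthetic data: what it does and does not emulate

Generators are deterministic functions of parameters and a seed (single
seeded generator per call, seed recorded in the truth record). Camera noise:
Poisson shot noise on expected counts, Gaussian read noise (default SD 2),
constant baseline offset (default 100), rounded to integer counts.

Calcium movies follow the platform's standard protocol exactly — 20 s background, 10
pulses at 1 Hz, 60 ms width, 60 s total, 10 Hz sampling — on a 128×128 test
frame (the platform's full field is 1200×1200; the statistic is per-pixel, so
frame size only scales compute). Transients: ΔF/F₀ = 0.3 per pulse with
τ = 0.5 s exponential decay (typical Rhod-3 scale), zero latency, added to
a 1000-count cell baseline over a 250-count background. Responders are all
cells (full-field) or exactly the cells intersecting the 4.5 µm stripe
(waveguide mode). Under these conditions the harmonic map separates
responders cleanly: all responder pixels score > 0.5 of the FOV maximum,
≥ 99% of non-cell background pixels score < 0.1, and thresholding at 0.5
recovers the ground-truth responder set exactly over 10 seeds.
Non-responding somata are *not* as dark as empty background: their shot
noise scales with √brightness, putting their score floor at 0.10–0.15 of
the FOV maximum. That floor is a property of shot-noise-limited imaging,
not of the implementation, and is why the responder threshold sits at 0.5.

The generators do not model: realistic neurite morphology, optical PSF blur,
spontaneous background activity (off by default), photobleaching, spectral
cross-talk between markers, or motion. Passing recovery tests therefore
demonstrates correctness of the analysis chain under its stated noise model,
not robustness to those real-data effects.

Bead images use the exponential-on-sphere model with a 2.5×10³-count contact
peak at 0.11 µm pixels (the platform's imaging scale). Cut-back tables use
the platform's 1.2–8.1 cm device span with 0.3 dB Gaussian noise.

## Determinism and I/O

All randomness flows through explicit integer seeds; identical seeds give
bit-identical arrays. Pixel counts round-trip TIFF I/O exactly (16-bit when
integral, float32 for maps); metadata travels in JSON sidecars, and a
multi-frame stack without a frame interval is an error, never a guessed
default. Pipeline reports are timestamp-free with sorted keys, so a rerun of
the same config and seed is byte-identical. dB quantities are signed with
losses negative throughout.
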