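"""Declarative multi-stage runs: validate a config, execute stages in order,
and write a provenance-annotated JSON report.

The config is a single YAML dialect:

.. code-block:: yaml

    seed: 1
    output_dir: out
    stages:
      - name: simulate-movie
        params: {stimulation_mode: waveguide, stripe_center_px: 64}
      - name: map-response
        params: {}

Unknown stage names and unknown parameter keys are rejected before anything
runs; every run writes the resolved config next to its outputs.  Stage
failures abort with the stage identity; outputs of completed stages are
preserved.  Reports contain units, input hashes, the seed, and the package
version, and rerunning the same config and seed reproduces them byte for
byte (no timestamps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .beads import BeadSpec, run_bead_calibration
from .evanescent import N_SUCROSE
from .exceptions import StageError, ValidationError
from .io import (
    read_cutback_csv,
    read_stack,
    sha256_of,
    write_cutback_csv,
    write_json,
    write_response_map,
    write_stack,
    write_trace_csv,
)
from .loss import build_loss_budget, cutback_fit
from .response import classify_responders, response_map, roi_average_trace
from .stack import StimulationProtocol
from .synthetic import (
    CellRegion,
    ExcitationStripe,
    NoiseModel,
    SceneLayout,
    generate_bead_image,
    generate_calcium_movie,
    generate_cutback_data,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """A validated pipeline run: seed, output directory, ordered stages."""

    seed: int = 0
    output_dir: Path = Path("evanstim_out")
    stages: list[dict] = field(default_factory=list)
    verbosity: int = 1

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        allowed = {"seed", "output_dir", "stages", "verbosity"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages", [])
        if not isinstance(stages, list) or not stages:
            raise ValidationError("config must declare a non-empty 'stages' list")
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "evanstim_out")),
            stages=[dict(s) for s in stages],
            verbosity=int(raw.get("verbosity", 1)),
        )
        for stage in cfg.stages:
            unknown = set(stage) - {"name", "params"}
            if unknown:
                raise ValidationError(f"unknown stage keys: {sorted(unknown)}")
            name = stage.get("name")
            if name not in _STAGES:
                raise ValidationError(
                    f"unknown stage {name!r}; known: {sorted(_STAGES)}"
                )
            params = stage.get("params", {}) or {}
            spec = _STAGES[name]
            bad = set(params) - spec.allowed_params
            if bad:
                raise ValidationError(
                    f"stage {name!r} got unknown params: {sorted(bad)}"
                )
            spec.validate(params)  # constructs domain objects; raises early
        return cfg


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a YAML mapping")
    return RunConfig.from_dict(raw)


@dataclass(frozen=True)
class _StageSpec:
    allowed_params: frozenset
    validate: callable
    run: callable


def _protocol_from(params: dict) -> StimulationProtocol:
    keys = ("background_s", "n_pulses", "pulse_rate_hz", "pulse_width_s", "total_s")
    kwargs = {k: params[k] for k in keys if k in params}
    return StimulationProtocol(**kwargs)


# --- stage implementations -------------------------------------------------

def _validate_sim_movie(params: dict) -> None:
    _protocol_from(params)
    mode = params.get("stimulation_mode", "full_field")
    if mode not in ("full_field", "waveguide"):
        raise ValidationError(f"invalid stimulation_mode {mode!r}")


def _run_sim_movie(params: dict, ctx: dict, outdir: Path, seed: int) -> dict:
    protocol = _protocol_from(params)
    shape = tuple(params.get("frame_shape", (128, 128)))
    stripe = None
    if params.get("stimulation_mode", "full_field") == "waveguide" or "stripe_center_px" in params:
        stripe = ExcitationStripe(
            center_px=params.get("stripe_center_px", shape[0] / 2),
            width_um=params.get("stripe_width_um", 4.5),
        )
    rng = np.random.default_rng(seed)
    n_cells = int(params.get("n_cells", 6))
    cells = []
    rows, cols = shape
    for _ in range(n_cells):
        cells.append(
            CellRegion(
                center_px=(rng.uniform(10, cols - 10), rng.uniform(10, rows - 10)),
                radii_px=(rng.uniform(6, 10), rng.uniform(5, 8)),
                orientation_deg=rng.uniform(0, 180),
            )
        )
    layout = SceneLayout(
        cell_regions=tuple(cells),
        waveguide_stripe=stripe,
        frame_shape=shape,
        pixel_size_um=params.get("pixel_size_um", 0.55),
    )
    movie, truth = generate_calcium_movie(
        layout,
        protocol,
        stimulation_mode=params.get("stimulation_mode", "full_field"),
        noise=NoiseModel(seed=seed),
    )
    tiff = write_stack(movie, outdir / "movie.tif")
    mask_path = write_json(
        {k: truth[k] for k in ("responder_mask", "cell_mask") if truth[k] is not None},
        outdir / "movie_truth_masks.json",
    )
    truth_path = write_json(
        {k: v for k, v in truth.items() if not isinstance(v, np.ndarray)},
        outdir / "movie_truth.json",
    )
    ctx["movie"] = movie
    ctx["movie_truth"] = truth
    ctx["protocol"] = protocol
    return {
        "outputs": {
            "movie_tiff": tiff.name,
            "truth": truth_path.name,
            "truth_masks": mask_path.name,
        },
        "units": {"movie_tiff": "camera counts"},
    }


def _run_map_response(params: dict, ctx: dict, outdir: Path, seed: int) -> dict:
    if "movie" in ctx:
        movie = ctx["movie"]
    elif "movie_path" in params:
        movie = read_stack(params["movie_path"])
    else:
        raise ValidationError("map-response needs a preceding simulate-movie stage or movie_path")
    protocol = ctx.get("protocol", _protocol_from(params))
    window = params.get("window_s")
    result = response_map(movie, protocol, tuple(window) if window else None)
    map_path = write_response_map(result, outdir / "response_map.tif")
    threshold = params.get("responder_threshold", 0.5)
    responders = classify_responders(result, threshold)
    trace = roi_average_trace(movie, np.ones(movie.frame_shape, bool))
    trace_path = write_trace_csv(movie.times_s, trace, outdir / "fov_trace.csv")
    report = {
        "responder_threshold": threshold,
        "n_responder_pixels": int(responders.sum()),
        "raw_max_score": result.raw_max_score,
        "outputs": {"response_map": map_path.name, "fov_trace": trace_path.name},
        "units": {"response_map": "normalized score [0,1]", "fov_trace": "counts"},
    }
    ctx["response_map"] = result
    return report


def _run_sim_cutback(params: dict, ctx: dict, outdir: Path, seed: int) -> dict:
    data, truth = generate_cutback_data(
        slope_true=params.get("slope_true", -0.9),
        intercept_true=params.get("intercept_true", -13.4),
        noise_sd_dB=params.get("noise_sd_dB", 0.3),
        seed=seed,
    )
    csv = write_cutback_csv(data, outdir / "cutback.csv")
    write_json(truth, outdir / "cutback_truth.json")
    ctx["cutback"] = data
    return {"outputs": {"cutback_csv": csv.name}, "units": {"cutback_csv": "cm, dB"}}


def _run_cutback_fit(params: dict, ctx: dict, outdir: Path, seed: int) -> dict:
    if "cutback" in ctx:
        data = ctx["cutback"]
    elif "csv_path" in params:
        data = read_cutback_csv(params["csv_path"])
    else:
        raise ValidationError("cutback-fit needs a preceding simulate-cutback stage or csv_path")
    fit = cutback_fit(data)
    budget = build_loss_budget(
        fit,
        coupling_dB_per_facet=params.get("coupling_dB_per_facet", -5.5),
        coupling_se=params.get("coupling_se", 0.3),
        n_facets=int(params.get("n_facets", 2)),
        n_turns=params.get("n_turns"),
    )
    out = write_json(
        {
            "fit": budget.to_dict(),
            "units": {"propagation": "dB/cm", "intercept": "dB", "bend": "dB"},
        },
        outdir / "loss_budget.json",
    )
    return {"outputs": {"loss_budget": out.name}}


def _run_sim_beads(params: dict, ctx: dict, outdir: Path, seed: int) -> dict:
    stripe = None
    if "stripe_center_px" in params:
        stripe = ExcitationStripe(
            center_px=params["stripe_center_px"],
            width_um=params.get("stripe_width_um", 4.5),
        )
    image, truth = generate_bead_image(
        BeadSpec(diameter_um=params.get("bead_diameter_um", 7.38)),
        d_p_true_nm=params.get("d_p_true_nm", 96.8),
        peak_counts=params.get("peak_counts", 2.5e3),
        pixel_size_um=params.get("pixel_size_um", 0.11),
        excitation_stripe=stripe,
        noise=NoiseModel(seed=seed),
    )
    tiff = write_stack(image, outdir / "bead.tif")
    write_json(truth, outdir / "bead_truth.json")
    ctx["bead_image"] = image
    ctx["bead_truth"] = truth
    return {"outputs": {"bead_tiff": tiff.name}, "units": {"bead_tiff": "camera counts"}}


def _run_calibrate_beads(params: dict, ctx: dict, outdir: Path, seed: int) -> dict:
    if "bead_image" in ctx:
        image = ctx["bead_image"]
    elif "image_path" in params:
        image = read_stack(params["image_path"])
    else:
        raise ValidationError("calibrate-beads needs a preceding simulate-beads stage or image_path")
    fit = run_bead_calibration(
        image,
        BeadSpec(diameter_um=params.get("bead_diameter_um", 7.38)),
        medium_index=params.get("medium_index", N_SUCROSE),
        wavelength_nm=params.get("wavelength_nm", 491.0),
        y_max_nm=params.get("y_max_nm", 500.0),
    )
    out = write_json(
        {"bead_fit": fit.to_dict(), "units": {"d_p": "nm", "counts": "camera counts"}},
        outdir / "bead_fit.json",
    )
    ctx["bead_fit"] = fit
    return {"outputs": {"bead_fit": out.name}}


_STAGES: dict[str, _StageSpec] = {
    "simulate-movie": _StageSpec(
        frozenset(
            {
                "background_s", "n_pulses", "pulse_rate_hz", "pulse_width_s",
                "total_s", "stimulation_mode", "stripe_center_px",
                "stripe_width_um", "frame_shape", "n_cells", "pixel_size_um",
            }
        ),
        _validate_sim_movie,
        _run_sim_movie,
    ),
    "map-response": _StageSpec(
        frozenset(
            {
                "movie_path", "window_s", "responder_threshold", "background_s",
                "n_pulses", "pulse_rate_hz", "pulse_width_s", "total_s",
            }
        ),
        lambda params: _protocol_from(params),
        _run_map_response,
    ),
    "simulate-cutback": _StageSpec(
        frozenset({"slope_true", "intercept_true", "noise_sd_dB"}),
        lambda params: None,
        _run_sim_cutback,
    ),
    "cutback-fit": _StageSpec(
        frozenset({"csv_path", "coupling_dB_per_facet", "coupling_se", "n_facets", "n_turns"}),
        lambda params: None,
        _run_cutback_fit,
    ),
    "simulate-beads": _StageSpec(
        frozenset(
            {
                "bead_diameter_um", "d_p_true_nm", "peak_counts", "pixel_size_um",
                "stripe_center_px", "stripe_width_um",
            }
        ),
        lambda params: None,
        _run_sim_beads,
    ),
    "calibrate-beads": _StageSpec(
        frozenset(
            {"image_path", "bead_diameter_um", "medium_index", "wavelength_nm", "y_max_nm"}
        ),
        lambda params: None,
        _run_calibrate_beads,
    ),
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write ``report.json``.

    Input files named in stage params are hashed into the report; no stage
    mutates its inputs.  Raises :class:`StageError` (naming the stage) on the
    first failure; reports of completed stages are already on disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(
        {"seed": config.seed, "stages": config.stages, "verbosity": config.verbosity},
        outdir / "resolved_config.json",
    )
    ctx: dict = {}
    report: dict = {"package_version": __version__, "seed": config.seed, "stages": []}
    for stage in config.stages:
        name = stage["name"]
        params = stage.get("params", {}) or {}
        input_hashes = {
            key: sha256_of(params[key])
            for key in ("movie_path", "csv_path", "image_path")
            if key in params and Path(params[key]).exists()
        }
        try:
            stage_report = _STAGES[name].run(params, ctx, outdir, config.seed)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage identity
            write_json(report, outdir / "report.json")  # partial outputs preserved
            raise StageError(name, str(exc), cause=exc) from exc
        stage_report["name"] = name
        stage_report["input_sha256"] = input_hashes
        report["stages"].append(stage_report)
    write_json(report, outdir / "report.json")
    return report
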