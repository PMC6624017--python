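"""Configuration and end-to-end pipeline plumbing.

A single validated config drives synth -> extract -> calibrate ->
reconstruct -> classify and writes every artifact (CSV profiles, TIFF
stacks, YAML curves, JSON summary) into one output directory.  All
randomness flows from the one config seed, so two runs with equal configs
produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import calibration as cal
from . import extraction as ext
from . import model as mdl
from . import reconstruction as rec
from . import synth
from .units import percent_to_millimolar

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "load_config",
           "run_end_to_end", "SUMMARY_SCHEMA_VERSION"]

SUMMARY_SCHEMA_VERSION = 1
log = logging.getLogger("gradientscape")


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every violation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Strict):
    length_um: float = Field(800.0, gt=0)
    width_um: float = Field(50.0, gt=0)
    height_um: float = Field(4.5, gt=0)
    cell_diameter_um: float = Field(4.0, gt=0)


class UptakeConfig(_Strict):
    q_max: float = Field(0.11, ge=0)
    k_q: float = Field(1.0, gt=0)
    mode: str = Field("monod", pattern="^(monod|zero_order)$")


class GrowthConfig(_Strict):
    doubling_time_min: float = Field(90.0, gt=0)
    k_mu: float = Field(0.5, ge=0)


class ScenarioConfig(_Strict):
    c0_percent: float = Field(2.0, ge=0)
    diffusion_um2_per_s: float = Field(100.0, gt=0)
    noise_cv: float = Field(0.05, ge=0)
    perdurance_um: float = Field(100.0, ge=0)
    growth_cap: float = Field(1.0, gt=0, le=1)
    grid_points: int = Field(400, ge=16)


class ExtractionConfig(_Strict):
    bandpass_large_px: float = Field(40.0, gt=0)
    bandpass_small_px: float = Field(5.0, gt=0)
    threshold_fraction: float = Field(0.1, gt=0, lt=1)
    occupancy_fraction: float = Field(0.5, gt=0, lt=1)
    n_front_bins: int = Field(10, ge=1)
    n_track_bins: int = Field(16, ge=1)
    mig1_bin_width_um: float = Field(25.0, gt=0)
    depth_axis: str = Field("rows", pattern="^(rows|cols)$")
    n_frames: int = Field(15, ge=3)
    pixel_size_um: float = Field(2.0, gt=0)
    n_tracks: int = Field(120, ge=1)


class ReconstructionConfig(_Strict):
    reporter: str = "HXT7"
    smoothing_window_bins: int = Field(3, ge=1)
    n_landscape_bins: int = Field(80, ge=5)


class PipelineConfig(_Strict):
    """Validated, unit-checked end-to-end pipeline configuration."""

    seed: int = Field(..., ge=0, lt=2**31)
    output_dir: str = "gradientscape_out"
    verbosity: str = Field("info", pattern="^(debug|info|warning)$")
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    uptake: UptakeConfig = Field(default_factory=UptakeConfig)
    growth: GrowthConfig = Field(default_factory=GrowthConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    extraction: ExtractionConfig = Field(default_factory=ExtractionConfig)
    reconstruction: ReconstructionConfig = Field(default_factory=ReconstructionConfig)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def to_scenario(self) -> synth.SyntheticScenario:
        return synth.SyntheticScenario(
            geometry=mdl.ChamberGeometry(**self.geometry.model_dump()),
            uptake=mdl.UptakeKinetics(**self.uptake.model_dump()),
            growth=mdl.GrowthKinetics.from_doubling_time(
                self.growth.doubling_time_min, self.growth.k_mu),
            c0_mM=percent_to_millimolar(self.scenario.c0_percent),
            diffusion_um2_per_s=self.scenario.diffusion_um2_per_s,
            noise_cv=self.scenario.noise_cv,
            perdurance_um=self.scenario.perdurance_um,
            growth_cap=self.scenario.growth_cap,
            grid_points=self.scenario.grid_points,
            seed=self.seed,
        )


def validate_config(raw: dict) -> PipelineConfig:
    """Build a typed config from a raw mapping, listing every violation."""
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        issues = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors())
        raise ConfigError(f"invalid configuration ({exc.error_count()} issue(s)): "
                          f"{issues}") from exc


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:12]


def run_end_to_end(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic pipeline and write all artifacts.

    Stages: synthetic data generation, image/track extraction, dose-response
    calibration, gradient reconstruction and phase classification.  Returns
    the machine-readable summary (also written as ``summary.json``).  When
    the scenario carries no glucose the pipeline completes with a
    "no growth, no features" summary instead of failing.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: config digest %s", _digest(config.model_dump()))
    scenario = config.to_scenario()
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "config_digest": _digest(config.model_dump()),
        "c0_mM": scenario.c0_mM,
        "notes": [],
    }

    # --- synthetic stage ---------------------------------------------------
    log.info("stage synth: scenario c0=%.3g mM seed=%d", scenario.c0_mM, config.seed)
    scenario.glucose_profile.to_csv(out / "glucose_truth.csv")
    scenario.velocity_profile.to_csv(out / "velocity_truth.csv")
    summary["stall_depth_um"] = scenario.stall_depth_um

    reporters = ["HXT1", "HXT5", "HXT7", "HXK1", "HXK2", "PDC1", "SDH2"]
    landscapes = {}
    for name in reporters:
        ls = synth.generate_fluorescence_landscape(
            scenario, name, n_bins=config.reconstruction.n_landscape_bins)
        ls.to_csv(out / f"landscape_{name}.csv")
        landscapes[name] = ls

    facs = synth.generate_batch_facs_table(
        scenario.panel[config.reconstruction.reporter],
        noise_cv=scenario.noise_cv, n_replicates=6, seed=scenario.seed + 11)
    facs.to_csv(out / f"facs_{config.reconstruction.reporter}.csv")

    ec = config.extraction
    stack = synth.generate_timelapse_stack(scenario, n_frames=ec.n_frames,
                                           pixel_size_um=ec.pixel_size_um)
    stack.to_tiff(out / "stack.tif")
    tracks = synth.generate_tracks(scenario.velocity_profile, n_tracks=ec.n_tracks,
                                   seed=scenario.seed + 13,
                                   width_um=scenario.geometry.width_um)
    tracks.to_csv(out / "tracks.csv")
    mig1 = synth.generate_mig1_cells(scenario)
    mig1.to_csv(out / "mig1_cells.csv", index=False)

    # --- extraction stage --------------------------------------------------
    log.info("stage extract: motion map, track binning, MIG1 profile")
    mm = ext.motion_map(stack, threshold_fraction=ec.threshold_fraction)
    mm.to_frame().to_csv(out / "motion_profile.csv", index=False)
    summary["motion_penetration_depth_um"] = mm.penetration_depth_um

    vprof = ext.bin_track_velocities(tracks, n_bins=ec.n_track_bins,
                                     length_um=scenario.geometry.length_um)
    vprof.to_csv(out / "track_velocities.csv")

    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        mig1_profile, mig1_transition = ext.nuclear_fraction_profile(
            mig1["depth_um"].to_numpy(), mig1["is_nuclear"].to_numpy(),
            bin_width_um=ec.mig1_bin_width_um,
            length_um=scenario.geometry.length_um)
    mig1_profile.to_csv(out / "mig1_profile.csv", index=False)

    # --- calibration stage -------------------------------------------------
    log.info("stage calibrate: fitting %s dose-response", config.reconstruction.reporter)
    true_curve = scenario.panel[config.reconstruction.reporter]
    try:
        fitted = cal.fit_response(facs, true_curve.shape)
        fitted.to_yaml(out / f"curve_{config.reconstruction.reporter}.yaml")
        calib = {"reporter": fitted.reporter_name, "rmse": fitted.rmse}
        if fitted.shape == "peaked":
            calib["peak_mM"] = fitted.peak_mM
            calib["peak_mM_reference"] = true_curve.peak_mM
        else:
            calib["half_point_mM"] = fitted.half_point_mM
            calib["half_point_mM_reference"] = true_curve.half_point_mM
        summary["calibration"] = calib
    except cal.FitError as exc:
        summary["notes"].append(f"calibration failed: {exc}")

    # --- features and reconstruction ---------------------------------------
    log.info("stage reconstruct: features + gradient inversion")
    features = []
    for name in ("HXT7", "HXK1", "HXK2"):
        ls = landscapes[name]
        dynamic = float(ls.intensities_au.max() - ls.intensities_au.min())
        noise = float(np.median(ls.spread_au)) if ls.spread_au is not None else 0.0
        if dynamic <= 3.0 * noise:
            summary["notes"].append(f"{name}: flat landscape, no peak")
            continue
        feat = rec.find_peak_position(ls, config.reconstruction.smoothing_window_bins)
        if feat.note != "boundary_peak":
            features.append(feat)
        else:
            summary["notes"].append(f"{name}: boundary peak, excluded from features")
    for name in ("HXT1", "HXT5", "PDC1", "SDH2"):
        try:
            features.append(rec.find_transition_position(landscapes[name]))
        except rec.NoTransitionError as exc:
            summary["notes"].append(f"{name}: {exc}")
    if mig1_transition is not None:
        features.append(rec.LandscapeFeature("transition", mig1_transition,
                                             0.5, 0.0, "MIG1"))
    summary["features"] = [
        {"reporter": f.reporter_name, "kind": f.kind,
         "position_um": round(f.position_um, 3)} for f in features]

    recon_error = None
    try:
        # invert with the reference batch curve so the error metric isolates
        # the landscape inversion; calibration-fit quality is reported above
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # clamp count lands in summary
            result = rec.reconstruct_gradient(
                landscapes[config.reconstruction.reporter], true_curve,
                c0_mM=scenario.c0_mM,
                smoothing_window_bins=config.reconstruction.smoothing_window_bins)
        result.to_csv(out / "reconstruction.csv")
        m = result.valid_mask
        truth = scenario.glucose_profile.interpolate(result.positions_um[m])
        ok = truth > 0
        recon_error = float(np.median(
            np.abs(result.concentrations_mM[m][ok] - truth[ok]) / truth[ok]))
        summary["reconstruction"] = {
            "reporter": result.reporter_name,
            "valid_from_um": result.valid_from_um,
            "valid_to_um": result.valid_to_um,
            "n_clamped": result.n_clamped,
            "median_rel_error_vs_truth": recon_error,
        }
    except (rec.ReconstructionError, ValueError) as exc:
        summary["notes"].append(f"reconstruction skipped: {exc}")

    # --- phase classification ----------------------------------------------
    if features:
        phases = rec.classify_phases(features,
                                     length_um=scenario.geometry.length_um)
        summary["phase_boundary_um"] = phases.boundary_position_um
        summary["phase_boundary_width_um"] = phases.boundary_width_um
    else:
        summary["notes"].append("no growth, no features")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline done: %s", out / "summary.json")
    return summary
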