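"""Seeded generators for every input the analysis pipeline consumes.

These stand in for the study's imaging and FACS data with the statistical
structure the analysis assumes: FACS dose-response tables over a log2
glucose dilution ladder, reporter fluorescence landscapes composed from the
steady glucose gradient, time-lapse stacks of a monolayer whose cells are
advected by the growth-driven velocity field, single-cell tracks sampled
from that field, and per-cell MIG1 nuclear flags.

All generators are pure functions of their inputs and an explicit seed; no
global RNG state is touched.  Fluorescence noise is multiplicative lognormal
(intensities are positive and CV-parameterised); pixel noise is additive
Gaussian.

GFP perdurance: deep in the chamber cells stop dividing, so reporter protein
made earlier is neither degraded quickly nor diluted by division and the
fluorescence no longer tracks the local glucose concentration.  This is
modelled as an exponential spatial memory: beyond the kinematic stall depth
the landscape decays over ``perdurance_um`` from its stall-depth value
(never dropping below the instantaneous batch response, so
``perdurance_um = 0`` recovers pure dose-response tracking).  Vacuolar
re-localisation of the tagged protein is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .calibration import (
    DoseResponseCurve,
    FacsTable,
    default_concentration_series_percent,
    eval_response,
    make_default_panel,
)
from .extraction import ImageStack, TrackSet
from .model import (
    ChamberGeometry,
    FrontTrajectory,
    GlucoseProfile,
    GrowthKinetics,
    UptakeKinetics,
    VelocityProfile,
    solve_steady_gradient,
    velocity_field,
)
from .reconstruction import FluorescenceLandscape
from .units import percent_to_millimolar

__all__ = [
    "SyntheticScenario",
    "generate_batch_facs_table",
    "generate_fluorescence_landscape",
    "generate_timelapse_stack",
    "generate_tracks",
    "generate_mig1_cells",
    "STATIC_SPEED_UM_PER_H",
]

#: speed below which a cell is considered visibly static on imaging timescales
STATIC_SPEED_UM_PER_H: float = 1.0


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass
class SyntheticScenario:
    """Bundle of generative assumptions for one chamber at one glucose level."""

    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    uptake: UptakeKinetics = field(default_factory=UptakeKinetics)
    growth: GrowthKinetics = field(default_factory=GrowthKinetics)
    c0_mM: float = percent_to_millimolar(2.0)
    diffusion_um2_per_s: float = 100.0
    panel: dict[str, DoseResponseCurve] = field(default_factory=make_default_panel)
    noise_cv: float = 0.05
    perdurance_um: float = 100.0
    seed: int = 0
    grid_points: int = 400
    growth_cap: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.perdurance_um < 0:
            raise ValueError("perdurance_um must be non-negative")

    @cached_property
    def glucose_profile(self) -> GlucoseProfile:
        return solve_steady_gradient(self.geometry, self.uptake, 0.0, self.c0_mM,
                                     self.diffusion_um2_per_s, self.grid_points)

    @cached_property
    def velocity_profile(self) -> VelocityProfile:
        return velocity_field(self.glucose_profile, self.growth, self.growth_cap)

    @cached_property
    def stall_depth_um(self) -> float:
        """Kinematic stall depth: shallowest depth where the local speed drops
        below STATIC_SPEED_UM_PER_H (cells beyond it are visibly static)."""
        v = self.velocity_profile
        slow = v.speeds_um_per_h < STATIC_SPEED_UM_PER_H
        if not slow.any():
            return float(v.positions_um[-1])
        return float(v.positions_um[np.argmax(slow)])

    def replace(self, **kw) -> "SyntheticScenario":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# FACS tables
# ---------------------------------------------------------------------------

def generate_batch_facs_table(curve: DoseResponseCurve,
                              concentration_series_percent=None,
                              noise_cv: float = 0.05,
                              n_replicates: int = 3,
                              seed: int = 0) -> FacsTable:
    """Batch dose-response table over the log2 dilution ladder.

    Central values are the per-concentration mean over replicates of the true
    response times lognormal noise; the spread column is the replicate
    standard deviation.  ``noise_cv = 0`` reproduces the curve exactly.
    """
    if concentration_series_percent is None:
        concentration_series_percent = default_concentration_series_percent()
    pct = np.asarray(list(concentration_series_percent), dtype=float)
    if pct.size == 0:
        raise ValueError("concentration series must be non-empty")
    mM = np.array([percent_to_millimolar(p) for p in pct])
    rng = np.random.default_rng(seed)
    truth = np.asarray(eval_response(curve, mM))
    reps = truth[None, :] * _lognormal_factors(rng, noise_cv, (n_replicates, mM.size))
    return FacsTable(pct, mM, reps.mean(axis=0), reps.std(axis=0),
                     n_replicates, curve.reporter_name)


# ---------------------------------------------------------------------------
# fluorescence landscapes
# ---------------------------------------------------------------------------

def generate_fluorescence_landscape(scenario: SyntheticScenario,
                                    reporter_name: str,
                                    n_bins: int = 80,
                                    n_replicates: int = 9) -> FluorescenceLandscape:
    """Binned reporter intensity versus depth for one chamber.

    Composes the scenario's steady glucose gradient with the reporter's batch
    dose-response, applies the perdurance memory beyond the kinematic stall
    depth, and averages ``n_replicates`` multiplicative-noise realisations
    into per-bin mean and spread.
    """
    if reporter_name not in scenario.panel:
        raise KeyError(f"reporter {reporter_name!r} not in scenario panel")
    curve = scenario.panel[reporter_name]
    L = scenario.geometry.length_um
    edges = np.linspace(0.0, L, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    conc = scenario.glucose_profile.interpolate(centers)
    truth = np.asarray(eval_response(curve, conc))
    if scenario.perdurance_um > 0:
        y_stall = scenario.stall_depth_um
        deep = centers > y_stall
        if deep.any():
            c_stall = scenario.glucose_profile.interpolate(np.array([y_stall]))[0]
            f_stall = float(eval_response(curve, c_stall))
            memory = f_stall * np.exp(-(centers[deep] - y_stall) / scenario.perdurance_um)
            truth[deep] = np.maximum(memory, truth[deep])
    rng = np.random.default_rng(scenario.seed + _reporter_offset(reporter_name))
    reps = truth[None, :] * _lognormal_factors(rng, scenario.noise_cv,
                                               (n_replicates, n_bins))
    return FluorescenceLandscape(centers, reps.mean(axis=0), reps.std(axis=0),
                                 reporter_name, scenario.c0_mM)


def _reporter_offset(name: str) -> int:
    # stable per-reporter stream decorrelation, independent of dict order
    return sum(ord(ch) * (i + 1) for i, ch in enumerate(name)) % 10007


# ---------------------------------------------------------------------------
# time-lapse stacks
# ---------------------------------------------------------------------------

def generate_timelapse_stack(scenario: SyntheticScenario,
                             n_cells: int | None = None,
                             n_frames: int = 30,
                             pixel_size_um: float = 2.0,
                             frame_interval_min: float = 6.0,
                             front_trajectory: FrontTrajectory | None = None,
                             pixel_noise_fraction: float = 0.05,
                             cell_intensity: float = 1000.0) -> ImageStack:
    """Render a time-lapse of Gaussian-blob cells in the chamber.

    Steady-state mode (default): the chamber is full and every cell is
    advected by the scenario's velocity field; cells deeper than the
    kinematic stall depth are static; cells leaving at the opening are
    replaced in the moving region to keep the density steady.

    Filling mode (``front_trajectory`` given): the colony occupies
    [front(t), L] and cells shallower than the front are not yet present;
    this is the mode front detection is meant for.

    Blobs are isotropic Gaussians with FWHM of one cell diameter; the
    background sits at 10% of the blob peak and additive Gaussian pixel noise
    at ``pixel_noise_fraction`` of the blob peak.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    geom = scenario.geometry
    n_rows = int(round(geom.length_um / pixel_size_um))
    n_cols = int(round(geom.width_um / pixel_size_um))
    if n_rows < 2 or n_cols < 1:
        raise ValueError("pixel grid smaller than the chamber; decrease pixel size")
    if n_cells is None:
        n_cells = geom.capacity_cells
    rng = np.random.default_rng(scenario.seed + 1)

    sigma_px = (geom.cell_diameter_um / 2.355) / pixel_size_um
    blob_peak = cell_intensity / (2.0 * math.pi * sigma_px**2)
    background = 0.1 * blob_peak
    noise_sd = pixel_noise_fraction * blob_peak

    y = rng.uniform(0.0, geom.length_um, n_cells)
    x = rng.uniform(0.0, geom.width_um, n_cells)
    dt_h = frame_interval_min / 60.0
    vprof = scenario.velocity_profile
    y_stall = scenario.stall_depth_um

    frames = np.empty((n_frames, n_rows, n_cols))
    for t in range(n_frames):
        if front_trajectory is not None:
            t_h = t * dt_h
            front = float(np.interp(t_h, front_trajectory.times_h,
                                    front_trajectory.front_positions_um))
            visible = y >= front
        else:
            visible = np.ones(n_cells, dtype=bool)
        img = np.zeros((n_rows, n_cols))
        rows = np.clip((y[visible] / pixel_size_um).astype(int), 0, n_rows - 1)
        cols = np.clip((x[visible] / pixel_size_um).astype(int), 0, n_cols - 1)
        np.add.at(img, (rows, cols), cell_intensity)
        img = gaussian_filter(img, sigma_px, mode="constant")
        img += background
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, img.shape)
        frames[t] = np.clip(img, 0.0, None)
        # advect for the next frame (midpoint rule); static beyond stall
        if front_trajectory is None:
            moving = y <= y_stall
            v1 = vprof.interpolate(y[moving])
            y_mid = y[moving] - 0.5 * v1 * dt_h
            y[moving] = y[moving] - vprof.interpolate(np.clip(y_mid, 0, None)) * dt_h
            gone = y < 0
            if gone.any():
                y[gone] = rng.uniform(0.0, max(y_stall, 1.0), int(gone.sum()))
                x[gone] = rng.uniform(0.0, geom.width_um, int(gone.sum()))
    return ImageStack(frames, pixel_size_um, frame_interval_min)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def generate_tracks(velocity_profile: VelocityProfile,
                    n_tracks: int = 120,
                    duration_h: float = 2.0,
                    position_noise_um: float = 0.5,
                    seed: int = 0,
                    frame_interval_min: float = 6.0,
                    width_um: float = 50.0) -> TrackSet:
    """Single-cell tracks integrated through a depth-dependent velocity field.

    Start depths are stratified-uniform over the chamber (cells tile the
    packed monolayer roughly evenly, so clumped purely-random starts would
    misrepresent the sampling); each frame step advances the depth with a
    midpoint (RK2) rule and adds Gaussian positional jitter.  Tracks are
    truncated when they exit at the opening.
    """
    if n_tracks < 1:
        raise ValueError("need at least one track")
    rng = np.random.default_rng(seed)
    L = float(velocity_profile.positions_um[-1])
    dt_h = frame_interval_min / 60.0
    n_steps = max(2, int(round(duration_h / dt_h)) + 1)
    rows = []
    strata = rng.permutation(n_tracks)
    for tid in range(n_tracks):
        y = (strata[tid] + rng.uniform()) / n_tracks * L
        x = rng.uniform(0.0, width_um)
        for k in range(n_steps):
            jy = rng.normal(0.0, position_noise_um) if position_noise_um > 0 else 0.0
            jx = rng.normal(0.0, position_noise_um) if position_noise_um > 0 else 0.0
            rows.append((tid, k, k * dt_h, x + jx, y + jy))
            v_mid = velocity_profile.interpolate(
                np.clip(y - 0.5 * velocity_profile.interpolate(y) * dt_h, 0.0, L))
            y = y - float(v_mid) * dt_h
            if y < 0:
                break
    return TrackSet(pd.DataFrame(rows, columns=["track_id", "frame", "t_h",
                                                "x_um", "y_um"]))


# ---------------------------------------------------------------------------
# MIG1 nuclear flags
# ---------------------------------------------------------------------------

def generate_mig1_cells(scenario: SyntheticScenario,
                        n_cells: int = 500) -> pd.DataFrame:
    """Per-cell (depth, nuclear flag) records for the MIG1 reporter.

    Nuclear localisation is fast relative to GFP turnover, so the flag is
    Bernoulli with probability given by the MIG1 response at the local
    glucose concentration (no perdurance).
    """
    if "MIG1" not in scenario.panel:
        raise KeyError("scenario panel has no MIG1 curve")
    rng = np.random.default_rng(scenario.seed + 2)
    depths = rng.uniform(0.0, scenario.geometry.length_um, n_cells)
    conc = scenario.glucose_profile.interpolate(depths)
    prob = np.clip(np.asarray(eval_response(scenario.panel["MIG1"], conc)), 0.0, 1.0)
    nuclear = rng.random(n_cells) < prob
    return pd.DataFrame({"depth_um": depths, "is_nuclear": nuclear})
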