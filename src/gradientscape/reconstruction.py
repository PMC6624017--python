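"""Inference of the intra-colony glucose gradient from reporter landscapes.

A fluorescence landscape F(y) measured along the chamber and the reporter's
batch dose-response G(C) determine the glucose profile C(y) up to an affine
intensity mapping: microscope and cytometer units differ, but two anchors pin
the map — the front of the colony sits at the external concentration C0
(F(0) <-> G(C0)) and, for a peaked reporter such as HXT7, the landscape
maximum corresponds to the batch maximum at the peak concentration
(F_max <-> G(C_peak)).  Mapping every intensity through this affine
transform and inverting G on its high-concentration branch yields C(y) from
the front down to the peak position; deeper positions (below the peak
concentration, 0.016% w/vol for HXT7) are outside the invertible domain and
are marked invalid rather than extrapolated.

Landscape features (expression peaks of HXT7/HXK1/HXK2, low/high transitions
of HXT1/HXT5/PDC1/SDH2) line up near a common depth; their pooled median
defines the boundary between the fermentative, actively growing region
(phase I) and the deep, glucose-starved arrested region (phase II).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .calibration import (
    HXT7_PEAK_MM,
    BranchRangeError,
    DoseResponseCurve,
    eval_response,
    invert_on_branch,
)

__all__ = [
    "FluorescenceLandscape",
    "LandscapeFeature",
    "ReconstructionResult",
    "PhaseMap",
    "ReconstructionError",
    "NoTransitionError",
    "find_peak_position",
    "find_transition_position",
    "reconstruct_gradient",
    "classify_phases",
    "align_landscapes",
]


class ReconstructionError(RuntimeError):
    """Landscape/curve combination does not admit the anchored inversion."""


class NoTransitionError(RuntimeError):
    """Landscape has no resolvable low/high expression transition."""


@dataclass
class FluorescenceLandscape:
    """Binned reporter intensity versus depth at one external glucose level."""

    positions_um: np.ndarray
    intensities_au: np.ndarray
    spread_au: np.ndarray | None = None
    reporter_name: str = ""
    c0_mM: float = float("nan")

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities_au = np.asarray(self.intensities_au, dtype=float)
        if self.spread_au is not None:
            self.spread_au = np.asarray(self.spread_au, dtype=float)
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities_au < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.positions_um.size

    @property
    def front_intensity(self) -> float:
        """F0, the intensity at the chamber opening."""
        return float(self.intensities_au[0])

    def to_csv(self, path) -> None:
        from .units import millimolar_to_percent

        with open(path, "w") as fh:
            fh.write(f"# reporter={self.reporter_name}\n")
            if np.isfinite(self.c0_mM):
                fh.write(f"# c0_percent={millimolar_to_percent(self.c0_mM):.6g}\n")
            fh.write(f"# c0_mM={self.c0_mM}\n")
            df = pd.DataFrame({"position_um": self.positions_um,
                               "intensity_au": self.intensities_au,
                               "spread_au": (self.spread_au if self.spread_au
                                             is not None else np.nan)})
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "FluorescenceLandscape":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
        df = pd.read_csv(path, comment="#")
        spread = df["spread_au"].to_numpy() if "spread_au" in df else None
        if spread is not None and np.all(np.isnan(spread)):
            spread = None
        return cls(df["position_um"].to_numpy(), df["intensity_au"].to_numpy(),
                   spread, meta.get("reporter", ""),
                   float(meta.get("c0_mM", "nan")))

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.positions_um, self.intensities_au, label=self.reporter_name)
        if self.spread_au is not None:
            ax.fill_between(self.positions_um,
                            self.intensities_au - self.spread_au,
                            self.intensities_au + self.spread_au, alpha=0.3)
        ax.set_xlabel("depth (um)")
        ax.set_ylabel("fluorescence (a.u.)")
        return ax


@dataclass
class LandscapeFeature:
    """A located landscape landmark: an expression peak or a low/high transition."""

    kind: Literal["peak", "transition"]
    position_um: float
    value_au: float
    quality: float
    reporter_name: str = ""
    note: str = ""


@dataclass
class PhaseMap:
    """Fermentative (phase I) / arrested (phase II) partition of the chamber."""

    boundary_position_um: float
    boundary_width_um: float
    positions_um: np.ndarray
    labels: np.ndarray  # "phase_I" shallower than the boundary, "phase_II" deeper


@dataclass
class ReconstructionResult:
    """Inferred glucose concentration versus depth with its validity range.

    ``concentrations_mM`` is NaN outside [valid_from_um, valid_to_um].
    ``anchors`` records the two (fluorescence, batch response) pairs that fix
    the affine intensity map; ``n_clamped`` counts bins whose mapped
    fluorescence fell outside the invertible branch and was clamped.
    """

    positions_um: np.ndarray
    concentrations_mM: np.ndarray
    valid_from_um: float
    valid_to_um: float
    anchors: dict
    reporter_name: str = ""
    c0_mM: float = float("nan")
    n_clamped: int = 0

    @property
    def valid_mask(self) -> np.ndarray:
        return ((self.positions_um >= self.valid_from_um)
                & (self.positions_um <= self.valid_to_um)
                & np.isfinite(self.concentrations_mM))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_um": self.positions_um,
                             "concentration_mM": self.concentrations_mM,
                             "valid": self.valid_mask})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        m = self.valid_mask
        lines = [f"Glucose gradient reconstruction ({self.reporter_name})",
                 "-" * 48,
                 f"external glucose C0: {self.c0_mM:.3g} mM",
                 f"valid region: {self.valid_from_um:.0f} - {self.valid_to_um:.0f} um "
                 f"({int(m.sum())} bins)",
                 f"clamped bins: {self.n_clamped}"]
        for name, (f_val, g_val) in self.anchors.items():
            lines.append(f"anchor {name}: F={f_val:.4g} a.u. -> G={g_val:.4g} a.u.")
        if m.any():
            lines.append(f"concentration range: {np.nanmin(self.concentrations_mM[m]):.3g}"
                         f" - {np.nanmax(self.concentrations_mM[m]):.3g} mM")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.valid_mask
        ax.plot(self.positions_um[m], self.concentrations_mM[m])
        ax.set_xlabel("depth (um)")
        ax.set_ylabel("glucose (mM)")
        ax.set_yscale("log")
        return ax


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    kernel = np.ones(window) / window
    padded = np.pad(values.astype(float), window, mode="edge")
    return np.convolve(padded, kernel, mode="same")[window:-window]


def find_peak_position(landscape: FluorescenceLandscape,
                       smoothing_window_bins: int = 3) -> LandscapeFeature:
    """Locate the landscape's expression peak with sub-bin refinement.

    Moving-average smoothing, global maximum (ties broken toward the
    opening), then a quadratic fit through the three bins around the maximum.
    A maximum at either landscape edge is flagged ``boundary_peak`` — e.g. at
    very high external glucose the peak moves to the dead end or out of view.
    """
    if len(landscape) < 5:
        raise ValueError("need at least 5 bins to locate a peak")
    y = landscape.positions_um
    f = _smooth(landscape.intensities_au, smoothing_window_bins)
    i = int(np.argmax(f))
    rng = float(f.max() - f.min())
    quality = (float(f[i] - f.min()) / rng) if rng > 0 else 0.0
    if i == 0 or i == f.size - 1:
        return LandscapeFeature("peak", float(y[i]), float(landscape.intensities_au[i]),
                                quality, landscape.reporter_name, "boundary_peak")
    # quadratic through the three bins around the max
    y3, f3 = y[i - 1:i + 2], f[i - 1:i + 2]
    denom = (f3[0] - 2 * f3[1] + f3[2])
    if denom >= 0:  # flat triple; keep the bin centre
        pos, val = float(y3[1]), float(f3[1])
    else:
        delta = 0.5 * (f3[0] - f3[2]) / denom
        delta = float(np.clip(delta, -1.0, 1.0))
        pos = float(y3[1] + delta * (y3[2] - y3[1]))
        val = float(f3[1] - 0.25 * (f3[0] - f3[2]) * delta)
    return LandscapeFeature("peak", pos, val, quality, landscape.reporter_name)


def find_transition_position(landscape: FluorescenceLandscape) -> LandscapeFeature:
    """Locate the midpoint of a low/high expression transition.

    Fits a four-parameter logistic in position; the transition is the
    midpoint parameter and the quality is the fit RMSE over the dynamic
    range.  Raises NoTransitionError when the dynamic range does not exceed
    twice the median per-bin spread (no resolvable transition) or the
    midpoint falls outside the landscape.
    """
    y = landscape.positions_um
    f = landscape.intensities_au.astype(float)
    dynamic = float(f.max() - f.min())
    noise = float(np.median(landscape.spread_au)) if landscape.spread_au is not None else 0.0
    if dynamic <= 2.0 * noise or dynamic == 0.0:
        raise NoTransitionError(
            f"dynamic range {dynamic:.3g} below noise floor {noise:.3g} for "
            f"{landscape.reporter_name or 'landscape'}")

    from scipy.special import expit

    def logistic(x, lo, hi, x0, w):
        return lo + (hi - lo) * expit((x - x0) / w)

    span = float(y[-1] - y[0])
    x0_guess = float(y[np.argmin(np.abs(f - 0.5 * (f.max() + f.min())))])
    sign = 1.0 if f[-1] >= f[0] else -1.0
    p0 = [float(f.min()), float(f.max()), x0_guess, sign * span / 10.0]
    try:
        popt, _ = curve_fit(logistic, y, f, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise NoTransitionError(f"logistic fit failed: {exc}") from exc
    lo, hi, x0, w = popt
    if not (y[0] <= x0 <= y[-1]):
        raise NoTransitionError(
            f"fitted midpoint {x0:.0f} um outside the landscape "
            f"[{y[0]:.0f}, {y[-1]:.0f}] um (plateau, no transition)")
    if abs(hi - lo) <= 2.0 * noise:
        raise NoTransitionError(
            f"fitted plateaus differ by {abs(hi - lo):.3g}, within the noise "
            f"floor {noise:.3g}; no distinct low/high expression levels")
    rmse = float(np.sqrt(np.mean((logistic(y, *popt) - f) ** 2)))
    return LandscapeFeature("transition", float(x0),
                            float(logistic(x0, *popt)), rmse / dynamic,
                            landscape.reporter_name)


# ---------------------------------------------------------------------------
# gradient reconstruction
# ---------------------------------------------------------------------------

def _parabolic_refine(y: np.ndarray, f: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-bin extremum (position, value) from the 3 points around index i."""
    y3, f3 = y[i - 1:i + 2], f[i - 1:i + 2]
    denom = f3[0] - 2 * f3[1] + f3[2]
    if denom == 0:
        return float(y3[1]), float(f3[1])
    delta = float(np.clip(0.5 * (f3[0] - f3[2]) / denom, -1.0, 1.0))
    return (float(y3[1] + delta * (y3[2] - y3[1])),
            float(f3[1] - 0.25 * (f3[0] - f3[2]) * delta))


def reconstruct_gradient(landscape: FluorescenceLandscape,
                         batch_curve: DoseResponseCurve,
                         c0_mM: float | None = None,
                         c_low_mM: float | None = None,
                         smoothing_window_bins: int = 3) -> ReconstructionResult:
    """Anchor-map the landscape onto the batch curve and invert to glucose.

    Peaked curves: the affine intensity map sends the front intensity F0
    (linearly extrapolated to the chamber opening) to G(C0) and the landscape
    maximum F_max to the batch maximum; inversion on the high-concentration
    branch is valid from the front down to the peak position.
    Monotone-increasing curves (HXT1): the landscape minimum F_min maps to
    the curve's value at ``c_low_mM`` (default: the lower edge of the
    calibrated range, where the curve sits at its basal level, matching the
    glucose-exhausted deep region) and the valid region runs from the front
    to that minimum.  Mapped intensities that leave the branch range are
    clamped to the branch endpoint and counted in ``n_clamped``.

    The returned result carries an explicit sample at y = 0 whose
    concentration is C0 exactly (the anchor).
    """
    if c0_mM is None:
        c0_mM = landscape.c0_mM
    if not np.isfinite(c0_mM):
        raise ValueError("c0_mM must be given (landscape carries none)")
    lo, hi = batch_curve.valid_range_mM
    if not (lo <= c0_mM <= hi):
        raise ValueError(f"c0 = {c0_mM:.3g} mM outside the calibrated range "
                         f"[{lo:.3g}, {hi:.3g}] mM")
    y = landscape.positions_um
    f = landscape.intensities_au.astype(float)
    # intensity at the chamber opening, extrapolated from the first two bins
    if y[0] > 0 and y.size >= 2:
        f0 = float(f[0] - (f[1] - f[0]) / (y[1] - y[0]) * y[0])
        f0 = max(f0, 0.0)
    else:
        f0 = landscape.front_intensity
    g0 = float(eval_response(batch_curve, c0_mM))
    fs = _smooth(f, smoothing_window_bins)

    if batch_curve.shape == "peaked":
        i_pk = int(np.argmax(fs))
        if i_pk == 0 or i_pk == fs.size - 1:
            raise ReconstructionError(
                "landscape maximum sits at the edge (boundary peak); the "
                "high-concentration branch inversion is undefined")
        y_ref, f_ref = _parabolic_refine(y, f, i_pk)
        if f_ref <= f0:
            raise ReconstructionError(
                f"no interior peak: landscape maximum {f_ref:.4g} does not "
                f"exceed the front intensity {f0:.4g}")
        g_ref = batch_curve.max_response
        anchors = {"front": (f0, g0), "peak": (f_ref, g_ref)}
    elif batch_curve.shape == "monotone_increasing":
        if c_low_mM is None:
            c_low_mM = lo
        i_min = int(np.argmin(fs))
        f_ref, y_ref = float(f[i_min]), float(y[i_min])
        if f_ref >= f0:
            raise ReconstructionError(
                "landscape minimum does not lie below the front intensity; "
                "nothing to invert")
        g_ref = float(eval_response(batch_curve, c_low_mM))
        anchors = {"front": (f0, g0), "deep_minimum": (f_ref, g_ref)}
    else:
        raise ReconstructionError(
            "reconstruction needs a peaked or monotone_increasing batch curve")

    # affine map m(F) = a F + b with m(f0) = g0, m(f_ref) = g_ref
    a = (g_ref - g0) / (f_ref - f0)
    b = g0 - a * f0
    mapped = a * f + b

    branch = "high_concentration" if batch_curve.shape == "peaked" else "whole"
    if batch_curve.shape == "peaked":
        ends = (batch_curve.peak_mM, max(hi, batch_curve.peak_mM))
    else:
        ends = (lo, hi)
    g_ends = sorted(float(eval_response(batch_curve, e)) for e in ends)
    conc = np.full(y.size, np.nan)
    n_clamped = 0
    for i in range(y.size):
        if y[i] > y_ref:
            break
        g_val = mapped[i]
        try:
            conc[i] = invert_on_branch(batch_curve, g_val, branch)
        except BranchRangeError:
            n_clamped += 1
            conc[i] = invert_on_branch(
                batch_curve, float(np.clip(g_val, g_ends[0], g_ends[1])), branch)
    if n_clamped:
        warnings.warn(f"{n_clamped} bins mapped outside the invertible branch "
                      "and were clamped", stacklevel=2)
    # the inferred gradient lives between the landmark and the boundary value
    c_floor = batch_curve.peak_mM if batch_curve.shape == "peaked" else c_low_mM
    conc = np.clip(conc, min(c_floor, c0_mM), c0_mM)
    # prepend the exact front anchor at the chamber opening
    if y[0] > 0:
        positions = np.concatenate([[0.0], y])
        conc = np.concatenate([[c0_mM], conc])
    else:
        positions = y.copy()
        conc[0] = c0_mM
    return ReconstructionResult(positions, conc, 0.0, float(y_ref), anchors,
                                landscape.reporter_name or batch_curve.reporter_name,
                                c0_mM, n_clamped)


# ---------------------------------------------------------------------------
# phases and alignment
# ---------------------------------------------------------------------------

def classify_phases(features: Sequence[LandscapeFeature],
                    positions_um: np.ndarray | None = None,
                    length_um: float = 800.0) -> PhaseMap:
    """Partition the chamber at the pooled median of feature positions.

    The median over peaks and transitions is robust to one outlying
    reporter; the spread (standard deviation) of the feature positions is
    reported as the boundary width.
    """
    feats = list(features)
    if not feats:
        raise ValueError("need at least one landscape feature")
    pos = np.array([f.position_um for f in feats], dtype=float)
    boundary = float(np.median(pos))
    width = float(pos.std())
    if positions_um is None:
        positions_um = np.linspace(0.0, length_um, 81)
    positions_um = np.asarray(positions_um, dtype=float)
    labels = np.where(positions_um < boundary, "phase_I", "phase_II")
    return PhaseMap(boundary, width, positions_um, labels)


def align_landscapes(landscapes: Sequence[FluorescenceLandscape],
                     bin_grid: np.ndarray) -> pd.DataFrame:
    """Min-max-normalise landscapes and resample them onto a common grid.

    All landscapes must come from the same external concentration and their
    position ranges must cover the grid.  A constant landscape normalises to
    all zeros.
    """
    landscapes = list(landscapes)
    if not landscapes:
        raise ValueError("need at least one landscape")
    c0s = {round(ls.c0_mM, 9) for ls in landscapes if np.isfinite(ls.c0_mM)}
    if len(c0s) > 1:
        raise ValueError(f"landscapes come from different c0 values: {sorted(c0s)}")
    grid = np.asarray(bin_grid, dtype=float)
    rows = {}
    for ls in landscapes:
        if grid.min() < ls.positions_um.min() - 1e-9 or \
           grid.max() > ls.positions_um.max() + 1e-9:
            raise ValueError(f"grid extends beyond landscape {ls.reporter_name!r}")
        f = ls.intensities_au.astype(float)
        ptp = f.max() - f.min()
        norm = (f - f.min()) / ptp if ptp > 0 else np.zeros_like(f)
        rows[ls.reporter_name] = np.interp(grid, ls.positions_um, norm)
    return pd.DataFrame(rows, index=grid).T
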