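"""Batch dose-response calibration of glucose reporters.

Each GFP-tagged reporter has a characteristic batch-culture fluorescence
versus external glucose concentration: low-affinity transporters such as HXT1
rise with glucose, starvation markers such as HXT5 or the respiration marker
SDH2 fall with it, and high-affinity transporters (HXT7) and the hexokinases
(HXK1/HXK2) peak at low glucose.  Monotone responses are modelled as Hill
functions of concentration; peaked responses as the product of a rising and a
falling Hill term with a common steepness, which places the maximum exactly
at the geometric mean of the two half-points.  Curves are fitted to
FACS-style tables in log-concentration space and inverted per monotone
branch, which is what the gradient reconstruction relies on.

Fluorescence units are arbitrary (a.u.); default panel amplitudes are
order-1 and synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq, curve_fit

from .units import millimolar_to_percent, percent_to_millimolar

__all__ = [
    "DoseResponseCurve",
    "FacsTable",
    "DoseResponseModel",
    "DoseResponseFit",
    "FitError",
    "BranchRangeError",
    "HXT7_PEAK_MM",
    "CONCENTRATION_FLOOR_MM",
    "default_concentration_series_percent",
    "make_default_panel",
    "eval_response",
    "fit_response",
    "invert_on_branch",
]

Shape = Literal["monotone_increasing", "monotone_decreasing", "peaked"]

#: glucose concentration of peak HXT7/HXK1/HXK2 expression, 0.016% w/vol
HXT7_PEAK_MM: float = percent_to_millimolar(0.016)

#: 0% glucose is mapped onto this floor for log-concentration work
CONCENTRATION_FLOOR_MM: float = 1e-4


class FitError(RuntimeError):
    """Dose-response fit failed; carries the best residual reached."""

    def __init__(self, message: str, residual: float = float("nan")):
        super().__init__(message)
        self.residual = residual


class BranchRangeError(ValueError):
    """Requested fluorescence lies outside the invertible branch range."""


def default_concentration_series_percent() -> list[float]:
    """The batch calibration ladder: log2 dilutions from 8% down to
    0.0078125% w/vol (11 steps), plus a 0% point."""
    series = [8.0 / 2**k for k in range(11)]
    series.append(0.0)
    return series


@dataclass
class DoseResponseCurve:
    """Parametric batch fluorescence response G(C) of one reporter.

    Monotone shapes use ``half_point_mM`` and ``hill``; the peaked shape is
    the normalised product of an increasing and a decreasing Hill term with
    half-points peak_mM/exp(log_width) and peak_mM*exp(log_width), so the
    maximum value basal+amplitude is attained exactly at ``peak_mM``.
    """

    reporter_name: str
    shape: Shape
    basal: float
    amplitude: float
    hill: float
    half_point_mM: float | None = None
    peak_mM: float | None = None
    log_width: float | None = None
    valid_range_mM: tuple[float, float] = (CONCENTRATION_FLOOR_MM, 444.0)
    rmse: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.hill <= 0:
            raise ValueError("hill coefficient must be positive")
        if self.shape in ("monotone_increasing", "monotone_decreasing"):
            if self.half_point_mM is None or self.half_point_mM <= 0:
                raise ValueError("monotone shapes need a positive half_point_mM")
        elif self.shape == "peaked":
            if self.peak_mM is None or self.peak_mM <= 0:
                raise ValueError("peaked shape needs a positive peak_mM")
            if self.log_width is None or self.log_width <= 0:
                raise ValueError("peaked shape needs a positive log_width")
        else:
            raise ValueError(f"unknown shape {self.shape!r}")

    # -- evaluation ---------------------------------------------------------

    def __call__(self, concentration_mM) -> np.ndarray | float:
        return eval_response(self, concentration_mM)

    @property
    def max_response(self) -> float:
        return self.basal + self.amplitude

    def to_dict(self) -> dict:
        d = {"reporter_name": self.reporter_name, "shape": self.shape,
             "basal": float(self.basal), "amplitude": float(self.amplitude),
             "hill": float(self.hill),
             "valid_range_mM": [float(v) for v in self.valid_range_mM]}
        if self.shape == "peaked":
            d.update(peak_mM=float(self.peak_mM), log_width=float(self.log_width))
        else:
            d.update(half_point_mM=float(self.half_point_mM))
        if self.rmse is not None:
            d["rmse"] = float(self.rmse)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "DoseResponseCurve":
        d = dict(d)
        if "valid_range_mM" in d:
            d["valid_range_mM"] = tuple(d["valid_range_mM"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DoseResponseCurve":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _hill_up(c: np.ndarray, k: float, h: float) -> np.ndarray:
    ch = np.power(c, h)
    return ch / (ch + k**h)


def eval_response(curve: DoseResponseCurve, concentration_mM) -> np.ndarray | float:
    """Evaluate the calibration curve at one or many concentrations (mM)."""
    c = np.asarray(concentration_mM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    if curve.shape == "monotone_increasing":
        resp = curve.basal + curve.amplitude * _hill_up(c, curve.half_point_mM, curve.hill)
    elif curve.shape == "monotone_decreasing":
        resp = curve.basal + curve.amplitude * (1.0 - _hill_up(c, curve.half_point_mM, curve.hill))
    else:
        w = math.exp(curve.log_width)
        k_lo, k_hi = curve.peak_mM / w, curve.peak_mM * w
        g = _hill_up(c, k_lo, curve.hill) * (1.0 - _hill_up(c, k_hi, curve.hill))
        g_peak = (_hill_up(np.array([curve.peak_mM]), k_lo, curve.hill)
                  * (1.0 - _hill_up(np.array([curve.peak_mM]), k_hi, curve.hill)))[0]
        resp = curve.basal + curve.amplitude * g / g_peak
    return float(resp[0]) if scalar else resp


def invert_on_branch(curve: DoseResponseCurve, fluorescence_au: float,
                     branch: Literal["high_concentration", "low_concentration", "whole"]
                     = "high_concentration") -> float:
    """Invert the calibration on a monotone branch, returning mM.

    Peaked curves must name a branch; monotone curves accept "whole" (or
    either branch name, which is ignored).  Raises BranchRangeError when the
    fluorescence lies outside the response range of the selected branch.
    """
    lo, hi = curve.valid_range_mM
    if curve.shape == "peaked":
        if branch == "whole":
            raise ValueError("a peaked curve has no single-valued whole-range "
                             "inverse; choose high_concentration or low_concentration")
        if branch == "high_concentration":
            a, b = curve.peak_mM, max(hi, curve.peak_mM)
        else:
            a, b = min(lo, curve.peak_mM), curve.peak_mM
    else:
        a, b = lo, hi

    fa, fb = eval_response(curve, a), eval_response(curve, b)
    f_lo, f_hi = min(fa, fb), max(fa, fb)
    tol = 1e-9 * max(1.0, abs(f_hi))
    if fluorescence_au > f_hi + tol or fluorescence_au < f_lo - tol:
        raise BranchRangeError(
            f"fluorescence {fluorescence_au:.6g} outside branch range "
            f"[{f_lo:.6g}, {f_hi:.6g}] of {curve.reporter_name} ({branch})")
    f = min(max(fluorescence_au, f_lo), f_hi)
    if abs(f - fa) <= tol:
        return float(a)
    if abs(f - fb) <= tol:
        return float(b)
    # solve in log-concentration for relative accuracy
    la, lb = math.log(a), math.log(b)
    root = brentq(lambda lx: eval_response(curve, math.exp(lx)) - f,
                  la, lb, xtol=1e-14, rtol=1e-15)
    return float(math.exp(root))


# ---------------------------------------------------------------------------
# FACS tables and fitting
# ---------------------------------------------------------------------------

@dataclass
class FacsTable:
    """Batch FACS dose-response table: central fluorescence per concentration.

    The central value is treated as the per-sample median; ``spread`` is the
    replicate dispersion.
    """

    concentrations_percent: np.ndarray
    concentrations_mM: np.ndarray
    fluorescence_au: np.ndarray
    spread_au: np.ndarray
    n_replicates: int = 1
    reporter_name: str = ""

    def __post_init__(self) -> None:
        self.concentrations_percent = np.asarray(self.concentrations_percent, dtype=float)
        self.concentrations_mM = np.asarray(self.concentrations_mM, dtype=float)
        self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)
        self.spread_au = np.asarray(self.spread_au, dtype=float)
        n = self.concentrations_mM.size
        if not (self.concentrations_percent.size == self.fluorescence_au.size
                == self.spread_au.size == n):
            raise ValueError("all columns must have the same length")
        if np.any(self.concentrations_mM < 0) or np.any(self.fluorescence_au < 0):
            raise ValueError("concentrations and fluorescence must be non-negative")
        if np.unique(self.concentrations_mM).size != n:
            raise ValueError("duplicate concentrations in table")

    def __len__(self) -> int:
        return self.concentrations_mM.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "percent_w_vol": self.concentrations_percent,
            "mM": self.concentrations_mM,
            "fluorescence_au": self.fluorescence_au,
            "spread_au": self.spread_au,
            "n": self.n_replicates,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reporter_name: str = "") -> "FacsTable":
        df = pd.read_csv(path, comment="#")
        return cls(df["percent_w_vol"].to_numpy(), df["mM"].to_numpy(),
                   df["fluorescence_au"].to_numpy(), df["spread_au"].to_numpy(),
                   int(df["n"].iloc[0]), reporter_name)


class DoseResponseModel:
    """Least-squares dose-response model for one FACS table.

    Fits the chosen parametric shape in log-concentration space (0% rows are
    floored at CONCENTRATION_FLOOR_MM).  ``fit()`` returns a
    :class:`DoseResponseFit` carrying the curve, parameter standard errors
    and the residual RMSE.
    """

    def __init__(self, table: FacsTable, shape: Shape):
        if len(table) < 5:
            raise ValueError("need at least 5 distinct concentrations to fit")
        self.table = table
        self.shape = shape
        self._c = np.maximum(table.concentrations_mM, CONCENTRATION_FLOOR_MM)
        self._f = table.fluorescence_au

    # parameter vectors: monotone (basal, amplitude, ln_half, hill)
    #                    peaked   (basal, amplitude, ln_peak, log_width, hill)
    def _predict(self, params: np.ndarray) -> np.ndarray:
        return eval_response(self._curve_from_params(params), self._c)

    def _curve_from_params(self, p: np.ndarray) -> DoseResponseCurve:
        if self.shape == "peaked":
            return DoseResponseCurve(self.table.reporter_name or "fit", self.shape,
                                     basal=p[0], amplitude=p[1], hill=p[4],
                                     peak_mM=math.exp(p[2]), log_width=p[3])
        return DoseResponseCurve(self.table.reporter_name or "fit", self.shape,
                                 basal=p[0], amplitude=p[1], hill=p[3],
                                 half_point_mM=math.exp(p[2]))

    def _initial_guess(self) -> tuple[np.ndarray, tuple]:
        f, c = self._f, self._c
        fmin, fmax = float(f.min()), float(f.max())
        amp0 = max(fmax - fmin, 1e-6)
        lx = np.log(c)
        big = math.log(1e4)
        if self.shape == "peaked":
            x_peak = float(lx[np.argmax(f)])
            p0 = np.array([fmin, amp0, x_peak, 1.5, 1.5])
            bounds = ([0.0, 0.0, math.log(CONCENTRATION_FLOOR_MM), 0.05, 0.2],
                      [fmax, 10 * amp0 + 1, big, 6.0, 8.0])
        else:
            # half point near where the response crosses mid-range
            mid = 0.5 * (fmin + fmax)
            order = np.argsort(lx)
            fx = f[order]
            xs = lx[order]
            idx = int(np.argmin(np.abs(fx - mid)))
            p0 = np.array([fmin, amp0, xs[idx], 1.5])
            bounds = ([0.0, 0.0, math.log(CONCENTRATION_FLOOR_MM), 0.2],
                      [fmax, 10 * amp0 + 1, big, 8.0])
        p0 = np.clip(p0, bounds[0], bounds[1])
        return p0, bounds

    def fit(self) -> "DoseResponseFit":
        p0, bounds = self._initial_guess()
        n_params = p0.size
        if len(self.table) < n_params:
            raise ValueError(f"{len(self.table)} points cannot constrain "
                             f"{n_params} parameters")

        def f_model(lx, *p):
            return eval_response(self._curve_from_params(np.array(p)), np.exp(lx))

        try:
            popt, pcov = curve_fit(f_model, np.log(self._c), self._f, p0=p0,
                                   bounds=bounds, maxfev=20000)
        except RuntimeError as exc:
            resid = float(np.sqrt(np.mean((self._predict(p0) - self._f) ** 2)))
            raise FitError(f"dose-response fit did not converge: {exc}", resid) from exc
        resid = self._predict(popt) - self._f
        rmse = float(np.sqrt(np.mean(resid**2)))
        curve = self._curve_from_params(popt)
        curve.rmse = rmse
        with np.errstate(invalid="ignore"):
            bse = np.sqrt(np.diag(pcov))
        return DoseResponseFit(self, curve, popt, bse, rmse)


@dataclass
class DoseResponseFit:
    """Results of a dose-response fit."""

    model: DoseResponseModel
    curve: DoseResponseCurve
    params: np.ndarray
    bse: np.ndarray
    rmse: float

    @property
    def param_names(self) -> list[str]:
        if self.curve.shape == "peaked":
            return ["basal", "amplitude", "ln_peak_mM", "log_width", "hill"]
        return ["basal", "amplitude", "ln_half_point_mM", "hill"]

    def summary(self) -> str:
        lines = [f"Dose-response fit: {self.curve.reporter_name} ({self.curve.shape})",
                 "-" * 50,
                 f"{'parameter':<18}{'estimate':>12}{'std err':>12}"]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<18}{est:>12.4g}{se:>12.3g}")
        lines.append(f"RMSE: {self.rmse:.4g} a.u. on {len(self.model.table)} points")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.table
        c = np.maximum(t.concentrations_mM, CONCENTRATION_FLOOR_MM)
        ax.errorbar(c, t.fluorescence_au, yerr=t.spread_au, fmt="o", label="FACS")
        grid = np.geomspace(c.min(), c.max(), 200)
        ax.plot(grid, eval_response(self.curve, grid), label="fit")
        ax.set_xscale("log")
        ax.set_xlabel("glucose (mM)")
        ax.set_ylabel("fluorescence (a.u.)")
        ax.legend()
        return ax


def fit_response(table: FacsTable, shape: Shape) -> DoseResponseCurve:
    """Fit a dose-response curve of the given shape to a FACS table."""
    return DoseResponseModel(table, shape).fit().curve


# ---------------------------------------------------------------------------
# default reporter panel
# ---------------------------------------------------------------------------

def make_default_panel() -> dict[str, DoseResponseCurve]:
    """Reference dose-response panel for the reporter strains.

    Shapes follow the known glucose regulation of each gene: HXT1 and PDC1
    rise with glucose, HXT5 and SDH2 fall, HXT7/HXK1/HXK2 peak at the 0.016%
    w/vol landmark, HXT2-4 and HXT6 peak at intermediate concentrations, and
    MIG1 (nuclear fraction) is a near-binary switch.  Amplitudes are
    synthetic (arbitrary units); HXT2-4/HXT6 locations and widths are
    synthetic placeholders only shown graphically in batch data.
    """
    p = HXT7_PEAK_MM
    curves = [
        # HXT1 induction threshold sits near glucose exhaustion so the
        # in-colony HXT1/HXT7 landscapes are inversely correlated
        DoseResponseCurve("HXT1", "monotone_increasing", basal=0.05, amplitude=1.0,
                          hill=2.0, half_point_mM=1.0),
        DoseResponseCurve("HXT2", "peaked", basal=0.05, amplitude=0.8, hill=1.8,
                          peak_mM=5.0, log_width=1.4),
        DoseResponseCurve("HXT3", "peaked", basal=0.05, amplitude=0.9, hill=1.5,
                          peak_mM=20.0, log_width=2.0),
        DoseResponseCurve("HXT4", "peaked", basal=0.05, amplitude=0.7, hill=2.0,
                          peak_mM=2.0, log_width=1.1),
        DoseResponseCurve("HXT5", "monotone_decreasing", basal=0.03, amplitude=1.0,
                          hill=2.0, half_point_mM=0.1),
        DoseResponseCurve("HXT6", "peaked", basal=0.05, amplitude=0.6, hill=1.5,
                          peak_mM=0.5, log_width=1.8),
        DoseResponseCurve("HXT7", "peaked", basal=0.05, amplitude=1.0, hill=2.0,
                          peak_mM=p, log_width=1.5),
        DoseResponseCurve("HXK1", "peaked", basal=0.08, amplitude=0.8, hill=1.5,
                          peak_mM=p, log_width=1.8),
        DoseResponseCurve("HXK2", "peaked", basal=0.10, amplitude=0.9, hill=1.8,
                          peak_mM=p, log_width=1.6),
        DoseResponseCurve("PDC1", "monotone_increasing", basal=0.20, amplitude=1.0,
                          hill=1.5, half_point_mM=1.0),
        DoseResponseCurve("SDH2", "monotone_decreasing", basal=0.10, amplitude=0.8,
                          hill=1.5, half_point_mM=1.0),
        # MIG1 response is a nuclear-localisation probability, hence in [0, 1]
        DoseResponseCurve("MIG1", "monotone_increasing", basal=0.02, amplitude=0.93,
                          hill=4.0, half_point_mM=0.2),
    ]
    return {c.reporter_name: c for c in curves}
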