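"""Physical model of a glucose-fed yeast monolayer in a dead-end chamber.

A monolayer colony occupies a shallow chamber of length L that is open to the
nutrient channel at y = 0 and closed at y = L.  Glucose is held at C0 at the
colony front, diffuses into the cell-packed region with coefficient D and is
taken up by the cells, so a steady concentration gradient forms:

    D C''(y) = q(C),   C(front) = C0,   C'(L) = 0,   C >= 0,

with q either zero-order (constant q_max wherever glucose is present) or
Monod, q(C) = q_max C / (k_q + C).  Cells grow at a Monod rate
mu(C) = mu_max C / (k_mu + C); growth deeper in the chamber pushes everything
above it toward the opening, so the local speed is the cumulative growth

    v(y) = integral_y^L mu(C(z)) dz,

and the colony front advances at v(front).  Chamber filling is simulated
quasi-statically: the gradient re-equilibrates much faster than cells divide
(diffusion time L^2/D ~ 2 h versus 90 min doublings), so at every time step
the steady gradient is re-solved on the occupied region and the front moved
by v(front) dt.

Coordinates: y = 0 at the chamber opening, increasing to y = L at the dead
end; positions in um, concentrations in mM, times in hours.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .units import SECONDS_PER_HOUR

__all__ = [
    "ChamberGeometry",
    "UptakeKinetics",
    "GrowthKinetics",
    "GlucoseProfile",
    "VelocityProfile",
    "FrontTrajectory",
    "MonolayerModel",
    "SolverError",
    "StabilityError",
    "penetration_scale",
    "solve_steady_gradient",
    "velocity_field",
    "simulate_filling",
    "saturating_front_velocity",
    "layers_from_front_velocity",
]


class SolverError(RuntimeError):
    """Steady-gradient iteration failed to converge; carries the residual."""

    def __init__(self, message: str, residual_mM: float):
        super().__init__(f"{message} (residual {residual_mM:.3e} mM)")
        self.residual_mM = residual_mM


class StabilityError(RuntimeError):
    """Quasi-static time step too large for the chosen grid."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChamberGeometry:
    """Dead-end chamber dimensions (um). Default is the 800 x 50 x 4.5 device."""

    length_um: float = 800.0
    width_um: float = 50.0
    height_um: float = 4.5
    cell_diameter_um: float = 4.0

    def __post_init__(self) -> None:
        for name in ("length_um", "width_um", "height_um", "cell_diameter_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.length_um < self.cell_diameter_um:
            raise ValueError("chamber must be at least one cell long")

    @property
    def capacity_cells(self) -> int:
        """Monolayer capacity: chamber area over the footprint of one cell."""
        return round(self.length_um * self.width_um / self.cell_diameter_um**2)

    def to_dict(self) -> dict:
        return {
            "length_um": self.length_um,
            "width_um": self.width_um,
            "height_um": self.height_um,
            "cell_diameter_um": self.cell_diameter_um,
        }


@dataclass(frozen=True)
class UptakeKinetics:
    """Volumetric glucose uptake of the packed monolayer.

    q_max is in mM/s per unit colony volume; with Monod kinetics the rate is
    q_max C/(k_q + C), in zero_order mode it is q_max wherever C > 0.
    """

    q_max: float = 0.11
    k_q: float = 1.0
    mode: Literal["zero_order", "monod"] = "monod"

    def __post_init__(self) -> None:
        if self.q_max < 0:
            raise ValueError("q_max must be non-negative")
        if self.mode == "monod" and self.k_q <= 0:
            raise ValueError("k_q must be positive for monod uptake")
        if self.mode not in ("zero_order", "monod"):
            raise ValueError(f"unknown uptake mode {self.mode!r}")

    def rate_mM_per_s(self, c_mM: np.ndarray) -> np.ndarray:
        c = np.asarray(c_mM, dtype=float)
        if self.mode == "zero_order":
            # regularised indicator: full rate above 1e-6 mM, linear ramp to
            # zero below, so the rate vanishes with C (keeps the solver's
            # fixed point stable and the flux balance exact)
            return self.q_max * np.clip(c / 1e-6, 0.0, 1.0)
        return self.q_max * c / (self.k_q + c)

    def to_dict(self) -> dict:
        return {"q_max": self.q_max, "k_q": self.k_q, "mode": self.mode}


@dataclass(frozen=True)
class GrowthKinetics:
    """Monod growth: mu(C) = mu_max C/(k_mu + C), mu_max = ln2 / doubling time."""

    mu_max: float = math.log(2) / 1.5
    k_mu: float = 0.5

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        if self.k_mu < 0:
            raise ValueError("k_mu must be non-negative")

    @classmethod
    def from_doubling_time(cls, doubling_time_min: float, k_mu: float = 0.5) -> "GrowthKinetics":
        if doubling_time_min <= 0:
            raise ValueError("doubling time must be positive")
        return cls(mu_max=math.log(2) / (doubling_time_min / 60.0), k_mu=k_mu)

    @property
    def doubling_time_min(self) -> float:
        return math.log(2) / self.mu_max * 60.0

    def rate_per_h(self, c_mM: np.ndarray) -> np.ndarray:
        c = np.asarray(c_mM, dtype=float)
        if self.k_mu == 0:
            return np.where(c > 0, self.mu_max, 0.0)
        return self.mu_max * c / (self.k_mu + c)

    def to_dict(self) -> dict:
        return {"mu_max": self.mu_max, "k_mu": self.k_mu,
                "doubling_time_min": self.doubling_time_min}


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class GlucoseProfile:
    """Steady glucose concentration versus depth on the occupied region.

    ``diffusive_influx`` and ``total_uptake`` (both mM.um/s) are the boundary
    flux at the front and the integrated uptake; at steady state they balance.
    """

    positions_um: np.ndarray
    concentrations_mM: np.ndarray
    c0_mM: float
    diffusion_um2_per_s: float = 100.0
    diffusive_influx: float | None = None
    total_uptake: float | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.concentrations_mM = np.asarray(self.concentrations_mM, dtype=float)
        if self.positions_um.ndim != 1 or self.positions_um.shape != self.concentrations_mM.shape:
            raise ValueError("positions and concentrations must be matching 1-D arrays")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.concentrations_mM < -1e-9):
            raise ValueError("concentrations must be non-negative")

    def interpolate(self, positions_um: np.ndarray) -> np.ndarray:
        return np.interp(positions_um, self.positions_um, self.concentrations_mM)

    def stall_depth_um(self, threshold_mM: float = 1e-6) -> float:
        """Depth of the first grid point where C drops below *threshold_mM*.

        Returns the last grid position if glucose never falls below threshold.
        """
        below = self.concentrations_mM < threshold_mM
        if not below.any():
            return float(self.positions_um[-1])
        return float(self.positions_um[np.argmax(below)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_um": self.positions_um,
                             "value": self.concentrations_mM})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, c0_mM: float | None = None) -> "GlucoseProfile":
        df = pd.read_csv(path, comment="#")
        c = df["value"].to_numpy()
        return cls(df["position_um"].to_numpy(), c,
                   c0_mM=float(c[0]) if c0_mM is None else c0_mM)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.positions_um, self.concentrations_mM)
        ax.set_xlabel("depth (um)")
        ax.set_ylabel("glucose (mM)")
        return ax


@dataclass
class VelocityProfile:
    """Depth-resolved local cell speed toward the opening (um/h)."""

    positions_um: np.ndarray
    speeds_um_per_h: np.ndarray
    spread_um_per_h: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.speeds_um_per_h = np.asarray(self.speeds_um_per_h, dtype=float)
        if self.positions_um.shape != self.speeds_um_per_h.shape:
            raise ValueError("positions and speeds must match")
        finite = np.isfinite(self.speeds_um_per_h)
        if np.any(self.speeds_um_per_h[finite] < -1e-9):
            raise ValueError("speeds must be non-negative")

    def interpolate(self, positions_um: np.ndarray) -> np.ndarray:
        return np.interp(positions_um, self.positions_um, self.speeds_um_per_h)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_um": self.positions_um,
                             "value": self.speeds_um_per_h})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class FrontTrajectory:
    """Front position over time; velocities are rates of front advance (um/h)."""

    times_h: np.ndarray
    front_positions_um: np.ndarray
    front_velocities_um_per_h: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.front_positions_um = np.asarray(self.front_positions_um, dtype=float)
        self.front_velocities_um_per_h = np.asarray(self.front_velocities_um_per_h, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")

    def terminal_velocity_um_per_h(self, tail_fraction: float = 0.1) -> float:
        """Plateau reading: mean over the trailing *tail_fraction* of samples."""
        v = self.front_velocities_um_per_h[np.isfinite(self.front_velocities_um_per_h)]
        if v.size == 0:
            return float("nan")
        n_tail = max(1, int(round(tail_fraction * v.size)))
        return float(np.mean(v[-n_tail:]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times_h,
            "front_um": self.front_positions_um,
            "velocity_um_per_h": self.front_velocities_um_per_h,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrontTrajectory":
        df = pd.read_csv(path, comment="#")
        return cls(df["time_h"].to_numpy(), df["front_um"].to_numpy(),
                   df["velocity_um_per_h"].to_numpy())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def penetration_scale(diffusion_um2_per_s: float, c0_mM: float,
                      q0_mM_per_s: float) -> float:
    """Order-of-magnitude glucose penetration depth, sqrt(D C0 / q0), in um.

    This is the dimensional-analysis estimate (no factor of 2); the exact
    zero-order stall depth of the solver is sqrt(2 D C0 / q0).
    """
    if diffusion_um2_per_s <= 0:
        raise ValueError("diffusion coefficient must be positive")
    if c0_mM < 0:
        raise ValueError("concentration must be non-negative")
    if q0_mM_per_s <= 0:
        raise ValueError("uptake rate must be positive (zero uptake gives "
                         "infinite penetration)")
    return math.sqrt(diffusion_um2_per_s * c0_mM / q0_mM_per_s)


def saturating_front_velocity(mu_per_h: float, length_um: float) -> float:
    """Front velocity when every cell in the chamber grows: V_F = mu L (um/h)."""
    if mu_per_h < 0 or length_um < 0:
        raise ValueError("growth rate and length must be non-negative")
    return mu_per_h * length_um


def layers_from_front_velocity(front_velocity_um_per_h: float,
                               per_layer_rate_um_per_h: float = 2.6) -> int:
    """Number of growing cell layers accounting for an observed front velocity.

    Each dividing layer contributes one cell diameter per doubling time
    (4 um / 90 min = 2.6 um/h by default), so e.g. 94 um/h ~ 36 layers.
    """
    if per_layer_rate_um_per_h <= 0:
        raise ValueError("per-layer expansion rate must be positive")
    if front_velocity_um_per_h < 0:
        raise ValueError("front velocity must be non-negative")
    return round(front_velocity_um_per_h / per_layer_rate_um_per_h)


def solve_steady_gradient(
    geometry: ChamberGeometry,
    uptake: UptakeKinetics,
    growth_region_start_um: float,
    c0_mM: float,
    diffusion_um2_per_s: float = 100.0,
    grid_points: int = 200,
    tol_mM: float = 1e-8,
    max_iter: int = 100_000,
    damping: float = 0.8,
    initial_guess: np.ndarray | None = None,
) -> GlucoseProfile:
    """Solve D C'' = q(C) on [front, L] with C(front)=C0 and zero flux at L.

    Second-order central differences with the nonlinear uptake handled by a
    damped Picard iteration: each sweep solves the tridiagonal system with the
    uptake linearised as q(C_old)/C_old * C, which keeps the operator an
    M-matrix and the iterate non-negative.  Converged when the max update is
    below *tol_mM*.
    """
    if grid_points < 16:
        raise ValueError("grid_points must be at least 16")
    L = geometry.length_um
    front = growth_region_start_um
    if not (0 <= front <= L):
        raise ValueError(f"front position {front} outside [0, {L}]")
    if c0_mM < 0:
        raise ValueError("c0 must be non-negative")

    y = np.linspace(front, L, grid_points)
    if c0_mM == 0 or uptake.q_max == 0 or front == L:
        c = np.full(grid_points, c0_mM)
        prof = GlucoseProfile(y, c, c0_mM, diffusion_um2_per_s,
                              diffusive_influx=0.0, total_uptake=0.0)
        return prof

    h = y[1] - y[0]
    D = diffusion_um2_per_s
    eps = 1e-12  # mM floor in the Picard linearisation

    c = np.full(grid_points, float(c0_mM)) if initial_guess is None \
        else np.clip(np.asarray(initial_guess, dtype=float), 0.0, None)
    c[0] = c0_mM

    n = grid_points
    residual = np.inf
    for _ in range(max_iter):
        r = uptake.rate_mM_per_s(c) / np.maximum(c, eps)  # effective 1st-order rate, 1/s
        # banded system for nodes 1..n-1 (node 0 is Dirichlet)
        m = n - 1
        diag = -2.0 * D / h**2 - r[1:]
        lower = np.full(m, D / h**2)
        upper = np.full(m, D / h**2)
        rhs = np.zeros(m)
        rhs[0] -= (D / h**2) * c0_mM
        # zero-flux at L via mirrored ghost node: C[n] = C[n-2]
        lower[-1] = 2.0 * D / h**2
        ab = np.zeros((3, m))
        ab[0, 1:] = upper[:-1]
        ab[1, :] = diag
        ab[2, :-1] = lower[1:]
        c_new = np.empty(n)
        c_new[0] = c0_mM
        c_new[1:] = solve_banded((1, 1), ab, rhs)
        c_new = np.clip(c_new, 0.0, None)
        c_next = (1.0 - damping) * c + damping * c_new
        residual = float(np.max(np.abs(c_next - c)))
        c = c_next
        if residual < tol_mM:
            break
    else:
        raise SolverError("steady-gradient iteration did not converge", residual)

    # boundary flux (2nd-order one-sided) and integrated uptake, mM.um/s
    influx = -D * (-3 * c[0] + 4 * c[1] - c[2]) / (2 * h)
    total_uptake = float(np.trapezoid(uptake.rate_mM_per_s(c), y))
    return GlucoseProfile(y, c, c0_mM, diffusion_um2_per_s,
                          diffusive_influx=float(influx), total_uptake=total_uptake)


def zero_order_closed_form(y_um: np.ndarray, c0_mM: float, q0_mM_per_s: float,
                           diffusion_um2_per_s: float,
                           front_um: float = 0.0) -> np.ndarray:
    """Exact zero-order-uptake profile: truncated parabola with stall depth
    H = sqrt(2 D C0 / q0) measured from the front."""
    yy = np.asarray(y_um, dtype=float) - front_um
    H = math.sqrt(2.0 * diffusion_um2_per_s * c0_mM / q0_mM_per_s)
    c = c0_mM - (q0_mM_per_s / diffusion_um2_per_s) * (H * yy - yy**2 / 2.0)
    c[yy >= H] = 0.0
    return np.clip(c, 0.0, None)


def velocity_field(profile: GlucoseProfile, growth: GrowthKinetics,
                   growth_cap: float = 1.0) -> VelocityProfile:
    """Local cell speed from cumulative downstream growth.

    v(y) = growth_cap * integral_y^L mu(C(z)) dz, trapezoid rule on the
    profile grid.  *growth_cap* in (0, 1] scales growth uniformly to mimic
    media where another nutrient (e.g. amino acids) co-limits growth.
    """
    if not (0 < growth_cap <= 1):
        raise ValueError("growth_cap must be in (0, 1]")
    y = profile.positions_um
    mu = growth.rate_per_h(profile.concentrations_mM) * growth_cap  # 1/h
    # reverse cumulative trapezoid: v[i] = int_{y_i}^{L} mu dz
    seg = 0.5 * (mu[1:] + mu[:-1]) * np.diff(y)
    v = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    return VelocityProfile(y, v)


def simulate_filling(
    geometry: ChamberGeometry,
    uptake: UptakeKinetics,
    growth: GrowthKinetics,
    c0_mM: float,
    diffusion_um2_per_s: float = 100.0,
    t_end_h: float = 24.0,
    dt_h: float = 0.05,
    grid_points: int = 200,
    growth_cap: float = 1.0,
) -> FrontTrajectory:
    """Quasi-static chamber filling from a seed layer at the dead end.

    At each step the steady gradient is solved on the occupied region
    [front, L], the front advances by v(front) dt, and the run stops when the
    front reaches the opening or t_end_h elapses.  Raises StabilityError if
    the front would jump more than two grid cells in one step.
    """
    L = geometry.length_um
    cell_h = L / (grid_points - 1)
    front = L - geometry.cell_diameter_um  # one seed layer of cells
    times = [0.0]
    fronts = [front]
    velocities = []
    guess = None
    t = 0.0
    while t < t_end_h and front > 0:
        prof = solve_steady_gradient(geometry, uptake, front, c0_mM,
                                     diffusion_um2_per_s, grid_points,
                                     initial_guess=guess)
        guess = prof.concentrations_mM
        vfield = velocity_field(prof, growth, growth_cap)
        v_front = float(vfield.speeds_um_per_h[0])
        step = v_front * dt_h
        if step > 2.0 * cell_h:
            raise StabilityError(
                f"front moved {step:.2f} um in one step (> 2 grid cells of "
                f"{cell_h:.2f} um); reduce dt_h")
        front = max(front - step, 0.0)
        t += dt_h
        times.append(t)
        fronts.append(front)
        velocities.append(v_front)
        if v_front == 0.0 and c0_mM == 0:
            break
    velocities.append(velocities[-1] if velocities else 0.0)
    return FrontTrajectory(np.array(times), np.array(fronts), np.array(velocities))


# ---------------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------------

class MonolayerModel:
    """Diffusion-uptake-growth model of one chamber at one external glucose level.

    Bundles geometry, uptake and growth kinetics with the boundary
    concentration; `solve_gradient`, `velocity_profile` and `simulate_filling`
    return the corresponding result objects.

    Examples
    --------
    >>> m = MonolayerModel(c0_mM=111.0)
    >>> prof = m.solve_gradient()
    >>> round(prof.concentrations_mM[0], 1)
    111.0
    """

    def __init__(self, geometry: ChamberGeometry | None = None,
                 uptake: UptakeKinetics | None = None,
                 growth: GrowthKinetics | None = None,
                 c0_mM: float = 111.0,
                 diffusion_um2_per_s: float = 100.0,
                 growth_cap: float = 1.0):
        self.geometry = geometry or ChamberGeometry()
        self.uptake = uptake or UptakeKinetics()
        self.growth = growth or GrowthKinetics()
        self.c0_mM = c0_mM
        self.diffusion_um2_per_s = diffusion_um2_per_s
        self.growth_cap = growth_cap

    def penetration_scale_um(self) -> float:
        return penetration_scale(self.diffusion_um2_per_s, self.c0_mM,
                                 self.uptake.q_max)

    def solve_gradient(self, front_um: float = 0.0,
                       grid_points: int = 200) -> GlucoseProfile:
        return solve_steady_gradient(self.geometry, self.uptake, front_um,
                                     self.c0_mM, self.diffusion_um2_per_s,
                                     grid_points)

    def velocity_profile(self, profile: GlucoseProfile | None = None,
                         grid_points: int = 200) -> VelocityProfile:
        if profile is None:
            profile = self.solve_gradient(grid_points=grid_points)
        return velocity_field(profile, self.growth, self.growth_cap)

    def simulate_filling(self, t_end_h: float = 24.0, dt_h: float = 0.05,
                         grid_points: int = 200) -> FrontTrajectory:
        return simulate_filling(self.geometry, self.uptake, self.growth,
                                self.c0_mM, self.diffusion_um2_per_s,
                                t_end_h, dt_h, grid_points, self.growth_cap)

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "uptake": self.uptake.to_dict(),
            "growth": self.growth.to_dict(),
            "c0_mM": self.c0_mM,
            "diffusion_um2_per_s": self.diffusion_um2_per_s,
            "growth_cap": self.growth_cap,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = ["Monolayer diffusion-uptake-growth model",
                 "---------------------------------------"]
        lines.append(json.dumps(d, indent=2))
        lines.append(f"penetration scale sqrt(D C0/q0): "
                     f"{self.penetration_scale_um():.1f} um")
        lines.append(f"saturating front velocity mu_max*L: "
                     f"{saturating_front_velocity(self.growth.mu_max, self.geometry.length_um):.1f} um/h")
        return "\n".join(lines)
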