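"""Image- and track-level measurements on monolayer time-lapse data.

The colony front and its velocity are read from low-magnification stacks by
background flattening (band-pass in Fourier space), Otsu thresholding and a
row-occupancy criterion; cellular motion deep in the chamber is summarised by
the per-pixel temporal standard deviation of the stack; local velocities come
from binning single-cell track steps by depth; the MIG1 nuclear/cytoplasmic
switch is summarised as a per-depth-bin nuclear fraction.

The depth axis must be declared by the caller (rows-increasing = deeper is
the default); there is no auto-detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu as _sk_threshold_otsu

from .model import FrontTrajectory, VelocityProfile

__all__ = [
    "ImageStack",
    "TrackSet",
    "MotionMap",
    "DegenerateImageError",
    "fft_bandpass",
    "otsu_threshold",
    "detect_front",
    "bin_front_velocities",
    "motion_map",
    "bin_track_velocities",
    "track_cells",
    "nuclear_fraction_profile",
]


class DegenerateImageError(ValueError):
    """Image carries no contrast to threshold."""


@dataclass
class ImageStack:
    """Time-lapse grayscale stack: frames indexed (time, row, col).

    Rows map to chamber depth (row 0 = chamber opening) unless stated
    otherwise by the caller of the extraction functions.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_min: float = 6.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (time, rows, cols) array with >= 1 frame")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def depth_positions_um(self) -> np.ndarray:
        return (np.arange(self.frames.shape[1]) + 0.5) * self.pixel_size_um

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min / 60.0

    def to_tiff(self, path) -> None:
        data = self.frames
        if data.dtype != np.uint16:
            top = float(data.max()) or 1.0
            data = np.clip(data / top * 65535, 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack", metadata={
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_min": self.frame_interval_min})

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float,
                  frame_interval_min: float = 6.0) -> "ImageStack":
        return cls(tifffile.imread(path).astype(float), pixel_size_um,
                   frame_interval_min)


@dataclass
class TrackSet:
    """Cell trajectories as a long table (track_id, frame, t_h, x_um, y_um)."""

    table: pd.DataFrame

    REQUIRED = ("track_id", "frame", "t_h", "x_um", "y_um")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        for _, grp in self.table.groupby("track_id"):
            if np.any(np.diff(grp["frame"].to_numpy()) <= 0):
                raise ValueError("frames must be strictly increasing within a track")

    def __len__(self) -> int:
        return self.table["track_id"].nunique()

    def tracks(self):
        for tid, grp in self.table.groupby("track_id"):
            yield tid, grp.sort_values("frame")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrackSet":
        return cls(pd.read_csv(path, comment="#"))


@dataclass
class MotionMap:
    """Temporal-std motion summary of a stack."""

    std_image: np.ndarray
    positions_um: np.ndarray
    profile: np.ndarray
    penetration_depth_um: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_um": self.positions_um, "value": self.profile})


# ---------------------------------------------------------------------------
# filtering and thresholding
# ---------------------------------------------------------------------------

def fft_bandpass(image: np.ndarray, large_structure_px: float = 40,
                 small_structure_px: float = 5) -> np.ndarray:
    """Band-pass an image in Fourier space to flatten shading and smooth noise.

    Structures larger than *large_structure_px* (slow background) and smaller
    than *small_structure_px* (pixel noise) are suppressed with a
    fourth-order super-Gaussian rolloff; the rolloff order keeps the passband
    flat so in-band content survives nearly unchanged and the filter is close
    to idempotent.  The DC component (image mean) is retained, so a constant
    image maps to itself.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("fft_bandpass expects a single 2-D image")
    if not (large_structure_px > small_structure_px > 0):
        raise ValueError("need large_structure_px > small_structure_px > 0")
    fy = np.fft.fftfreq(img.shape[0])[:, None]
    fx = np.fft.fftfreq(img.shape[1])[None, :]
    f = np.hypot(fy, fx)
    with np.errstate(over="ignore"):
        transfer = ((1.0 - np.exp(-((f * large_structure_px) ** 4)))
                    * np.exp(-((f * small_structure_px) ** 4)))
    transfer[0, 0] = 1.0  # keep the mean
    return np.real(np.fft.ifft2(np.fft.fft2(img) * transfer))


def otsu_threshold(image: np.ndarray) -> float:
    """Between-class-variance-maximising threshold on a 256-bin histogram."""
    img = np.asarray(image, dtype=float)
    if img.size == 0 or float(img.min()) == float(img.max()):
        raise DegenerateImageError("constant image has no Otsu threshold")
    return float(_sk_threshold_otsu(img, nbins=256))


# ---------------------------------------------------------------------------
# front detection
# ---------------------------------------------------------------------------

def detect_front(stack: ImageStack,
                 large_structure_px: float = 40,
                 small_structure_px: float = 5,
                 occupancy_fraction: float = 0.5) -> FrontTrajectory:
    """Per-frame colony front position and its advance velocity.

    Each frame is band-passed, thresholded (Otsu) and the binary mask closed
    (3x3) to bridge the gaps between cell-texture lobes; the front is the
    shallowest depth row whose foreground occupancy across the chamber width
    exceeds *occupancy_fraction*.  Velocities are centred finite differences
    of front position over time (forward/backward at the ends), clipped at
    zero since the front only advances.  Frames without foreground yield NaN.
    """
    from scipy.ndimage import binary_closing

    fronts = np.full(stack.n_frames, np.nan)
    for i in range(stack.n_frames):
        frame = stack.frames[i].astype(float)
        try:
            bp = fft_bandpass(frame, large_structure_px, small_structure_px)
            thr = otsu_threshold(bp)
        except DegenerateImageError:
            continue
        mask = binary_closing(bp > thr, structure=np.ones((3, 3)))
        occupancy = mask.mean(axis=1)
        rows = np.nonzero(occupancy > occupancy_fraction)[0]
        if rows.size:
            fronts[i] = stack.depth_positions_um[rows.min()]
    if np.all(np.isnan(fronts)):
        warnings.warn("no foreground detected in any frame", stacklevel=2)
    times = stack.times_h
    velocities = np.full_like(fronts, np.nan)
    valid = np.isfinite(fronts)
    if valid.sum() >= 2:
        grad = np.gradient(fronts, times)  # um/h, NaN propagates locally
        velocities = np.clip(-grad, 0.0, None)
    return FrontTrajectory(times, fronts, velocities)


def bin_front_velocities(trajectories, n_bins: int = 10,
                         length_um: float = 800.0) -> pd.DataFrame:
    """Pool (front position, velocity) samples and bin them over [0, L].

    Returns a frame with bin centres, per-bin mean and standard deviation and
    sample count; empty bins carry NaN.
    """
    if isinstance(trajectories, FrontTrajectory):
        trajectories = [trajectories]
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    pos = np.concatenate([t.front_positions_um for t in trajectories])
    vel = np.concatenate([t.front_velocities_um_per_h for t in trajectories])
    ok = np.isfinite(pos) & np.isfinite(vel)
    return _bin_samples(pos[ok], vel[ok], n_bins, length_um)


def _bin_samples(positions: np.ndarray, values: np.ndarray, n_bins: int,
                 length_um: float) -> pd.DataFrame:
    edges = np.linspace(0.0, length_um, n_bins + 1)
    idx = np.clip(np.digitize(positions, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    std = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        count[b] = int(sel.sum())
        if count[b]:
            mean[b] = values[sel].mean()
            std[b] = values[sel].std()
    return pd.DataFrame({
        "bin_center_um": 0.5 * (edges[:-1] + edges[1:]),
        "mean": mean, "std": std, "n": count,
    })


# ---------------------------------------------------------------------------
# motion map
# ---------------------------------------------------------------------------

def motion_map(stack: ImageStack, threshold_fraction: float = 0.1) -> MotionMap:
    """Per-pixel temporal standard deviation and the motion penetration depth.

    The depth profile is the row-mean of the std image; the penetration depth
    is the shallowest depth beyond which the profile stays below
    background + threshold_fraction * (max - background) for every deeper
    row, with background taken as the profile minimum.
    """
    if stack.n_frames < 3:
        raise ValueError("motion map needs at least 3 frames")
    std_image = stack.frames.astype(float).std(axis=0)
    profile = std_image.mean(axis=1)
    positions = stack.depth_positions_um
    background = float(profile.min())
    dynamic = float(profile.max()) - background
    if dynamic <= 1e-9 * max(1.0, float(np.abs(stack.frames).max())):
        return MotionMap(std_image, positions, profile, 0.0)
    thr = background + threshold_fraction * dynamic
    below = profile < thr
    # shallowest row such that every row from there on is below threshold
    above_idx = np.nonzero(~below)[0]
    if above_idx.size == 0:
        depth = 0.0
    elif above_idx[-1] == profile.size - 1:
        depth = float(positions[-1])
    else:
        depth = float(positions[above_idx[-1] + 1])
    return MotionMap(std_image, positions, profile, depth)


# ---------------------------------------------------------------------------
# track velocities
# ---------------------------------------------------------------------------

def bin_track_velocities(tracks: TrackSet, n_bins: int = 16,
                         length_um: float = 800.0) -> VelocityProfile:
    """Depth-binned local cell speeds from track steps.

    Each consecutive pair of track points contributes a speed along the depth
    axis, (y_i - y_{i+1}) / dt (positive toward the opening), assigned to the
    bin of the step midpoint.  Binned means are clipped at zero (the local
    speed is non-negative; negative means only arise from positional noise).
    """
    mids, speeds = [], []
    for _, grp in tracks.tracks():
        y = grp["y_um"].to_numpy()
        t = grp["t_h"].to_numpy()
        if y.size < 2:
            continue
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("track times must be strictly increasing")
        speeds.append((y[:-1] - y[1:]) / dt)
        mids.append(0.5 * (y[:-1] + y[1:]))
    if not mids:
        raise ValueError("no track with at least 2 points")
    df = _bin_samples(np.concatenate(mids), np.concatenate(speeds), n_bins, length_um)
    return VelocityProfile(df["bin_center_um"].to_numpy(),
                           np.clip(df["mean"].to_numpy(), 0.0, None),
                           spread_um_per_h=df["std"].to_numpy())


# ---------------------------------------------------------------------------
# cell tracking
# ---------------------------------------------------------------------------

def track_cells(stack: ImageStack, cell_diameter_um: float = 4.0,
                large_structure_px: float = 40,
                small_structure_px: float = 5,
                min_track_length: int = 2) -> TrackSet:
    """Detect and link cells across frames.

    Detection: local maxima of the band-passed frame above its Otsu
    threshold, separated by at least one cell radius.  Linking: greedy
    nearest neighbour between consecutive frames with a maximum step of two
    cell diameters; unmatched detections seed new tracks.  This deliberately
    simple linker assumes motion per frame is small against the cell
    spacing, which holds at the 6 min default frame interval.
    """
    from skimage.feature import peak_local_max

    min_dist_px = max(1, int(round(0.5 * cell_diameter_um / stack.pixel_size_um)))
    max_step_um = 2.0 * cell_diameter_um
    dt_h = stack.frame_interval_min / 60.0

    detections = []
    for i in range(stack.n_frames):
        bp = fft_bandpass(stack.frames[i].astype(float),
                          large_structure_px, small_structure_px)
        try:
            thr = otsu_threshold(bp)
        except DegenerateImageError:
            detections.append(np.empty((0, 2)))
            continue
        peaks = peak_local_max(bp, min_distance=min_dist_px, threshold_abs=thr)
        detections.append(peaks.astype(float) * stack.pixel_size_um)  # (y, x)

    rows = []
    next_id = 0
    active: dict[int, np.ndarray] = {}
    for frame_idx, dets in enumerate(detections):
        assigned: dict[int, int] = {}
        if active and dets.shape[0]:
            track_ids = list(active)
            prev = np.array([active[t] for t in track_ids])
            d2 = ((prev[:, None, :] - dets[None, :, :]) ** 2).sum(axis=2)
            order = np.argsort(d2, axis=None)
            used_tracks, used_dets = set(), set()
            for flat in order:
                ti, di = divmod(int(flat), dets.shape[0])
                if d2[ti, di] > max_step_um**2:
                    break
                if ti in used_tracks or di in used_dets:
                    continue
                used_tracks.add(ti)
                used_dets.add(di)
                assigned[di] = track_ids[ti]
        new_active = {}
        for di in range(dets.shape[0]):
            tid = assigned.get(di)
            if tid is None:
                tid = next_id
                next_id += 1
            new_active[tid] = dets[di]
            rows.append((tid, frame_idx, frame_idx * dt_h,
                         dets[di][1], dets[di][0]))
        active = new_active
    table = pd.DataFrame(rows, columns=["track_id", "frame", "t_h",
                                        "x_um", "y_um"])
    counts = table["track_id"].value_counts()
    keep = counts[counts >= min_track_length].index
    return TrackSet(table[table["track_id"].isin(keep)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# MIG1 nuclear fraction
# ---------------------------------------------------------------------------

def nuclear_fraction_profile(depths_um: np.ndarray, is_nuclear: np.ndarray,
                             bin_width_um: float = 25.0,
                             length_um: float = 800.0
                             ) -> tuple[pd.DataFrame, float | None]:
    """Per-depth-bin nuclear-localisation fraction and the 0.5 crossing.

    Returns the binned fractions (empty bins dropped) and the transition
    position where the fraction first crosses 0.5 going deeper, linearly
    interpolated between the adjacent bin centres; None (with a warning) when
    no crossing exists.
    """
    depths = np.asarray(depths_um, dtype=float)
    nuc = np.asarray(is_nuclear, dtype=bool)
    if depths.size == 0:
        raise ValueError("need at least one cell record")
    n_bins = int(np.ceil(length_um / bin_width_um))
    edges = np.arange(n_bins + 1) * bin_width_um
    idx = np.clip(np.digitize(depths, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            rows.append((0.5 * (edges[b] + edges[b + 1]), nuc[sel].mean(),
                         int(sel.sum())))
    frame = pd.DataFrame(rows, columns=["bin_center_um", "fraction_nuclear", "n"])
    centers = frame["bin_center_um"].to_numpy()
    frac = frame["fraction_nuclear"].to_numpy()
    transition = None
    for i in range(len(frac) - 1):
        if frac[i] >= 0.5 > frac[i + 1]:
            f0, f1 = frac[i], frac[i + 1]
            transition = float(centers[i] + (f0 - 0.5) / (f0 - f1)
                               * (centers[i + 1] - centers[i]))
            break
    if transition is None:
        warnings.warn("nuclear fraction never crosses 0.5 going deeper; "
                      "no transition position", stacklevel=2)
    return frame, transition
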