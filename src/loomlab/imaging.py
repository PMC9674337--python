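"""Calcium-imaging analysis: dF/F, ROI metrics, and the retinotopy test.

Wide-field calcium fluorescence of the LGMD dendritic fields (5 Hz frame
rate, 0.9 um/pixel) reports synaptic activation through calcium-permeable
nAChR channels. The analysis chain is: translational motion correction
(integer-pixel phase correlation against a baseline reference) and 3x3
median filtering; dF/F against a pre-stimulus baseline (constant mean or
extrapolated linear fit when the baseline drifts); ROI and subregion peak
metrics for loom and post-loom flash responses; and the retinotopy test --
the per-frame intensity-weighted center of mass (CoM) of dF/F within a
dendritic field, compared to the stimulus trajectory (Pearson correlation
per axis) and to a null ensemble obtained by randomly redistributing the
pixels within the field mask. A retinotopically organized field (field A)
yields CoM trajectories that track the stimulus and leave the shuffle null
band; a randomly mapped field (field C) does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.registration import phase_cross_correlation


@dataclass
class Timeline:
    """Stimulus event markers on the recording clock (seconds)."""

    stim_start: float
    stim_end: float                  # end of expansion
    flash_time: float | None = None


@dataclass
class FluorMovie:
    """Fluorescence image stack with acquisition metadata."""

    frames: np.ndarray               # (T, H, W) counts >= 0
    frame_rate: float = 5.0          # Hz
    pixel_size: float = 0.9          # um / pixel
    timeline: Timeline | None = None
    excluded_frames: np.ndarray | None = None   # registration failures

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) / self.frame_rate


@dataclass
class ROI:
    """Boolean mask plus a label (field A / field C / SIZ / subregion-k)."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


@dataclass
class CoMTrajectory:
    """Per-frame weighted-centroid path of dF/F within a field mask."""

    xy_um: np.ndarray                # (T, 2) of (x, y); NaN where undefined
    valid: np.ndarray                # frames with positive dF/F mass
    frame_indices: np.ndarray
    label: str = ""
    shuffled: bool = False

    def spread_um(self) -> float:
        """Largest per-axis range of the trajectory (um); 0 if degenerate."""
        pts = self.xy_um[self.valid]
        if pts.shape[0] < 2:
            return 0.0
        return float(np.max(pts.max(axis=0) - pts.min(axis=0)))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def register_translation(movie: FluorMovie,
                         reference: np.ndarray | None = None,
                         max_shift_fraction: float = 0.10,
                         ) -> tuple[FluorMovie, np.ndarray]:
    """Integer-pixel translational registration by phase correlation.

    Frames are aligned to ``reference`` (default: the temporal mean of the
    pre-stimulus baseline window, or of the whole movie without a
    timeline). Frames whose shift exceeds ``max_shift_fraction`` of the
    frame size are flagged and excluded. Returns the registered movie and
    the (T, 2) array of applied (row, col) shifts.
    """
    frames = movie.frames
    if frames.shape[0] < 2:
        raise ValueError("registration needs at least 2 frames")
    if reference is None:
        if movie.timeline is not None:
            n_base = max(1, int(movie.timeline.stim_start * movie.frame_rate))
            reference = frames[:n_base].mean(axis=0)
        else:
            reference = frames.mean(axis=0)
    shifts = np.zeros((frames.shape[0], 2), dtype=int)
    out = np.empty_like(frames)
    limit = max_shift_fraction * min(frames.shape[1], frames.shape[2])
    excluded = np.zeros(frames.shape[0], dtype=bool)
    for k in range(frames.shape[0]):
        shift, _, _ = phase_cross_correlation(reference, frames[k],
                                              upsample_factor=1)
        shift = np.round(shift).astype(int)
        if np.max(np.abs(shift)) > limit:
            excluded[k] = True
            out[k] = frames[k]
            continue
        shifts[k] = shift
        out[k] = np.roll(frames[k], tuple(shift), axis=(0, 1))
    if excluded.any():
        warnings.warn(f"{int(excluded.sum())} frames exceeded the "
                      "registration shift limit and were excluded",
                      stacklevel=2)
    reg = FluorMovie(out, movie.frame_rate, movie.pixel_size,
                     movie.timeline, excluded_frames=excluded)
    return reg, shifts


def preprocess_movie(movie: FluorMovie) -> FluorMovie:
    """Motion-correct then 3x3 median filter (the standard cleanup chain)."""
    reg, _ = register_translation(movie)
    filt = ndimage.median_filter(reg.frames, size=(1, 3, 3))
    return FluorMovie(filt, movie.frame_rate, movie.pixel_size,
                      movie.timeline, excluded_frames=reg.excluded_frames)


# ---------------------------------------------------------------------------
# dF/F
# ---------------------------------------------------------------------------

def compute_dff(movie: FluorMovie, baseline_window_s: float = 2.0,
                detrend: str = "constant") -> np.ndarray:
    """Per-pixel dF/F against the pre-stimulus baseline.

    ``detrend='constant'``: F0 is the per-pixel mean over the
    ``baseline_window_s`` seconds before stimulus onset and
    dF/F = (F - F0)/F0. ``detrend='linear'``: a per-pixel linear fit to the
    baseline is extrapolated over the whole recording and subtracted, and
    the fit's value at the start of the recording (the pre-drift level)
    normalizes -- for recordings whose baseline fluorescence drifts.
    Pixels with non-positive baseline are set to NaN and excluded from ROI
    means downstream.
    """
    if detrend not in ("constant", "linear"):
        raise ValueError("detrend must be 'constant' or 'linear'")
    t0 = movie.timeline.stim_start if movie.timeline else baseline_window_s
    n_base = int(round(min(baseline_window_s, t0) * movie.frame_rate))
    if n_base < 1 or t0 < 0:
        raise ValueError("baseline window not within the recording")
    f = movie.frames.astype(np.float64)
    tt = movie.times
    base = f[:n_base]
    f0_norm = base.mean(axis=0)
    if detrend == "constant":
        f0_t = np.broadcast_to(f0_norm, f.shape)
    else:
        if n_base < 2:
            raise ValueError("linear detrend needs >= 2 baseline frames")
        tb = tt[:n_base]
        slope, intercept = np.polyfit(tb, base.reshape(n_base, -1), 1)
        f0_t = (tt[:, None] * slope + intercept).reshape(f.shape)
        f0_norm = intercept.reshape(f.shape[1:])   # pre-drift level
    invalid = f0_norm <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (f - f0_t) / f0_norm
    dff[:, invalid] = np.nan
    return dff


# ---------------------------------------------------------------------------
# ROI metrics
# ---------------------------------------------------------------------------

def roi_trace(dff: np.ndarray, roi: ROI) -> np.ndarray:
    """Mean dF/F over the ROI per frame (NaN pixels excluded)."""
    sub = dff[:, roi.mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(sub, axis=1)


def roi_peak_metrics(dff: np.ndarray, roi: ROI, timeline: Timeline,
                     frame_rate: float = 5.0) -> dict:
    """Loom-window peak, its time, and the post-loom flash peak for an ROI.

    The looming response window runs from stimulus start until 1 s after
    the end of expansion. The flash peak is the maximum dF/F within 1.5 s
    after the flash minus the minimum in the 1 s before it.
    """
    trace = roi_trace(dff, roi)
    tt = np.arange(trace.size) / frame_rate
    loom = (tt >= timeline.stim_start) & (tt <= timeline.stim_end + 1.0)
    if not loom.any():
        raise ValueError("looming window lies outside the recording")
    loom_idx = np.flatnonzero(loom)
    k = loom_idx[np.nanargmax(trace[loom])]
    out = {"loom_peak": float(trace[k]), "loom_peak_time": float(tt[k]),
           "flash_peak": np.nan}
    if timeline.flash_time is not None:
        tf = timeline.flash_time
        post = (tt > tf) & (tt <= tf + 1.5)
        pre = (tt >= tf - 1.0) & (tt <= tf)
        if not post.any() or not pre.any():
            raise ValueError("flash window lies outside the recording")
        out["flash_peak"] = float(np.nanmax(trace[post])
                                  - np.nanmin(trace[pre]))
    return out


def peak_time_range(subregion_traces: list[np.ndarray], timeline: Timeline,
                    frame_rate: float = 5.0) -> float:
    """Range (max - min, s) of per-subregion loom-response peak times.

    Subregions whose trace has no finite value inside the loom window are
    excluded with a warning. A retinotopically swept field shows a large
    range; a synchronously activated field shows ~0.
    """
    if len(subregion_traces) < 2:
        raise ValueError("need at least 2 subregion traces")
    peak_times = []
    for i, trace in enumerate(subregion_traces):
        tt = np.arange(len(trace)) / frame_rate
        loom = (tt >= timeline.stim_start) & (tt <= timeline.stim_end + 1.0)
        vals = np.asarray(trace)[loom]
        if not np.isfinite(vals).any():
            warnings.warn(f"subregion {i} has no loom-window peak; excluded",
                          stacklevel=2)
            continue
        peak_times.append(tt[np.flatnonzero(loom)[np.nanargmax(vals)]])
    return float(np.max(peak_times) - np.min(peak_times))


# ---------------------------------------------------------------------------
# center-of-mass retinotopy test
# ---------------------------------------------------------------------------

def com_trajectory(dff: np.ndarray, mask: np.ndarray,
                   frame_window: tuple[int, int] | None = None,
                   pixel_size: float = 0.9, label: str = "") -> CoMTrajectory:
    """Intensity-weighted centroid of dF/F within a field mask, per frame.

    Negative dF/F is clipped to zero for weighting (centroids need
    non-negative mass); frames with zero total mass are skipped. Positions
    are (x, y) in um, with x along image columns and y along rows.
    """
    mask = np.asarray(mask, dtype=bool)
    t0, t1 = frame_window if frame_window is not None else (0, dff.shape[0])
    frames = np.arange(t0, t1)
    rr, cc = np.nonzero(mask)
    xy = np.full((frames.size, 2), np.nan)
    valid = np.zeros(frames.size, dtype=bool)
    for j, k in enumerate(frames):
        w = dff[k][mask]
        w = np.where(np.isfinite(w), np.clip(w, 0.0, None), 0.0)
        total = w.sum()
        if total <= 0:
            continue
        xy[j, 0] = (w * cc).sum() / total * pixel_size
        xy[j, 1] = (w * rr).sum() / total * pixel_size
        valid[j] = True
    if not valid.any():
        warnings.warn("all-zero dF/F window: empty CoM trajectory",
                      stacklevel=2)
    return CoMTrajectory(xy_um=xy, valid=valid, frame_indices=frames,
                         label=label)


def shuffle_null_trajectory(dff: np.ndarray, mask: np.ndarray,
                            n_shuffles: int = 100, seed: int = 0,
                            frame_window: tuple[int, int] | None = None,
                            pixel_size: float = 0.9) -> list[CoMTrajectory]:
    """CoM trajectories after random pixel redistribution within the mask.

    Each shuffle independently permutes the within-mask pixel values of
    every frame (preserving the per-frame mass exactly) and recomputes the
    trajectory, building the null ensemble for the retinotopy test.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)
    t0, t1 = frame_window if frame_window is not None else (0, dff.shape[0])
    vals = dff[t0:t1][:, mask]
    out = []
    for _ in range(n_shuffles):
        shuf = np.empty_like(vals)
        for j in range(vals.shape[0]):
            shuf[j] = rng.permutation(vals[j])
        stack = np.zeros((t1 - t0,) + mask.shape)
        stack[:, mask] = shuf
        traj = com_trajectory(stack, mask, pixel_size=pixel_size)
        traj.shuffled = True
        traj.frame_indices = np.arange(t0, t1)
        out.append(traj)
    return out


def outside_null_band(trajectory: CoMTrajectory,
                      null_ensemble: list[CoMTrajectory],
                      alpha: float = 0.05) -> bool:
    """Does the trajectory's spatial spread exceed the null (1-alpha) band?

    The test statistic is the largest per-axis range of the CoM path; the
    band edge is the (1-alpha) quantile of the statistic over the shuffled
    ensemble.
    """
    null_spread = np.array([t.spread_um() for t in null_ensemble])
    edge = np.quantile(null_spread, 1.0 - alpha)
    return trajectory.spread_um() > edge


@dataclass
class CorrelationResult:
    """Pearson r between CoM and stimulus position, one entry per axis."""

    r: np.ndarray
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(2, bool))


def position_correlation(trajectory: CoMTrajectory,
                         stimulus_positions: np.ndarray) -> CorrelationResult:
    """Pearson r between each CoM coordinate and the stimulus position.

    ``stimulus_positions`` is (T,) or (T, 2), sampled on the same frames as
    the trajectory. Degenerate axes (zero variance) report r = 0 with the
    ``degenerate`` flag set rather than raising mid-pipeline.
    """
    pos = np.asarray(stimulus_positions, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    valid = trajectory.valid & np.isfinite(pos).all(axis=1)
    if valid.sum() < 3:
        raise ValueError("need at least 3 common frames for correlation")
    r = np.zeros(trajectory.xy_um.shape[1])
    degen = np.zeros(r.size, dtype=bool)
    for ax in range(r.size):
        x = trajectory.xy_um[valid, ax]
        y = pos[valid, min(ax, pos.shape[1] - 1)]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            degen[ax] = True
            continue
        r[ax] = stats.pearsonr(x, y).statistic
    return CorrelationResult(r=r, degenerate=degen)
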