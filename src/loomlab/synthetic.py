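"""Synthetic data generators with known ground truth.

Every analysis stage in this package is tested against data produced here:
fluorescence movies that emulate the imaging conditions (5 Hz, 0.9 um/px,
two dendritic-field masks) with either a retinotopically sweeping
activation spot (the field A phenotype) or spatially uniform activation
(the field C phenotype), plus Gaussian pixel noise, optional linear
baseline drift and frame-wise translational "breathing" motion; paired
ON/OFF movies with a prescribed peak-response ratio; and synaptic event
trains with exact counts and loom-like temporal profiles. Each generator
returns its ground truth alongside the data, and is a pure function of
(spec, seed). The field geometry is a stylized crescent ("A") and blob
("C") -- no anatomical fidelity is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encode import SynapticEventTrain
from .imaging import FluorMovie, Timeline


@dataclass
class SyntheticMovieSpec:
    """Conditions for one synthetic fluorescence movie."""

    shape: tuple = (64, 80)          # (H, W) pixels
    n_frames: int = 50
    frame_rate: float = 5.0          # Hz
    pixel_size: float = 0.9          # um / px
    activation_mode: str = "retinotopic_sweep"   # or "uniform"
    amplitude: float = 0.5           # peak dF/F
    baseline: float = 1000.0         # counts
    noise_sigma: float = 0.0         # fraction of peak dF signal
    drift_slope: float = 0.0         # dF/F per s
    motion_amplitude: int = 0        # px
    texture_sigma: float = 0.15      # static dye-fill heterogeneity (frac.)
    spot_sigma_px: float = 4.0
    stim_start_s: float = 2.0
    stim_end_s: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def field_masks(shape: tuple = (64, 80)) -> dict[str, np.ndarray]:
    """Stylized dendritic-field masks: crescent 'A' and blob 'C', disjoint."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h * 0.55, w * 0.35
    r = np.hypot(yy - cy, xx - cx)
    crescent = (r > 0.28 * w) & (r < 0.42 * w) & (xx < cx + 0.1 * w)
    by, bx = h * 0.30, w * 0.75
    blob = ((yy - by) ** 2 / (0.14 * h) ** 2
            + (xx - bx) ** 2 / (0.11 * w) ** 2) < 1.0
    blob &= ~crescent
    return {"A": crescent, "C": blob}


def _sweep_path(mask: np.ndarray, n_active: int) -> np.ndarray:
    """Left-to-right path of (row, col) spot centers through a mask."""
    rr, cc = np.nonzero(mask)
    order = np.argsort(cc, kind="stable")
    idx = np.linspace(0, rr.size - 1, n_active).astype(int)
    return np.column_stack([rr[order][idx], cc[order][idx]]).astype(float)


def gen_field_movie(spec: SyntheticMovieSpec,
                    mask: np.ndarray | None = None
                    ) -> tuple[FluorMovie, dict]:
    """Synthesize one field's fluorescence movie plus its ground truth.

    retinotopic_sweep: a Gaussian activation spot traverses the field mask
    left to right during the stimulus window, in register with a linear
    stimulus-position track. uniform: the whole mask rises and falls with a
    single common time course. Gaussian pixel noise, linear baseline drift,
    and frame-wise integer translation are added afterwards per the spec.

    Returns (movie, ground_truth) where the ground truth holds the spot
    path (px), the stimulus-position track, per-frame activation
    amplitudes, the injected shifts, and the masks used.
    """
    mask = field_masks(spec.shape)["A"] if mask is None else np.asarray(mask,
                                                                        bool)
    if not mask.any():
        raise ValueError("field mask is empty")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    tt = np.arange(spec.n_frames) / spec.frame_rate
    active = (tt >= spec.stim_start_s) & (tt <= spec.stim_end_s)
    n_active = int(active.sum())
    peak_df = spec.amplitude * spec.baseline

    signal = np.zeros((spec.n_frames, h, w))
    truth: dict = {"mask": mask, "mode": spec.activation_mode,
                   "amplitude": spec.amplitude,
                   "stim_frames": np.flatnonzero(active)}
    if spec.activation_mode == "retinotopic_sweep":
        path = _sweep_path(mask, n_active)
        yy, xx = np.mgrid[0:h, 0:w]
        for j, k in enumerate(np.flatnonzero(active)):
            r0, c0 = path[j]
            spot = np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2)
                          / (2.0 * spec.spot_sigma_px ** 2))
            signal[k] = peak_df * spot * mask
        truth["spot_path_px"] = path
        truth["stimulus_positions"] = np.linspace(0.0, 1.0, n_active)
    elif spec.activation_mode == "uniform":
        course = np.sin(np.linspace(0.0, np.pi, n_active)) ** 2
        signal[active] = (peak_df * course)[:, None, None] * mask
        truth["time_course"] = course
    else:
        raise ValueError(f"unknown activation mode {spec.activation_mode!r}")

    # static multiplicative texture emulating uneven intracellular dye fill;
    # gives motion correction real spatial structure to lock onto
    texture = np.ones((h, w))
    if spec.texture_sigma:
        texture += np.clip(rng.normal(0.0, spec.texture_sigma, (h, w)),
                           -0.9, None)
    truth["texture"] = texture
    frames = (spec.baseline + signal) * texture
    if spec.drift_slope:
        frames = frames + (spec.drift_slope * spec.baseline
                           * tt)[:, None, None]
        truth["drift_slope"] = spec.drift_slope
    if spec.noise_sigma:
        frames = frames + rng.normal(0.0, spec.noise_sigma * peak_df,
                                     size=frames.shape)
    shifts = np.zeros((spec.n_frames, 2), dtype=int)
    if spec.motion_amplitude:
        shifts = rng.integers(-spec.motion_amplitude,
                              spec.motion_amplitude + 1,
                              size=(spec.n_frames, 2))
        for k in range(spec.n_frames):
            frames[k] = np.roll(frames[k], tuple(shifts[k]), axis=(0, 1))
    truth["shifts"] = shifts
    movie = FluorMovie(np.clip(frames, 0.0, None),
                       frame_rate=spec.frame_rate,
                       pixel_size=spec.pixel_size,
                       timeline=Timeline(stim_start=spec.stim_start_s,
                                         stim_end=spec.stim_end_s))
    return movie, truth


def gen_polarity_movies(spec: SyntheticMovieSpec, ratio_true: float,
                        mask: np.ndarray | None = None
                        ) -> tuple[FluorMovie, FluorMovie, dict]:
    """Paired ON-stim / OFF-stim movies with a prescribed peak-dF/F ratio.

    The ON movie's activation amplitude is ``ratio_true`` times the OFF
    movie's, so the noise-free ROI loom-peak ratio (ON/OFF) equals
    ``ratio_true`` exactly; used for pipeline parameter-recovery tests.
    """
    if ratio_true <= 0:
        raise ValueError("ratio_true must be > 0")
    base = spec if spec.activation_mode == "uniform" else \
        SyntheticMovieSpec(**{**spec.__dict__, "activation_mode": "uniform"})
    on_spec = SyntheticMovieSpec(**{**base.__dict__,
                                    "amplitude": base.amplitude * ratio_true,
                                    "seed": base.seed})
    off_spec = SyntheticMovieSpec(**{**base.__dict__,
                                     "seed": base.seed + 1})
    on_movie, on_truth = gen_field_movie(on_spec, mask)
    off_movie, off_truth = gen_field_movie(off_spec, mask)
    truth = {"ratio_true": ratio_true, "on": on_truth, "off": off_truth}
    return on_movie, off_movie, truth


def gen_reference_eventset(n_exc: int = 80_000, n_inh: int = 7_000,
                           duration: float = 2.5,
                           temporal_profile: str = "loom_like",
                           l_over_v_ms: float = 80.0,
                           t_start: float | None = None,
                           seed: int = 0) -> SynapticEventTrain:
    """Event train with exact counts; stands in for the encoder's output.

    ``loom_like`` draws event times from a density proportional to the
    looming angular-velocity profile theta_dot(t) = (l/|v|)/(t^2 +
    (l/|v|)^2), which ramps toward the projected collision at t = 0 (the
    window is [t_start, 0] with t_start = -duration by default);
    ``uniform`` draws times uniformly. Polarities are labeled OFF
    (excitatory, the black-loom pathway) and facet ids drawn uniformly
    from a 61x61 lattice.
    """
    if n_exc < 0 or n_inh < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    t0 = -duration if t_start is None else t_start
    t1 = t0 + duration

    def draw(n: int) -> np.ndarray:
        if temporal_profile == "uniform":
            return rng.uniform(t0, t1, size=n)
        if temporal_profile != "loom_like":
            raise ValueError(f"unknown profile {temporal_profile!r}")
        # inverse-CDF sampling of theta_dot(t) ~ a/(t^2+a^2) on [t0, t1]
        a = l_over_v_ms / 1000.0
        u = rng.uniform(size=n)
        lo, hi = np.arctan(t0 / a), np.arctan(t1 / a)
        return a * np.tan(lo + u * (hi - lo))

    n_facets = 61 * 61
    parts = []
    for n, class_ in ((n_exc, "excitatory"), (n_inh, "inhibitory")):
        if n == 0:
            continue
        parts.append(pd.DataFrame({
            "time_s": draw(n), "polarity": "OFF", "class": class_,
            "facet_id": rng.integers(0, n_facets, size=n),
            "source": "visual"}))
    if not parts:
        parts = [pd.DataFrame({"time_s": [], "polarity": [], "class": [],
                               "facet_id": [], "source": []})]
    return SynapticEventTrain(pd.concat(parts, ignore_index=True))
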