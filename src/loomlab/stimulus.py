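"""Looming / translating / flash stimuli and ommatidial sampling.

A looming stimulus simulates a square object of half-size l approaching the
eye at constant speed v < 0. Its half-angle on the retina grows as

    theta(t) = arctan( (l/|v|) / |t| ),   t < 0,

so the approach is fully characterized by the ratio l/|v| (in ms); theta
reaches 90 deg (a full angle of 180 deg) at the projected collision time
t = 0. Stimuli are rendered in eye-centered angular coordinates
(azimuth/elevation, degrees) on a pixel grid, in one of four contrast
classes: solid black on a light background, solid white on a dark
background, and checkered or concentric-square patterns on a 50% luminance
background.

Spatial-coherence manipulation proceeds in two steps, mirroring the
experimental design: the movie is first pixelated at the ~2.5 deg resolution
of photoreceptor receptive fields (replacing local edge motion by local
luminance change), then the coarse pixels are displaced by a random
distance-bounded permutation. Each coarse cell keeps its own luminance time
course, so the per-frame luminance histogram is conserved at every coherence
level; at 100% coherence the permutation is the identity and at 0% the
displacement is unrestricted.

Finally, movies are sampled at the eye's ~2 deg ommatidial resolution:
each facet reports a Gaussian-weighted average of luminance around its
receptive-field center, per frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import sparse


class Polarity(str, Enum):
    BLACK = "black"
    WHITE = "white"
    CHECKERED = "checkered"
    CONCENTRIC = "concentric"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LoomParams:
    """Kinematic and display parameters of one looming stimulus.

    ``l_over_v`` is in ms; ``t_start``/``t_end`` are in seconds relative to
    the projected collision at t = 0 (t_end > 0 holds the full-size square).
    """

    l_over_v: float = 80.0
    polarity: Polarity | str = Polarity.BLACK
    background_luminance: float | None = None
    coherence: float = 100.0
    coarse_pixel_deg: float = 2.5
    refresh_rate: float = 240.0
    t_start: float = -2.5
    t_end: float = 0.0
    extent_deg: float = 120.0
    pixel_pitch_deg: float = 1.0
    n_checks: int = 8
    n_rings: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.polarity = Polarity(self.polarity)
        if self.l_over_v <= 0:
            raise ValueError("l_over_v must be > 0")
        if not 0.0 <= self.coherence <= 100.0:
            raise ValueError("coherence must be in [0, 100]")
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.background_luminance is None:
            self.background_luminance = _default_background(self.polarity)


def _default_background(polarity: Polarity) -> float:
    if polarity is Polarity.BLACK:
        return 1.0
    if polarity is Polarity.WHITE:
        return 0.0
    return 0.5  # checkered / concentric squares sit on 50% luminance


@dataclass
class TranslatingParams:
    """A square of fixed angular size sweeping at constant angular speed."""

    size_deg: float = 10.0
    speed_deg_s: float = 20.0
    elevation_deg: float = 0.0
    polarity: Polarity | str = Polarity.BLACK
    background_luminance: float | None = None
    refresh_rate: float = 240.0
    t_start: float = 0.0
    t_end: float = 4.0
    extent_deg: float = 120.0
    pixel_pitch_deg: float = 1.0

    def __post_init__(self) -> None:
        self.polarity = Polarity(self.polarity)
        if self.background_luminance is None:
            self.background_luminance = _default_background(self.polarity)

    def position_deg(self, t: np.ndarray) -> np.ndarray:
        """Azimuth of the square center; sweep is centered on azimuth 0."""
        t = np.asarray(t, dtype=float)
        t_mid = 0.5 * (self.t_start + self.t_end)
        return (t - t_mid) * self.speed_deg_s


@dataclass
class FlashParams:
    """Abrupt luminance step back to background after a loom hold."""

    pre_luminance: float = 0.0
    post_luminance: float = 1.0
    t_step: float = 0.5
    duration: float = 1.0
    refresh_rate: float = 240.0
    extent_deg: float = 120.0
    pixel_pitch_deg: float = 1.0


@dataclass
class StimulusMovie:
    """Time-resolved luminance field in eye-centered angular coordinates."""

    frames: np.ndarray               # (T, H, W) luminance in [0, 1]
    frame_rate: float                # Hz
    pixel_pitch: float               # degrees / pixel
    t_start: float = 0.0             # time of first frame, s
    coarse_pixel_deg: float | None = None   # set once coarsened

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def angular_extent(self) -> tuple[float, float]:
        """(height, width) extent in degrees."""
        return (self.frames.shape[1] * self.pixel_pitch,
                self.frames.shape[2] * self.pixel_pitch)

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_frames) / self.frame_rate

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(elevation, azimuth) of pixel centers, degrees; (0,0) at center."""
        _, h, w = self.frames.shape
        el = (np.arange(h) - (h - 1) / 2.0) * self.pixel_pitch
        az = (np.arange(w) - (w - 1) / 2.0) * self.pixel_pitch
        return el, az


@dataclass
class FacetGrid:
    """Ommatidial sampling lattice: receptive-field centers and width."""

    facet_centers: np.ndarray        # (n, 2) of (azimuth, elevation), deg
    acceptance_hwhm: float = 2.0     # Gaussian half-width at half-max, deg

    def __post_init__(self) -> None:
        self.facet_centers = np.atleast_2d(
            np.asarray(self.facet_centers, dtype=float))
        if self.facet_centers.size == 0:
            raise ValueError("facet grid must contain at least one facet")

    @property
    def n_facets(self) -> int:
        return self.facet_centers.shape[0]

    @classmethod
    def regular(cls, extent_deg: float = 120.0, spacing_deg: float = 2.0,
                acceptance_hwhm: float = 2.0) -> "FacetGrid":
        """Square lattice at the eye's ~2 deg spacing, inside the extent."""
        half = extent_deg / 2.0 - spacing_deg / 2.0
        n = int(np.floor(2 * half / spacing_deg)) + 1
        coords = (np.arange(n) - (n - 1) / 2.0) * spacing_deg
        az, el = np.meshgrid(coords, coords)
        centers = np.column_stack([az.ravel(), el.ravel()])
        g = cls(centers, acceptance_hwhm)
        g.shape = (n, n)  # row-major (elevation, azimuth) lattice shape
        return g


@dataclass
class FacetLuminance:
    """Per-facet luminance time courses sampled from a movie."""

    traces: np.ndarray               # (n_facets, T) in [0, 1]
    frame_rate: float
    t_start: float = 0.0
    grid: FacetGrid | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.traces.shape[1]) / self.frame_rate


# ---------------------------------------------------------------------------
# loom kinematics
# ---------------------------------------------------------------------------

def loom_half_angle(t, l_over_v: float):
    """Half-angle theta(t) = arctan((l/|v|)/|t|) in degrees, for t < 0.

    ``t`` is seconds before projected collision (negative); ``l_over_v`` is
    in ms. Strictly increasing as t -> 0-, approaching 90 deg (a full angle
    of 180 deg) at collision.
    """
    if l_over_v <= 0:
        raise ValueError("l_over_v must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr >= 0):
        raise ValueError("collision reached: loom_half_angle requires t < 0")
    theta = np.degrees(np.arctan((l_over_v / 1000.0) / np.abs(t_arr)))
    return float(theta) if np.isscalar(t) else theta


def _half_angle_clamped(t: np.ndarray, l_over_v: float) -> np.ndarray:
    """Half-angle with the post-collision hold at 90 deg."""
    theta = np.full(t.shape, 90.0)
    pre = t < 0
    theta[pre] = np.degrees(np.arctan((l_over_v / 1000.0) / np.abs(t[pre])))
    return theta


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _interval_coverage(centers: np.ndarray, pitch: float,
                       half_width: float) -> np.ndarray:
    """Fraction of each pixel (1-D) covered by [-half_width, half_width]."""
    lo = centers - pitch / 2.0
    hi = centers + pitch / 2.0
    cov = (np.minimum(hi, half_width) - np.maximum(lo, -half_width)) / pitch
    return np.clip(cov, 0.0, 1.0)


def _pattern_frame(el: np.ndarray, az: np.ndarray, theta: float,
                   params: LoomParams) -> np.ndarray:
    """One rendered frame of the square at half-angle theta (degrees)."""
    pol = params.polarity
    bg = params.background_luminance
    h, w = el.size, az.size
    frame = np.full((h, w), bg, dtype=np.float64)
    if theta <= 0:
        return frame
    cov = np.outer(_interval_coverage(el, params.pixel_pitch_deg, theta),
                   _interval_coverage(az, params.pixel_pitch_deg, theta))
    if pol is Polarity.BLACK:
        obj = 0.0
        frame += cov * (obj - bg)
    elif pol is Polarity.WHITE:
        obj = 1.0
        frame += cov * (obj - bg)
    else:
        inside = cov > 0.5  # pattern drawn without subpixel AA
        if pol is Polarity.CHECKERED:
            # checkers scale with the square: n_checks per side
            step = 2.0 * theta / params.n_checks
            ci = np.floor((el[:, None] + theta) / step).astype(int)
            cj = np.floor((az[None, :] + theta) / step).astype(int)
            pattern = ((ci + cj) % 2).astype(float)
        else:  # concentric alternating square rings, OFF-center by default
            cheb = np.maximum(np.abs(el)[:, None], np.abs(az)[None, :])
            ring = np.floor(cheb / (theta / params.n_rings)).astype(int)
            ring = np.clip(ring, 0, params.n_rings - 1)
            pattern = (ring % 2).astype(float)
        frame[inside] = np.broadcast_to(pattern, (h, w))[inside]
    return frame


def render_stimulus(params) -> StimulusMovie:
    """Render a loom, translating square, or flash into a StimulusMovie."""
    if isinstance(params, LoomParams):
        return _render_loom(params)
    if isinstance(params, TranslatingParams):
        return _render_translating(params)
    if isinstance(params, FlashParams):
        return _render_flash(params)
    raise TypeError(f"unsupported stimulus spec: {type(params)!r}")


def _frame_times(t_start: float, t_end: float, rate: float) -> np.ndarray:
    n = int(round((t_end - t_start) * rate))
    return t_start + np.arange(n) / rate


def _render_loom(params: LoomParams) -> StimulusMovie:
    t = _frame_times(params.t_start, params.t_end, params.refresh_rate)
    theta = _half_angle_clamped(t, params.l_over_v)
    final_theta = theta[-1] if theta.size else 0.0
    if 2 * final_theta > params.extent_deg:
        warnings.warn("final stimulus exceeds screen extent; clipped",
                      stacklevel=2)
    h = w = int(round(params.extent_deg / params.pixel_pitch_deg))
    el = (np.arange(h) - (h - 1) / 2.0) * params.pixel_pitch_deg
    az = (np.arange(w) - (w - 1) / 2.0) * params.pixel_pitch_deg
    frames = np.empty((t.size, h, w), dtype=np.float32)
    for k in range(t.size):
        frames[k] = _pattern_frame(el, az, theta[k], params)
    return StimulusMovie(frames, params.refresh_rate,
                         params.pixel_pitch_deg, t_start=params.t_start)


def _render_translating(params: TranslatingParams) -> StimulusMovie:
    t = _frame_times(params.t_start, params.t_end, params.refresh_rate)
    h = w = int(round(params.extent_deg / params.pixel_pitch_deg))
    el = (np.arange(h) - (h - 1) / 2.0) * params.pixel_pitch_deg
    az = (np.arange(w) - (w - 1) / 2.0) * params.pixel_pitch_deg
    bg = params.background_luminance
    obj = 0.0 if params.polarity is Polarity.BLACK else 1.0
    half = params.size_deg / 2.0
    pos = params.position_deg(t)
    cov_el = _interval_coverage(el - params.elevation_deg,
                                params.pixel_pitch_deg, half)
    frames = np.empty((t.size, h, w), dtype=np.float32)
    for k in range(t.size):
        cov = np.outer(cov_el, _interval_coverage(
            az - pos[k], params.pixel_pitch_deg, half))
        frames[k] = bg + cov * (obj - bg)
    return StimulusMovie(frames, params.refresh_rate,
                         params.pixel_pitch_deg, t_start=params.t_start)


def _render_flash(params: FlashParams) -> StimulusMovie:
    t = _frame_times(0.0, params.duration, params.refresh_rate)
    h = w = int(round(params.extent_deg / params.pixel_pitch_deg))
    lum = np.where(t < params.t_step, params.pre_luminance,
                   params.post_luminance).astype(np.float32)
    frames = np.broadcast_to(lum[:, None, None], (t.size, h, w)).copy()
    return StimulusMovie(frames, params.refresh_rate,
                         params.pixel_pitch_deg, t_start=0.0)


# ---------------------------------------------------------------------------
# coarse pixelation and coherence scrambling
# ---------------------------------------------------------------------------

def _cell_index(n_pix: int, pitch: float, cell_deg: float) -> np.ndarray:
    """Coarse-cell index of each fine pixel along one axis."""
    edges = np.arange(n_pix) * pitch
    idx = np.floor(edges / cell_deg + 1e-9).astype(int)
    return idx


def coarsen_pixelate(movie: StimulusMovie,
                     pixel_deg: float = 2.5) -> StimulusMovie:
    """Replace each coarse cell's content by its mean luminance per frame.

    This removes local edge motion within a cell, leaving only the local
    luminance change, at the spatial resolution of photoreceptor receptive
    fields (default 2.5 deg). The coarse grid is aligned to the screen
    corner; border cells that are only partially covered are averaged over
    the covered area. The output stays on the fine pixel grid, so the
    frame-mean luminance is preserved exactly and the operation is
    idempotent at fixed ``pixel_deg``.
    """
    if pixel_deg < movie.pixel_pitch:
        raise ValueError("pixel_deg must be >= the movie's pixel pitch")
    t_, h, w = movie.frames.shape
    iy = _cell_index(h, movie.pixel_pitch, pixel_deg)
    ix = _cell_index(w, movie.pixel_pitch, pixel_deg)
    ny, nx = iy[-1] + 1, ix[-1] + 1
    flat_cell = (iy[:, None] * nx + ix[None, :]).ravel()
    counts = np.bincount(flat_cell, minlength=ny * nx).astype(np.float64)
    frames = movie.frames.reshape(t_, -1).astype(np.float64)
    sums = np.zeros((t_, ny * nx))
    np.add.at(sums.T, flat_cell, frames.T)
    means = sums / counts
    out = means[:, flat_cell].reshape(t_, h, w)  # float64: exact cell means
    return StimulusMovie(out, movie.frame_rate, movie.pixel_pitch,
                         t_start=movie.t_start, coarse_pixel_deg=pixel_deg)


def _bounded_permutation(centers: np.ndarray, r: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Random bijection of cells with every displacement <= r (degrees).

    Solved as a perfect matching with i.i.d. random costs inside the radius
    and prohibitive costs outside (the identity is always feasible, so a
    bound-respecting bijection exists). r = 0 returns the identity; a radius
    covering the whole grid yields an unrestricted random permutation.
    """
    from scipy.optimize import linear_sum_assignment

    n = centers.shape[0]
    if r <= 0:
        return np.arange(n)
    d2 = np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    if (d2 <= r * r).all():
        return rng.permutation(n)
    cost = rng.random((n, n))
    cost[d2 > r * r] = 1e9
    _, perm = linear_sum_assignment(cost)
    return perm


#: Exponent of the coherence -> displacement-radius law. The radius grows
#: as r(c) = r_max * (1 - c/100)**gamma with r_max half the screen extent:
#: the identity at 100% coherence and unrestricted displacement at 0%. The
#: exponent spreads the transition across the coherence axis so that the
#: manipulation degrades retinotopic structure gradually rather than all at
#: once near full coherence (displacements beyond the ommatidial sampling
#: scale are equivalent to fully random ones).
COHERENCE_RADIUS_EXPONENT = 2.75


def scramble_coherence(movie: StimulusMovie, coherence: float,
                       seed: int = 0) -> StimulusMovie:
    """Displace coarse cells by a random distance-bounded permutation.

    The displacement radius is r(c) = r_max * (1 - c/100)**gamma with r_max
    half the screen extent and gamma = COHERENCE_RADIUS_EXPONENT, so 100%
    coherence is the identity and 0% allows unrestricted displacement. One
    permutation (drawn from ``seed``) is applied to every frame: each cell
    keeps its own luminance time course, only its retinotopic position
    changes, and the per-frame multiset of coarse-cell luminances is
    conserved exactly.
    """
    if movie.coarse_pixel_deg is None:
        raise ValueError("movie must be coarsened before scrambling "
                         "(run coarsen_pixelate first)")
    if not 0.0 <= coherence <= 100.0:
        raise ValueError("coherence must be in [0, 100]")
    if coherence == 100.0:
        return StimulusMovie(movie.frames.copy(), movie.frame_rate,
                             movie.pixel_pitch, t_start=movie.t_start,
                             coarse_pixel_deg=movie.coarse_pixel_deg)
    t_, h, w = movie.frames.shape
    cell = movie.coarse_pixel_deg
    iy = _cell_index(h, movie.pixel_pitch, cell)
    ix = _cell_index(w, movie.pixel_pitch, cell)
    ny, nx = iy[-1] + 1, ix[-1] + 1
    cy, cx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    centers = np.column_stack([cy.ravel(), cx.ravel()]) * cell
    extent = max(h, w) * movie.pixel_pitch
    r_max = extent / 2.0
    r = r_max * (1.0 - coherence / 100.0) ** COHERENCE_RADIUS_EXPONENT
    if coherence == 0.0:
        r = extent * 2.0  # unrestricted
    rng = np.random.default_rng(seed)
    perm = _bounded_permutation(centers, r, rng)
    # extract one luminance value per cell per frame (cells are uniform),
    # permute, and paint back onto the fine grid
    rep_y = np.searchsorted(iy, np.arange(ny))
    rep_x = np.searchsorted(ix, np.arange(nx))
    cell_lum = movie.frames[:, rep_y[:, None], rep_x[None, :]]
    cell_lum = cell_lum.reshape(t_, ny * nx)
    scrambled = np.empty_like(cell_lum)
    scrambled[:, perm] = cell_lum
    flat_cell = iy[:, None] * nx + ix[None, :]
    out = scrambled[:, flat_cell.ravel()].reshape(t_, h, w)
    return StimulusMovie(out, movie.frame_rate, movie.pixel_pitch,
                         t_start=movie.t_start, coarse_pixel_deg=cell)


# ---------------------------------------------------------------------------
# facet sampling
# ---------------------------------------------------------------------------

def _facet_weight_matrix(grid: FacetGrid, movie: StimulusMovie
                         ) -> sparse.csr_matrix:
    el, az = movie.pixel_coords()
    sigma = grid.acceptance_hwhm / np.sqrt(2.0 * np.log(2.0))
    cutoff = 3.0 * sigma
    h, w = el.size, az.size
    rows, cols, vals = [], [], []
    for f, (faz, fel) in enumerate(grid.facet_centers):
        sel_el = np.flatnonzero(np.abs(el - fel) <= cutoff)
        sel_az = np.flatnonzero(np.abs(az - faz) <= cutoff)
        if sel_el.size == 0 or sel_az.size == 0:
            # facet outside the movie: falls back to nearest pixel
            sel_el = np.array([np.argmin(np.abs(el - fel))])
            sel_az = np.array([np.argmin(np.abs(az - faz))])
        wy = np.exp(-0.5 * ((el[sel_el] - fel) / sigma) ** 2)
        wx = np.exp(-0.5 * ((az[sel_az] - faz) / sigma) ** 2)
        wgt = np.outer(wy, wx)
        wgt /= wgt.sum()
        pix = (sel_el[:, None] * w + sel_az[None, :]).ravel()
        rows.append(np.full(pix.size, f))
        cols.append(pix)
        vals.append(wgt.ravel())
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(grid.n_facets, h * w))
    return mat


def sample_facets(movie: StimulusMovie, grid: FacetGrid) -> FacetLuminance:
    """Gaussian-weighted luminance time course within each facet's RF."""
    if grid.n_facets == 0:
        raise ValueError("empty facet grid")
    wmat = _facet_weight_matrix(grid, movie)
    t_ = movie.frames.shape[0]
    flat = movie.frames.reshape(t_, -1).astype(np.float64)
    traces = np.asarray(wmat @ flat.T)
    return FacetLuminance(traces, movie.frame_rate,
                          t_start=movie.t_start, grid=grid)
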