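"""Reduced compartmental LGMD model with polarity-specific input mappings.

The LGMD is approximated by a branched compartment tree with six labeled
regions: the large distal dendritic field A (laid out as a 2-D grid
isomorphic to the ommatidial lattice, the target of retinotopic OFF
excitation), the smaller proximal fields B and C (ON inhibition and
non-retinotopic ON excitation, respectively), the main trunk, the spike
initiation zone (SIZ) and the axon. Field C attaches to the trunk near the
SIZ through a single connecting segment, making it electrotonically closer
to the SIZ than field A; scaling that segment's axial resistance is the
model manipulation that equalizes the two fields' synaptic efficacy.

Membrane dynamics follow the Hodgkin-Huxley formalism with the channel
complement of the detailed LGMD models: fast Na+ and delayed-rectifier K+
(SIZ/axon), HCN (field A dendrites; absent from field C), an inactivating
K+ conductance (field A dendrites), M-type K+ (axon), and low-threshold
Ca2+ plus Ca2+-dependent K+ near the SIZ. Kinetics are standard
Boltzmann/bell-shaped parameterizations; densities live in a versioned YAML
channel-set file and were tuned once so the cell rests near -65 mV and the
reference loom yields a firing profile peaking near projected collision
(see docs/methods.md).

Synaptic events are alpha conductances g(t) = g_max (t/tau) e^(1 - t/tau)
(excitatory: 0.15 ms, 14 nS, +10 mV; inhibitory: 2 ms, 8 nS, -78 mV),
delivered per event to the compartment chosen by the mapping scheme. The
cable equation on the tree is integrated with an unconditionally stable
implicit scheme (Crank-Nicolson with Hines elimination; gates by
Rush-Larsen exponential updates with voltage-indexed lookup tables),
default time step 0.02 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from numba import njit

from .encode import SynapticEventTrain
from .stimulus import loom_half_angle

REGIONS = ("A", "B", "C", "trunk", "SIZ", "axon")

# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


@dataclass
class MorphologyConfig:
    """Parametric description of the reduced LGMD morphology.

    The compartment counts are a deliberate reduction of the detailed
    anatomical model (2518 compartments); region proportions, not counts,
    are mirrored. Dimensions are in um, axial resistivity in ohm*cm,
    capacitance in uF/cm^2, leak in S/cm^2 and mV.
    """

    a_rows: int = 10
    a_cols: int = 12
    n_c: int = 30
    c_branches: int = 5
    n_b: int = 6
    n_trunk: int = 5
    n_siz: int = 5
    n_axon: int = 5
    a_len: float = 30.0
    a_diam: float = 6.0
    c_len: float = 40.0
    c_diam: float = 1.2
    b_len: float = 30.0
    b_diam: float = 8.0
    trunk_len: float = 40.0
    trunk_diam: float = 14.0
    siz_len: float = 20.0
    siz_diam: float = 6.0
    axon_len: float = 30.0
    axon_diam: float = 5.0
    c_link_len: float = 30.0
    c_link_diam: float = 2.7
    axial_resistivity: float = 60.0
    cm: float = 1.0
    g_leak: float = 2.5e-4            # tau_m = 4 ms
    e_leak: float = -58.0


@dataclass
class Morphology:
    """Branched compartment tree with region labels and 3-D positions."""

    parent: np.ndarray               # (N,) int; -1 at the root
    length: np.ndarray               # um
    diam: np.ndarray                 # um
    region: np.ndarray               # (N,) of str labels in REGIONS
    position: np.ndarray             # (N, 3) um
    axial_resistivity: np.ndarray    # ohm*cm per compartment
    cm: float
    g_leak: float
    e_leak: float
    a_grid: np.ndarray = None        # (a_rows, a_cols) comp ids, or None
    c_link: int = -1                 # id of the segment connecting C->trunk

    @property
    def n(self) -> int:
        return self.parent.size

    def ids(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region == region)

    @property
    def siz_id(self) -> int:
        return int(self.ids("SIZ")[0])

    @property
    def axon_tip(self) -> int:
        return int(self.ids("axon")[-1])

    def area_cm2(self) -> np.ndarray:
        return np.pi * self.diam * self.length * 1e-8

    def axial_conductance_us(self) -> np.ndarray:
        """Coupling conductance (uS) between each compartment and its parent."""
        # per-compartment half axial resistance, ohm
        r_half = (2.0 * self.axial_resistivity * (self.length * 1e-4)
                  / (np.pi * (self.diam * 1e-4) ** 2))
        g = np.zeros(self.n)
        for i in range(self.n):
            p = self.parent[i]
            if p >= 0:
                g[i] = 1e6 / (r_half[i] + r_half[p])  # ohm -> uS
        return g

    def validate(self) -> None:
        if np.sum(self.parent < 0) != 1:
            raise ValueError("morphology must have exactly one root")
        order = self.parent < np.arange(self.n)
        if not order.all():
            raise ValueError("parents must precede children")
        for r in ("A", "C", "trunk", "SIZ", "axon"):
            if not np.any(self.region == r):
                raise ValueError(f"region {r} is empty")


def build_morphology(config: MorphologyConfig | None = None) -> Morphology:
    """Assemble the reduced LGMD tree from a parametric config.

    Layout: trunk chain (root at the field-A end) -> SIZ chain -> axon
    chain. Field A rows hang off the distal trunk end as parallel chains,
    one grid row each, so the (row, col) lattice is isomorphic to the facet
    grid. Field B attaches mid-trunk. Field C branches radiate from a single
    connecting segment that joins the trunk next to the SIZ; field C
    compartments carry 3-D positions so inter-compartment distances are
    defined for clustered mappings.
    """
    cfg = config or MorphologyConfig()
    parent, length, diam, region, pos, ra = [], [], [], [], [], []

    def add(par, ln, dm, reg, xyz):
        parent.append(par)
        length.append(ln)
        diam.append(dm)
        region.append(reg)
        pos.append(xyz)
        ra.append(cfg.axial_resistivity)
        return len(parent) - 1

    # trunk: root at the distal (field A) end, indices increasing toward SIZ
    trunk = []
    for k in range(cfg.n_trunk):
        par = -1 if k == 0 else trunk[-1]
        trunk.append(add(par, cfg.trunk_len, cfg.trunk_diam, "trunk",
                         (0.0, -k * cfg.trunk_len, 0.0)))
    siz = []
    for k in range(cfg.n_siz):
        par = trunk[-1] if k == 0 else siz[-1]
        siz.append(add(par, cfg.siz_len, cfg.siz_diam, "SIZ",
                       (0.0, -(cfg.n_trunk * cfg.trunk_len + k * cfg.siz_len),
                        0.0)))
    axon = []
    for k in range(cfg.n_axon):
        par = siz[-1] if k == 0 else axon[-1]
        axon.append(add(par, cfg.axon_len, cfg.axon_diam, "axon",
                        (0.0, -(cfg.n_trunk * cfg.trunk_len
                                + cfg.n_siz * cfg.siz_len
                                + k * cfg.axon_len), 0.0)))

    # field A: one chain per grid row, attached at the trunk root
    a_grid = np.empty((cfg.a_rows, cfg.a_cols), dtype=int)
    for r in range(cfg.a_rows):
        prev = trunk[0]
        y0 = (r - (cfg.a_rows - 1) / 2.0) * cfg.a_len
        for c in range(cfg.a_cols):
            cid = add(prev, cfg.a_len, cfg.a_diam, "A",
                      (-(c + 1) * cfg.a_len, y0, 50.0))
            a_grid[r, c] = cid
            prev = cid

    # field C: branches radiating in 3-D from one connecting segment that
    # joins the trunk next to the SIZ
    link_parent = trunk[-1]
    c_link = add(link_parent, cfg.c_link_len, cfg.c_link_diam, "trunk",
                 (cfg.c_link_len, -(cfg.n_trunk - 1) * cfg.trunk_len, 0.0))

    # field B: short proximal chain sharing the B/C junction at the end of
    # the connecting segment (fields B and C are both proximal to the SIZ)
    prev = c_link
    for k in range(cfg.n_b):
        prev = add(prev, cfg.b_len, cfg.b_diam, "B",
                   (cfg.c_link_len + 20.0 + k * cfg.b_len,
                    -2 * cfg.trunk_len, -20.0))
    # field C is reduced to an equivalent "brush": every dendrite joins the
    # connecting segment directly, so all field C compartments share the
    # same electrotonic proximity to the SIZ and mapping manipulations act
    # purely through input concentration, not through which compartment
    # happens to lie closer to the trunk. Positions fan out in 3-D over a
    # field-like spatial extent for the clustered-mapping geometry.
    base = np.array(pos[c_link])
    golden = np.pi * (3.0 - np.sqrt(5.0))
    span = cfg.c_len * (cfg.n_c / cfg.c_branches)   # spatial radius, um
    for k in range(cfg.n_c):
        frac = (k + 0.5) / cfg.n_c
        ang = golden * k
        radius = span * np.sqrt(frac)
        xyz = base + np.array([np.cos(ang) * radius, 0.3 * span * frac,
                               np.sin(ang) * radius])
        add(c_link, cfg.c_len, cfg.c_diam, "C", tuple(xyz))

    morph = Morphology(
        parent=np.asarray(parent, dtype=np.int64),
        length=np.asarray(length, dtype=float),
        diam=np.asarray(diam, dtype=float),
        region=np.asarray(region, dtype=object),
        position=np.asarray(pos, dtype=float),
        axial_resistivity=np.asarray(ra, dtype=float),
        cm=cfg.cm, g_leak=cfg.g_leak, e_leak=cfg.e_leak,
        a_grid=a_grid, c_link=c_link)
    morph.validate()
    return morph


def cylinder_morphology(n: int = 10, length_um: float = 100.0,
                        diam_um: float = 2.0, ra: float = 100.0,
                        cm: float = 1.0, g_leak: float = 1e-4,
                        e_leak: float = -65.0) -> Morphology:
    """Unbranched passive cylinder (n compartments); analytic test bed."""
    parent = np.arange(-1, n - 1, dtype=np.int64)
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * length_um
    m = Morphology(parent=parent,
                   length=np.full(n, length_um),
                   diam=np.full(n, diam_um),
                   region=np.asarray(["trunk"] * n, dtype=object),
                   position=pos,
                   axial_resistivity=np.full(n, ra),
                   cm=cm, g_leak=g_leak, e_leak=e_leak)
    return m


def scale_axial_resistance(morph: Morphology, region_link: str = "C_link",
                           factor: float = 1.0) -> Morphology:
    """Scale the axial resistivity of the field C connecting segment.

    Only the segment linking field C to the main neurite is altered; the
    branch properties within field C are untouched. ``factor`` > 1 pushes
    field C electrotonically away from the SIZ.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if region_link != "C_link":
        raise ValueError(f"unknown link {region_link!r}; only 'C_link' "
                         "is defined in the reduced morphology")
    if morph.c_link < 0:
        raise ValueError("morphology has no C link segment")
    ra = morph.axial_resistivity.copy()
    ra[morph.c_link] *= factor
    return replace(morph, axial_resistivity=ra)


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

GATES = ("na_m", "na_h", "kdr_n", "hcn_q", "kd_a", "kd_b", "m_z",
         "cat_t", "cat_u")

# Boltzmann (vh, k) and bell-shaped tau (tau_min, tau_amp, v_center, v_width)
# for each gate; ms and mV. k < 0 marks inactivation-type steady states.
GATE_KINETICS = {
    "na_m": {"vh": -45.0, "k": 5.5, "tau": (0.06, 0.06, -48.0, 15.0)},
    "na_h": {"vh": -53.0, "k": -5.0, "tau": (0.6, 6.0, -60.0, 18.0)},
    "kdr_n": {"vh": -42.0, "k": 8.0, "tau": (0.8, 4.0, -50.0, 25.0)},
    "hcn_q": {"vh": -75.0, "k": -5.5, "tau": (120.0, 60.0, -80.0, 25.0)},
    "kd_a": {"vh": -40.0, "k": 10.0, "tau": (1.5, 3.0, -55.0, 25.0)},
    "kd_b": {"vh": -63.0, "k": -6.0, "tau": (150.0, 250.0, -65.0, 25.0)},
    "m_z": {"vh": -35.0, "k": 9.0, "tau": (60.0, 60.0, -40.0, 25.0)},
    "cat_t": {"vh": -56.0, "k": 6.5, "tau": (2.0, 4.0, -60.0, 20.0)},
    "cat_u": {"vh": -68.0, "k": -6.0, "tau": (40.0, 60.0, -70.0, 25.0)},
}

E_NA, E_K, E_H, E_CA = 50.0, -80.0, -35.0, 120.0


@dataclass
class ChannelSet:
    """Per-region maximal conductance densities (S/cm^2) for each channel."""

    densities: dict                  # channel -> {region: density}
    ca_tau_ms: float = 80.0
    ca_phi: float = 0.2              # Ca pool gain per unit Ca current
    kca_half: float = 0.5            # half-activation of K_Ca, pool units

    def density_vector(self, channel: str, morph: Morphology) -> np.ndarray:
        per_region = self.densities.get(channel, {})
        out = np.zeros(morph.n)
        for reg, dens in per_region.items():
            out[morph.region == reg] = dens
        return out

    def validate(self) -> None:
        for ch, per_region in self.densities.items():
            for reg, dens in per_region.items():
                if dens < 0:
                    raise ValueError(f"negative density for {ch}/{reg}")
        if self.densities.get("hcn", {}).get("C", 0.0) != 0.0:
            raise ValueError("HCN must be absent from field C")


def load_channelset(path=None) -> ChannelSet:
    """Load the channel-set YAML (package default if no path given)."""
    if path is None:
        src = (resources.files("loomlab") / "data" / "channels.yaml")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    cs = ChannelSet(densities=raw["densities"],
                    ca_tau_ms=raw.get("ca_tau_ms", 80.0),
                    ca_phi=raw.get("ca_phi", 0.2),
                    kca_half=raw.get("kca_half", 0.5))
    cs.validate()
    return cs


def passive_channelset() -> ChannelSet:
    return ChannelSet(densities={})


def _gate_tables(dt_ms: float, v_lo: float = -120.0, v_hi: float = 60.0,
                 v_step: float = 0.05) -> tuple[np.ndarray, np.ndarray,
                                                float, float]:
    """Voltage-indexed inf and exponential-update tables for every gate."""
    v = np.arange(v_lo, v_hi + v_step, v_step)
    inf = np.empty((len(GATES), v.size))
    fac = np.empty((len(GATES), v.size))
    for gi, g in enumerate(GATES):
        kin = GATE_KINETICS[g]
        inf[gi] = 1.0 / (1.0 + np.exp(-(v - kin["vh"]) / kin["k"]))
        tmin, tamp, vc, vw = kin["tau"]
        tau = tmin + tamp * np.exp(-((v - vc) / vw) ** 2)
        fac[gi] = 1.0 - np.exp(-dt_ms / tau)
    return inf, fac, v_lo, v_step


# ---------------------------------------------------------------------------
# synapses and mapping
# ---------------------------------------------------------------------------

@dataclass
class SynapseParams:
    """Alpha-synapse parameters for one class of inputs."""

    tau_ms: float
    g_max_ns: float
    e_rev_mv: float


EXC_SYNAPSE = SynapseParams(tau_ms=0.15, g_max_ns=14.0, e_rev_mv=10.0)
INH_SYNAPSE = SynapseParams(tau_ms=2.0, g_max_ns=8.0, e_rev_mv=-78.0)

MAPPING_MODES = ("retinotopic_A", "random_C", "clustered_C", "split",
                 "checkered")


@dataclass
class SynapseMap:
    """Resolved event -> compartment assignment for one simulation run."""

    times_s: np.ndarray              # (n_events,)
    comp: np.ndarray                 # (n_events,) compartment ids
    weight: np.ndarray               # (n_events,) conductance scale in (0,1]
    is_exc: np.ndarray               # (n_events,) bool
    mode: str = ""

    def __post_init__(self) -> None:
        order = np.argsort(self.times_s, kind="stable")
        self.times_s = np.asarray(self.times_s, float)[order]
        self.comp = np.asarray(self.comp, np.int64)[order]
        self.weight = np.asarray(self.weight, float)[order]
        self.is_exc = np.asarray(self.is_exc, bool)[order]

    @property
    def n_events(self) -> int:
        return self.times_s.size


def _facet_to_a_comp(facet_ids: np.ndarray, facet_shape: tuple[int, int],
                     morph: Morphology) -> np.ndarray:
    """Retinotopic facet -> field A compartment lookup (grid-proportional)."""
    nf_r, nf_c = facet_shape
    na_r, na_c = morph.a_grid.shape
    fr, fc = facet_ids // nf_c, facet_ids % nf_c
    ar = np.clip(np.round(fr * (na_r - 1) / max(nf_r - 1, 1)), 0,
                 na_r - 1).astype(int)
    ac = np.clip(np.round(fc * (na_c - 1) / max(nf_c - 1, 1)), 0,
                 na_c - 1).astype(int)
    return morph.a_grid[ar, ac]


def map_events(train: SynapticEventTrain, morph: Morphology,
               mode: str = "retinotopic_A", options: dict | None = None,
               seed: int = 0) -> SynapseMap:
    """Assign every synaptic event to a compartment under a mapping scheme.

    Modes
    -----
    retinotopic_A
        Visually driven excitatory events go to the field A compartment
        matching their facet (grid-proportional); spontaneous excitation is
        spread uniformly over field A. OFF inhibition targets random field C
        compartments and ON inhibition field B, the baseline arrangement of
        the black-loom simulations.
    random_C
        All excitation is moved to uniformly random field C compartments;
        the matching (here: full) percentage of field C inhibition moves to
        field B, its amount unchanged. ``options['removal_fraction']``
        removes a random subset of the relocated excitatory events, or
        ``options['conductance_scale']`` scales their conductance instead;
        both reductions are equivalent in effect.
    clustered_C
        Excitation goes to field C but recruitment spreads from a central
        compartment as the loom grows: a compartment at distance d (um)
        from the center is eligible with weight
        1/(1+exp((d - R(t))/steepness)), R(t) growing with the stimulus
        half-angle. ``steepness_um`` defaults to 80; ``extent_scale`` < 1
        narrows the clustering. Inhibition moves to field B as in random_C.
    split
        A fraction f of excitatory events moves to random field C locations,
        with 60% of the moved events removed (or conductance x0.4), and the
        matching fraction of field C inhibition moves to field B.
    checkered
        ON excitatory events map randomly to field C, OFF excitatory events
        retinotopically to field A (mixed-polarity looms).
    """
    if mode not in MAPPING_MODES:
        raise ValueError(f"unknown mapping mode {mode!r}")
    opts = dict(options or {})
    rng = np.random.default_rng(seed)
    ev = train.events
    n = len(ev)
    times = ev["time_s"].to_numpy(float)
    is_exc = (ev["class"] == "excitatory").to_numpy()
    polarity = ev["polarity"].to_numpy()
    facet_id = ev["facet_id"].to_numpy(int)
    comp = np.empty(n, dtype=np.int64)
    weight = np.ones(n, dtype=float)
    keep = np.ones(n, dtype=bool)

    a_ids = morph.ids("A")
    b_ids = morph.ids("B")
    c_ids = morph.ids("C")
    facet_shape = opts.get("facet_grid_shape")

    def retinotopic_target(sel: np.ndarray) -> np.ndarray:
        out = np.empty(sel.sum(), dtype=np.int64)
        fids = facet_id[sel]
        vis = fids >= 0
        if vis.any():
            if facet_shape is None or morph.a_grid is None:
                raise ValueError("retinotopic mapping needs "
                                 "options['facet_grid_shape'] and an A grid")
            out[vis] = _facet_to_a_comp(fids[vis], facet_shape, morph)
        if (~vis).any():
            out[~vis] = rng.choice(a_ids, size=int((~vis).sum()))
        return out

    # inhibition: OFF -> field C, ON -> field B (all modes; split moves some)
    inh = ~is_exc
    inh_off = inh & (polarity == "OFF")
    inh_on = inh & (polarity == "ON")
    comp[inh_off] = rng.choice(c_ids, size=int(inh_off.sum()))
    comp[inh_on] = rng.choice(b_ids, size=int(inh_on.sum()))

    if mode == "retinotopic_A":
        comp[is_exc] = retinotopic_target(is_exc)

    elif mode == "random_C":
        comp[is_exc] = rng.choice(c_ids, size=int(is_exc.sum()))
        # all excitation left field A, so all field C inhibition moves to
        # field B (same amount, new location)
        comp[inh_off] = rng.choice(b_ids, size=int(inh_off.sum()))
        removal = opts.get("removal_fraction", 0.0)
        g_scale = opts.get("conductance_scale", None)
        if removal and g_scale is not None:
            raise ValueError("give removal_fraction or conductance_scale, "
                             "not both")
        if removal:
            if not 0.0 <= removal <= 1.0:
                raise ValueError("removal_fraction must be in [0, 1]")
            drop = rng.random(n) < removal
            keep &= ~(is_exc & drop)
        if g_scale is not None:
            weight[is_exc] = g_scale

    elif mode == "clustered_C":
        comp[is_exc] = _clustered_c_targets(
            times[is_exc], morph, c_ids, rng, opts)
        comp[inh_off] = rng.choice(b_ids, size=int(inh_off.sum()))

    elif mode == "split":
        f = opts.get("fraction", 0.5)
        if not 0.0 <= f <= 1.0:
            raise ValueError("split fraction must be in [0, 1]")
        removal = opts.get("removal_fraction", 0.6)
        reduce_by = opts.get("reduce_by", "removal")
        comp[is_exc] = retinotopic_target(is_exc)
        moved = is_exc & (rng.random(n) < f)
        comp[moved] = rng.choice(c_ids, size=int(moved.sum()))
        if reduce_by == "removal":
            keep &= ~(moved & (rng.random(n) < removal))
        elif reduce_by == "conductance":
            weight[moved] = 1.0 - removal
        else:
            raise ValueError("reduce_by must be 'removal' or 'conductance'")
        # matching percentage of field C inhibition moves to field B
        move_inh = inh_off & (rng.random(n) < f)
        comp[move_inh] = rng.choice(b_ids, size=int(move_inh.sum()))

    elif mode == "checkered":
        exc_on = is_exc & (polarity == "ON")
        exc_off = is_exc & (polarity == "OFF")
        comp[exc_on] = rng.choice(c_ids, size=int(exc_on.sum()))
        comp[exc_off] = retinotopic_target(exc_off)

    return SynapseMap(times_s=times[keep], comp=comp[keep],
                      weight=weight[keep], is_exc=is_exc[keep], mode=mode)


def _clustered_c_targets(t_exc: np.ndarray, morph: Morphology,
                         c_ids: np.ndarray, rng: np.random.Generator,
                         opts: dict) -> np.ndarray:
    center = opts.get("center")
    if center is None:
        centroid = morph.position[c_ids].mean(axis=0)
        center = int(c_ids[np.argmin(
            np.linalg.norm(morph.position[c_ids] - centroid, axis=1))])
    if center not in set(c_ids.tolist()):
        raise ValueError("cluster center must be a field C compartment")
    steep = opts.get("steepness_um", 80.0) * opts.get("extent_scale", 1.0)
    dist = np.linalg.norm(morph.position[c_ids]
                          - morph.position[center], axis=1)
    r_max = opts.get("r_max_um", float(dist.max())) \
        * opts.get("extent_scale", 1.0)
    l_over_v = opts.get("l_over_v", 80.0)
    if t_exc.size == 0:
        return np.empty(0, dtype=np.int64)
    theta = np.full(t_exc.shape, 90.0)
    pre = t_exc < 0
    theta[pre] = loom_half_angle(t_exc[pre], l_over_v)
    theta0 = theta.min()
    frac = (theta - theta0) / max(90.0 - theta0, 1e-9)
    radius = r_max * frac
    # sample each event's compartment with sigmoidal eligibility weights
    w = 1.0 / (1.0 + np.exp((dist[None, :] - radius[:, None])
                            / max(steep, 1e-6)))
    w_sum = w.sum(axis=1, keepdims=True)
    cdf = np.cumsum(w / w_sum, axis=1)
    u = rng.random(t_exc.size)
    idx = (cdf < u[:, None]).sum(axis=1).clip(0, c_ids.size - 1)
    return c_ids[idx]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Run configuration for one simulation."""

    dt_ms: float = 0.02
    t_start_s: float = 0.0           # first simulated time (events clock)
    t_end_s: float = 1.0
    settle_ms: float = 400.0         # pre-roll to reach steady state
    v_init_mv: float = -65.0
    exc: SynapseParams = field(default_factory=lambda: EXC_SYNAPSE)
    inh: SynapseParams = field(default_factory=lambda: INH_SYNAPSE)
    record: tuple = ("SIZ", "axon")  # regions or explicit compartment ids
    spike_threshold_mv: float = -20.0
    refractory_ms: float = 2.0
    inj_comp: int = -1               # constant current injection (optional)
    inj_na: float = 0.0
    inj_t0_s: float = 0.0
    inj_t1_s: float = 0.0
    clamp_mv: float | None = None    # voltage clamp the whole tree


@dataclass
class SimResult:
    """Membrane potential, spikes, and synaptic charge from one run."""

    t_s: np.ndarray                  # (n_steps,) times of saved samples
    vm_mv: np.ndarray                # (n_rec, n_steps)
    rec_comps: np.ndarray            # recorded compartment ids
    spike_times_s: np.ndarray
    total_excitatory_charge_nc: float
    dt_ms: float
    morph: Morphology | None = None

    @property
    def n_spikes(self) -> int:
        return self.spike_times_s.size

    def vm_at(self, comp: int) -> np.ndarray:
        idx = np.flatnonzero(self.rec_comps == comp)
        if idx.size == 0:
            raise KeyError(f"compartment {comp} was not recorded")
        return self.vm_mv[idx[0]]


@njit(cache=True)
def _run_kernel(n_steps, dt, parent, g_ax, ax_diag, c_nf, gl_us, el,
                gbar, inf_tab, fac_tab, v_lo, v_step,
                ca_tau, ca_phi, kca_half, area_cm2,
                ev_step, ev_comp, ev_w, ev_exc,
                taue, ge_unit, e_e, taui, gi_unit, e_i,
                rec_idx, v0, inj_comp, inj_na, inj_k0, inj_k1,
                clamp_on, clamp_v):
    n = parent.size
    v = np.full(n, v0)
    if clamp_on:
        v[:] = clamp_v
    gates = np.empty((9, n))
    nv = inf_tab.shape[1]
    for gi in range(9):
        for i in range(n):
            idx = int((v[i] - v_lo) / v_step + 0.5)
            if idx < 0:
                idx = 0
            elif idx >= nv:
                idx = nv - 1
            gates[gi, i] = inf_tab[gi, idx]
    ca = np.zeros(n)
    s1e = np.zeros(n)
    s2e = np.zeros(n)
    s1i = np.zeros(n)
    s2i = np.zeros(n)
    de = math.exp(-dt / taue)
    di = math.exp(-dt / taui)
    # exact per-step integrals of the alpha-state s2: given (s1, s2) at the
    # step start, int_0^dt (s2 + u*s1) e^(-u/tau) du
    ie_s2 = taue * (1.0 - de)
    ie_s1 = taue * taue * (1.0 - de) - taue * dt * de
    ii_s2 = taui * (1.0 - di)
    ii_s1 = taui * taui * (1.0 - di) - taui * dt * di
    diag = np.empty(n)
    rhs = np.empty(n)
    gsyn_e = np.empty(n)
    vm_rec = np.empty((rec_idx.size, n_steps))
    q_exc = 0.0
    ptr = 0
    n_ev = ev_step.size
    for k in range(n_steps):
        # deliver this step's events
        while ptr < n_ev and ev_step[ptr] == k:
            c = ev_comp[ptr]
            if ev_exc[ptr]:
                s1e[c] += ev_w[ptr]
            else:
                s1i[c] += ev_w[ptr]
            ptr += 1
        # gate updates (Rush-Larsen with tabulated inf and 1-exp(-dt/tau))
        for i in range(n):
            idx = int((v[i] - v_lo) / v_step + 0.5)
            if idx < 0:
                idx = 0
            elif idx >= nv:
                idx = nv - 1
            for gi in range(9):
                x = gates[gi, i]
                gates[gi, i] = x + (inf_tab[gi, idx] - x) * fac_tab[gi, idx]
        # assemble the Crank-Nicolson system; synaptic conductances enter
        # as their exact average over the step (the alpha time constant can
        # be shorter than dt, so a point sample would lose charge)
        for i in range(n):
            m3h = gates[0, i] ** 3 * gates[1, i]
            g_na = gbar[0, i] * m3h
            g_kdr = gbar[1, i] * gates[2, i] ** 2
            g_hcn = gbar[2, i] * gates[3, i]
            g_kd = gbar[3, i] * gates[4, i] * gates[5, i]
            g_m = gbar[4, i] * gates[6, i]
            g_cat = gbar[5, i] * gates[7, i] ** 2 * gates[8, i]
            g_kca = gbar[6, i] * ca[i] / (ca[i] + kca_half)
            # calcium pool driven by the T-type current density
            i_ca = g_cat * (v[i] - E_CA) / max(area_cm2[i], 1e-12) * 1e-9
            dca = -ca_phi * i_ca - ca[i] / ca_tau
            ca[i] += dt * dca
            if ca[i] < 0.0:
                ca[i] = 0.0
            g_se = ge_unit * (s2e[i] * ie_s2 + s1e[i] * ie_s1) / dt
            g_si = gi_unit * (s2i[i] * ii_s2 + s1i[i] * ii_s1) / dt
            gsyn_e[i] = g_se
            g_sum = (gl_us[i] + g_na + g_kdr + g_hcn + g_kd + g_m
                     + g_cat + g_kca + g_se + g_si)
            b = (c_nf[i] / dt * v[i]
                 - 0.5 * (g_sum + ax_diag[i]) * v[i]
                 + gl_us[i] * el
                 + g_na * E_NA + g_kdr * E_K + g_hcn * E_H + g_kd * E_K
                 + g_m * E_K + g_cat * E_CA + g_kca * E_K
                 + g_se * e_e + g_si * e_i)
            if i == inj_comp and inj_k0 <= k < inj_k1:
                b += inj_na
            diag[i] = c_nf[i] / dt + 0.5 * (g_sum + ax_diag[i])
            rhs[i] = b
        # explicit half of the axial coupling
        for i in range(1, n):
            p = parent[i]
            rhs[i] += 0.5 * g_ax[i] * v[p]
            rhs[p] += 0.5 * g_ax[i] * v[i]
        # advance the alpha-synapse states to the step end (exact recursion)
        for i in range(n):
            s2e[i] = (s2e[i] + dt * s1e[i]) * de
            s1e[i] *= de
            s2i[i] = (s2i[i] + dt * s1i[i]) * di
            s1i[i] *= di
        if clamp_on:
            # membrane held fixed; only tally synaptic charge
            for i in range(n):
                q_exc += gsyn_e[i] * (e_e - v[i]) * dt
        else:
            # Hines elimination (children have larger indices than parents)
            for i in range(n - 1, 0, -1):
                p = parent[i]
                f = 0.5 * g_ax[i] / diag[i]
                diag[p] -= f * 0.5 * g_ax[i]
                rhs[p] += f * rhs[i]
            v[0] = rhs[0] / diag[0]
            for i in range(1, n):
                p = parent[i]
                v[i] = (rhs[i] + 0.5 * g_ax[i] * v[p]) / diag[i]
            for i in range(n):
                q_exc += gsyn_e[i] * (e_e - v[i]) * dt
        for r in range(rec_idx.size):
            vm_rec[r, k] = v[rec_idx[r]]
    return vm_rec, q_exc


def _resolve_record(morph: Morphology, record) -> np.ndarray:
    out = []
    for item in record:
        if isinstance(item, str):
            ids = morph.ids(item)
            # the axon resolves to its tip (the spike-detection site),
            # other regions to a representative middle compartment
            out.append(int(ids[-1] if item == "axon" else ids[len(ids) // 2]))
        else:
            out.append(int(item))
    return np.asarray(sorted(set(out)), dtype=np.int64)


def simulate(morph: Morphology, channels: ChannelSet | None,
             synmap: SynapseMap | None, params: SimParams | None = None,
             ) -> SimResult:
    """Integrate the compartmental model and return Vm, spikes, and charge.

    The membrane equation is advanced by a Crank-Nicolson step with Hines
    elimination on the tree (second order, unconditionally stable); synaptic
    conductances enter as exact step averages of the alpha function, and
    gating variables use Rush-Larsen exponential updates from
    voltage-indexed lookup tables. A settle period
    (``params.settle_ms``) is prepended so the run starts from steady state;
    events before ``t_start_s`` or after ``t_end_s`` are ignored with a
    warning. Total excitatory synaptic charge is accumulated as
    sum_i g_exc,i(t) (E_rev - V_i(t)) dt in nC.
    """
    import warnings as _w
    params = params or SimParams()
    channels = channels or passive_channelset()
    dt = params.dt_ms
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_settle = int(round(params.settle_ms / dt))
    n_main = int(round((params.t_end_s - params.t_start_s) * 1000.0 / dt))
    n_steps = n_settle + n_main

    area = morph.area_cm2()
    c_nf = morph.cm * area * 1e3          # uF/cm^2 * cm^2 -> nF... (uF=1e3 nF)
    gl_us = morph.g_leak * area * 1e6     # S -> uS
    g_ax = morph.axial_conductance_us()
    ax_diag = np.zeros(morph.n)
    for i in range(morph.n):
        p = morph.parent[i]
        if p >= 0:
            ax_diag[i] += g_ax[i]
            ax_diag[p] += g_ax[i]

    order = ["na", "kdr", "hcn", "kd", "m", "cat", "kca"]
    gbar = np.stack([channels.density_vector(ch, morph) * area * 1e6
                     for ch in order])

    inf_tab, fac_tab, v_lo, v_step = _gate_tables(dt)

    if synmap is not None and synmap.n_events:
        rel_ms = (synmap.times_s - params.t_start_s) * 1000.0
        step = np.floor(rel_ms / dt).astype(np.int64) + n_settle
        ok = (step >= n_settle) & (step < n_steps)
        if not ok.all():
            _w.warn(f"{int((~ok).sum())} events outside the simulated "
                    "window were ignored", stacklevel=2)
        ev_step = step[ok]
        ev_comp = synmap.comp[ok]
        ev_w = synmap.weight[ok]
        ev_exc = synmap.is_exc[ok]
        srt = np.argsort(ev_step, kind="stable")
        ev_step, ev_comp = ev_step[srt], ev_comp[srt]
        ev_w, ev_exc = ev_w[srt], ev_exc[srt]
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_comp = np.empty(0, dtype=np.int64)
        ev_w = np.empty(0, dtype=float)
        ev_exc = np.empty(0, dtype=bool)

    rec_idx = _resolve_record(morph, params.record)
    exc, inh = params.exc, params.inh
    ge_unit = exc.g_max_ns * 1e-3 * math.e / exc.tau_ms  # uS per (ms * s2)
    gi_unit = inh.g_max_ns * 1e-3 * math.e / inh.tau_ms

    inj_k0 = n_settle + int(round((params.inj_t0_s - params.t_start_s)
                                  * 1000.0 / dt))
    inj_k1 = n_settle + int(round((params.inj_t1_s - params.t_start_s)
                                  * 1000.0 / dt))

    vm, q_exc = _run_kernel(
        n_steps, dt, morph.parent, g_ax, ax_diag, c_nf, gl_us, morph.e_leak,
        gbar, inf_tab, fac_tab, v_lo, v_step,
        channels.ca_tau_ms, channels.ca_phi, channels.kca_half, area,
        ev_step, ev_comp, ev_w, ev_exc,
        exc.tau_ms, ge_unit, exc.e_rev_mv, inh.tau_ms, gi_unit, inh.e_rev_mv,
        rec_idx, params.v_init_mv, params.inj_comp, params.inj_na,
        inj_k0, inj_k1,
        params.clamp_mv is not None,
        params.clamp_mv if params.clamp_mv is not None else 0.0)

    if not np.isfinite(vm).all():
        raise FloatingPointError("simulation diverged (non-finite Vm); "
                                 "check dt, densities, and morphology")

    # drop the settle period from the returned traces
    vm = vm[:, n_settle:]
    t_s = params.t_start_s + (np.arange(n_main) + 1) * dt / 1000.0
    result = SimResult(t_s=t_s, vm_mv=vm, rec_comps=rec_idx,
                       spike_times_s=np.empty(0),
                       total_excitatory_charge_nc=q_exc * 1e-3,  # pC -> nC
                       dt_ms=dt, morph=morph)
    has_axon = np.any(morph.region == "axon")
    spike_comp = (morph.axon_tip
                  if has_axon and morph.axon_tip in rec_idx else rec_idx[-1])
    spikes, _ = detect_spikes_ifr(result, comp=spike_comp,
                                  threshold_mv=params.spike_threshold_mv,
                                  refractory_ms=params.refractory_ms,
                                  ifr=False)
    result.spike_times_s = spikes
    return result


# ---------------------------------------------------------------------------
# spike detection / IFR
# ---------------------------------------------------------------------------

def detect_spikes_ifr(result: SimResult, comp: int | None = None,
                      threshold_mv: float = -20.0,
                      refractory_ms: float = 2.0,
                      kernel_sd_ms: float = 20.0,
                      ifr: bool = True):
    """Threshold-crossing spike times and Gaussian-smoothed firing rate.

    Spikes are upward crossings of ``threshold_mv`` de-duplicated with a
    refractory window; the instantaneous firing rate is the spike train
    convolved with a normalized Gaussian kernel (default SD 20 ms), in
    spikes/s on the result's time base. Returns (spike_times_s, ifr) with
    ifr None when not requested.
    """
    if comp is None:
        comp = int(result.rec_comps[-1])
    v = result.vm_at(comp)
    above = v >= threshold_mv
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    spikes = []
    last = -np.inf
    refr_s = refractory_ms / 1000.0
    for k in crossings:
        t = result.t_s[k]
        if t - last >= refr_s:
            spikes.append(t)
            last = t
    spike_times = np.asarray(spikes)
    if not ifr:
        return spike_times, None
    sd_s = kernel_sd_ms / 1000.0
    rate = np.zeros_like(result.t_s)
    for t0 in spike_times:
        rate += np.exp(-0.5 * ((result.t_s - t0) / sd_s) ** 2)
    rate /= sd_s * np.sqrt(2.0 * np.pi)
    return spike_times, rate
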