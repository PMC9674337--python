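# Methods

`loomlab` re-implements, as one tested pipeline, the computational chain
behind a question in collision-avoidance neuroscience: how the mapping of
ON and OFF excitatory synaptic inputs onto different dendritic fields of
the locust LGMD (lobula giant movement detector) neuron shapes its spiking
output, its ability to discriminate the spatial coherence of approaching
objects, and the metabolic cost of detection. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic data do and do not establish.

## Looming stimuli

A looming stimulus simulates a square of half-size l approaching at
constant speed v < 0; its retinal half-angle grows as
theta(t) = arctan((l/|v|)/|t|) and reaches 90 deg (full angle 180 deg) at
the projected collision t = 0. The single kinematic parameter l/|v| is
expressed in ms (default 80 ms, the mid value of the behavioral range).
Stimuli are rendered in eye-centered angular coordinates on a square pixel
grid (default 120 deg extent, 1 deg/pixel, 240 Hz — the display refresh
rate of the imaging experiments) in four contrast classes: black on white,
white on black, and checkered or five-ring concentric patterns on a 50%
luminance background. The solid square's outer edge is drawn with
area-weighted anti-aliasing; the checker/ring interior patterns are drawn
at pixel resolution. The physical screen (placed 20 mm from the eye in the
experiments) is not modeled; the simulation works directly in visual
angle. The default simulated window runs from 2.5 s before collision
(full angle ~3.7 deg) to 0.1 s after, during which the full-size square is
held.

### Coherence manipulation

Spatial coherence is reduced in two steps. First, `coarsen_pixelate`
replaces each 2.5 deg cell (the scale of photoreceptor receptive fields)
by its mean luminance per frame, converting local edge motion into local
luminance change. The output stays on the fine pixel grid, so the frame
mean is conserved exactly and the operation is idempotent. Second,
`scramble_coherence` applies one random distance-bounded bijection of the
coarse cells to every frame: each cell keeps its own luminance time
course, only its retinotopic position changes, so the per-frame luminance
histogram is conserved at every coherence level. The bijection is found as
a perfect matching with i.i.d. random costs inside the allowed radius
(identity always feasible).

The displacement radius follows r(c) = r_max (1 - c/100)^gamma with r_max
half the screen extent and gamma = 2.75: the identity at 100% coherence
and unrestricted displacement at 0%. The exponent is a design choice made
once, from a dose-response sweep of the model's peak firing rate against a
fixed displacement radius: the reduced model resolves displacements only
up to roughly its field A grid scale (~10-15 deg), so a radius linear in
(1 - c/100) would concentrate the entire behavioral transition just below
100% coherence and make the manipulation effectively binary. The exponent
spreads the transition across the coherence axis, matching the graded
dose-response the same manipulation produces experimentally. The original
experiments' exact displacement law is published only in earlier work and
was not available here.

### Ommatidial sampling

The eye is modeled as a square lattice of facets at 2 deg spacing (the
acceptance-matched resolution of the compound eye), each reporting a
Gaussian-weighted luminance average with half-width at half-maximum 2 deg
(the angular profile is not constrained by data; a Gaussian is the
conventional choice). Sampling is a sparse matrix product, with weights
truncated at 3 sigma.

## Encoding into synaptic events

The presynaptic pathway is reduced to a luminance-change encoder. Each
facet's trace is band-pass filtered by a difference of two first-order
low-passes (tau_fast = 10 ms, tau_slow = 100 ms), initialized at steady
state so constant luminance yields exactly zero drive. The positive lobe
is the ON drive and the sign-flipped negative lobe the OFF drive; a
threshold (0.02 drive units) stands in for medullary spike threshold.
Excitatory events are drawn per facet as an inhomogeneous Poisson process
with intensity gain x max(drive - threshold, 0). The exact shape of the
photoreceptor/lamina transforms is not reproduced; the model experiments
downstream depend on event counts, their timing order, and their mapping,
not on the transform's detailed waveform.

Feed-forward inhibition is wide-field: the suprathreshold drive is pooled
over all facets and both polarity channels, lagged by 30 ms, and split
into ON and OFF pools by the instantaneous polarity share. Pooling both
channels (rather than only the channel opposite to the excitation) is
required for solid single-polarity looms, whose opposite channel carries
essentially no energy; it represents the assumption that feed-forward
inhibition tracks overall stimulus drive. The ON pool feeds the field B
pathway and the OFF pool the field C pathway.

`calibrate_event_gain` fixes the two gains so the *expected* totals for
the reference black coherent loom equal the model budgets of 80,000
excitatory and 7,000 inhibitory events; realized Poisson counts then land
within ~0.5%. Each event stands for one activation of a lumped synapse
(fewer, stronger synapses than the real afferents). Spontaneous background
events are appended at aggregate rates of 500 Hz (excitatory) and 30 Hz
(inhibitory), the level that reproduced the recorded membrane-potential
noise in the detailed model.

## Reduced compartmental model

The LGMD is reduced from its ~2518-compartment anatomical reconstruction
to 172 compartments mirroring the region layout, not the counts: a
12 x 10 field A grid (rows of 30 um x 6 um cylinders chained off the
distal trunk, the lattice isomorphic to the facet grid for retinotopic
mapping), a 5-compartment trunk (14 um diameter), 5 SIZ and 5 axon
compartments, and proximal fields B (6 x 8 um) and C. Field C is an
electrically uniform "brush": 30 thin dendrites (40 x 1.2 um), each
joining a single connecting segment (30 x 2.7 um) that meets the trunk
next to the SIZ; field B attaches at the same junction. The brush is a
deliberate reduction: with so few compartments, any within-field gradient
of electrotonic proximity would let mapping manipulations act through
*which* compartments happen to lie closer to the trunk rather than through
input concentration, which is the mechanism under study. Compartment
positions fan out in 3-D over a field-like extent so inter-compartment
distances remain defined for clustered mappings. Passive properties:
Cm = 1 uF/cm2, Ra = 60 ohm cm, g_leak = 2.5e-4 S/cm2 (tau_m = 4 ms),
E_leak = -58 mV.

### Channels and tuning

Channels follow the complement of the detailed LGMD models — fast Na+ and
delayed-rectifier K+ at the SIZ/axon, HCN in field A dendrites (absent
from field C, enforced), an inactivating K+ conductance (K_D-like) in
field A, M-type K+ in the axon, and low-threshold Ca2+ with
Ca2+-dependent K+ at the SIZ — with standard Boltzmann steady states and
bell-shaped time constants (`GATE_KINETICS`). The exact kinetics of the
original models were not available, so densities (stored in the versioned
`data/channels.yaml`) were tuned once with `scripts/tune_model.py` against
six simultaneous targets: a stable rest; larger single-EPSP SIZ
depolarization from field C than from field A; a reference-loom firing
profile peaking near projected collision; integrated excitatory charge
within 15% of the analytic per-event estimate; all-field-C input with 60%
removal matching the all-field-A spike count within one spike; and split
excitation maximal at an even split. The tuned cell rests near -70 mV
rather than the -65 mV first targeted: the K_D density needed for
driving-force fidelity (the charge target) pulls rest down, and -70 mV is
within the experimentally reported range for this neuron. The K_D
conductance plays the same role here as in the real dendrites: it shunts
sustained depolarization, holding the dendritic membrane near -50 mV
during the loom so that synaptic driving force — and hence the per-event
charge that the energy budget rests on — is largely preserved.

### Synapses and mapping schemes

Each excitatory event activates an alpha conductance
g(t) = g_max (t/tau) e^(1-t/tau) with tau = 0.15 ms, g_max = 14 nS,
E_rev = +10 mV; inhibitory events use 2 ms, 8 nS, -78 mV. Mappings:

- **retinotopic_A** — visually driven excitation goes to the field A
  compartment matching its facet (grid-proportional lookup); OFF
  inhibition to random field C compartments and ON inhibition to field B.
  This is the baseline black-loom arrangement.
- **random_C** — all excitation to uniformly random field C compartments;
  the field C inhibition moves to field B (amount unchanged). A removal
  fraction deletes a random subset of the relocated events, or
  equivalently a conductance scale multiplies their strength; the two
  reductions produce the same spike count within one spike.
- **clustered_C** — as random_C, but recruitment spreads from a central
  compartment with sigmoidal eligibility
  1/(1 + exp((d - R(t))/steepness)), steepness 80 um, R(t) growing with
  the stimulus half-angle; an extent scale < 1 narrows the clustering.
- **split** — a fraction f of excitatory events moves to random field C
  locations with 60% of the moved events removed (or conductance x 0.4),
  and the matching fraction of field C inhibition moves to field B.
- **checkered** — ON excitatory events map randomly to field C and OFF
  events retinotopically to field A, for mixed-polarity stimuli.

Whenever excitation leaves field A for field C, the matching percentage of
inhibition moves from field C to field B with its amount unchanged — the
procedure described for the original simulations. Spontaneous events
(facet id -1) are spread uniformly over the target region of their class.

### Numerics

The cable equation on the tree is advanced by a Crank-Nicolson step with
Hines elimination (one O(N) solve per step, second order, unconditionally
stable), default dt = 0.02 ms. Because the excitatory alpha time constant
(0.15 ms) is only a few steps long, synaptic conductances enter the matrix
as their *exact* average over the step, computed from the closed-form
integral of the alpha states; the states themselves follow an exact
exponential recursion, so event timing suffers no accumulation error.
Gating variables use Rush-Larsen exponential updates with
voltage-indexed lookup tables (0.05 mV resolution, rebuilt per dt). A
settle period (default 400 ms) precedes every run. On the toy passive
two-compartment circuit the scheme tracks a dense-output ODE reference
within 0.1 mV at the default step, and halving dt leaves the
reference-loom spike count unchanged. Spikes are upward crossings of
-20 mV at the axon tip with a 2 ms refractory window; the instantaneous
firing rate is the spike train convolved with a normalized Gaussian
(SD 20 ms). Total excitatory synaptic charge is accumulated as
sum_i g_i(t) (E_rev - V_i(t)) dt; under voltage clamp this reproduces the
per-event closed form to 0.2%.

## Energy accounting

The per-EPSP charge uses the exact conductance integral of the alpha
synapse, Q = g_max tau e (E_rev - V): 0.34 pC at V = -50 mV, the
loom-representative depolarized potential (the averaging potential is a
convention; -50 mV reproduces the published per-event value and is
consistent with the simulated dendritic envelope). The loom budget follows
as 80,000 x 0.34 pC = 27 nC = 1.7e11 monovalent ions (Q/e). Pump
stoichiometry converts ions to ATP: 3 Na+ per ATP for the Na+/K+ pump and
1 Ca2+ (carrying 2e) per ATP for the Na+/Ca2+ exchanger, giving
ATP = (Q/e) [(1-x)/3 + x/2] for a Ca2+ charge fraction x. x is not known;
the default 0.117 is a calibration chosen so the chain lands on the
6e10 ATP figure produced by the independent synapse-count estimate
E_tot = E_syn N_syn N_spk (70,000 ATP/synapse x 26,200 synapses x 32
presynaptic spikes = 5.9e10), and is documented as such, not as a measured
quantity. The two routes agree within 3%. Relocating a fraction f of
excitation to field C saves baseline x f x 0.6 ATP per loom (3.6e10 for
full relocation, half that for an even split). The mean-current helper
assumes a 5.4 s loom, the duration consistent with 27 nC at 5 nA.

An end-to-end check compares the simulation's integrated charge with the
analytic event-count product; they agree within 15% (the simulated
driving force dips below 60 mV near collision, which is also why the
analytic potential is -50 mV rather than rest).

## Imaging analysis

Fluorescence movies (5 Hz, 0.9 um/pixel) are first motion-corrected by
integer-pixel phase correlation against the temporal mean of the
pre-stimulus baseline (frames shifting more than 10% of the frame are
excluded with a warning), then median-filtered with a 3 x 3 window. dF/F
uses the per-pixel mean of the 2 s pre-stimulus baseline; when the
baseline drifts, a per-pixel linear fit is extrapolated and subtracted
instead, normalized by the fit's value at the recording start (the
pre-drift level), which recovers injected step amplitudes exactly.
Non-positive-baseline pixels become NaN and are excluded from ROI means.

ROI metrics follow the experimental conventions: the looming response
window runs from stimulus onset to 1 s after the end of expansion; the
flash peak is the post-flash maximum (within 1.5 s) minus the pre-flash
minimum (within 1 s). The subregion peak-time range (max minus min of
per-subregion peak times) separates sequentially activated, retinotopic
fields from synchronously activated ones.

The retinotopy test computes the per-frame intensity-weighted centroid of
dF/F within a field mask (negative dF/F clipped to zero — centroids need
non-negative mass; zero-mass frames skipped), in um. The null ensemble
randomly redistributes the within-mask pixels independently per frame
(preserving per-frame mass) and recomputes the trajectory; a trajectory is
called retinotopic when its largest per-axis range exceeds the 95th
percentile of the null ensemble's. Correlations between CoM coordinates
and stimulus position are Pearson r per axis; degenerate (zero-variance)
axes report r = 0 with a flag rather than raising mid-pipeline.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
the biology that produced it: stylized crescent (field A) and blob
(field C) masks; a Gaussian activation spot sweeping the mask in register
with a linear stimulus-position track (retinotopic mode) or a single
common time course over the whole mask (uniform mode); static
multiplicative texture standing in for uneven dye fill (it cancels in
dF/F but gives registration real structure); additive Gaussian pixel
noise; optional linear baseline drift and frame-wise integer translation
("breathing"). Paired ON/OFF movies embed a prescribed peak-response
ratio for recovery tests, and the reference event-set generator draws
exact event counts from the looming angular-velocity density
theta_dot ~ a/(t^2 + a^2) by inverse-CDF sampling. Every generator
returns its ground truth and is a pure function of (spec, seed).

Passing recovery tests on these movies shows the pipeline is correct and
well-conditioned at realistic noise; it does not show robustness to the
things the generator omits — photon shot noise statistics, non-rigid
motion, indicator saturation and buffering kinetics, or anatomically
realistic field shapes.

## Problem sizes and determinism

Default analysis scale: 600-frame stimulus movies (2.5 s at 240 Hz,
120 x 120 px), 3,600 facets, ~88,000 synaptic events per reference loom,
and a 172-compartment model integrated at dt = 0.02 ms (~3 s of CPU per
loom simulation). The test suite and the acceptance script average over
small seed ensembles (2-10) chosen to keep full runs in minutes on one
core. All randomness flows through explicit seeds; simulations with the
same inputs are bit-reproducible.

## Known limitations

- The reduced morphology reproduces region-level electrotonic relations,
  not the detailed geometry; quantities tied to the full reconstruction
  (e.g. the published 15% clustered-mapping reduction) are reproduced only
  as monotonic trends.
- Channel kinetics are generic HH-style parameterizations tuned at the
  behavior level, not fits to voltage-clamp data.
- The encoder is a phenomenological luminance-change model; it does not
  reproduce photoreceptor/lamina membrane potentials or
  luminance-dependent contrast gain.
- The inhibitory pathway's drive construction, its ON/OFF budget split,
  and its placement within field C are assumptions; only the total budget
  (7,000 events) is constrained.
- The energy chain's Ca2+ charge fraction is calibrated, not measured; all
  downstream ATP figures inherit that convention.
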