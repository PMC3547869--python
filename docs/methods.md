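# Methods

`dictyosc` studies how collective adhesion dynamics of starved
*Dictyostelium discoideum* ensembles show up in electrode impedance. The
experimental situation it models: ~130 amebas on a 250 µm circular gold
electrode (≈3,750 cells/mm²) develop cAMP-driven collective oscillations a
few hours into starvation; the 4 kHz impedance magnitude |Z| spikes
periodically, with the period shrinking from 10–12 min to 6–7 min; and
because TIRF microscopy cannot be performed through the gold electrode,
the impedance and TIRF experiments are *separate* recordings, bridged via
a bright-field channel present in both. Every quantity the package
computes exists to test one question: which optical descriptor of the
ensemble co-oscillates with |Z|, and with what sign.

## The synthetic ensemble

All tests run against a generator with known ground truth rather than
recordings, so every recovery claim is checkable.

**Contact oscillation.** A global phase φ advances as dφ/dt = 2π/T(t)
with T(t) ramping linearly from `period_start_s` (720 s) to
`period_end_s` (390 s) over the run (`duration_s` = 10,800 s = 3 h); the
phase integral uses the trapezoidal rule. Cell *i* carries a fixed phase
offset drawn from N(0, `phase_jitter_sd_rad` = 0.25) and has contact
fraction

    c_i(t) = c_min + (c_max − c_min) · (1 + cos(φ(t) + φ_i)) / 2,

with the gap height the affine decreasing map
h_i = `gap_max_nm` − (`gap_max_nm` − `gap_min_nm`)·c_i. The default gap
range is 80–120 nm: the point of the contact-zone picture is that the
*minimal* cell–substrate distance barely changes while the contact area
does, so the gap modulation is kept mild and roughly centred on the
~100 nm evanescent length scale of TIRF.

**Motion and clustering.** Per 10 s step each cell takes a Gaussian
random-walk kick (`motility_sd_um` = 0.4 per axis) plus a signed
interaction with its nearest neighbour, gated at mid-contact:

* high-contact half-cycle (mean contact > 1/2): an adhesive surge of up
  to `attraction_um` = 2.5 µm/step toward the nearest neighbour, applied
  only to cells not yet in contact and only within a
  `capture_radius_um` = 25 µm range — clusters grow by accretion into
  small groups (maximum observed size ≈ 6–7, matching the handful of
  cells per transient aggregate seen experimentally) rather than one
  collapse;
* low-contact half-cycle: a slow de-adhesion push-off of up to
  `dispersal_um` = 0.4 µm/step, applied only to cells still near
  contact. The speed asymmetry is deliberate: forming a contact requires
  covering the inter-cell distance (µm to tens of µm), breaking one
  requires only ~1 µm of separation. With both responses prompt, the
  isolated-cell count stays in phase with the contact oscillation
  (minima within 10% of a period of the contact maxima; a purely
  attraction-proportional rule lags by 80–100 s, which is 20%+ of the
  late-run period).

Hard-disc non-overlap is enforced by iterative pairwise push-apart;
cells are confined to the electrode. Cluster membership is the connected
component of the contact graph (centre distance ≤ 2r + `contact_tol_um`,
1 µm). Initial placement is dart-throwing with 2 µm edge-to-edge
clearance. Cell number is conserved.

**Impedance forward model.**

    |Z|(t) = Z₀·[1 + w_h·(h_ref/h̄(t) − 1) + w_c·(R_net(t)/R_ref − 1)]
               ·(1 + drift·t) + ε(t),

sampled at 0.7 Hz. h̄ is the ensemble-mean gap with h_ref the gap at
half-contact; a narrower mean cleft raises |Z| (current squeezed through
a thinner film). R_net is the 1-D ladder resistance (below) of the
canonical arrangement built from the instantaneous cluster-size
distribution, R_ref that of the all-singleton arrangement, so clustering
also raises |Z|. Defaults w_h = 0.25, w_c = 0.05 put the detrended
oscillation at ~15% of baseline (the experimental amplitude is "well
beyond 10%"); drift is −10⁻⁵/s (impedance slowly decreases over hours)
and ε is white Gaussian with sd 0.5% of Z₀.

Note one deliberate nonlinearity: |Z| is convex (through 1/h̄) in the
contact fraction while the TIRF intensity is exactly linear in it, so
even noise-free the two correlate at ≈0.995, not 1. This is a property
of the physics-style forward model, not an artifact.

**TIRF rendering** follows the contact-zone model: cell *i* is a bright
disc of area c_i·πr² at fixed peak brightness, normalized so the summed
foreground intensity is *exactly* proportional to the total contact
area. An optional evanescent mode multiplies the brightness by
exp(−h_i/d_p), d_p = 100 nm; it is off by default because the
contact-zone interpretation, not distance decay, is the mechanism being
modeled.

**Bright-field rendering.** Cells are dark on a bright background: a
fixed rim (depth 0.5 of background) plus an interior whose darkness is
0.1 + 0.1·(1 − c_i) of background — a spread cell fades toward the
background (contrast loss at high contact) while remaining segmentable
through its rim. On top of the slow centroid motion each cell's rendered
outline gyrates deterministically around its centroid with radius
`bf_flicker_um`·c_i (2.5 µm at full contact) at a fixed angular rate and
a random per-cell phase; members of one cluster gyrate coherently. This
models pseudopodial remodeling during spreading and is what makes the
lagged difference image light up during contact spikes. Frames get a
1.2 px Gaussian blur (optics) and pixel noise. The gyration amplitude,
blur and interior-contrast span were calibrated jointly so that the
60 s-lag subtraction trace is a monotone, near-linear readout of the
mean contact fraction; stronger gyration saturates the blurred edge
response and deeper interior modulation adds an anti-phase derivative
term.

**Seeding.** One integer seed, split via `SeedSequence.spawn` into
motion, impedance-noise and pixel-noise streams: rendering never
perturbs the motion, and identical configs give bit-identical output.

## Image analysis

Segmentation: optional top-hat flattening, Otsu threshold on the
inverted frame (auto-detecting whether cells are dark or bright), hole
filling, a size filter at 25% of the nominal cell area, and marker-based
watershed on the smoothed distance transform with marker suppression at
1.4× the nominal cell radius (below the 2r spacing of touching cells,
wide enough that a blurred cell never carries two markers). Perimeters
use the Crofton (4-direction) estimator; circularity is 4πA/P². Crofton
is exact only as a directional average — an axis-aligned or 45°-rotated
square reads ~12% high at any scale, generic orientations within a few
percent — and rasterized discs may exceed circularity 1 by up to
`EPS_RASTER` = 0.10 (worst at radii ≲5 px).

Dense clusters are not per-cell resolvable (the original experimenters
made the same observation about their automated contours), so each label
carries an *estimated cell count*: its area divided by a single-cell
reference area measured once per stack from resolvable singles. The
descriptor N(t) sums these estimates; mean area and circularity average
over single-cell labels only.

Cluster classification: two labels are in contact when they come within
`contact_tol_px` (1) pixels along at least `min_contact_px` pixel pairs.
The function default is 1 pair (any touch); the pipeline's stack
analysis uses 17 pairs — a contact must extend over a few µm of shared
boundary ("conformal contact") — because with ~1 µm pixels and blurred
outlines, grazing proximity otherwise reads as contact (with the
permissive setting the image isolated count collapsed to ~40% of ground
truth; with 17 it tracks truth at ρ ≈ 0.98). N_s is the number of
single-cell components.

The BF-subtraction series sums |frame(t) − frame(t − 60 s)| with
nearest-earlier pairing and samples stamped at the later frame; the
pipeline re-stamps at the pair midpoint before correlating, removing the
systematic lag/2 phase delay.

## Signal analysis

* Detrending: centred moving average with symmetrically shrinking edge
  windows (full-length output); the canonical window is 800 points at
  0.7 Hz ≈ 19 min, and the pipeline converts that timescale to points at
  each trace's own sampling rate. The mean is subtracted before the
  running sums so constants detrend to exact zero.
* Correlation: population-moment Pearson coefficient; zero variance is
  an error, never reported as 0; NaN samples are dropped pairwise.
* Autocorrelation: biased (1/n) estimator, normalized to 1 at lag 0;
  the dominant period is the first side maximum.
* Peak detection: `scipy.signal.find_peaks` with prominence
  k × MAD (k = 3) and 240 s minimum separation. The MAD-based default
  targets spiky detrended traces; for a clean sinusoid MAD ≈ 0.7 of the
  amplitude, so such signals need an explicit lower k.
* Stretch search: grid 0.5–3.0 in steps of 0.01 (grid values rounded so
  1.0 is exact); for each factor the second series' time axis is
  scaled, both are linearly resampled onto the coarser interval over
  their overlap, and the Pearson coefficient recorded. Linear
  resampling of a T = 360 s sinusoid from a 10 s grid carries a
  worst-case error of (dt²/8)(2π/T)² ≈ 3.8 × 10⁻³ of the amplitude.

The descriptor-correlation report takes an explicit oscillatory-window
argument; the pipeline default is the span of prominent impedance spikes
padded by one median interval. The optional uncertainty per coefficient
is a moving-block bootstrap (it accounts for serial correlation, and is
labeled as such — not as a reproduction of any published error bar).

## The 1-D cluster-resistance model

A row of M sites, covered (cell plaque) or open. One cleft node per
site: electrode→cleft via R_iface; cleft→bulk via R_open (open) or
R_block ≫ R_open (covered); adjacent clefts via R_lat when either site
is covered, and via an ideal short when both are open (two open sites
share the unobstructed bulk — this also makes R_lat the *only*
arrangement-sensitive element: with R_lat = 0 every arrangement at equal
coverage gives identical resistance). Open boundaries. The two-terminal
resistance is the grounded Kirchhoff solve after contracting
zero-resistance edges, so ideal shorts are exact, and `inf` is returned
when no conducting path exists.

At fixed coverage, merging covered runs lengthens lateral paths and
never decreases the resistance (verified exhaustively on ≤12 sites
against an independent Laplacian-pseudoinverse solver). Defaults
R_iface = 1, R_open = 0.1, R_lat = 1, R_block = 10⁶ Ω are a calibration:
regrouping dimers into trimers at coverage 1/2 changes R by +9.4%, the
order of the observed impedance oscillation amplitude. The 2-D→1-D
bridge (`canonical_arrangement`) lays down sorted cluster sizes as
covered runs separated by single gaps — only the run-length distribution
survives the projection, which is the only feature the ladder consumes.

## What the generator does and does not emulate

It reproduces: the density, sampling rates, shrinking period schedule,
oscillation amplitude, in-phase contact/TIRF/impedance structure,
anti-phase isolated-cell count, weakly correlated cell-number
fluctuation (counts fluctuating in the high-120s–130s), reversible
small-cluster formation, and the two-experiment bridging geometry with a
controllable period ratio.

It does not emulate: cAMP reaction–diffusion or spiral waves, real cell
shapes or shape change (circularity in rendered frames varies only
through rasterization and cluster contact, so its correlation with
impedance is an artifact of clustering, not a model of cringing),
fluorescence photophysics, electrode electrochemistry, or instrument
drift structure beyond a linear trend. Passing tests demonstrate that
the *analysis* recovers known ground truth under realistic geometry and
noise — not that the biological mechanism is as modeled.

## Problem sizes and determinism

The default run is 3 h at 10 s frames (1,081 frames, 270×270 px at
1 µm/px) and 0.7 Hz impedance (7,561 samples); the bridging scenario
uses two 2 h runs. These sizes keep a full test-suite pass and the
reproduction script in the minutes range while leaving ≥19 oscillation
periods for interval statistics. All randomness flows from the single
config seed; re-running a manifest reproduces every CSV byte for byte.
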