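"""Synthetic ensemble of oscillating, clustering amebas on an electrode.

Ground truth first, observables second. :func:`simulate_ensemble` evolves a
small ensemble of cells (default: 130 cells on a 250 µm circular electrode,
i.e. ~3,750 cells/mm²) whose cell–substrate contact oscillates collectively
with a period that shortens over the run (default 12 min down to 6.5 min,
the range seen in starvation-induced cAMP chemotaxis), and whose lateral
motion alternates between diffusive dispersal and contact-gated mutual
attraction, producing reversible 2-D clustering in phase with the contact
oscillation.

From that ground truth three observables are rendered with known forward
models:

* :func:`forward_impedance` — an ECIS-like |Z| trace sampled at 0.7 Hz:
  contact up -> mean cell–substrate gap down -> impedance up, plus a
  clustering term through the 1-D ohmic ladder of
  :mod:`dictyosc.cluster_model`, multiplicative linear drift and additive
  Gaussian noise;
* :func:`render_bf_stack` — bright-field-like frames every 10 s in which a
  cell's interior contrast *fades* as its contact grows (intensity gain in
  TIRF corresponds to contrast loss in bright field);
* :func:`render_tirf_stack` — TIRF-like frames in which each cell is a
  bright plaque of *area* proportional to its contact fraction at fixed
  peak brightness (contact-zone model; an evanescent-decay mode
  ``exp(-h/d_p)`` is available but off by default).

All randomness flows from a single integer seed, split hierarchically into
independent streams (placement/motion, impedance noise, pixel noise) so
that toggling rendering never changes the motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .cluster_model import NetworkParams, canonical_arrangement, effective_resistance
from .imagestack import ImageStack
from .timeseries import TimeSeries

__all__ = [
    "SimulationConfig",
    "EnsembleState",
    "GroundTruth",
    "simulate_ensemble",
    "forward_impedance",
    "render_bf_stack",
    "render_tirf_stack",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic recording. Units in field names.

    The defaults are the study conditions: a 250 µm circular electrode
    carrying 130 cells, impedance sampled at 0.7 Hz, imaging every 10 s,
    oscillation period shrinking linearly from 12 min to 6.5 min over a
    3 h run, impedance oscillation amplitude of order 10% of the baseline
    with a slow negative drift.
    """

    electrode_diameter_um: float = 250.0
    n_cells: int = 130
    cell_radius_um: float = 5.0
    period_start_s: float = 720.0
    period_end_s: float = 390.0
    phase_jitter_sd_rad: float = 0.25
    contact_min: float = 0.0
    contact_max: float = 1.0
    gap_min_nm: float = 80.0
    gap_max_nm: float = 120.0
    impedance_base_ohm: float = 10_000.0
    weight_distance: float = 0.25
    weight_cluster: float = 0.05
    drift_rate_per_s: float = -1.0e-5
    noise_sd: float = 0.005
    ecis_dt_s: float = 1.0 / 0.7
    frame_dt_s: float = 10.0
    duration_s: float = 10_800.0
    pixel_size_um: float = 1.0
    rng_seed: int = 0

    # motion model (exposed, with defaults tuned on the default ensemble)
    motility_sd_um: float = 0.4          # random-walk step sd per frame step
    attraction_um: float = 2.5           # max adhesive step toward nearest neighbor
    dispersal_um: float = 0.4            # max migration step away from neighbor
    capture_radius_um: float = 25.0      # attraction range (nearest neighbor)
    contact_tol_um: float = 1.0          # edge-to-edge distance counting as contact
    init_clearance_um: float = 2.0       # min edge-to-edge clearance at t = 0
    bf_flicker_um: float = 2.5           # outline-gyration radius at full contact
    tirf_evanescent: bool = False        # distance-decay TIRF mode
    tirf_penetration_nm: float = 100.0   # evanescent depth d_p

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        numeric = {
            k: v for k, v in asdict(self).items() if isinstance(v, (int, float))
        }
        for k, v in numeric.items():
            if not np.isfinite(v):
                raise ValueError(f"{k} must be finite, got {v}")
        for k in (
            "electrode_diameter_um", "cell_radius_um", "period_start_s",
            "period_end_s", "gap_min_nm", "gap_max_nm", "impedance_base_ohm",
            "ecis_dt_s", "frame_dt_s", "duration_s", "pixel_size_um",
        ):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.contact_min < self.contact_max <= 1.0:
            raise ValueError("need 0 <= contact_min < contact_max <= 1")
        if self.gap_min_nm >= self.gap_max_nm:
            raise ValueError("gap_min_nm must be below gap_max_nm")
        if self.period_end_s > self.period_start_s:
            raise ValueError("period_end_s must not exceed period_start_s")
        if self.duration_s < self.period_start_s:
            raise ValueError("duration_s must cover at least one period")
        area = np.pi * (self.electrode_diameter_um / 2) ** 2
        if self.n_cells * np.pi * self.cell_radius_um**2 >= area:
            raise ValueError("cells do not fit on the electrode")

    # ------------------------------------------------------------- I/O
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def period_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous period T(t): linear ramp start -> end over the run."""
        frac = np.clip(np.asarray(t, dtype=float) / self.duration_s, 0.0, 1.0)
        return self.period_start_s + (self.period_end_s - self.period_start_s) * frac


@dataclass
class EnsembleState:
    """Per-cell ground truth at one time step."""

    time_s: float
    global_phase_rad: float
    x_um: np.ndarray
    y_um: np.ndarray
    contact_fraction: np.ndarray
    gap_height_nm: np.ndarray
    footprint_radius_um: np.ndarray
    cluster_id: np.ndarray


@dataclass
class GroundTruth:
    """Full trajectory of the ensemble plus derived true traces."""

    config: SimulationConfig
    time_s: np.ndarray                 # (n_t,)
    global_phase_rad: np.ndarray       # (n_t,)
    positions_um: np.ndarray           # (n_t, n_cells, 2)
    contact_fraction: np.ndarray       # (n_t, n_cells)
    gap_height_nm: np.ndarray          # (n_t, n_cells)
    cluster_id: np.ndarray             # (n_t, n_cells) int
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.time_s.size

    def state(self, k: int) -> EnsembleState:
        return EnsembleState(
            time_s=float(self.time_s[k]),
            global_phase_rad=float(self.global_phase_rad[k]),
            x_um=self.positions_um[k, :, 0],
            y_um=self.positions_um[k, :, 1],
            contact_fraction=self.contact_fraction[k],
            gap_height_nm=self.gap_height_nm[k],
            footprint_radius_um=np.full(
                self.config.n_cells, self.config.cell_radius_um
            ),
            cluster_id=self.cluster_id[k],
        )

    # ------------------------------------------------- derived true traces
    def mean_gap_trace(self) -> TimeSeries:
        return TimeSeries(
            self.time_s, self.gap_height_nm.mean(axis=1), "nm", "true_mean_gap"
        )

    def contact_area_trace(self) -> TimeSeries:
        cell_area = np.pi * self.config.cell_radius_um**2
        return TimeSeries(
            self.time_s,
            self.contact_fraction.sum(axis=1) * cell_area,
            "um^2",
            "true_contact_area",
        )

    def cluster_sizes(self, k: int) -> list[int]:
        _, counts = np.unique(self.cluster_id[k], return_counts=True)
        return sorted(counts.tolist(), reverse=True)

    def isolated_count_trace(self) -> TimeSeries:
        ns = np.empty(len(self))
        for k in range(len(self)):
            _, counts = np.unique(self.cluster_id[k], return_counts=True)
            ns[k] = int((counts == 1).sum())
        return TimeSeries(self.time_s, ns, "cells", "true_isolated_count")

    def cluster_count_trace(self) -> TimeSeries:
        nc = np.empty(len(self))
        for k in range(len(self)):
            nc[k] = np.unique(self.cluster_id[k]).size
        return TimeSeries(self.time_s, nc, "clusters", "true_cluster_count")

    def instantaneous_period_trace(self) -> TimeSeries:
        return TimeSeries(
            self.time_s, self.config.period_at(self.time_s), "s", "true_period"
        )

    def traces_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time_s": self.time_s,
                "mean_gap_nm": self.mean_gap_trace().value,
                "contact_area_um2": self.contact_area_trace().value,
                "isolated_count": self.isolated_count_trace().value,
                "cluster_count": self.cluster_count_trace().value,
                "period_s": self.instantaneous_period_trace().value,
            }
        ).to_csv(path, index=False)


# =====================================================================
# simulation
# =====================================================================

def _rngs(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """Independent child streams so rendering never perturbs motion."""
    ss = np.random.SeedSequence(config.rng_seed)
    motion, imp_noise, pix_noise = ss.spawn(3)
    return {
        "motion": np.random.default_rng(motion),
        "impedance": np.random.default_rng(imp_noise),
        "pixels": np.random.default_rng(pix_noise),
    }


def _initial_positions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement inside the electrode with edge clearance."""
    r_max = config.electrode_diameter_um / 2 - config.cell_radius_um
    min_sep = 2 * config.cell_radius_um + config.init_clearance_um
    pos = np.empty((config.n_cells, 2))
    placed = 0
    for _ in range(200_000):
        cand = rng.uniform(-r_max, r_max, size=2)
        if cand @ cand > r_max**2:
            continue
        if placed and np.min(np.hypot(*(pos[:placed] - cand).T)) < min_sep:
            continue
        pos[placed] = cand
        placed += 1
        if placed == config.n_cells:
            return pos
    raise RuntimeError("could not place cells; density too high for the clearance")


def _resolve_overlaps(pos: np.ndarray, min_dist: float, r_max: float, n_iter: int = 8) -> None:
    """Hard-disc constraint: push overlapping pairs apart, keep cells on the electrode."""
    n = pos.shape[0]
    for _ in range(n_iter):
        d = squareform(pdist(pos))
        np.fill_diagonal(d, np.inf)
        ii, jj = np.where(np.triu(d < min_dist, k=1))
        if ii.size == 0:
            break
        for i, j in zip(ii, jj):
            delta = pos[j] - pos[i]
            dist = np.hypot(*delta)
            if dist < 1e-9:
                delta, dist = np.array([1e-3, 0.0]), 1e-3
            push = (min_dist - dist) / 2 * delta / dist
            pos[i] -= push
            pos[j] += push
        radii = np.hypot(pos[:, 0], pos[:, 1])
        out = radii > r_max
        if out.any():
            pos[out] *= (r_max / radii[out])[:, None]


def _cluster_ids(pos: np.ndarray, contact_dist: float) -> np.ndarray:
    """Connected components of the cell-contact graph."""
    d = squareform(pdist(pos))
    adj = csr_matrix(d <= contact_dist)
    _, labels = connected_components(adj, directed=False)
    return labels


def simulate_ensemble(config: SimulationConfig) -> GroundTruth:
    """Evolve the ensemble and return its full ground truth.

    The shared phase advances as dphi/dt = 2*pi/T(t) with T(t) ramping
    linearly from ``period_start_s`` to ``period_end_s``; each cell carries
    a fixed phase offset drawn from N(0, phase_jitter_sd_rad). The contact
    fraction is c_i(t) = c_min + (c_max - c_min) * (1 + cos(phi + phi_i))/2
    and the gap height the affine decreasing map
    h_i = gap_max - (gap_max - gap_min) * c_i.

    Motion: per frame step, a Gaussian random-walk kick plus an attraction
    step toward the nearest neighbor whose length is proportional to the
    ensemble-mean contact fraction (``attraction_um * mean(c)``), with
    hard-disc non-overlap and confinement to the electrode. Clustering
    therefore waxes and wanes in phase with the contact oscillation.
    Deterministic for a given seed.
    """
    config.validate()
    rng = _rngs(config)["motion"]
    n_t = int(np.floor(config.duration_s / config.frame_dt_s)) + 1
    times = np.arange(n_t) * config.frame_dt_s

    # phase integral of 2 pi / T(t), trapezoidal in the rate
    rate = 2 * np.pi / np.asarray(config.period_at(times))
    dphi = 0.5 * (rate[:-1] + rate[1:]) * config.frame_dt_s
    phase = np.concatenate(([0.0], np.cumsum(dphi)))

    offsets = (
        rng.normal(0.0, config.phase_jitter_sd_rad, size=config.n_cells)
        if config.phase_jitter_sd_rad > 0
        else np.zeros(config.n_cells)
    )
    span = config.contact_max - config.contact_min
    contact = config.contact_min + span * 0.5 * (
        1.0 + np.cos(phase[:, None] + offsets[None, :])
    )
    gap = config.gap_max_nm - (config.gap_max_nm - config.gap_min_nm) * contact

    r_max = config.electrode_diameter_um / 2 - config.cell_radius_um
    min_dist = 2 * config.cell_radius_um
    contact_dist = min_dist + config.contact_tol_um

    pos = _initial_positions(config, rng)
    positions = np.empty((n_t, config.n_cells, 2))
    cluster_id = np.empty((n_t, config.n_cells), dtype=int)
    positions[0] = pos
    cluster_id[0] = _cluster_ids(pos, contact_dist)

    attract_on = config.attraction_um > 0
    for k in range(1, n_t):
        kick = rng.normal(0.0, config.motility_sd_um, size=pos.shape)
        pos = pos + kick
        if attract_on and config.n_cells > 1:
            # Signed neighbor interaction gated at mid-contact: adhesive
            # surge toward the nearest neighbor in the spread
            # (high-contact) half-cycle, active migration away in the
            # mobile (low-contact) half-cycle. The approach speed is much
            # larger than the retreat speed because forming a contact
            # requires covering the inter-cell distance while breaking one
            # takes only ~1 um of separation; both respond promptly, so
            # clustering stays in phase with the contact oscillation.
            c_mean = contact[k].mean()
            if c_mean >= 0.5:
                gain = config.attraction_um * 2.0 * (c_mean - 0.5)
            else:
                gain = -config.dispersal_um * 2.0 * (0.5 - c_mean)
            if abs(gain) > 1e-12:
                d = squareform(pdist(pos))
                np.fill_diagonal(d, np.inf)
                nearest = d.argmin(axis=1)
                delta = pos[nearest] - pos
                dist = np.hypot(delta[:, 0], delta[:, 1])
                if gain > 0:
                    # approach, never past hard-disc contact; only free
                    # cells within the capture range respond, so clusters
                    # grow by accretion into small groups instead of
                    # collapsing into one large aggregate
                    step = np.minimum(gain, np.maximum(dist - min_dist, 0.0))
                    step = np.where(
                        (dist > contact_dist) & (dist < config.capture_radius_um),
                        step,
                        0.0,
                    )
                else:
                    # retreat is de-adhesion: only cells still near contact
                    # push off their neighbor, already-free cells just walk
                    step = np.where(
                        dist < contact_dist + 2 * config.contact_tol_um, gain, 0.0
                    )
                good = dist > 1e-9
                pos[good] += (delta[good] / dist[good, None]) * np.broadcast_to(
                    step, dist.shape
                )[good, None]
        radii = np.hypot(pos[:, 0], pos[:, 1])
        out = radii > r_max
        if out.any():
            pos[out] *= (r_max / radii[out])[:, None]
        _resolve_overlaps(pos, min_dist, r_max)
        positions[k] = pos
        cluster_id[k] = _cluster_ids(pos, contact_dist)

    return GroundTruth(
        config=config,
        time_s=times,
        global_phase_rad=phase,
        positions_um=positions,
        contact_fraction=contact,
        gap_height_nm=gap,
        cluster_id=cluster_id,
    )


# =====================================================================
# forward models
# =====================================================================

def forward_impedance(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    network_params: NetworkParams | None = None,
) -> TimeSeries:
    """ECIS-like |Z|(t) rendered from the ground truth.

    |Z|(t) = Z0 * [1 + w_h*(h_ref/hbar(t) - 1) + w_c*(R_net(t)/R_ref - 1)]
                * (1 + drift*t) + noise,

    where hbar is the ensemble-mean gap height (reference: the gap at
    half-contact), and R_net the 1-D ladder resistance of the canonical
    arrangement built from the instantaneous cluster-size distribution
    (reference: the all-singleton arrangement). A narrower mean cleft and a
    more clustered arrangement both raise |Z|. Sampled at ``ecis_dt_s``
    with additive Gaussian noise of relative sd ``noise_sd``; deterministic
    for a given seed.
    """
    if config is None:
        config = truth.config
    if len(truth) == 0:
        raise ValueError("empty ground truth")
    rng = _rngs(config)["impedance"]

    hbar = truth.gap_height_nm.mean(axis=1)
    if np.any(hbar <= 0):
        raise ValueError("mean gap height must stay positive")
    h_ref = 0.5 * (config.gap_min_nm + config.gap_max_nm)

    p = network_params or NetworkParams()
    total_sites = 2 * config.n_cells
    r_ref = effective_resistance(
        canonical_arrangement([1] * config.n_cells, total_sites), p
    )
    cache: dict[tuple, float] = {}
    r_net = np.empty(len(truth))
    for k in range(len(truth)):
        key = tuple(truth.cluster_sizes(k))
        if key not in cache:
            cache[key] = effective_resistance(
                canonical_arrangement(key, total_sites), p
            )
        r_net[k] = cache[key]

    t = np.arange(0.0, config.duration_s + 1e-9, config.ecis_dt_s)
    h_t = np.interp(t, truth.time_s, hbar)
    r_t = np.interp(t, truth.time_s, r_net)
    z = config.impedance_base_ohm * (
        1.0
        + config.weight_distance * (h_ref / h_t - 1.0)
        + config.weight_cluster * (r_t / r_ref - 1.0)
    )
    z = z * (1.0 + config.drift_rate_per_s * t)
    if config.noise_sd > 0:
        z = z + rng.normal(0.0, config.noise_sd * config.impedance_base_ohm, t.size)
    return TimeSeries(t, z, "ohm", "impedance")


def _fov_grid(config: SimulationConfig, margin_um: float = 10.0):
    """Square field of view covering the electrode plus a margin."""
    half = config.electrode_diameter_um / 2 + margin_um
    n_px = int(np.ceil(2 * half / config.pixel_size_um))
    if n_px < 1:
        raise ValueError("pixel size too large for the field of view")
    # pixel-center coordinates in um, origin at electrode center
    coords = (np.arange(n_px) + 0.5) * config.pixel_size_um - half
    return n_px, coords


def _disc_patch(
    n_px: int, coords: np.ndarray, cx: float, cy: float, radius_um: float, px_um: float
) -> tuple[slice, slice, np.ndarray]:
    """Local patch around a disc: slices plus center distance in pixels."""
    ix = np.searchsorted(coords, [cx - radius_um - 2 * px_um, cx + radius_um + 2 * px_um])
    iy = np.searchsorted(coords, [cy - radius_um - 2 * px_um, cy + radius_um + 2 * px_um])
    sx, sy = slice(*np.clip(ix, 0, n_px)), slice(*np.clip(iy, 0, n_px))
    xs, ys = coords[sx], coords[sy]
    dist = np.hypot(ys[:, None] - cy, xs[None, :] - cx) / px_um
    return sy, sx, dist


def _gaussian_blur(frame: np.ndarray, sigma_px: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(frame, sigma_px, mode="nearest")


def _coverage(dist_px: np.ndarray, radius_um: float, px_um: float) -> np.ndarray:
    """Per-pixel disc coverage with a one-pixel linear edge ramp."""
    if radius_um <= 0:
        return np.zeros_like(dist_px)
    return np.clip(radius_um / px_um + 0.5 - dist_px, 0.0, 1.0)


def render_bf_stack(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    background: float = 3000.0,
    rim_depth: float = 0.5,
    interior_depth: float = 0.1,
    interior_floor: float = 0.1,
    blur_sigma_px: float = 1.2,
) -> ImageStack:
    """Bright-field-like frames: dark cells on a bright background.

    Each cell is drawn as a dark rim of fixed depth plus an interior whose
    darkness is ``interior_floor + interior_depth * (1 - c_i(t))`` times
    the background: a cell in full substrate contact almost vanishes into
    the background (contrast loss) while a detached cell is strongly
    contrasted. The fixed rim keeps every cell segmentable at any phase.

    On top of the slow centroid motion, the rendered outline of each cell
    jitters frame to frame by a random sub-cell offset whose amplitude is
    ``bf_flicker_um * c_i(t)`` — the pseudopodial remodeling that makes
    spreading cells churn the difference image, so the lagged
    bright-field-subtraction trace peaks together with the contact (and
    hence impedance) spikes. Gaussian pixel noise of sd
    ``noise_sd * background`` is added last.
    """
    if config is None:
        config = truth.config
    if config.pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    rng = _rngs(config)["pixels"]
    n_px, coords = _fov_grid(config)
    px = config.pixel_size_um
    r_cell = config.cell_radius_um
    rim_width_um = max(px, 0.15 * r_cell)

    # Per-frame outline gyration: each cell's rendered outline circles its
    # true centroid with radius bf_flicker_um * c_i(t) at a fixed angular
    # rate and a random per-cell phase — pseudopodial remodeling whose
    # frame-to-frame displacement is deterministic in magnitude, so the
    # lagged difference image reads out the contact fraction cleanly.
    if config.bf_flicker_um > 0:
        gyr_rate = 2.4  # rad per frame step, incommensurate with the lag
        cell_phase = rng.uniform(0, 2 * np.pi, config.n_cells)
        # cells in conformal contact remodel coherently: every member of a
        # cluster gyrates with the phase of the cluster's lowest-index cell,
        # so rendered contacts are not torn open by independent offsets
        phase = np.empty((len(truth), config.n_cells))
        for k in range(len(truth)):
            cid = truth.cluster_id[k]
            rep = {c: np.min(np.where(cid == c)[0]) for c in np.unique(cid)}
            phase[k] = cell_phase[[rep[c] for c in cid]]
        theta = gyr_rate * np.arange(len(truth))[:, None] + phase
        amp = config.bf_flicker_um * truth.contact_fraction
        flicker = np.stack([amp * np.cos(theta), amp * np.sin(theta)], axis=-1)
    else:
        flicker = np.zeros((len(truth), config.n_cells, 2))

    frames = np.empty((len(truth), n_px, n_px), dtype=np.float32)
    for k in range(len(truth)):
        frame = np.full((n_px, n_px), background, dtype=np.float64)
        for i in range(config.n_cells):
            cx, cy = truth.positions_um[k, i] + flicker[k, i]
            sy, sx, dist = _disc_patch(n_px, coords, cx, cy, r_cell, px)
            if dist.size == 0:
                continue
            cov = _coverage(dist, r_cell, px)
            cov_in = _coverage(dist, r_cell - rim_width_um, px)
            rim = cov - cov_in
            interior = interior_floor + interior_depth * (
                1.0 - truth.contact_fraction[k, i]
            )
            depth = background * (rim_depth * rim + interior * cov_in)
            patch = frame[sy, sx]
            np.minimum(patch, background - depth, out=patch)
        if blur_sigma_px > 0:
            # optical point-spread blur; also keeps the edge response
            # linear for sub-pixel outline displacements
            frame = _gaussian_blur(frame, blur_sigma_px)
        if config.noise_sd > 0:
            frame = frame + rng.normal(0.0, config.noise_sd * background, frame.shape)
        frames[k] = frame
    return ImageStack(frames, truth.time_s.copy(), px, role="bf")


def render_tirf_stack(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    background: float = 100.0,
    peak_brightness: float = 3000.0,
) -> ImageStack:
    """TIRF-like frames: bright contact plaques on a dark background.

    Contact-zone model: cell i is a disc of area c_i * pi * r^2 at fixed
    peak brightness, so the summed frame intensity is background plus a
    term exactly proportional to the total contact area. With
    ``tirf_evanescent`` the brightness is additionally scaled by
    exp(-h_i / d_p) (d_p = ``tirf_penetration_nm``), trading the pure
    proportionality for an explicit distance dependence.
    """
    if config is None:
        config = truth.config
    if config.pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    rng = _rngs(config)["pixels"]
    # keep the pixel stream aligned with the BF render: draw from a child
    rng = np.random.default_rng(rng.integers(0, 2**31))
    n_px, coords = _fov_grid(config)
    px = config.pixel_size_um
    r_cell = config.cell_radius_um
    px_area = px * px

    frames = np.empty((len(truth), n_px, n_px), dtype=np.float32)
    for k in range(len(truth)):
        frame = np.full((n_px, n_px), background, dtype=np.float64)
        for i in range(config.n_cells):
            c = truth.contact_fraction[k, i]
            if c <= 0:
                continue
            radius = r_cell * np.sqrt(c)
            cx, cy = truth.positions_um[k, i]
            sy, sx, dist = _disc_patch(n_px, coords, cx, cy, radius, px)
            cov = _coverage(dist, radius, px)
            mass = cov.sum()
            if mass <= 0:
                continue
            bright = peak_brightness
            if config.tirf_evanescent:
                bright *= np.exp(
                    -truth.gap_height_nm[k, i] / config.tirf_penetration_nm
                )
            # normalize so the integrated foreground is exactly
            # brightness * (disc area / pixel area): intensity strictly
            # proportional to the contact fraction
            target = bright * np.pi * radius**2 / px_area
            frame[sy, sx] += cov * (target / mass)
        if config.noise_sd > 0:
            frame = frame + rng.normal(0.0, config.noise_sd * background, frame.shape)
        frames[k] = frame
    return ImageStack(frames, truth.time_s.copy(), px, role="tirf")
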