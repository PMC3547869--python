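"""End-to-end orchestration: simulate -> analyze -> correlate -> report.

Stages communicate exclusively through on-disk artifacts (TIFF stacks, CSV
traces, YAML config, JSON summaries), so each stage can be re-run or
replaced independently. A :class:`RunManifest` snapshots the configuration,
the seed and every artifact path, and is sufficient to reproduce a run
bit-identically.

The bridging workflow mirrors the two-experiment design of the study: the
impedance experiment (opaque gold electrode, no TIRF possible) and the TIRF
experiment (glass substrate, no impedance) each carry a simultaneous
bright-field channel; the two BF-subtraction series are matched by a
time-stretch search, and the recovered factor rescales the TIRF trace onto
the impedance clock so the two can be correlated.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imagestack import ImageStack
from .image_analysis import (
    SegmentationParams,
    bf_subtraction_series,
    ensemble_descriptors,
    segment_stack,
    tirf_total_intensity,
)
from .signal_analysis import (
    autocorrelation,
    cross_correlation,
    descriptor_correlation_report,
    detect_peaks,
    detrend_moving_average,
    resample_align,
    stretch_factor_search,
)
from .synthetic import (
    SimulationConfig,
    forward_impedance,
    render_bf_stack,
    render_tirf_stack,
    simulate_ensemble,
)
from .timeseries import TimeSeries

__all__ = [
    "RunManifest",
    "run_simulation",
    "rerun_from_manifest",
    "analyze_images",
    "detrend_for",
    "oscillatory_window",
    "run_bridge_workflow",
    "full_report",
]

#: default detrending timescale: 800 points at the 0.7 Hz impedance
#: sampling rate, expressed in seconds so coarser traces use an
#: equivalent window
DETREND_BOX_S = 800 / 0.7


@dataclass
class RunManifest:
    """Snapshot of one simulation run: config, seed, artifact paths."""

    seed: int
    config_path: str
    artifacts: dict = field(default_factory=dict)
    version: str = __version__
    created_unix: float = 0.0

    def write(self, path: str | Path) -> None:
        for name, p in self.artifacts.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest artifact {name!r} missing: {p}")
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def run_simulation(config: SimulationConfig, out_dir: str | Path) -> RunManifest:
    """Simulate the ensemble and write every observable to ``out_dir``.

    Writes ``impedance.csv``, ``truth_traces.csv``, ``bf.tif`` /
    ``tirf.tif`` with timestamp sidecars, ``config.yaml`` and
    ``manifest.json``. Deterministic for a given config (the seed lives in
    the config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_ensemble(config)
    impedance = forward_impedance(truth, config)
    bf = render_bf_stack(truth, config)
    tirf = render_tirf_stack(truth, config)

    config.to_yaml(out / "config.yaml")
    impedance.to_csv(out / "impedance.csv")
    truth.traces_to_csv(out / "truth_traces.csv")
    bf.write(out / "bf.tif")
    tirf.write(out / "tirf.tif")

    manifest = RunManifest(
        seed=config.rng_seed,
        config_path=str(out / "config.yaml"),
        artifacts={
            "impedance": str(out / "impedance.csv"),
            "truth_traces": str(out / "truth_traces.csv"),
            "bf_stack": str(out / "bf.tif"),
            "bf_timestamps": str(out / "bf_timestamps.csv"),
            "tirf_stack": str(out / "tirf.tif"),
            "tirf_timestamps": str(out / "tirf_timestamps.csv"),
        },
        created_unix=time.time(),
    )
    manifest.write(out / "manifest.json")
    return manifest


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> RunManifest:
    """Re-run a simulation from its manifest (bit-identical CSV output)."""
    manifest = RunManifest.read(manifest_path)
    config = SimulationConfig.from_yaml(manifest.config_path)
    return run_simulation(config, out_dir)


def analyze_images(
    bf: ImageStack | None,
    tirf: ImageStack | None,
    seg_params: SegmentationParams | None = None,
    bf_lag_s: float = 60.0,
) -> dict[str, TimeSeries]:
    """Extract every image-derived descriptor trace from the stacks.

    From the BF stack: segmentation descriptors N, A_mean, A_total, C_mean,
    Ns and the BF-subtraction series; from the TIRF stack: the total
    intensity trace. Either stack may be None.

    The default segmentation parameters require a conformal contact of at
    least 17 shared-boundary pixel pairs before two cells count as
    clustered: with ~1 um pixels and optically blurred cell outlines,
    grazing proximity otherwise reads as contact.
    """
    if seg_params is None:
        seg_params = SegmentationParams(min_contact_px=17)
    traces: dict[str, TimeSeries] = {}
    if bf is not None:
        segs = segment_stack(bf, seg_params)
        traces.update(ensemble_descriptors(segs))
        if bf.time_s[-1] - bf.time_s[0] > bf_lag_s:
            traces["BF_sub"] = center_on_pair_midpoint(
                bf_subtraction_series(bf, bf_lag_s)
            )
    if tirf is not None:
        traces["TIRF"] = tirf_total_intensity(tirf)
    if not traces:
        raise ValueError("no stack given")
    return traces


def write_descriptor_csv(traces: dict[str, TimeSeries], path: str | Path) -> None:
    """Descriptor traces sharing the frame time base as one CSV table."""
    frame_keys = [k for k in ("N", "A_mean", "A_total", "C_mean", "Ns") if k in traces]
    if not frame_keys:
        raise ValueError("no frame-based descriptors to write")
    t = traces[frame_keys[0]].time_s
    cols = {"time_s": t}
    rename = {"A_mean": "A_um2", "A_total": "A_total_um2"}
    for k in frame_keys:
        cols[rename.get(k, k)] = traces[k].value
    pd.DataFrame(cols).to_csv(path, index=False)


def center_on_pair_midpoint(sub: TimeSeries) -> TimeSeries:
    """Re-stamp a lagged-subtraction series at the midpoint of each pair.

    The subtraction of frames at t and t - lag estimates change around
    t - lag/2 although the sample is stamped at t; shifting the time axis
    back by half the (median effective) lag removes the systematic phase
    delay before correlating against instantaneous traces.
    """
    lags = sub.meta.get("effective_lag_s")
    shift = float(np.median(lags)) / 2 if lags is not None else 0.0
    out = TimeSeries(sub.time_s - shift, sub.value, sub.units, sub.label)
    out.meta = dict(sub.meta)
    return out


def detrend_for(ts: TimeSeries, box_s: float = DETREND_BOX_S) -> TimeSeries:
    """Moving-average detrend with the window given as a timescale.

    Converts ``box_s`` to points at the series' own sampling interval
    (clipped to the series length), so the impedance at 0.7 Hz gets the
    canonical 800-point box and a 10 s frame trace an equivalent window.
    """
    ts = ts.dropna()
    box = int(round(box_s / ts.median_dt_s))
    box = max(3, min(box, len(ts)))
    return detrend_moving_average(ts, box)


def oscillatory_window(
    detrended_impedance: TimeSeries,
    min_separation_s: float = 240.0,
    prominence_k: float = 3.0,
) -> tuple[float, float]:
    """Span where the detrended impedance shows prominent spikes.

    First-to-last detected peak, padded by one peak interval on each side;
    falls back to the full record when fewer than two peaks are found.
    """
    train = detect_peaks(detrended_impedance, min_separation_s, prominence_k)
    if len(train) < 2:
        return float(detrended_impedance.time_s[0]), float(detrended_impedance.time_s[-1])
    pad = float(np.median(train.intervals_s))
    return (
        max(float(detrended_impedance.time_s[0]), train.peak_times_s[0] - pad),
        min(float(detrended_impedance.time_s[-1]), train.peak_times_s[-1] + pad),
    )


def run_bridge_workflow(
    ecis_run_dir: str | Path,
    tirf_run_dir: str | Path,
    out_path: str | Path | None = None,
    factors: np.ndarray | None = None,
    box_s: float = DETREND_BOX_S,
    seg_params: SegmentationParams | None = None,
    bf_lag_s: float = 60.0,
) -> dict:
    """Bridge an impedance run and a TIRF run via their BF channels.

    Loads impedance + BF stack from ``ecis_run_dir`` and TIRF + BF stack
    from ``tirf_run_dir``, computes both BF-subtraction series, detrends
    all four traces, estimates the period ratio by a stretch-factor search
    on the two BF-subtraction series, rescales the TIRF-side time axes by
    that factor, and reports rho(impedance, BF_ecis), rho(TIRF, BF_tirf)
    and rho(impedance, rescaled TIRF). When the rescaled traces no longer
    overlap the correlation is reported as None rather than a number.
    """
    ecis_dir, tirf_dir = Path(ecis_run_dir), Path(tirf_run_dir)
    impedance = TimeSeries.from_csv(ecis_dir / "impedance.csv", "ohm", "impedance")
    bf_e = ImageStack.read(ecis_dir / "bf.tif", role="bf")
    bf_t = ImageStack.read(tirf_dir / "bf.tif", role="bf")
    tirf = tirf_total_intensity(ImageStack.read(tirf_dir / "tirf.tif", role="tirf"))

    sub_e = center_on_pair_midpoint(bf_subtraction_series(bf_e, bf_lag_s))
    sub_t = center_on_pair_midpoint(bf_subtraction_series(bf_t, bf_lag_s))

    z_d = detrend_for(impedance, box_s)
    tirf_d = detrend_for(tirf, box_s)
    sub_e_d = detrend_for(sub_e, box_s)
    sub_t_d = detrend_for(sub_t, box_s)

    factor, curve = stretch_factor_search(sub_e_d, sub_t_d, factors)

    def _rho(a: TimeSeries, b: TimeSeries):
        try:
            ga, gb = resample_align(a, b)
            return cross_correlation(ga, gb)
        except ValueError:
            return None

    tirf_rescaled = TimeSeries(
        tirf_d.time_s * factor, tirf_d.value, tirf_d.units, "tirf_rescaled"
    )
    r_z_bfe = _rho(z_d, sub_e_d)
    r_t_bft = _rho(tirf_d, sub_t_d)
    r_z_tirf = _rho(z_d, tirf_rescaled)

    report = {
        "stretch_factor": factor,
        "rho_impedance_bf_ecis": None if r_z_bfe is None else r_z_bfe.rho,
        "rho_tirf_bf_tirf": None if r_t_bft is None else r_t_bft.rho,
        "rho_impedance_tirf_rescaled": None if r_z_tirf is None else r_z_tirf.rho,
        "n_overlap_impedance_tirf": 0 if r_z_tirf is None else r_z_tirf.n_overlap,
    }
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        out_path.write_text(json.dumps(report, indent=2))
        curve.to_csv(out_path.with_suffix(".curve.csv"), index=False)
    return report


def full_report(
    run_dir: str | Path,
    out_dir: str | Path | None = None,
    box_s: float = DETREND_BOX_S,
    seg_params: SegmentationParams | None = None,
    window_s: tuple[float, float] | None = None,
    make_plots: bool = True,
    n_bootstrap: int = 0,
) -> dict:
    """Descriptor-correlation report for one completed run directory.

    Detrends the impedance and every image descriptor, restricts the
    analysis to the oscillatory window (explicit ``window_s`` or the
    span of prominent impedance spikes), and emits the correlation table,
    the impedance peak-interval series, autocorrelations and (optionally)
    aligned-trace plots. All numbers also land in ``report.json``.
    Missing stage outputs produce a partial report with explicit gaps.
    """
    run_dir = Path(run_dir)
    out = Path(out_dir) if out_dir is not None else run_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    gaps: list[str] = []

    imp_path = run_dir / "impedance.csv"
    if not imp_path.exists():
        raise FileNotFoundError(f"no impedance trace in {run_dir}")
    impedance = TimeSeries.from_csv(imp_path, "ohm", "impedance")
    z_d = detrend_for(impedance, box_s)

    traces: dict[str, TimeSeries] = {}
    bf_path, tirf_path = run_dir / "bf.tif", run_dir / "tirf.tif"
    bf = ImageStack.read(bf_path, role="bf") if bf_path.exists() else None
    tirf = ImageStack.read(tirf_path, role="tirf") if tirf_path.exists() else None
    if bf is None:
        gaps.append("bf_stack")
    if tirf is None:
        gaps.append("tirf_stack")
    if bf is not None or tirf is not None:
        traces = analyze_images(bf, tirf, seg_params)
        write_descriptor_csv(
            {k: v for k, v in traces.items() if k in ("N", "A_mean", "A_total", "C_mean", "Ns")},
            out / "descriptors.csv",
        )

    if window_s is None:
        window_s = oscillatory_window(z_d)

    detrended = {}
    for name, ts in traces.items():
        try:
            detrended[name] = detrend_for(ts, box_s)
        except ValueError:
            gaps.append(f"descriptor:{name}")
    # fluctuation traces are the detrended ones; correlate each with impedance
    table = descriptor_correlation_report(
        z_d, detrended, window_s=window_s, n_bootstrap=n_bootstrap
    )
    table.to_csv(out / "correlations.csv", index=False)

    train = detect_peaks(z_d)
    pd.DataFrame(
        {"peak_time_s": train.peak_times_s, "peak_height": train.peak_heights}
    ).to_csv(out / "impedance_peaks.csv", index=False)

    acfs = {}
    for name, ts in [("impedance", z_d)] + list(detrended.items()):
        try:
            uniform, _ = resample_align(ts, ts)
            acfs[name] = autocorrelation(uniform, max_lag_s=uniform.duration_s / 2)
        except ValueError:
            gaps.append(f"autocorrelation:{name}")
    if acfs:
        lag = next(iter(acfs.values())).time_s
        pd.DataFrame(
            {"lag_s": lag}
            | {k: np.interp(lag, v.time_s, v.value) for k, v in acfs.items()}
        ).to_csv(out / "autocorrelations.csv", index=False)

    if make_plots:
        _plot_aligned(z_d, detrended, window_s, out / "aligned_traces.png")

    report = {
        "window_s": list(window_s),
        "correlations": {
            row["descriptor"]: row["rho"] for _, row in table.iterrows()
        },
        "n_impedance_peaks": int(len(train)),
        "median_peak_interval_s": (
            float(np.median(train.intervals_s)) if len(train) >= 2 else None
        ),
        "gaps": gaps,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _plot_aligned(z_d, detrended, window_s, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(detrended)
    fig, axes = plt.subplots(
        len(names) + 1, 1, figsize=(8, 1.8 * (len(names) + 1)), sharex=True
    )
    axes = np.atleast_1d(axes)
    axes[0].plot(z_d.time_s / 60, z_d.value, lw=0.7, color="C0")
    axes[0].set_ylabel("|Z| detr. (ohm)")
    for ax, name in zip(axes[1:], names):
        ts = detrended[name]
        ax.plot(ts.time_s / 60, ts.value, lw=0.7, color="C1")
        ax.set_ylabel(name)
    for ax in axes:
        ax.axvspan(window_s[0] / 60, window_s[1] / 60, alpha=0.08, color="k")
    axes[-1].set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
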