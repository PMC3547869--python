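# dictyosc

Analysis pipeline for collective cell-contact oscillations of starved
*Dictyostelium discoideum* on small electrodes.

When ~130 starving amebas sit on a 250 µm gold electrode (≈3,750
cells/mm²), cAMP-driven chemotaxis makes the 4 kHz impedance magnitude
|Z| spike periodically, the period shrinking from 10–12 min to 6–7 min
over hours. Two synchronous processes can produce those spikes: the
cells periodically flatten onto the substrate (larger contact zone,
thinner electrolyte cleft under the cell), and they reversibly gather
into small 2-D clusters (longer electrolyte paths under cell groups).
This package provides, as tested, composable pieces:

* a **synthetic-data generator** that simulates such an ensemble with
  known ground truth and renders the three observables an experiment
  would record — an impedance trace, bright-field (BF) frames and TIRF
  frames — so every analysis step can be validated against truth;
* **image analysis**: cell segmentation with physical-unit shape
  descriptors (area A_i, perimeter P_i, circularity C_i = 4πA_i/P_i²),
  per-frame ensemble traces N(t), A(t), ⟨C⟩(t), the isolated-vs-
  clustered classification N_s(t), the lagged BF-subtraction motion
  proxy Σ|I(t) − I(t − 60 s)|, and the total TIRF intensity;
* **signal analysis**: moving-average detrending (canonical box: 800
  points at 0.7 Hz), the cross-correlation coefficient
  ρ_{Z,y} = cov(|Z|, y)/(σ_|Z| σ_y), autocorrelation, spike detection
  with inter-peak intervals, and a time-stretch search that aligns two
  asynchronous experiments by maximizing ρ over a rescaling of one time
  axis;
* a **1-D ohmic cluster model**: insulating cell plaques and conducting
  gaps on a site ladder, solved exactly by nodal analysis, showing that
  at constant coverage a more clustered arrangement has higher
  resistance;
* a **pipeline/CLI** that chains the stages and implements the
  ECIS↔TIRF bridging workflow: BF-subtraction traces from both
  experiments are matched by the stretch search, and the rescaled TIRF
  trace is then correlated with the impedance.

## Worked example

```python
import numpy as np
from dictyosc import (SimulationConfig, simulate_ensemble, forward_impedance,
                      render_tirf_stack, tirf_total_intensity,
                      cross_correlation, resample_align, detect_peaks)
from dictyosc.pipeline import detrend_for

cfg = SimulationConfig(rng_seed=1, duration_s=7200)   # 2 h recording
truth = simulate_ensemble(cfg)
z = detrend_for(forward_impedance(truth, cfg))

spikes = detect_peaks(z)
print(f"impedance spikes: {len(spikes)}, "
      f"median interval {np.median(spikes.intervals_s)/60:.1f} min")

tirf = tirf_total_intensity(render_tirf_stack(truth, cfg))
gz, gt = resample_align(z, detrend_for(tirf))
print(f"rho(|Z|, TIRF intensity) = {cross_correlation(gz, gt).rho:+.2f}")

iso = detrend_for(truth.isolated_count_trace())
gz, gi = resample_align(z, iso)
print(f"rho(|Z|, isolated cells) = {cross_correlation(gz, gi).rho:+.2f}")
```

prints

```
impedance spikes: 12, median interval 8.8 min
rho(|Z|, TIRF intensity) = +0.98
rho(|Z|, isolated cells) = -0.89
```

Reading: across a 2 h run whose oscillation period shrinks from 12 to
~8 min, the detrended impedance spikes 12 times; total TIRF intensity
(proportional to the total cell–substrate contact area) rises and falls
with |Z|, while the number of isolated cells moves opposite to it —
every impedance peak coincides with a clustering maximum. That sign
structure (contact-area proxies positive, isolated count strongly
negative, cell-number fluctuation weakly correlated) is the package's
central qualitative result and mirrors what correlation analysis of
such recordings shows.

The same stages are scriptable from the shell:

```bash
dictyosc simulate --out run/ --seed 1
dictyosc analyze-images --bf run/bf.tif --tirf run/tirf.tif --out traces.csv
dictyosc report --run run/
dictyosc cluster-model --sites 60 --coverage 0.5 --runs 1,2,3,4,6 --out sweep.csv
dictyosc bridge --ecis run_ecis/ --tirf run_tirf/ --out bridge.json
```

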