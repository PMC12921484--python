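# greendose

Dose–response threshold analysis of EEG stress recovery during green-space
exposure.

Short visits to urban green spaces — parks, remnant forests, wetland parks —
measurably reduce physiological stress, but the benefit is not linear in
time: recovery accelerates, then plateaus. `greendose` implements the
physiological-health-effects (PHE) threshold analysis used to quantify that
curve from multichannel EEG: it takes raw recordings of a two-phase session
(stress induction 0–4 min, exposure 4–20 min), extracts relative band-power
indices every 30 s, aggregates them into group-level dose–response
trajectories, and reports per environment and index:

- **Efficiency threshold (ET)** — the exposure time at which recovery
  accelerates: the earliest dose-grid point where the marginal gain `g′(t)`
  reaches `κ·max g′` (default κ = 0.5), with
  `g(t) = d·(f(t) − f(t₀))` the beneficial gain of the fitted index curve
  `f` and `d ∈ {+1, −1}` the index's beneficial direction;
- **Benefit threshold (BT)** — where benefits plateau: the earliest point at
  or after ET with `g(t) ≥ (1 − δ)·max g` (default δ = 0.05);
- **AUC** — the cumulative restoration volume
  `∫ₐᵇ (f(t) − baseline) dt` by the trapezoidal rule over the exposure
  window, baseline = stress-phase mean, so indices that stay below their
  stressed level integrate to a negative area.

Four indices are tracked, from relative band powers over a 4–32 Hz total:
relative α (relaxation, d = +1), relative β (stress, d = −1), β/α
(alertness, d = −1) and relative (α+θ) (cognitive depth, d = +1), with
θ 4–8, α 8–13, β 13–32 Hz.

Because raw participant EEG from field studies is rarely shareable, the
package ships a first-class synthetic-cohort generator: band-limited noise
whose instantaneous band-power composition follows a parameterized
stress→recovery logistic with known ground-truth ET/BT/AUC, plus injected
blink transients, 50 Hz line noise and >±100 μV spikes. Every stage of the
pipeline — 0.16/43 Hz zero-phase band-pass, 50 Hz notch, ICA blink removal,
amplitude rejection, Welch band powers, spline fitting with GCV smoothing,
threshold detection — is validated by recovering that ground truth.

A separate module scores the *visual naturalness* of exposure sites from
pre-labeled panorama segmentation masks (percentage of natural pixels among
natural + man-made, sky and humans excluded, unweighted mean over sampling
points).

## Worked example

```python
from greendose import results_wide_table
from greendose.pipeline import PipelineConfig, analyze_specs, three_environment_specs

specs = three_environment_specs(n_participants=6, seed=1)   # UP, RF, WP cohorts
out = analyze_specs(specs, PipelineConfig(seed=1))
print(results_wide_table(out["results"]).round(2).to_string())
```

prints (also `python examples/threshold_analysis.py`):

```
environment                   RF                   UP                   WP
                          ET_min BT_min    AUC ET_min BT_min    AUC ET_min BT_min    AUC
index           condition
rel_alpha       OE          11.5   17.0   1.35    6.0   11.5   2.32    7.5   13.5   2.09
rel_beta        OE          11.5   17.0  -1.60    5.5   11.0  -3.04    8.0   13.5  -2.66
beta_alpha      OE          11.0   16.0 -11.89    5.0   10.5 -20.88    7.0   12.5 -18.30
rel_alpha_theta OE          11.5   17.0   1.60    5.5   11.0   3.04    8.0   13.5   2.66
```

The three cohorts were simulated with recovery midpoints ordered
UP (8 min) < WP (10 min) < RF (12 min), and the detected thresholds
reproduce that ordering: the urban-park group reaches its efficiency
threshold at 6.0 min of session time and plateaus at 11.5 min, the forest
group roughly four minutes later. Negative AUC for relative β means β power
stayed below its stressed baseline throughout exposure — stress relief.

Other entry points: `examples/simulate_cohort.py` (write a cohort to disk
with its ground-truth sidecar), `examples/recovery_check.py` (estimate vs
truth), `examples/naturalness_scoring.py`, and a CLI
(`greendose simulate|analyze|naturalness|recovery-report --help`).

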