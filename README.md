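# fawave

Mechanochemical analysis of single focal adhesions (FAs) in migrating
cells. Cells on micropillar arrays pull on individual elastomer posts while
a FRET biosensor reports focal adhesion kinase (FAK) activity at the same
adhesions; `fawave` turns such multichannel time-lapse recordings into
per-FA traction forces, FAK activity ratios and size trajectories, and
quantifies how the three are coupled in time and space.

It is written for quantitative cell biologists and image analysts studying
mechanotransduction at adhesions: people who need traction forces from
pillar deflections, ratiometric FRET done carefully (background, spectral
bleed-through), FA tracking with explicit retention rules, and honest
statistics for oscillation periods and lead-lag times.

## What it computes

- **Traction forces** — pillar tops detected sub-pixel, an undeformed
  reference lattice fitted from out-of-cell (unloaded) pillars, and each
  deflection δ converted by Euler–Bernoulli cantilever bending,
  `F = 3EIδ/L³` with `I = πr⁴/4`.
- **FAK activity** — Costes automatic background, subtraction, corrected
  FRET `cFRET = I_FRET − α·I_ECFP − β·I_YPet` (α = 0.175, β = 0.056), and
  the donor/cFRET ratio summarised per FA (median).
- **FA segmentation & tracking** — LoG + 3D median filtering, triangle
  threshold, watershed splitting, a 0.2–20 µm² area gate; LAP linking with
  a 2 µm displacement gate, merge handling, split/over-movement exclusion,
  and retention of tracks spanning ≥ 7 consecutive frames.
- **Dynamics** — per-cell temporal z-scores, per-minute rates, rolling
  5-min force-slope classification (increasing ⇔ slope ≥ 0.01 nN/min),
  autocorrelation periods, and cross-correlation lead-lags with sub-frame
  peak interpolation (positive lag = first series leads).
- **Spatial maps** — migration-frame alignment and time-averaged maps of
  z-scored force, FAK activity and FA size, with leading-edge correlations.
- **Migration** — trajectory speed (path length / duration) and
  straightness (net / total path).
- **Synthetic data** — generators for trace ensembles (shared latent
  oscillation with a configurable lead-lag chain and noise calibrated to
  target correlations in closed form) and for rendered image stacks whose
  channel synthesis inverts the FRET correction exactly — every stage is
  testable against embedded ground truth.

## Worked example

Generate a synthetic ensemble of 100 FAs under untreated-cell conditions
(5-min latent oscillation; force leads FAK by 32 s, FAK leads area by 21 s;
noise calibrated to the correlation triple 0.67/0.61/0.49) and run the
dynamics stage:

```python
from fawave.synthetic import trace_preset, generate_traces
from fawave.pipeline import analyze_traces

cfg = trace_preset("paper_default", n_fas=100, duration_s=1200.0, seed=1)
traces, truth = generate_traces(cfg)
res = analyze_traces(traces, frame_interval_s=10.0)

for pair in ("force:fak", "fak:area", "force:area"):
    s = res["lags"][pair]
    print(f"{pair:>10}: mean lag {s['mean_lag_s']:5.1f} s   "
          f"peak r {s['ensemble_peak_r']:.2f}   (n={s['n']})")
print(f"median force-rate period: {res['period']['median_period_s']/60:.1f} min")
```

prints

```
 force:fak: mean lag  33.1 s   peak r 0.62   (n=100)
  fak:area: mean lag  21.6 s   peak r 0.49   (n=100)
force:area: mean lag  52.1 s   peak r 0.68   (n=100)
median force-rate period: 5.0 min
```

Reading it: the force rate leads the FAK-activity rate by ~33 s and FAK
leads area growth by ~22 s (both recovered within one 10-s frame of the
embedded 32 s and 21 s, despite the lags being sub-frame fractions), the
force→area lag is consistent with the chain sum, the coupling strengths
match the calibrated targets, and the 5-min oscillation period is
recovered from the autocorrelation of the force rate.

The same stages run from the shell:

```bash
fawave simulate traces --preset paper_default --n-fas 100 --seed 1 --out sim/
fawave dynamics --traces sim/traces.csv --frame-interval-s 10 --out results/
fawave simulate stack --preset control --n-fas 10 --seed 2 --out simstack/
fawave run --stack simstack/stack.ome.tiff --out results_stack/
```

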