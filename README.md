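# nfdyn

Simulation and quantification of single-cell NF-κB nuclear-translocation
dynamics from two-channel fluorescence time-lapse movies.

## The problem

When cells are stimulated with lipopolysaccharide (LPS), the transcription
factor NF-κB (p65/RelA) shuttles from cytoplasm to nucleus. Live-cell imaging
of a p65 fluorescent fusion reporter, together with a constitutive nuclear
marker (an H2B fusion) for segmentation and tracking, turns this into a
per-cell time series: the **relative nuclear localization**

    I(t) = mean nuclear reporter intensity at t
           ─────────────────────────────────────
           pre-stimulus mean cytoplasmic intensity

Different LPS preparations (Sigma L4524, Invivogen LPS-EB, and its Ultrapure
form, "UP") drive markedly different single-cell dynamics — different peak
amplitudes, times-to-peak, response durations, potency windows, and
sensitivity to blocking of paracrine TNF signaling with soluble TNF receptor
(sTNFRII).

`nfdyn` provides, as tested, reproducible code:

* **response model** — a phenomenological generator of single-cell traces
  (gamma-shaped pulse + persistent plateau + delayed secondary activation),
  Hill-type fraction-active dose–response, lognormal cell-to-cell
  heterogeneity, transient/persistent/secondary responder classes, and an
  sTNFRII modifier. Shipped presets for the three preparations encode the
  published cross-preparation population statistics (e.g. EB amplitude =
  0.49 × Sigma, EB time-to-peak = 3 × Sigma, the UP time-to-peak series
  52/69/129 min at 5/0.5/0.05 µg/mL).
* **movie simulator** — renders cell populations into noisy two-channel
  TIFF movies (120 frames, 5 min cadence) with exported ground truth,
  conserving reporter between nucleus and cytoplasm per cell.
* **segmentation & tracking** — Otsu + distance-transform watershed nuclear
  segmentation, annular cytoplasmic measurement rings, mutual-nearest-centroid
  tracking with gap closing.
* **trace features** — per-cell activity call, peak amplitude, time-to-peak,
  width at half maximum, secondary-activation count.
* **population analysis** — fraction-active dose–response curves, average
  time courses of active cells, cosine-distance similarity matrices between
  conditions, and ±sTNFRII cosine distances.
* **pipeline & CLI** — staged, seed-reproducible runs with standard-format
  intermediates (TIFF/CSV/JSON).

## Worked example

Simulate one field of 30 cells stimulated with the Sigma preset at
0.5 µg/mL, run the full measurement pipeline on the rendered movie, and
summarize the recovered population:

```python
from nfdyn import (
    ImagingConfig, SegmentationConfig, simulate_condition, analyze_movie,
    default_presets, summarize_condition,
)
from nfdyn.population import default_grid

presets = default_presets()
cfg = ImagingConfig(height=256, width=256, nucleus_semi_axes=(5, 7), cyto_extent=9)
movie, truth = simulate_condition(presets["Sigma"], 0.5, False, 30, cfg, seed=1)
labels, tracks, traces, table = analyze_movie(movie, SegmentationConfig(min_peak_distance=5))
summary = summarize_condition("Sigma", 0.5, False, traces, table, default_grid())
print(f"active cells: {summary.n_active}/{summary.n_total} "
      f"(fraction {summary.fraction_active:.2f})")
for k, v in summary.feature_means.items():
    print(f"mean {k}: {v:.2f} (sd {summary.feature_sds[k]:.2f})")
```

prints

```
active cells: 30/30 (fraction 1.00)
mean peak_amp: 1.89 (sd 0.20)
mean time_to_peak: 46.33 (sd 12.59)
mean peak_width: 91.47 (sd 24.51)
```

At this saturating concentration every cell responds (the Sigma preset's
half-activation concentration is 10⁻⁴ µg/mL). The mean measured peak is
1.89× the pre-stimulus cytoplasmic level, reached ~46 min after stimulation,
and the response stays above half maximum for ~91 min — the pipeline's
estimates of the preset's central parameters (peak 1.9, time-to-peak
47.6 min, width 90 min) from a noisy rendered movie.

The same stages are available from the shell:

```sh
nfdyn simulate --preset Sigma --conc 0.5 --cells 30 --seed 1 --out out/movie.tif
nfdyn run-all --config config.yaml --seed 1 --out out/ --plots
```

`run-all` persists every intermediate (movies, label stacks, tracks, traces,
features, condition summaries, similarity matrices) and a resolved-config
snapshot, so a run is exactly repeatable and any stage can be re-run from the
previous one's files.

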