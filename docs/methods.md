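# Methods

This note documents the models, conventions and numerical choices behind
`nfdyn`. Times are minutes, concentrations µg/mL, intensities dimensionless
(normalized to the pre-stimulus cytoplasmic mean) unless stated otherwise.

## Single-cell trace model

The measured quantity is the relative nuclear localization of the p65
reporter, I(t) = (nuclear mean) / (pre-stimulus cytoplasmic mean). The
generator models one cell's trace as

    I(t) = b                                             t < 0
    I(t) = b + A·(t/τ)^s·exp(s·(1 − t/τ))                primary pulse
             + P·(1 − exp(−t/τ_p))                       plateau
             + A2·r(t − t2)·exp(−(t − t2)/λ)             secondary, t ≥ t2

with r(u) = 1 − exp(−u/5 min) a fast rise keeping the trace continuous at
the secondary onset (for u ≫ 5 min the term is a plain exponential decay;
the effective secondary peak is ≈ 0.75·A2, which the class presets
compensate). This family was chosen because it controls the four measured
quantities independently: baseline b, peak amplitude A (the pure pulse peaks
at exactly b + A at t = τ), time-to-peak τ, and width at half maximum via
the shape s. The plateau term produces persistent responders, the delayed
term secondary activations. It is phenomenological — no IKK/IκB mechanism is
implied — and is not intended for fitting to real data.

**Width ↔ shape.** The pure pulse crosses half maximum where
ln x + 1 − x = −ln 2 / s (x = t/τ); the two roots are Lambert-W branches, so
width(τ, s) = τ·(x₂ − x₁) is closed-form and monotone decreasing in s.
`solve_shape_for_width` inverts this by bracketed root finding (tolerance
well under the 0.1 min contract). Any positive width is feasible (s → 0
flattens the pulse without bound); requests narrower than the s = 10⁶ limit
raise an error naming the feasible range. The pulse itself is evaluated in
log space, exp(s·(ln x + 1 − x)), to avoid overflow of x^s at large s.

## Population structure

**Dose–response.** The probability that a cell responds at concentration c
is Hill-shaped: p(c) = pmax·cʰ/(cʰ + Kʰ), evaluated as pmax/(1 + (K/c)ʰ)
for stability over nine decades; p(0) = 0. Preset parameters (pmax = 0.95
for all; Sigma K = 10⁻⁴, h = 1; EB K = 10⁻⁸, h = 0.7; UP K = 0.15, h = 1.2)
place Sigma's potency window near 5·10⁻⁴–5·10⁻³ µg/mL, UP's at 0.5–5 µg/mL
with essentially no response at the lowest concentrations, and EB active
across the whole range — the qualitative windows reported for these
preparations.

**Heterogeneity.** Central amplitude, time-to-peak and baseline are
multiplied per cell by mean-preserving lognormal factors with CVs 0.25,
0.25 and 0.05. Mean preservation matters: population means of sampled
parameters equal the central values, so cross-preparation ratios survive
sampling. Active cells draw a responder class — transient, persistent, or
secondary-activation — from a per-preset mixture (Sigma 50/50/0,
EB 45/15/40, UP 80/20/0), reflecting the reported phenotypes: marked
transient/persistent heterogeneity under Sigma, frequent strong secondary
activations under EB.

**Class effects.** Persistent cells gain a plateau P = 0.2·A with
τ_p = 150 min; secondary cells gain A2 = 0.8·A at t2 = τ + 180 min with
λ = 60 min. The plateau magnitude was set from the model's analytics before
any end-to-end run: large enough that TNF-receptor blocking visibly changes
the average course, small enough that the plateau's contribution at the
primary peak (P·(1−e^{−τ/τ_p}) ≈ 0.05·A for Sigma) perturbs the anchored
cross-preparation amplitude and time-to-peak ratios by well under their
recovery tolerances.

**sTNFRII.** Blocking paracrine TNF multiplies the persistent-class
probability by 0.1 (renormalized) and surviving plateaus by 0.2, encoding
"persistent activation depends on secreted TNF". Because Sigma has the
largest persistent fraction, its ±sTNFRII cosine distance exceeds UP's.

**Anchors.** At 0.5 µg/mL the central parameters satisfy: EB A = 0.49 ×
Sigma A; EB τ = 3.0 × Sigma τ; UP A = 1.17 × Sigma A; UP τ = 1.45 × Sigma τ;
Sigma width = 1.475 × EB width (the midpoint of the reported 40–55% range,
read as peak width). UP's τ(c) interpolates 52/69/129 min at 5/0.5/0.05
µg/mL log-linearly; parameter curves are flat beyond their outermost
anchors. Absolute scales not fixed by ratios were set once: Sigma A = 0.9
above baseline b = 1.0, EB/UP width 61 min, Sigma width 90 min.

## Movie rendering

Nuclei are hard-edged ellipses (semi-axes drawn from a configured range,
default 7–11 px at 512×512) on a jittered grid with pitch
2·(max semi-axis + cytoplasm extent) + 12 px. The nuclear-marker channel is
a constant per-cell brightness (±20% cell-to-cell) over background; the
reporter channel gives each cell a nuclear level n(t) and an annular
cytoplasmic level c(t) with

    n(t) / c_pre = I(t)          and      n(t)·A_nuc + c(t)·A_cyto = const,

enforced per frame with that frame's rasterized areas, so total reporter is
conserved exactly and a noiseless render reproduces I(t) up to pixel
quantization. Edges are rendered hard rather than smoothed: a soft edge
makes the nuclear mean a biased fraction of the generative trace, violating
the renderer's own ±2% fidelity contract; edge tolerance is instead handled
by the segmenter's Gaussian blur.

Cells move by a tethered random walk: per-frame Gaussian steps of sd 1 px
with a mean-reverting pull (rate 0.05/frame) toward the cell's home site,
reflected at the field margins. Adherent fibroblasts wander locally rather
than diffusing freely; an untethered walk drifts ~11 px over 120 frames,
which at realistic densities pushes neighbours' cytoplasm over each other's
nuclei and corrupts traces (the sort of cell a manual curator would drop,
and this pipeline has no curator). The tether bounds excursions to ~3 px
while preserving genuine 1 px/frame steps for the tracker.

Noise is Poisson shot noise — observed = Poisson(clean·photon_scale)/
photon_scale, so variance equals the mean in photon units — plus Gaussian
read noise (sd 2), clipped at zero. photon_scale = 0 disables shot noise.
Not modeled: photobleaching, illumination shading, PSF blur, division,
apoptosis, nucleoli.

## Measurement pipeline

**Segmentation** (nuclear-marker channel, per frame): Gaussian blur
(σ = 1.5 px) → global Otsu threshold (fixed-value override available; a
blank frame yields zero labels) → hole filling → distance-transform
watershed seeded at distance-map peaks (min separation 7 px by default,
5 px for the small-nucleus geometry) → area filter [40, 2000] px. Regions
are 8-connected. Touching nuclei split whenever their centers exceed about
two semi-axes.

**Cytoplasmic ring**: pixels at distance (r_in, r_out] = (2, 8] px from a
nucleus, excluding all nuclear pixels; pixels inside several nuclei's bands
go to the nearer centroid. The annulus stands in for full-cell
segmentation: the normalization needs a representative cytoplasmic mean,
not the whole cell. The rendered cytoplasm extent must exceed r_out
(defaults 10 px at 512², 9 px at 256²), otherwise the ring dips into
background and inflates every trace.

**Tracking**: frame-to-frame mutual-nearest-centroid linking, gated at
10 px, ties broken by smaller label id then smaller track id (bit-exact
reruns); unmatched tracks survive up to 2 frames before closing; unmatched
detections open new tracks. No merge/split resolution — divisions are not
simulated.

**Trace extraction**: I(f) = (nuclear mean − bg) / (pre-stimulus ring mean
− bg), the pre-stimulus ring mean averaged over all pre-stimulus frames;
bg is a configured constant or, by default, the median over the four image
corners. Cells with no valid pre-stimulus cytoplasm are excluded with a
logged reason. Gap frames are flagged invalid and excluded from extrema
rather than interpolated.

**Features**: activity = trace ≥ baseline + 0.2 for ≥ 3 consecutive valid
post-stimulus frames (automated surrogate for the original manual
"uniformly brighter nuclei" curation; both thresholds configurable).
Peak amplitude = max over valid post-stimulus frames, first frame on ties;
time-to-peak = its time minus stimulation time. The half level is
(post-stimulus min + max)/2 — a literal reading of the half-maximum
convention; a baseline-anchored alternative is available via
`half_level_from_baseline`. Width = length of the contiguous interval
around the peak where the linearly interpolated trace exceeds the half
level; if the trace never falls below it, the width is right-censored at
the last frame and flagged (censored widths are excluded from width means
but never dropped from tables). Secondary activations = local maxima
outside the primary half-max interval with prominence ≥ 0.5·(peak −
baseline) and ≥ 60 min from the primary peak.

## Population analysis

Average time courses use only cells classified active, linearly resampled
to a fixed 5-min grid (0–595 min; edge values held). Cosine distance
1 − u·v/(‖u‖‖v‖) is computed on raw average courses — no baseline
subtraction or rescaling, since the comparison is defined on activation
profiles as measured; alternatives can be applied upstream. Similarity
matrices order conditions by preparation, then descending concentration.
An empty condition (no active cells) propagates as an explicit marker; the
±sTNFRII distance for such a condition is reported as NaN and flagged
not-defensible rather than raised.

## Reproducibility

Every stochastic step flows from one global seed. Per-movie streams are
derived as SeedSequence([global_seed, crc32(preset|conc|stnfr|movie)]), so
adding conditions never shifts existing streams; fixed seeds give
byte-identical movies, label stacks and CSVs. The staged pipeline persists
TIFF/CSV/JSON intermediates and skips stages whose outputs exist, making
single-stage recomputation exact.

## Problem sizes

Unit and property tests run on small fields (128–400 px, ≤ 60 frames).
The segmentation/tracking recovery test uses the full default geometry:
one 512×512, 120-frame, 60-cell noisy movie. End-to-end recovery tests use
256×256 fields of 30 cells with full 120-frame acquisitions — 4 movies per
condition (17 for UP at 0.05 µg/mL, where the dose model activates only
~20% of cells), giving roughly 100 active cells per condition, matching
the reported experimental scale of ~100 cells over ≥3 replicates. The
acceptance script uses 16/16/16/8/17 movies per condition (~350–450 active
cells at 0.5 µg/mL) so the cross-preparation ratio estimators have ~2-point
standard errors.

## Known limitations

* The trace family cannot produce genuine oscillations (only one secondary
  activation) and the plateau slightly inflates persistent cells' measured
  peak amplitude (+5% of A at Sigma's τ) and shifts their argmax by ~1 min.
* Synthetic movies are far cleaner than real microscopy: no focus drift,
  shading, bleaching, debris, division or apoptosis. Passing recovery tests
  shows the measurement code is correct and unbiased under the stated noise
  and motion model — not that it would survive arbitrary real data.
* The activity call is threshold-based; very weak responders
  (A < theta = 0.2) are by construction classified inactive.
* Cytoplasm is an annulus, not a segmented cell body; on real images with
  touching cells the nearest-centroid partition can still mix neighbours'
  cytoplasm.
* The 52/69/129-min series is mapped to 5/0.5/0.05 µg/mL; the middle
  concentration is a preset choice, as is reading the "40–55% longer
  localization" as peak width at its midpoint 47.5%.
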