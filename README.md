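# flimox

FLIM-FRET oxygen mapping for mitochondria, plus the companion qPCR / DRIP
quantification arithmetic.

`flimox` turns raw TCSPC photon-decay stacks — per-pixel histograms of
photon arrival times from a fluorescence lifetime microscope — into
calibrated per-mitochondrion oxygen partial pressure (pO2) maps and the
downstream readouts a metabolic imaging study needs: lifetime-distribution
histograms, high-/low-OCR subpopulation fractions, FLIM-based redox ratios
(FLIRR), and group statistics.  It is aimed at labs using genetically
encoded FRET oxygen sensors (myoglobin–mCherry fusions) together with
NAD(P)H/FAD autofluorescence lifetime imaging, and at anyone who wants a
tested, scriptable alternative to closed instrument software for
biexponential decay fitting.  A synthetic-data generator with full ground
truth stands in for the microscope (and the qPCR machine), so every stage
of the pipeline is testable end to end.

## The model

Each pixel's decay is fit by weighted nonlinear least squares to a
double-exponential over the channel-integrated model

  N(t) = A₁ e^(−t/τ₁) + A₂ e^(−t/τ₂),

yielding the amplitude fractions a₁%, a₂% and the amplitude-weighted mean
lifetime τ_mean = a₁τ₁ + a₂τ₂.  The oxygen sensor's lifetime follows a
rectangular hyperbola in pO2,

  τ(pO2) = (τ_max − 0.914) · pO2 / (K + pO2) + 0.914   [ns, mmHg],

where 0.914 ns is the deoxygenated asymptote of the probe, K is an
affinity-like fitting constant and τ_max the fully oxygenated lifetime.
The curve is anchored with a respiration-inhibited (rotenone) reference
condition, in which intracellular pO2 equals the media-imposed pO2.
Fixing K and τ_max from that reference, the fitted curve is inverted
per pixel:

  pO2(τ) = K (τ − 0.914) / (τ_max − τ),

giving pseudocolor oxygen maps (warm = low pO2 = high oxygen consumption),
and the redox ratio FLIRR = a₂%(NAD(P)H) / a₁%(FAD).  Details, defaults and
numerical choices are in [docs/methods.md](docs/methods.md).

## Worked example

The single-command demo simulates a two-condition experiment (a
wild-type-like population dominated by respiring, oxygen-depleted
mitochondria versus a knockout-like population dominated by quiescent,
oxygen-replete ones), calibrates against a simulated rotenone series, maps
pO2 and compares the conditions:

```bash
flimox demo --out demo_run --seed 1
# demo complete: K=14.57 mmHg, tau_max=2.486 ns; report at demo_run/report.json
```

The run directory contains the TIFF stacks, fitted parameter maps,
pseudocolor pO2 PNGs and `report.json`.  Key numbers from that report
(seed 1; the scene was generated with true K = 15 mmHg, τ_max = 2.5 ns):

| quantity | WT-like | KO-like |
|---|---|---|
| pooled high-OCR fraction (pO2 ≤ 30 mmHg) | 0.601 | 0.299 |
| pooled low-OCR fraction (pO2 ≥ 40 mmHg) | 0.382 | 0.680 |
| per-image median pO2 (mmHg) | 17.3, 10.5, 16.8, 17.6 | 44.1, 71.2, 51.8, 52.3 |

The recovered calibration (K = 14.57, τ_max = 2.486) sits within a few
percent of the generating truth; the high-OCR fraction matches the 60%/20%
mixture weights the scenes were drawn from; and the Mann–Whitney test on
per-image median pO2 gives U = 0, p = 0.029 — the two condition
distributions do not overlap even at n = 4 images per group.

The same stages are available individually (`flimox simulate decay`,
`fit`, `calibrate`, `po2map`, `flirr`, `summarize`, `qpcr`, `dripsignal`,
`run --config`), and everything is importable as a library:

```python
import flimox as fx

spec = fx.SceneSpec(image_height=64, image_width=64, mito_count=8,
                    mito_radius_range=(2, 3.5), seed=7)
image, truth = fx.generate_decay_image(spec)
fit = fx.fit_image(image, spatial_binning=3)
omap = fx.po2_map(fit, spec.truth_calibration())
print(fx.subpopulation_fractions(omap, 30.0, 40.0))
```

The qPCR side implements 2^ΔCt immunoprecipitation enrichment with
dilution correction (`drip_enrichment`, `rnaseh_normalize`), mtDNA copy
number (`mtdna_copy_number`), and binned/smoothed RPKM coverage on a
circular genome (`binned_rpkm`, `smooth_signal`, `normalize_tracks`,
bedGraph export).

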