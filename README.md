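# scoskit

Multi-channel **speckle contrast optical spectroscopy (SCOS)** analysis
toolkit, paired with a synthetic two-layer (scalp/brain) speckle-camera
simulator so that every pipeline stage is verifiable without human data.

The package covers:

* **`scoskit.synthetic`** — a forward model that renders 16-bit multi-frame
  camera stacks for seven fiber channels: a pulsatile two-compartment flow
  model with an optional scalp-occlusion window drives per-channel speckle
  decorrelation; pixel ensembles follow gamma speckle statistics with Poisson
  shot noise, Gaussian read noise, quantization and clipping. Ground truth
  (true squared contrast, flow and volume indices, closed-form segment-ratio
  oracles) is emitted alongside every stack.
* **`scoskit.contrast`** — raw spatial speckle contrast `K² = var(I)/mean(I)²`
  per channel region and frame, noise-adjusted contrast
  `K²_adj = K²_raw − γ/μ − 1/(12μ²) − σ²_dark/μ²` (all in camera counts,
  γ = gain / conversion factor, dark statistics from dark-frame calibration),
  blood flow index `BFI = 1/K²_adj`, min–max normalized nBFI, and the
  log-attenuation blood volume index `BVI = log10(I₀/μ(t))` with its linear
  approximation.
* **`scoskit.hemodynamics`** — pre / during / post occlusion segmentation,
  per-segment means and standard deviations of nBFI, during/pre and post/pre
  ratio curves vs source–detector distance, cohort aggregation with SNR-based
  exclusion bookkeeping, and a convergence-distance estimate against a control
  (non-occlusive) cohort.
* **`scoskit.waveform`** — FFT heart-rate extraction, a frequency-domain SNR
  with a 10 dB usability threshold, beat detection on a band-passed trace,
  phase-normalized beat averaging per segment, and cardiac amplitude-ratio
  curves for flow and volume traces.
* **`scoskit.io` / `scoskit.pipeline` / `scoskit.cli`** — multi-page TIFF or
  raw + JSON-sidecar stack formats, JSON layouts/calibrations/configs, tidy
  CSV series, and a deterministic, manifest-tracked
  simulate → calibrate → process → analyze → report workflow.

## Command line

```bash
# render a 3-subject synthetic cohort (stacks, dark frames, layout, truth)
scoskit simulate --out sim/ --subjects 3 --seed 1

# dark-frame calibration and per-subject processing
scoskit calibrate --dark sim/dark.tif --out calib.json
scoskit process --stack sim/subject_00.tif --layout sim/layout.json \
    --calib calib.json --out series_00.csv --subject 0

# segment/ratio and waveform analysis over a cohort of series CSVs
scoskit analyze --series series_00.csv --series series_01.csv --out analysis/
scoskit report --analysis analysis/ --out report.json

# or the full demo pipeline (occlusion + matched control) in one step
scoskit run --out run/ --subjects 3 --seed 1
```

All outputs are plain CSV/JSON; identical config + seed reruns are
byte-identical.

## Notes

* Simulator defaults (suppression fractions, layer-sensitivity profiles) are
  exercise parameters for testing the pipeline, not physiological estimates.
* The occlusion window is configurable; presets for an 8–16 s and an 8–17 s
  protocol are provided.
* The linear BVI coefficient defaults to the Taylor value `1/ln 10`; the
  alternative coefficient `2` found in parts of the literature is available
  via `bvi_from_intensity(..., method="linear", linear_coefficient=2.0)`.
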