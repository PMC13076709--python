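# adcphantom

Simulation and analysis pipeline for studying how reconstruction-stage
denoising affects apparent-diffusion-coefficient (ADC) quantification and
histogram metrics, using a synthetic QIBA/NIST-style multi-vial diffusion
phantom.

The package covers the whole chain:

1. **`adcphantom.phantom`** — seeded simulation of a 13-vial (full FOV) or
   11-vial (reduced FOV) PVP-concentration phantom: mono-exponential decay
   over five b-values (0–2,000 s/mm²), Rician noise with NEX-style magnitude
   averaging, a per-concentration polynomial nominal-ADC(T) model, and
   denoising-strength emulation (OFF/LOW/MEDIUM/HIGH) via in-plane Gaussian
   smoothing applied to one shared raw realisation per repeat.
2. **`adcphantom.fitting`** — voxelwise log-linear OLS ADC maps with a
   configurable signal floor and missing-value propagation.
3. **`adcphantom.voi`** — cylindrical VOIs (voxel-centre-in-circle rule,
   three consecutive slices), reused bit-identically across levels/repeats.
4. **`adcphantom.histogram`** — fixed-bin histograms (5 × 10⁻⁶ mm²/s) on a
   shared bin grid, mean histograms across repeats, and eleven first-order
   radiomic features (mean, SD, median, IQR, P10/P25/P75/P90, kurtosis,
   skewness, entropy).
5. **`adcphantom.stats`** — cumulative-histogram Wasserstein distance (bin
   index units), tie-corrected Friedman test, paired Wilcoxon signed-rank
   test with an exact small-n null, percent differences.
6. **`adcphantom.repeatability`** — accuracy vs nominal references,
   intra-session CV, maximum percent deviations, cross-session pooling.
7. **`adcphantom.pipeline` / `adcphantom.cli`** — configuration-driven
   orchestration with deterministic CSV outputs and a run manifest.

## CLI

```bash
# whole pipeline, in memory, all tables written to ./results
adcphantom all --config config.yaml --out results --seed 1

# or stage by stage against on-disk artifacts (NIfTI + sidecars + CSVs),
# so real scanner data can enter at the fit or extract stage:
adcphantom simulate --config config.yaml
adcphantom fit      --config config.yaml
adcphantom extract  --config config.yaml
adcphantom analyze  --config config.yaml
adcphantom report   --config config.yaml
```

A minimal `config.yaml`:

```yaml
sequences: [both]        # ffov, rfov or both
seed: 1
output_dir: results
n_repeats: 5
sessions: [[S1, 21.0], [S2, 22.0]]
# optional: matrix, n_slices, pixel_mm, noise_sigma, levels,
#           voi_diameter_fraction, voi_n_slices, bin_width
```

Outputs: `features.csv`, `accuracy.csv`, `accuracy_repeats.csv`,
`repeatability.csv`, `wasserstein.csv`, `friedman.csv`, `wilcoxon.csv`,
`percent_diff.csv`, pooled cross-session summaries, `feature_trends.csv`,
`significance_matrix.csv`, `summary.txt` and `manifest.json`.  Re-running
with an identical config reproduces every CSV byte for byte.

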