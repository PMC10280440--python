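# bloomcast

Pixel-level forecasting of chlorophyll-a concentration image time series —
the early-warning quantity for cyanobacteria blooms in eutrophic lakes.

Water managers receive satellite-derived chlorophyll-a maps as color-coded
rasters: nine display grades, each standing for a concentration band in
µg/L described by a per-image legend. `bloomcast` takes such a series,
repairs its defects, and predicts the next day's map at every pixel, so
that locations heading toward bloom concentrations can be flagged a day
ahead.

The package implements the full pipeline:

1. **Preprocessing** — three stages turn an imperfect raw series into a
   model-ready one:
   * *scale unification*: per-grade legend bounds are averaged over all
     images (LN_i(max) = avg Σ L_iⁿ(max), likewise for minima) and each
     image's grades are re-mapped to the unified grade with the nearest
     (min, max) pair in Euclidean distance;
   * *gap repair*: cloud/anomaly pixels are filled from a spatial-weight
     stencil, P = (Σ w₁P₁ + Σ w₂P₂) / (n·w₁ + m·w₂) with w₁ = 1/d² for the
     four edge neighbors and w₂ = 1/d for the diagonals, peeling each gap
     from its contour inward;
   * *daily interpolation*: missing days are filled linearly,
     P(m+λ) = P(m) + λ·(P(n) − P(m))/(n − m), then the series is cut into
     sliding windows of 30 input frames plus one target.
2. **Model** — a conditional GAN. The generator folds the 30 historical
   frames through a channel-attention ConvGRU
   (r_t = σ[M_c(X_t∗W_xr + H_{t−1}∗W_hr + b_r)], M_c(F) = σ(MLP(AvgPool F)) ∘ F,
   H_t = z_t∘H_{t−1} + (1−z_t)∘tanh(H̃_t)) and decodes the hidden map with a
   residual U-net (a stem plus seven stride-2 down-sampling layers with
   1×1/3×3 residual bottlenecks, seven mirrored up-sampling layers with skip
   concatenation, tanh output). The discriminator is a PatchGAN conditioned
   on the 30 histories stacked along channels (93 input channels), trained
   with L_D = ½[BCE(D(real|h),1) + BCE(D(fake|h),0)] and
   L_G = BCE(D(fake|h),1) + λ_L1·mean|fake − real|, Adam, lr 0.001.
3. **Evaluation** — SSIM, PSNR, cosine similarity and mutual information
   between predicted and real frames, per frame and as mean/maximum.
4. **Synthetic data** — a seeded generator of lake-shaped, palette-coded
   series with a drifting Gaussian bloom and every defect class above, so
   the entire pipeline runs and is tested with no downloads.

The network stack runs on a compact numpy autodiff core inside the package
(`bloomcast.autodiff`, `bloomcast.nn`) — no GPU framework required; all
runs are seeded and bit-reproducible on CPU.

## Worked example

```python
from bloomcast import (SynthConfig, generate_series, preprocess_series,
                       BloomForecastModel, TrainConfig,
                       GeneratorConfig, DiscriminatorConfig, ssim, psnr)

# a 40-day synthetic lake with clouds, legend jitter and dropped days
cfg = SynthConfig(shape=(128, 128), n_days=40, p_drop=0.5, seed=42)
raw_frames, legends, truth = generate_series(cfg)
print(f"{len(raw_frames)} acquisitions over {cfg.n_days} days")

result = preprocess_series(raw_frames, legends, input_len=30)
print(result.stats)

model = BloomForecastModel(result.windows, TrainConfig(seed=0, iterations=60),
                           GeneratorConfig.reduced(), DiscriminatorConfig.reduced(),
                           scale=result.unified_scale)
fit = model.fit()
print(fit.summary())

pred = fit.predict(list(result.windows[-1].inputs))
real = truth[-1]
print(f"forecast {pred.date}: SSIM {ssim(pred, real):.3f}, PSNR {psnr(pred, real):.1f} dB")
```

Output:

```
21 acquisitions over 40 days
{'frames_read': 21, 'pixels_repaired': 3387, 'days_inserted': 19, 'windows_emitted': 10}
Adversarial forecast model
==========================
generator parameters:     1,159,983
discriminator parameters: 56,281
iterations:               60
final generator loss:     20.7272
final discriminator loss: 0.5611
first/final mean |err|:   0.4913 / 0.2026
best validation |err|:    0.2897
forecast 2011-11-25: SSIM 0.858, PSNR 23.9 dB
```

Reading the numbers: of the 40 simulated days only 21 survived as
acquisitions; preprocessing repaired 3,387 cloud/anomaly pixels, inserted
the 19 missing days, and assembled 10 training windows. Sixty iterations of
the reduced model cut the mean per-pixel error (on the [−1, 1] scale) from
0.49 to 0.20, and the day-41 forecast agrees with the withheld truth frame
at SSIM 0.86. Longer training tightens this considerably (see below).
`fit.plot_losses()` draws the loss trajectories, and the same pipeline is
available from the shell:

```
bloomcast simulate   --out sim/ --seed 42
bloomcast preprocess --manifest sim/raw/manifest.csv --out pre/
bloomcast train      --frames pre/ --out ckpt/model.npz --reduced --seed 0
bloomcast predict    --ckpt ckpt/model.npz --history pre/ --out pred.png
bloomcast evaluate   --pred preds/ --real truth/ --out report.csv
```

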