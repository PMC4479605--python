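# riftrack

High-content analysis of DNA damage-response time-lapse movies: tracking
radiation-induced 53BP1 foci (RIF) across hundreds of cells and days of
imaging, and turning the raw two-channel image stacks into repair kinetics,
protein-flow estimates and foci-motion statistics.

The package is aimed at radiation biologists and microscopists who image
adherent cells expressing a chromatin marker (e.g. H2B-GFP, used for nucleus
segmentation) and a repair-protein marker (e.g. 53BP1-mCherry, which
concentrates into foci at double-strand breaks). It provides the full
pipeline — and a seeded synthetic-movie generator with exact ground truth, so
every stage can be validated end to end without microscope data.

## What the pipeline computes

1. **Nucleus segmentation** — pixel classification (Gaussian smoothing +
   Otsu + hole filling) followed by a *convexity-restricted watershed*:
   single nuclei are convex, so a connected component whose Douglas–Peucker
   simplified contour has no concave vertex is never split, while touching
   nuclei (concave necks) are separated by a distance-transform watershed.
2. **Lineage tracking** — optimal (Hungarian) frame-to-frame assignment with
   displacement/area gates; mitosis calls require a terminating parent, two
   nearby small daughters, loss of repair-channel signal and a rise in
   nuclear-channel signal; deaths are mid-field disappearances; giant nuclei
   exceed control mean + 2 SD. Outputs tracking and ancestry CSVs.
3. **Focus detection** — the H-dome transform
   `dome = f − R_f(f − h)` (reconstruction by dilation) isolates intensity
   peaks; thresholded domes inside each nucleus become focus masks, measured
   on the original image. Per nucleus, `I_nuclear` is the summed pixel
   intensity over the nucleus and `I_foci` the part inside focus masks.
4. **Focus classification** — a Gaussian mixture over
   (log total area, log mean intensity), fitted 10 times on random
   10,000-point subsamples with BIC selecting K ≤ 5; classes are relabelled
   1 (small/dim) … K (large/bright).
5. **Mass-balance protein flows** — with class 0 the diffuse (non-focus)
   nuclear protein pool and classes 1–4 the focus classes, consecutive
   frames obey

   ```
   I_k(t) = I_k(t−δt) + P_k − R_k
   P_k = Σ_{j≠k} C_jk · I_j(t−δt)      (inflow)
   R_k = Σ_{j≠k} C_kj · I_k(t−δt)      (outflow)
   ```

   The 20 off-diagonal conversion rates `C_jk ∈ [0,1]` are underdetermined by
   the 5 balance equations, so the sparsest transport is selected by a linear
   program minimising `Σ C_jk` (+ heavily weighted slack for non-conserved
   intensity). Flows `C_jk·I_j` are accumulated into induction (0→k),
   resolving (k→0) and merging (j→k, j<k) curves, optionally sham-normalised
   (subtract the control curve, clip at 0).
6. **Repair domains and foci motion** — single-cell crops are rigidly
   registered (FFT-magnitude polar correlation for rotation, sub-pixel phase
   correlation for translation); a temporal maximum-intensity projection over
   4–24 h post-irradiation reveals the compact sub-nuclear *repair domains*
   that foci keep visiting, which are segmented and measured in µm².
   Focus trajectories give the ensemble mean square displacement relative to
   the first post-irradiation frame: free diffusion has `MSD = 4Dτ`
   (D = slope/4), while confinement in a disc of radius r makes the MSD
   plateau at `r²`, so `π × plateau` estimates the domain area.

Control wells are handled the way the kinetics require: spontaneous foci
counts are fitted with `A·e^(−λt) + plateau` and the *fitted* curve (never
the noisy raw series) is subtracted from dosed wells before half-life
estimation.

## Worked example

```python
import numpy as np
import riftrack
from riftrack import kinetics, motion, synthetic

cfg = riftrack.SyntheticConfig(
    field_size_px=192, n_cells=4, pre_hours=1.0, post_hours=4.0,
    dose_gy=2.0, doubling_time_h=None, seed=11,
)
movie, truth = riftrack.generate_movie(cfg)

series = truth.class_intensity
I = series[[f"I{k}" for k in range(5)]].to_numpy()
step = kinetics.estimate_conversion_rates(
    I[10], I[11], dt_min=series.time_min[11] - series.time_min[10])
for j in range(5):
    for k in range(5):
        if step.rates[j, k] > 1e-6:
            print(f"C[{j}->{k}] = {step.rates[j,k]:.4f} (flow {step.flows[j,k]:.0f} a.u.)")

pos, times = synthetic.generate_trajectories(
    cfg, 500, n_frames=60, dt_min=5.0, rng=np.random.default_rng(1))
msd = motion.compute_msd(motion.trajectories_to_table(pos, times))
print(f"D = {motion.fit_diffusion(msd, n_lags=12).D_um2_min:.4f} um^2/min")
```

prints

```
C[1->4] = 0.0494 (flow 266 a.u.)
C[2->4] = 0.0089 (flow 152 a.u.)
C[3->4] = 0.0009 (flow 28 a.u.)
D = 0.0051 um^2/min
```

i.e. shortly after a 2 Gy exposure the estimated protein transport runs from
the small/medium focus classes into the large-cluster class 4 (foci merging
rather than gradual growth), and the simulated foci diffuse at the configured
0.005 µm²/min.

A full run (`riftrack run --config cfg.yaml`, or `pipeline.run_pipeline` from
Python) chains simulate → segment → track → foci → classify → rates →
domains → msd → report, writing CSV tables, a class-model JSON, plots and a
manifest with per-output checksums; identical config + seed reproduces every
CSV bit-for-bit. Each stage is also available as its own subcommand
(`simulate`, `segment`, `track`, `foci`, `classify`, `rates`, `domains`,
`msd`, `report`).

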