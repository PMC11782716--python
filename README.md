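# smscine

Simulation, iterative reconstruction, and quantitative evaluation of
**simultaneous multi-slice (SMS) real-time spiral cardiac MRI**, built for
studying whether SMS acquisitions preserve image quality relative to
single-band (SB) imaging of the beating heart.

Real-time cardiac MRI acquires images continuously, without ECG gating or
breath-holds, which matters for patients with arrhythmia or who cannot hold
their breath. SMS excites several short-axis slices at once (here a factor
of 3 with blipped-CAIPI phase cycling), cutting total scan time threefold at
the cost of a harder reconstruction problem and partial saturation of
in-flowing blood. This package provides the complete computational pipeline
of such a feasibility study on synthetic data with known ground truth:

- **trajectory** — golden-angle uniform-density (Archimedean) spiral design,
  density compensation (Pipe-Menon / Voronoi / radial), and binning of arms
  into fixed 45 ms real-time frames (6 arms/frame at the 6.6 ms SMS TR,
  8 arms/frame at the 5.3 ms SB TR).
- **phantom** — a dynamic multi-slice left-ventricle phantom (blood pool,
  myocardial ring, papillary muscles, optional irregular beats) with a
  forward simulator producing multi-coil SMS-CAIPI spiral k-space with known
  noise, coil maps and endocardial border.
- **encoding** — the forward model **A = ΦFS** (CAIPI phase table Φ,
  Kaiser-Bessel gridding NUFFT F, coil sensitivities S), Walsh adaptive
  sensitivity estimation, and density-compensated gridding reconstruction.
- **stcr** — spatiotemporal constrained reconstruction: minimize

  ```
  ‖Am − d‖² + λs Σ √(|∇x m|² + |∇y m|² + ε) + λt Σ √(|∇t m|² + ε)
  ```

  by Fletcher-Reeves nonlinear conjugate gradient with an Armijo line
  search, with λt = 0.05·C, λs = 0.005·C where C is the peak intensity of
  the density-compensated adjoint ("gridding") reconstruction of the data.
- **metrics** — the image-quality evaluation: the mid-cavity myocardium is
  split into the six AHA segments S7-S12 around the endocardial ellipse,
  Nl = 50 radial lines per segment are profiled (100× interpolation),
  a 4-parameter logistic `a + b/(1+exp(−s(x−x0)))` is fitted to each line,
  edge sharpness ES = |s| (per mm) and normalized contrast
  (I80 − I20)/σ are tabulated, and SMS-vs-SB comparisons are corrected with
  the Benjamini-Hochberg FDR procedure. σ is estimated from the background
  of Nyquist-rate (144 arms/frame) gridded images, rescaled to the iterative
  series via the LV blood pool.
- **io / cli / pipeline** — an HDF5 raw container, NIfTI export, a YAML run
  configuration, and the `smscine` command-line tool
  (`simulate`, `recon`, `evaluate`, `report`, `pipeline`).

## Worked example

Run the paired SMS / single-band experiment at desk scale (64×64 matrix,
6 coils, one second of simulated acquisition per mode):

```python
from smscine.pipeline import run_pipeline

results = run_pipeline({
    "phantom": {"matrix_size": 64, "pixel_spacing": 3.4, "n_coils": 6,
                "body_semiaxes": (90, 100)},
    "acquisition": {"duration_s": 1.0},
    "evaluation": {"n_lines_per_segment": 25},
    "seed": 7,
}, "out")
print(open("out/report.txt").read())
```

prints (excerpt):

```
Normalized contrast
 segment        mid-/SMS         mid-/SB        end-/SMS         end-/SB
      S7      13.98±2.49      25.34±6.96      11.46±2.39      18.55±7.74
      S8      17.02±0.92      37.96±1.41      16.85±2.29      35.97±1.99
      ...
     AVG           15.75           33.45           14.12           28.03
  SMS vs SB significant after BH (q=0.05): 12/12 comparisons

ES score
 segment        mid-/SMS         mid-/SB        end-/SMS         end-/SB
      ...
     AVG            0.68            0.86            0.71            0.90
  SMS vs SB significant after BH (q=0.05): 9/12 comparisons

AVG contrast ratio SB/SMS: mid-diastole 2.12, end-systole 1.99
```

Reading this: each cell is the mean ± SD of the per-line metric over a
segment's 25 lines at the selected cardiac phase. Single-band contrast is
roughly twice the SMS contrast at both phases — the signature of the
inflow-saturation penalty of multi-band excitation (the simulator's
`sms_blood_attenuation = 0.5`) — and the contrast difference survives FDR
correction in every segment, while edge sharpness is affected far less.
Segments S7 and S11 carry the papillary muscles and show the lowest
contrast and largest spread.

The same experiment from the shell:

```bash
smscine pipeline --seed 7 --out-dir out
smscine simulate --mode SB --seed 2 --out raw.h5
smscine recon --input raw.h5 --arms-per-frame 8 --out series.nii.gz --log recon.json
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full experiment from scratch at a fixed desk scale — both
simulations, both STCR reconstructions, the Nyquist-rate gridding noise
reference, the segment metrics and the FDR comparison — prints a summary
(contrast ratios, noise level, config hash) and writes the results JSON.
Runtime is a few minutes on one CPU.

## Layout

```
src/smscine/        trajectory, phantom, encoding, stcr, metrics, io,
                    pipeline, cli
tests/              unit, property and acceptance tests (pytest)
docs/methods.md     models, assumptions, parameter choices, limitations
```
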