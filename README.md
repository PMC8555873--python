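# veinmf — oriented matched-filter vein extraction

`veinmf` extracts subcutaneous veins from near-infrared (NIR) images.
Deoxygenated hemoglobin absorbs 850/940 nm light more strongly than the
surrounding tissue, so veins image as dark curvilinear structures whose
cross-section intensity is an inverted bell, well modelled by a Gaussian
dip. The package is aimed at people building or evaluating real-time vein
visualization pipelines (e.g. venipuncture-assist devices) who need a
tested software reference for the filtering algorithm and for its
fixed-point hardware realization.

## The method

The matched filter for a vessel of spread σ is a truncated, zero-mean
negative Gaussian ridge. On the grid point p = [x, y], rotated into the
kernel frame by [u, v] = p·R(θ),

    K(u, v) = −exp(−u² / 2σ²)   on the neighborhood |u| ≤ 3σ, |v| ≤ L/2

with the neighborhood mean m = (1/A) Σ K subtracted so the kernel has zero
DC response (A is the number of grid points in the neighborhood). A bank
of n = 180/θ_step rotated copies covers all orientations; with the default
45° step that is 4 kernels at 0°, 45°, 90°, 135° on a 21×21 grid with
σ = 3.3 and L = 16. The per-pixel output is the maximum response over the
bank, the segmentation threshold is α·max(response) (default α = 0.5;
α = 1 keeps only the peak pixels), and the depth image multiplies the
binary mask back into the response so deeper/thicker vessels render
brighter.

Two arithmetic paths produce the response:

* **float** — correlation with the real coefficients;
* **fixed** — a bit-exact model of a pipelined fixed-point datapath:
  coefficients quantized to signed 8-bit integers by truncating to two
  decimal places ×100, products formed by shift-add multiplication,
  window sums by a halving adder tree, and a per-pixel maximum stage.
  A cost model (4 + 9 + 2 clocks for multiply/add/max, one pixel per
  clock) prices a frame at H·W + 14 clocks — 360 974 clocks for 752×480,
  i.e. 66.5 fps at a 24 MHz pixel clock.

Supporting modules provide the quality metrics used to compare raw and
filtered images (Tenengrad, variance, Laplacian smoothness ψ, SNR,
standard deviation), cross-section sampling plus inverted-Gaussian
fitting `g(x) = a − b·exp(−(x−x₀)²/2σ²)` to pick σ from data (thin,
low-contrast veins fit a high σ; thick dark ones a low σ), and a seeded
synthetic phantom generator with ground-truth centerline/vessel masks.

## Worked example

```sh
veinmf synth --out fixtures --seed 7          # phantom suite + masks + manifest
veinmf filter fixtures/two_vessel_noisy.png --out run
veinmf metrics fixtures/two_vessel_noisy.png run/depth.png
veinmf fit fixtures/bar_000.png --start 27.5 47.5 --end 67.5 47.5
veinmf cycles --height 480 --width 752
```

prints

```
threshold=1546 mask_pixels=662 response_shape=(108, 108)
two_vessel_noisy.png: tenengrad=1.8073e+07 variance=309.25 smoothness=1.32909e+06 snr_db=20.77 std=17.5855
depth.png: tenengrad=2.50301e+08 variance=1873.92 smoothness=3.10102e+06 snr_db=-12.92 std=43.2888
{ ... "sigma_fit": 3.34586010564827, "converged": true ... }
latency_clocks_per_pixel=15
total_clocks=360974
frame_time_s=0.015041
fps=66.487
fps_floor=66
```

The two-vessel phantom holds vessels of absorption depth 80 and 40 gray
levels; the α = 0.5 threshold (1546 on the response scale) segments the
strong vessel, and `run/depth.png` renders it with its response-ordered
intensity. The cross-section fit on a noiseless vessel of true σ = 3.3
recovers σ̂ = 3.346 (the residual is 8-bit image quantization). The cycle
report prices the default 752×480 frame at 360 974 clocks (15 per pixel),
0.0150 s per frame, 66.5 fps at 24 MHz. Every output directory contains
the exact `run_config.json` used, so runs are reproducible from their
outputs alone.

The same pipeline is available as a library:

```python
from veinmf import KernelSpec, build_bank, extract_veins
from veinmf.synth import generate_phantom, two_vessel_config

phantom = generate_phantom(two_vessel_config())
bank = build_bank(KernelSpec())          # 21x21, sigma 3.3, L 16, 45 deg
result = extract_veins(phantom.image.pixels, bank, alpha=0.5, path="fixed")
result.response, result.binary_mask, result.depth_image
```

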