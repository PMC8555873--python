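# Methods

## Signal model

A vein illuminated at 850/940 nm absorbs more light than the surrounding
tissue, so across the vessel the image intensity dips below the tissue
baseline in an inverted-bell profile. We model the cross-section as

    I(x) = a − b·exp(−(x − x₀)² / 2σ²)

with baseline `a` (gray levels), absorption depth `b`, center `x₀` and
spread `σ` (pixels). The matched filter for this structure is the same
shape with the baseline removed: a negative Gaussian ridge, constant
along the vessel axis.

## Kernel construction (`veinmf.kernels`)

Each kernel lives on an odd N×N integer grid centered at the origin.
A grid point p = [x, y] (x = column offset, y = row offset; image origin
top-left) is rotated into the kernel frame as a row vector, [u, v] = p·R(θ)
with R the standard counterclockwise rotation matrix. Points with
|u| ≤ 3σ and |v| ≤ L/2 (boundary inclusive) form the truncation
neighborhood N of size A; they receive the raw coefficient
−exp(−u²/2σ²), all other grid points are zero. The neighborhood mean
m = (1/A)·ΣK is subtracted from every in-neighborhood coefficient, so the
kernel sums to zero and cannot respond to uniform brightness — without
this the filter would grade scene brightness, not vessel shape.

Angular convention: the θ = 0 kernel matches a vessel running along image
rows (vertical); a vessel at angle φ (same convention) is matched by the
kernel at θ = φ. The bank holds n = 180/θ_step kernels in ascending
angle; θ_step must divide 180.

Defaults: σ = 3.3, L = 16, N = 21, θ_step = 45° (n = 4). With these the
neighborhood needs 6σ+1 = 20.8 ≤ 21 grid cells, so nothing is clipped; a
spec whose neighborhood exceeds the grid warns and truncates at the grid
edge rather than erroring, since near-boundary coefficients are tiny.

**Quantization.** Fixed-point coefficients keep the first two decimal
places: each real coefficient is scaled by 100 and truncated toward zero
(a scaled value is pre-rounded at 1e-9 so binary float fuzz cannot drop a
decimal digit), then clamped to the signed 8-bit range. Consequences we
rely on and test: |real·100 − int| < 1 per coefficient, and the integer
kernel sum is bounded by the neighborhood size A. A round-half-away
mode exists behind a flag. Mean subtraction happens in real arithmetic
before quantization by default; `quantize_domain="integer"` quantizes
first and subtracts the truncated integer mean, since fixed-point
implementations differ on the ordering and neither choice is canonical.

## Filtering (`veinmf.filtering`)

Template matching uses **correlation** (no kernel flip); the kernels are
close to symmetric so the distinction is small, but it is fixed and
documented. Border handling defaults to `valid` — a windowed hardware
pipeline only produces fully covered positions — with zero-padded `same`
available. The per-pixel response is the maximum over the bank, ties
broken to the lowest orientation index (deterministic).

The **fixed-point path** is a functional model of a pipelined datapath,
bit-exact by construction and verified against direct integer
correlation: pixels (unsigned 8-bit) times coefficients (signed 8-bit)
via shift-add multiplication — scan the coefficient magnitude's bits,
accumulate the pixel shifted left by each set bit's index, apply the
sign — giving exact signed 16-bit products; the window sum reduces by a
halving adder tree (front half plus back half, odd lengths carry the
middle element), which equals sequential summation exactly. Products are
held in 16 signed bits as the datapath defines them; the accumulator is
widened (int64 workspace) because adder-tree bit growth is otherwise
unspecified and 21×21 windows of extreme operands exceed 16 bits.
Line buffering is modelled functionally by the sliding window: buffer
structure changes timing, not values, and timing is captured by the cost
model. The fixed path processes windows in row blocks to bound memory.

**Thresholding.** The threshold is anchored to the response maximum:
t = α·max(response), mask = response ≥ t. α = 1 reproduces the literal
"maximum as threshold" rule, which keeps only the arg-max pixels and is
degenerate as a segmentation; the default α = 0.5 preserves the
max-anchored rule while producing usable masks. Note a structural
property of this rule: a vessel whose absorption depth is exactly half
the strongest vessel's sits exactly at the α = 0.5 threshold, and 8-bit
image quantization can tip it to either side (in the packaged two-vessel
phantom, depths 80/40, the weak vessel lands at ≈0.4993·max and is
excluded). This is a knife-edge of the threshold rule, not a numerical
defect; α = 0.45 segments both vessels. A non-positive response maximum
yields an empty mask with a warning.

**Depth rendering.** The mask is multiplied back into the response and
the masked values rescaled linearly to [0, 255] (a uniform masked
response maps to 255; an empty mask to all zeros); rescaling preserves
the within-mask response ordering, which is what makes deeper/thicker
vessels render brighter. The raw mask×response product, whose display
normalization is otherwise unspecified, is available behind a flag.

**Cycle model.** Stage latencies: multiply 4, add 9, max 2 clocks
(latency 15); one pixel enters per clock and the pipeline drains after
the last, so a frame costs H·W + latency − 1 clocks: 360 974 for
752×480. At the 24 MHz pixel clock that is 0.01504 s per frame and
66.49 fps; the CLI prints the unrounded rate plus its floor rather than
endorsing either of the two roundings (66 and 67) one might quote.
Whether real line-buffer fill latency should be added is not modelled;
the pixel-pipeline expression above is the model's definition.

## Metrics (`veinmf.metrics`)

All windowed sums run over interior pixels only (border indices would
read out of bounds). Tenengrad is Σ(Gx² + Gy²) with the standard 3×3
Sobel operators and no gradient threshold. Variance and std use the
population convention. The Laplacian smoothness score ψ sums
[f(i+1,j) + f(i−1,j) + f(i,j+1) + f(i,j−1) − k·f(i,j)]² with k = 4 by
default — the true 4-connected Laplacian, zero on constant images, which
is what a smoothness measure should be — and k = 1 as an `as_printed`
variant for fidelity with formulations that keep a unit center weight.
SNR has no canonical definition for this kind of imagery, so the package
convention is documented as such: 20·log₁₀(mean(signal)/std(background))
given a signal mask, 20·log₁₀(mean/std) of the whole image without one;
zero denominators return +inf with a warning. A contrast indicator is
deliberately omitted rather than guessing among Michelson/RMS variants.

## Cross-section fitting (`veinmf.profilefit`)

Profiles are sampled by bilinear interpolation at equally spaced points
on a user-given segment. The inverted-Gaussian model (above) is fitted
by nonlinear least squares (`scipy.optimize.curve_fit`), initialized
from the data: a ← max, b ← max−min, x₀ ← position of the minimum,
σ ← half-width at half depth / 1.177 (HWHM = σ√(2 ln 2)); bounds
σ ∈ (0.1, profile length), b ≥ 0. Flat profiles return a non-converged
result with a warning instead of raising. Noiseless recovery is exact to
≤1e-4 relative across σ ∈ {1.5…8.2}; at noise std 2 gray levels the
median relative σ error stays under 5% (both tested).

`recommend_sigma` returns the median fitted σ over converged fits plus
an ordinal thickness label — "thin" above a 5.0 px cut, "thick" below.
The cut and the median are package conventions; no quantitative mapping
from σ to physical depth in millimetres is attempted because none is
derivable from first principles here, only the ordinal rule (thin ↔ high
σ, thick ↔ low σ) is established.

## Synthetic phantoms (`veinmf.synth`)

The generator renders the same model the filter assumes:
I(p) = B + gradient(p) − Σ D·exp(−d(p)²/2σ_v²), clamped to [0, 255],
plus seeded additive Gaussian noise, quantized to 8 bits. d(p) is the
Euclidean distance to the vessel centerline — closed form for straight
vessels, nearest-neighbor over a densely sampled centerline (0.25 px
step, KD-tree) for sinusoid and quadratic models. Ground truth is
derived before noise: centerline mask d ≤ 0.5 px, vessel mask d ≤ 2σ_v
(the dilation convention used for Dice computations).

Defaults are chosen to emulate the target imaging conditions:
752×480 frames, tissue background 200 gray levels, vessels of depth 80
and spread 3.3 px, additive Gaussian noise of 2 gray levels (Poisson
shot noise optional — the default is Gaussian because the sensor noise
is not characterized further). Same config + seed reproduces identical
bytes. What the phantoms do **not** emulate: skin texture, hair,
specular reflections, illumination falloff beyond a linear gradient,
vessel branching, or depth-dependent blur; tests passing on phantoms
therefore validate the algorithmic contract (orientation selectivity,
depth ordering, recovery of generating parameters), not clinical
segmentation accuracy on real hands.

## Numerical choices

* Float correlation uses FFT convolution; zero-response assertions use
  tolerances (~1e-6 on 8-bit data) accordingly. The fixed path is exact
  integer arithmetic and is asserted bit-for-bit.
* Neighborhood membership uses ≤ on both bounds exactly; with the
  defaults the axis-aligned neighborhood holds 19×17 = 323 grid points.
* Rotated kernels sample the continuous Gaussian at rotated grid points;
  no discrete-kernel interpolation is involved, so θ and θ+90° grids are
  exact transpose/flip images of each other and 45°/135° are mirror
  images — both asserted in tests.
* Argmax ties: lowest orientation index. Degenerate rescales (uniform
  masked response) map to full brightness. Empty masks render black.

## Limitations

* The α = 0.5 default is a usability compromise on top of the
  max-anchored threshold rule; heavily multi-vessel scenes with widely
  varying depths will drop vessels below α·max (see knife-edge note).
* The cost model prices the steady-state pixel pipeline only; memory
  interfaces and frame I/O are out of scope.
* σ selection assumes user-placed cross-sections; there is no automatic
  centerline detection.
* Phantom realism limits are listed above; quality-metric comparisons on
  phantoms should not be read as device-level image-quality claims.
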