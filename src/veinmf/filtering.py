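"""Matched-filter application, thresholding, depth rendering, cycle accounting.

Two numerically distinct paths compute the per-pixel filter response:

* a float path — correlation of the real zero-mean kernels with the image;
* a fixed-point path — a functional model of a pipelined hardware datapath,
  in which every product is formed by shift-add multiplication of an
  unsigned 8-bit pixel with a signed 8-bit coefficient and the window sum
  is reduced by a halving adder tree.  The model is bit-exact: it equals a
  direct integer correlation with the quantized kernel, and its purpose is
  to let the arithmetic be verified operand-for-operand.

The per-pixel response is the maximum over the orientation bank; the
segmentation threshold is anchored to the global response maximum; and the
depth image multiplies the binary mask back into the response so stronger
(deeper/thicker) vessels render brighter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .kernels import KernelBank, MatchedKernel

__all__ = [
    "GrayImage",
    "FilterResponse",
    "PipelineCostModel",
    "convolve_float",
    "convolve_fixed",
    "shiftadd_multiply",
    "tree_sum",
    "respond",
    "threshold_from_max",
    "depth_render",
    "extract_veins",
    "cycle_count",
]


@dataclass(frozen=True)
class GrayImage:
    """8-bit single-channel raster; origin top-left, x = column, y = row."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"expected a non-empty 2-D array, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def as_uint8(self) -> np.ndarray:
        return np.round(self.pixels).astype(np.uint8)


@dataclass
class FilterResponse:
    """Bank response, winning orientation, threshold, mask and depth image."""

    response: np.ndarray
    arg_orientation: np.ndarray
    threshold_value: Optional[float] = None
    binary_mask: Optional[np.ndarray] = None
    depth_image: Optional[np.ndarray] = None


@dataclass(frozen=True)
class PipelineCostModel:
    """Stage latencies of the pipelined convolution datapath.

    One pixel enters the pipeline per clock; a pixel's result emerges after
    the multiply, adder-tree and maximum stages have drained, so a frame of
    H*W pixels costs H*W + latency - 1 clocks.
    """

    clocks_multiply: int = 4
    clocks_add: int = 9
    clocks_max: int = 2
    pixel_clock_hz: float = 24_000_000.0

    def __post_init__(self) -> None:
        for name in ("clocks_multiply", "clocks_add", "clocks_max"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @property
    def latency(self) -> int:
        return self.clocks_multiply + self.clocks_add + self.clocks_max


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, GrayImage) else np.asarray(image)


def convolve_float(image, kernel, border: str = "valid") -> np.ndarray:
    """Correlate a kernel's real coefficients with the image.

    Template matching uses correlation (no kernel flip).  ``border="valid"``
    returns only fully covered positions, shape (H-N+1, W-N+1);
    ``border="same"`` zero-pads to the input shape.
    """
    px = _as_pixels(image).astype(np.float64)
    grid = kernel.real_grid if isinstance(kernel, MatchedKernel) else np.asarray(kernel, float)
    if border not in ("valid", "same"):
        raise ValueError(f"border must be 'valid' or 'same', got {border!r}")
    if px.shape[0] < grid.shape[0] or px.shape[1] < grid.shape[1]:
        raise ValueError(
            f"image {px.shape} smaller than kernel {grid.shape}; cannot filter"
        )
    # correlation == convolution with the doubly flipped kernel
    return signal.fftconvolve(px, grid[::-1, ::-1], mode=border)


def shiftadd_multiply(pixel, coeff):
    """Multiply an unsigned 8-bit pixel by a signed 8-bit coefficient by shift-add.

    The coefficient magnitude is scanned bit by bit; for every set bit i the
    pixel shifted left by i is added to the running sum, and the sign is
    applied afterwards.  Accepts scalars or broadcastable integer arrays and
    returns the exact product as a signed integer (int32 workspace; every
    value fits 16 signed bits).
    """
    p = np.asarray(pixel, dtype=np.int32)
    c = np.asarray(coeff, dtype=np.int32)
    if np.any(p < 0) or np.any(p > 255):
        raise ValueError("pixel operand out of the unsigned 8-bit range")
    if np.any(c < -128) or np.any(c > 127):
        raise ValueError("coefficient operand out of the signed 8-bit range")
    mag = np.abs(c)
    acc = np.zeros(np.broadcast(p, mag).shape, dtype=np.int32)
    for i in range(8):
        bit = (mag >> i) & 1
        acc += bit * (p << i)
    result = np.where(c < 0, -acc, acc)
    if result.ndim == 0:
        return int(result)
    return result


def tree_sum(products, axis: int = -1):
    """Sum by halving adder tree: add the front and back halves, recursing.

    At each step the list of n values is split into its first and last
    floor(n/2) elements, which are added pairwise; an odd length carries the
    middle element to the next round.  Equal to the sequential sum exactly.
    Accepts a 1-D sequence (returns a Python int) or an ndarray reduced
    along ``axis`` with a widened accumulator.
    """
    arr = np.asarray(products)
    if arr.size == 0 or arr.shape[axis] == 0:
        raise ValueError("tree_sum of an empty list is undefined")
    arr = np.moveaxis(arr, axis, -1).astype(np.int64)
    scalar_out = arr.ndim == 1
    n = arr.shape[-1]
    while n > 1:
        h = n // 2
        merged = arr[..., :h] + arr[..., n - h:]
        if n % 2:
            merged = np.concatenate([merged, arr[..., h: h + 1]], axis=-1)
        arr = merged
        n = arr.shape[-1]
    out = arr[..., 0]
    return int(out) if scalar_out else out


def convolve_fixed(image, kernel, border: str = "valid", block_rows: int = 64) -> np.ndarray:
    """Integer correlation computed entirely through the hardware model.

    Every window/coefficient product goes through :func:`shiftadd_multiply`
    (products fit 16 signed bits) and the per-window reduction through
    :func:`tree_sum` with a widened accumulator.  The result is bit-exact
    with the direct integer correlation of the image with ``int_grid``.
    """
    px = _as_pixels(image)
    if not np.issubdtype(px.dtype, np.integer):
        if np.any(px != np.round(px)):
            raise ValueError("fixed-point path requires integer-valued pixels")
        px = np.round(px).astype(np.int64)
    grid = kernel.int_grid if isinstance(kernel, MatchedKernel) else np.asarray(kernel)
    if border not in ("valid", "same"):
        raise ValueError(f"border must be 'valid' or 'same', got {border!r}")
    n = grid.shape[0]
    if border == "same":
        pad = (n - 1) // 2
        px = np.pad(px, pad, mode="constant")
    if px.shape[0] < n or px.shape[1] < grid.shape[1]:
        raise ValueError(f"image {px.shape} smaller than kernel {grid.shape}")
    windows = sliding_window_view(px, grid.shape)  # (H', W', n, n)
    flat_kernel = grid.reshape(-1)
    out = np.empty(windows.shape[:2], dtype=np.int64)
    for r0 in range(0, windows.shape[0], block_rows):  # bound peak memory
        block = windows[r0: r0 + block_rows].reshape(-1, windows.shape[1], n * n)
        products = shiftadd_multiply(block, flat_kernel[np.newaxis, np.newaxis, :])
        out[r0: r0 + block.shape[0]] = tree_sum(products.astype(np.int16), axis=-1)
    return out


def respond(image, bank: KernelBank, path: str = "float", border: str = "valid") -> FilterResponse:
    """Per-pixel maximum response and winning orientation over the bank.

    Ties go to the lowest orientation index.  ``path`` selects the float
    correlation or the bit-exact fixed-point model (fixed responses are on
    the integer coefficient scale, i.e. ~scale x the float values).
    """
    if len(bank) == 0:
        raise ValueError("cannot respond with an empty kernel bank")
    if path == "float":
        stack = np.stack([convolve_float(image, k, border=border) for k in bank])
    elif path == "fixed":
        stack = np.stack([convolve_fixed(image, k, border=border) for k in bank])
    else:
        raise ValueError(f"path must be 'float' or 'fixed', got {path!r}")
    arg = np.argmax(stack, axis=0)  # first max wins ties
    response = np.take_along_axis(stack, arg[np.newaxis], axis=0)[0]
    return FilterResponse(response=response, arg_orientation=arg)


def threshold_from_max(response: np.ndarray, alpha: float = 0.5) -> float:
    """Threshold anchored to the global response maximum: alpha * max(response).

    ``alpha=1.0`` reproduces the literal max-as-threshold rule (only the
    arg-max pixels survive); the 0.5 default yields usable vessel masks
    while keeping the threshold tied to the strongest vessel response.
    """
    response = np.asarray(response)
    if response.size == 0:
        raise ValueError("empty response")
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    peak = float(response.max())
    if peak <= 0:
        warnings.warn(
            "response maximum is non-positive; the vessel mask will be empty",
            UserWarning,
            stacklevel=2,
        )
    return alpha * peak


def apply_threshold(response: np.ndarray, threshold_value: float) -> np.ndarray:
    """Binary mask: response >= threshold; empty if the maximum is non-positive."""
    response = np.asarray(response)
    if response.max() <= 0:
        return np.zeros(response.shape, dtype=bool)
    return response >= threshold_value


def depth_render(response: np.ndarray, binary_mask: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Depth-preserving rendering: the mask multiplied into the response.

    Masked response values are linearly rescaled to [0, 255] (a uniform
    masked response maps to 255); unmasked pixels are 0.  ``rescale=False``
    returns the raw mask*response product instead.
    """
    response = np.asarray(response, dtype=np.float64)
    binary_mask = np.asarray(binary_mask, dtype=bool)
    if response.shape != binary_mask.shape:
        raise ValueError(f"shape mismatch: {response.shape} vs {binary_mask.shape}")
    if not rescale:
        return response * binary_mask
    out = np.zeros(response.shape, dtype=np.float64)
    if not binary_mask.any():
        return out
    vals = response[binary_mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        out[binary_mask] = 255.0
    else:
        out[binary_mask] = 255.0 * (vals - lo) / (hi - lo)
    return out


def extract_veins(
    image,
    bank: KernelBank,
    alpha: float = 0.5,
    path: str = "float",
    border: str = "valid",
    rescale_depth: bool = True,
) -> FilterResponse:
    """Full pipeline: bank response -> max threshold -> mask -> depth image."""
    fr = respond(image, bank, path=path, border=border)
    fr.threshold_value = threshold_from_max(fr.response, alpha=alpha)
    fr.binary_mask = apply_threshold(fr.response, fr.threshold_value)
    fr.depth_image = depth_render(fr.response, fr.binary_mask, rescale=rescale_depth)
    return fr


def cycle_count(height: int, width: int, model: PipelineCostModel = PipelineCostModel()) -> int:
    """Total clocks to filter an H x W frame on the pipelined datapath.

    One pixel enters per clock and the pipeline drains after the last one:
    total = H*W + (multiply + add + max latency) - 1.  With the default
    4 + 9 + 2 stage model a 752 x 480 frame costs 360974 clocks.
    """
    if height < 1 or width < 1:
        raise ValueError("frame dimensions must be positive")
    return height * width + model.latency - 1


def frame_time_s(height: int, width: int, model: PipelineCostModel = PipelineCostModel()) -> float:
    """Seconds to process one frame at the model's pixel clock."""
    return cycle_count(height, width, model) / model.pixel_clock_hz


def frames_per_second(height: int, width: int, model: PipelineCostModel = PipelineCostModel()) -> float:
    """Unrounded sustainable frame rate at the model's pixel clock."""
    return 1.0 / frame_time_s(height, width, model)
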