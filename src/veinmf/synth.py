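"""Seeded synthetic NIR-like vein phantoms with ground truth.

Deoxygenated hemoglobin absorbs near-infrared light more strongly than the
surrounding tissue, so veins image as dark curvilinear structures on a
brighter, noisy background, with an inverted-bell (Gaussian dip) intensity
profile across each vessel.  The generator renders exactly that model:

    I(p) = B + gradient(p) - sum_vessels D * exp(-d(p)^2 / (2 sigma_v^2))

with ``d(p)`` the Euclidean distance from pixel ``p`` to the vessel
centerline, clamped to [0, 255], plus seeded additive Gaussian noise
(Poisson shot noise is available as an option).  Ground-truth centerline
and vessel masks are derived from the noiseless geometry, which makes the
phantoms usable as oracles for filtering and profile-fitting tests.

Vessel orientation uses the same angular convention as the kernel bank:
0 degrees is a vessel running along image rows (vertical), angles grow
so that a vessel at angle phi is matched by the kernel at theta = phi.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .filtering import GrayImage
from .profilefit import CrossSectionProfile

__all__ = [
    "VesselSpec",
    "SynthConfig",
    "Phantom",
    "generate_phantom",
    "generate_profile",
    "make_fixture_suite",
    "single_bar_config",
    "two_vessel_config",
]


@dataclass(frozen=True)
class VesselSpec:
    """One vessel: centerline model, geometry parameters, cross-section.

    Models
    ------
    line      params: point (x, y) on the line; angle_deg (bank convention)
    sinusoid  params: y0, amplitude, period, phase — y(x) = y0 + A sin(2 pi (x - phase)/period)
    quadratic params: y0, curvature, xc — y(x) = y0 + curvature (x - xc)^2
    """

    model: str = "line"
    params: dict = field(default_factory=dict)
    sigma_v: float = 3.3
    depth_D: float = 80.0

    def __post_init__(self) -> None:
        if self.model not in ("line", "sinusoid", "quadratic"):
            raise ValueError(f"unknown centerline model {self.model!r}")
        if self.sigma_v <= 0:
            raise ValueError("sigma_v must be positive")
        if self.depth_D <= 0:
            raise ValueError("depth_D must be positive")


@dataclass(frozen=True)
class SynthConfig:
    """Phantom recipe; same config + seed reproduces identical bytes.

    Defaults emulate the imaging conditions the package targets: a
    752 x 480 frame, tissue background near gray level 200, vessels of
    absorption depth ~80 gray levels and spread ~3.3 px, and additive
    Gaussian sensor noise of 2 gray levels.
    """

    height: int = 480
    width: int = 752
    vessels: tuple = ()
    background_B: float = 200.0
    background_gradient: tuple = (0.0, 0.0)  # gray levels per pixel along (x, y)
    noise_std: float = 2.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.background_B <= 255):
            raise ValueError("background_B must lie in (0, 255]")
        for v in self.vessels:
            if v.depth_D > self.background_B:
                raise ValueError("vessel depth_D cannot exceed the background level")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def to_dict(self) -> dict:
        # round-trip through JSON so tuples normalize to lists and the dict
        # compares equal to its on-disk form
        return json.loads(json.dumps(self._raw_dict()))

    def _raw_dict(self) -> dict:
        return {
            "height": self.height,
            "width": self.width,
            "vessels": [
                {"model": v.model, "params": dict(v.params), "sigma_v": v.sigma_v, "depth_D": v.depth_D}
                for v in self.vessels
            ],
            "background_B": self.background_B,
            "background_gradient": list(self.background_gradient),
            "noise_std": self.noise_std,
            "noise_model": self.noise_model,
            "seed": self.seed,
        }

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Phantom:
    """Rendered phantom with per-vessel ground truth."""

    image: GrayImage
    centerline_mask: np.ndarray
    vessel_mask: np.ndarray
    vessel_info: tuple
    config: SynthConfig
    noiseless: np.ndarray


def _line_distance(xx, yy, params) -> np.ndarray:
    """Closed-form point-to-line distance; angle in the kernel convention."""
    cx, cy = params.get("point", (0.0, 0.0))
    phi = np.deg2rad(params.get("angle_deg", 0.0))
    return np.abs((xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi))


def _sampled_distance(xx, yy, xs, ys) -> np.ndarray:
    """Min distance to a densely sampled centerline via a KD-tree."""
    from scipy.spatial import cKDTree

    tree = cKDTree(np.column_stack([xs, ys]))
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    d, _ = tree.query(pts, workers=-1)
    return d.reshape(xx.shape)


def vessel_distance_field(vessel: VesselSpec, height: int, width: int, step: float = 0.25) -> np.ndarray:
    """Distance from every pixel center to the vessel centerline, in pixels."""
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    p = vessel.params
    if vessel.model == "line":
        return _line_distance(xx, yy, p)
    span = np.arange(-0.5, width - 0.5 + step, step)
    if vessel.model == "sinusoid":
        y0 = p.get("y0", height / 2)
        amp = p.get("amplitude", height / 8)
        period = p.get("period", width / 2)
        phase = p.get("phase", 0.0)
        ys = y0 + amp * np.sin(2 * np.pi * (span - phase) / period)
    else:  # quadratic
        y0 = p.get("y0", height / 2)
        curv = p.get("curvature", 1.0 / width)
        xc = p.get("xc", width / 2)
        ys = y0 + curv * (span - xc) ** 2
    return _sampled_distance(xx, yy, span, ys)


def generate_phantom(config: SynthConfig) -> Phantom:
    """Render a phantom image plus ground-truth masks from a config.

    The noiseless intensity field is the background plus linear gradient
    minus the sum of Gaussian absorption dips; masks come from the
    distance fields before noise (centerline: d <= 0.5 px; vessel mask:
    centerline dilated to radius 2 sigma_v).
    """
    h, w = config.height, config.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    gx, gy = config.background_gradient
    field_img = config.background_B + gx * xx + gy * yy
    centerline = np.zeros((h, w), dtype=bool)
    vessel_mask = np.zeros((h, w), dtype=bool)
    info = []
    for v in config.vessels:
        d = vessel_distance_field(v, h, w)
        field_img -= v.depth_D * np.exp(-(d**2) / (2 * v.sigma_v**2))
        in_frame = d <= 2 * v.sigma_v
        if not in_frame.any():
            warnings.warn("vessel lies entirely outside the frame", UserWarning, stacklevel=2)
        centerline |= d <= 0.5
        vessel_mask |= in_frame
        info.append(
            {
                "model": v.model,
                "angle_deg": v.params.get("angle_deg"),
                "sigma_v": v.sigma_v,
                "depth_D": v.depth_D,
            }
        )
    noiseless = np.clip(field_img, 0.0, 255.0)
    rng = np.random.default_rng(config.seed)
    if config.noise_model == "gaussian":
        noisy = noiseless + rng.normal(0.0, config.noise_std, size=noiseless.shape) if config.noise_std > 0 else noiseless
    else:
        noisy = rng.poisson(np.maximum(noiseless, 0.0)).astype(np.float64)
    pixels = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
    return Phantom(
        image=GrayImage(pixels),
        centerline_mask=centerline,
        vessel_mask=vessel_mask,
        vessel_info=tuple(info),
        config=config,
        noiseless=noiseless,
    )


def generate_profile(
    a: float, b: float, x0: float, sigma: float, n: int = 41, noise_std: float = 0.0, seed: int = 0
) -> CrossSectionProfile:
    """Synthetic cross-section: a - b exp(-(x-x0)^2/(2 sigma^2)) on a
    symmetric unit-spaced grid of n points, plus seeded Gaussian noise."""
    if n < 5:
        raise ValueError("need at least 5 samples")
    x = np.linspace(-(n - 1) / 2.0, (n - 1) / 2.0, n)
    y = a - b * np.exp(-((x - x0) ** 2) / (2 * sigma**2))
    if noise_std > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_std, size=n)
    return CrossSectionProfile(positions=x, values=y)


def single_bar_config(
    angle_deg: float,
    size: int = 96,
    sigma_v: float = 3.3,
    depth_D: float = 80.0,
    noise_std: float = 0.0,
    seed: int = 0,
) -> SynthConfig:
    """One straight vessel through the frame center at a given angle."""
    vessel = VesselSpec(
        model="line",
        params={"point": ((size - 1) / 2.0, (size - 1) / 2.0), "angle_deg": angle_deg},
        sigma_v=sigma_v,
        depth_D=depth_D,
    )
    return SynthConfig(height=size, width=size, vessels=(vessel,), noise_std=noise_std, seed=seed)


def two_vessel_config(
    size: int = 128,
    sigma_v: float = 3.3,
    depth_D: float = 80.0,
    noise_std: float = 0.0,
    seed: int = 0,
) -> SynthConfig:
    """Two parallel vertical vessels with absorption depths D and D/2."""
    x1, x2 = size / 3.0, 2 * size / 3.0
    v1 = VesselSpec("line", {"point": (x1, 0.0), "angle_deg": 0.0}, sigma_v, depth_D)
    v2 = VesselSpec("line", {"point": (x2, 0.0), "angle_deg": 0.0}, sigma_v, depth_D / 2.0)
    return SynthConfig(height=size, width=size, vessels=(v1, v2), noise_std=noise_std, seed=seed)


def make_fixture_suite(out_dir, bar_size: int = 96, two_vessel_size: int = 128, seed: int = 0) -> dict:
    """Write the pinned phantom fixtures: 12 single-bar angles, the
    two-vessel depth phantom (noiseless and noisy), masks and a manifest.

    Returns the manifest (also written as ``manifest.json``), which lists
    every file with the config hash that produced it.
    """
    from . import cli_io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []

    def _emit(name: str, config: SynthConfig) -> None:
        ph = generate_phantom(config)
        img_path = out_dir / f"{name}.png"
        cli_io.write_gray(img_path, ph.image)
        cli_io.write_mask(out_dir / f"{name}_centerline.png", ph.centerline_mask)
        cli_io.write_mask(out_dir / f"{name}_vessel.png", ph.vessel_mask)
        entries.append(
            {
                "name": name,
                "files": [f"{name}.png", f"{name}_centerline.png", f"{name}_vessel.png"],
                "config": config.to_dict(),
                "config_hash": config.digest(),
            }
        )

    for angle in range(0, 180, 15):
        _emit(f"bar_{angle:03d}", single_bar_config(angle, size=bar_size, seed=seed))
    _emit("two_vessel_noiseless", two_vessel_config(size=two_vessel_size, noise_std=0.0, seed=seed))
    _emit("two_vessel_noisy", two_vessel_config(size=two_vessel_size, noise_std=2.0, seed=seed))
    manifest = {"fixtures": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
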