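"""Synthetic echocardiography phantoms.

Real apical four-chamber echocardiograms are private clinical data, so the
package ships a generator that emulates their qualitative structure: a dark
sector-shaped ultrasound field of view, a dark elliptical left-ventricle
cavity surrounded by a brighter myocardial ring, multiplicative speckle
noise, and a smooth intensity-inhomogeneity field.  Each sample is paired
with the exact binary cavity mask, and the whole sample is a pure function
of its configuration (including the seed).

The cavity outline is an ellipse perturbed by a few low-frequency radial
harmonics, so its shape is not learnable as a fixed template and the
network must use image evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["PhantomConfig", "EchoSample", "generate_phantom", "generate_dataset",
           "read_manifest"]

# region intensities of the noise-free phantom (exterior, tissue, ring, cavity)
_I_EXTERIOR = 0.05
_I_TISSUE = 0.35
_I_RING = 0.75
_I_CAVITY = 0.12


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom.

    Parameters
    ----------
    image_size : side length in pixels of the square image (>= 32).
    sector_apex_angle : opening angle of the ultrasound sector, degrees.
    cavity_axes_range : (min, max) ellipse semi-axes as fractions of the
        image side; both must lie in (0, 0.5).
    myocardium_thickness_range : (min, max) ring thickness in pixels; when
        ``None`` it defaults to 2.5%-5.5% of the image side.
    speckle_scale : strength of the multiplicative speckle (0 disables it).
    inhomogeneity_strength : amplitude in [0, 1] of the smooth
        multiplicative intensity bias (0 disables it).
    seed : RNG seed; identical configs produce bit-identical samples.
    """

    image_size: int = 512
    sector_apex_angle: float = 75.0
    cavity_axes_range: tuple[float, float] = (0.10, 0.20)
    myocardium_thickness_range: tuple[float, float] | None = None
    speckle_scale: float = 0.35
    inhomogeneity_strength: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        lo, hi = self.cavity_axes_range
        if not (0.0 < lo < hi < 0.5):
            raise ValueError("cavity_axes_range must satisfy 0 < min < max < 0.5")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")
        if not 0.0 <= self.inhomogeneity_strength <= 1.0:
            raise ValueError("inhomogeneity_strength must lie in [0, 1]")
        if self.myocardium_thickness_range is None:
            t = (max(2.0, 0.025 * self.image_size), max(3.0, 0.055 * self.image_size))
            object.__setattr__(self, "myocardium_thickness_range", t)
        tlo, thi = self.myocardium_thickness_range
        if not (0 < tlo <= thi):
            raise ValueError("myocardium_thickness_range must satisfy 0 < min <= max")


@dataclass
class EchoSample:
    """One phantom: grayscale image in [0,1], binary mask, and metadata."""

    image: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)


def _sector_mask(size: int, apex_angle_deg: float) -> np.ndarray:
    """Downward-opening sector with its apex near the top centre."""
    rows, cols = np.mgrid[0:size, 0:size]
    apex = (0.04 * size, size / 2.0)
    dy = rows - apex[0]
    dx = cols - apex[1]
    r = np.hypot(dx, dy)
    # angle measured from the downward vertical
    ang = np.degrees(np.arctan2(dx, dy))
    half = apex_angle_deg / 2.0
    return (np.abs(ang) <= half) & (r <= 0.92 * size) & (dy >= 0)


def _cavity_mask(size: int, centre, axes, rotation, harmonics) -> np.ndarray:
    """Ellipse with low-frequency radial perturbation, rasterized."""
    rows, cols = np.mgrid[0:size, 0:size]
    dy = rows - centre[0]
    dx = cols - centre[1]
    ct, st = np.cos(rotation), np.sin(rotation)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    theta = np.arctan2(v / axes[1], u / axes[0])
    radius = np.sqrt((u / axes[0]) ** 2 + (v / axes[1]) ** 2)
    bump = np.zeros_like(theta)
    for k, amp, phase in harmonics:
        bump += amp * np.cos(k * theta + phase)
    return radius <= 1.0 + bump


def generate_phantom(config: PhantomConfig) -> EchoSample:
    """Generate one image/mask pair deterministically from ``config``."""
    size = config.image_size
    rng = np.random.default_rng(config.seed)
    sector = _sector_mask(size, config.sector_apex_angle)

    # geometry: jitter the cavity until it (plus its ring) sits fully inside
    # the sector with a margin; the loop is bounded and seed-deterministic
    lo, hi = config.cavity_axes_range
    tlo, thi = config.myocardium_thickness_range
    for _ in range(64):
        axes = rng.uniform(lo * size, hi * size, size=2)
        centre = (rng.uniform(0.45, 0.62) * size, rng.uniform(0.40, 0.60) * size)
        rotation = rng.uniform(-0.5, 0.5)
        n_harm = rng.integers(3, 6)
        harmonics = [(int(k), rng.uniform(0.01, 0.06), rng.uniform(0, 2 * np.pi))
                     for k in rng.choice(np.arange(2, 7), size=n_harm, replace=False)]
        thickness = rng.uniform(tlo, thi)
        cavity = _cavity_mask(size, centre, axes, rotation, harmonics)
        ring_outer = cavity | (ndimage.distance_transform_edt(~cavity) <= thickness)
        frac = cavity.mean()
        inside = not (ring_outer & ~sector).any()
        border = (ring_outer[0, :].any() or ring_outer[-1, :].any()
                  or ring_outer[:, 0].any() or ring_outer[:, -1].any())
        if inside and not border and 0.01 <= frac <= 0.30:
            break
    else:  # pragma: no cover - extremely defensive
        raise RuntimeError("could not place a cavity inside the sector")

    ring = ring_outer & ~cavity
    image = np.full((size, size), _I_EXTERIOR)
    image[sector] = _I_TISSUE
    image[ring] = _I_RING
    image[cavity] = _I_CAVITY

    if config.inhomogeneity_strength > 0:
        bias = _bias_field(size, rng, config.inhomogeneity_strength)
        image = image * bias

    if config.speckle_scale > 0:
        noise = rng.rayleigh(scale=1.0, size=(size, size))
        noise = ndimage.gaussian_filter(noise, sigma=1.0)
        noise = noise / noise.mean()
        image = image * (1.0 + config.speckle_scale * (noise - 1.0))

    image = np.clip(image, 0.0, 1.0)
    meta = asdict(config)
    meta.update(realized={
        "centre": [float(c) for c in centre],
        "axes": [float(a) for a in axes],
        "rotation": float(rotation),
        "thickness": float(thickness),
        "harmonics": [[int(k), float(a), float(p)] for k, a, p in harmonics],
    })
    return EchoSample(image=image, mask=cavity.astype(np.uint8), meta=meta)


def _bias_field(size: int, rng: np.random.Generator, strength: float) -> np.ndarray:
    """Smooth multiplicative field in [1-strength, 1+strength]: a few
    random Gaussian bumps, normalized."""
    rows, cols = np.mgrid[0:size, 0:size] / size
    field_ = np.zeros((size, size))
    for _ in range(rng.integers(2, 5)):
        cy, cx = rng.uniform(0.1, 0.9, size=2)
        sig = rng.uniform(0.2, 0.5)
        amp = rng.uniform(-1.0, 1.0)
        field_ += amp * np.exp(-((rows - cy) ** 2 + (cols - cx) ** 2) / (2 * sig ** 2))
    span = np.abs(field_).max()
    if span > 0:
        field_ = field_ / span
    return 1.0 + strength * field_


# --------------------------------------------------------------- dataset I/O


def save_png(path: Path, array: np.ndarray, binary: bool) -> None:
    if binary:
        data = (array.astype(np.uint8) * 255)
    else:
        data = np.round(np.clip(array, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def generate_dataset(config: PhantomConfig, n: int, out_dir: str | Path) -> Path:
    """Write ``n`` image/mask PNG pairs plus a manifest; returns its path.

    Per-sample seeds are spawned deterministically from ``config.seed`` so
    the whole corpus regenerates byte-identically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable") from exc

    seed_rng = np.random.default_rng(config.seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=n)
    rows = []
    for i, seed in enumerate(seeds):
        sample = generate_phantom(replace(config, seed=int(seed)))
        img_name, mask_name = f"img_{i:05d}.png", f"mask_{i:05d}.png"
        save_png(out_dir / img_name, sample.image, binary=False)
        save_png(out_dir / mask_name, sample.mask, binary=True)
        rows.append((img_name, mask_name, int(seed)))

    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("image\tmask\tseed\n")
        for img_name, mask_name, seed in rows:
            fh.write(f"{img_name}\t{mask_name}\t{seed}\n")
    with open(out_dir / "config.json", "w") as fh:
        json.dump(asdict(config) | {"n": n}, fh, indent=2)
    return manifest


def read_manifest(manifest: str | Path) -> list[tuple[Path, Path]]:
    """Read a manifest back as (image_path, mask_path) pairs."""
    manifest = Path(manifest)
    root = manifest.parent
    pairs = []
    with open(manifest) as fh:
        header = fh.readline()
        if not header.startswith("image"):
            raise ValueError("manifest must start with an 'image\\tmask' header")
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 2:
                continue
            pairs.append((root / parts[0], root / parts[1]))
    return pairs
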