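"""Synthetic tumor-phantom generator at VOI scale.

Emulates the appearance of a single hypodense liver lesion inside a
liver-like background within an 80 x 80 x 60 volume of interest: a blob
(sphere, ellipsoid, or lobulated union of spheres) of controllable size and
contrast, with optional multiplicative texture heterogeneity inside the
lesion, partial-volume edge blur, and additive Gaussian noise.  The ground
truth is the noiseless geometric support, so segmentation quality is exactly
measurable.

Default intensities are HU-like: background 100, lesion 60 (hypodense).
Everything is bit-deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .volume import ScalarVolume

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]

_TEXTURE_SMOOTH_SIGMA = 4.0  # voxels; spatial scale of intratumoral heterogeneity


@dataclass
class PhantomSpec:
    """Parameters of one synthetic VOI.

    ``equiv_radius`` is in voxels and must fit inside ``shape`` with at least
    a 2-voxel margin; ``texture_sigma`` is the relative amplitude of the
    smoothed multiplicative heterogeneity applied inside the lesion only.
    """

    shape: tuple[int, int, int] = (80, 80, 60)
    tumor_kind: str = "sphere"
    equiv_radius: float = 12.0
    center: tuple[float, float, float] | None = None
    intensity_bg: float = 100.0
    intensity_fg: float = 60.0
    texture_sigma: float = 0.0
    noise_sigma: float = 0.0
    edge_blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"implausible VOI shape {self.shape}")
        if self.tumor_kind not in ("sphere", "ellipsoid", "lobulated"):
            raise ValueError(f"unknown tumor_kind {self.tumor_kind!r}")
        if self.center is None:
            self.center = tuple((s - 1) / 2.0 for s in self.shape)
        self.center = tuple(float(c) for c in self.center)
        if self.equiv_radius < 3:
            raise ValueError("equiv_radius must be >= 3 voxels")
        for sig, name in (
            (self.noise_sigma, "noise_sigma"),
            (self.texture_sigma, "texture_sigma"),
            (self.edge_blur_sigma, "edge_blur_sigma"),
        ):
            if sig < 0:
                raise ValueError(f"{name} must be >= 0")
        # the lesion (including lobulated children, <= 1.6x parent extent)
        # must fit with a 2-voxel margin
        extent = self.equiv_radius * (1.6 if self.tumor_kind == "lobulated" else 1.0)
        for c, s in zip(self.center, self.shape):
            if c - extent < 2 or c + extent > s - 3:
                raise ValueError(
                    f"tumor of extent {extent:.1f} at {self.center} does not fit "
                    f"shape {self.shape} with a 2-voxel margin"
                )

    def to_dict(self) -> dict:
        return asdict(self)


def _radius_grid(shape, center) -> np.ndarray:
    axes = [np.arange(n, dtype=np.float64) - c for n, c in zip(shape, center)]
    return np.sqrt(
        axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    )


def _tumor_support(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape, c, r = spec.shape, spec.center, spec.equiv_radius
    if spec.tumor_kind == "sphere":
        return _radius_grid(shape, c) <= r
    if spec.tumor_kind == "ellipsoid":
        # random axis ratios with the same equivalent radius (abc)^(1/3) = r
        logr = rng.uniform(-0.35, 0.35, size=3)
        logr -= logr.mean()
        semi = r * np.exp(logr)
        axes = [
            (np.arange(n, dtype=np.float64) - cc) / s
            for n, cc, s in zip(shape, c, semi)
        ]
        q = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        return q <= 1.0
    # lobulated: parent sphere plus 2-4 children (30-60% radius) on its surface
    mask = _radius_grid(shape, c) <= r
    n_children = int(rng.integers(2, 5))
    for _ in range(n_children):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        child_r = r * rng.uniform(0.3, 0.6)
        child_c = np.asarray(c) + u * r
        mask |= _radius_grid(shape, child_c) <= child_r
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, np.ndarray]:
    """Render one phantom.  Returns ``(volume, gt_mask)``.

    The ground-truth mask is the noiseless geometric support of the lesion
    and is unaffected by texture, blur and noise settings.
    """
    rng = np.random.default_rng(spec.seed)
    gt = _tumor_support(spec, rng)
    img = np.full(spec.shape, spec.intensity_bg, dtype=np.float64)
    fg = np.full(spec.shape, spec.intensity_fg, dtype=np.float64)
    if spec.texture_sigma > 0:
        white = rng.standard_normal(spec.shape)
        tex = ndimage.gaussian_filter(white, _TEXTURE_SMOOTH_SIGMA)
        tex /= max(tex.std(), 1e-12)
        fg = fg * (1.0 + spec.texture_sigma * tex)
    img[gt] = fg[gt]
    if spec.edge_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.edge_blur_sigma)
    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * rng.standard_normal(spec.shape)
    return ScalarVolume(img), gt


_RANGE_KEYS = (
    "equiv_radius",
    "contrast",
    "noise_sigma",
    "texture_sigma",
    "edge_blur_sigma",
)


def generate_dataset(n: int, ranges: dict, seed: int = 0, *,
                     shape=(80, 80, 60), tumor_kind: str = "sphere",
                     intensity_bg: float = 100.0):
    """Draw ``n`` independent phantoms with parameters uniform in ``ranges``.

    ``ranges`` maps any of ``equiv_radius, contrast, noise_sigma,
    texture_sigma, edge_blur_sigma`` to a ``(low, high)`` pair (a point value
    is expressed as ``low == high``).  ``contrast`` is ``intensity_bg -
    intensity_fg`` (positive = hypodense lesion).  Returns a list of
    ``(volume, gt_mask, spec)`` triples, reproducible per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not ranges:
        raise ValueError("ranges must be non-empty")
    unknown = set(ranges) - set(_RANGE_KEYS)
    if unknown:
        raise ValueError(f"unknown range keys {sorted(unknown)}; valid: {_RANGE_KEYS}")
    for k, bounds in ranges.items():
        lo, hi = bounds
        if hi < lo:
            raise ValueError(f"range for {k} is empty: {bounds}")
    rng = np.random.default_rng(seed)
    defaults = {
        "equiv_radius": (12.0, 12.0),
        "contrast": (40.0, 40.0),
        "noise_sigma": (0.0, 0.0),
        "texture_sigma": (0.0, 0.0),
        "edge_blur_sigma": (1.0, 1.0),
    }
    defaults.update(ranges)
    out = []
    for _ in range(n):
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in defaults.items()}
        spec = PhantomSpec(
            shape=shape,
            tumor_kind=tumor_kind,
            equiv_radius=draw["equiv_radius"],
            intensity_bg=intensity_bg,
            intensity_fg=intensity_bg - draw["contrast"],
            texture_sigma=draw["texture_sigma"],
            noise_sigma=draw["noise_sigma"],
            edge_blur_sigma=draw["edge_blur_sigma"],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, gt = generate_phantom(spec)
        out.append((vol, gt, spec))
    return out
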