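"""Dynamic regulation of level-set parameters from contour-position probabilities.

The segmenter's energy weights (lambda1, lambda2), its per-iteration local
window radius, and its initialization are all driven by a 3-class estimate of
where the current zero level set sits relative to the tumor boundary:

* ``p1`` -- contour inside the tumor,
* ``p2`` -- contour near the tumor boundary,
* ``p3`` -- contour outside the tumor.

The weight rule is

    lambda1 = exp((1 + p1 + p2) / (1 + p2 + p3))
    lambda2 = exp((1 + p2 + p3) / (1 + p1 + p2))

so both weights live in [e^0.5, e^2]: an inside contour puts the maximal
weight on the interior-statistics channel (lambda1), an outside contour on
the exterior one (lambda2), and a near-boundary contour gets
lambda1 ~ lambda2 so that local texture decides the fine positioning.

The window rule returns a fixed near-boundary radius (8 voxels) when
0.4 < p2 < 0.6 and otherwise grows the window with the inside/outside
imbalance |p1 - p3|, so that a far-away contour sees enough of the opposite
region to move in the right direction.

The probabilities may come from the trained 3D CNN
(:mod:`drls.classifier`) or from the deterministic geometric oracle below,
which scores a contour by its mean signed distance to a ground-truth boundary
and makes the whole pipeline testable without any training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PositionProbabilities",
    "RegulationConfig",
    "regulate_lambdas",
    "regulate_window",
    "oracle_position_probs",
    "select_initialization",
    "OracleClassifier",
    "FixedClassifier",
]

_SIMPLEX_TOL = 1e-6


@dataclass(frozen=True)
class PositionProbabilities:
    """Simplex triple (p1, p2, p3) = (inside, near-boundary, outside)."""

    p1: float
    p2: float
    p3: float

    def __post_init__(self) -> None:
        for name, p in (("p1", self.p1), ("p2", self.p2), ("p3", self.p3)):
            if not (-_SIMPLEX_TOL <= p <= 1 + _SIMPLEX_TOL):
                raise ValueError(f"{name}={p} not in [0, 1]")
        s = self.p1 + self.p2 + self.p3
        if abs(s - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"probabilities sum to {s}, expected 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p1, self.p2, self.p3)

    @property
    def argmax(self) -> int:
        """0 = inside, 1 = boundary, 2 = outside."""
        return int(np.argmax(self.as_tuple()))


@dataclass
class RegulationConfig:
    """Constants of the window-regulation rule and of initialization search.

    ``window_rule`` selects the reading of the far-from-boundary branch:

    * ``"literal"``: rad = round(25 * |p1 - p3|), clamped to [rad_min, rad_max]
    * ``"additive"``: rad = round(5 + 5 * |p1 - p3|)
    """

    window_rule: str = "literal"
    rad_near: int = 8
    rad_min: int = 5
    rad_max: int = 25
    p2_low: float = 0.4
    p2_high: float = 0.6
    candidate_radii: tuple[int, ...] = (6, 10, 20, 30, 40)
    sigma_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.window_rule not in ("literal", "additive"):
            raise ValueError(f"unknown window_rule {self.window_rule!r}")
        if not (self.rad_min <= self.rad_near <= self.rad_max):
            raise ValueError("require rad_min <= rad_near <= rad_max")
        if not (0.0 <= self.p2_low < self.p2_high <= 1.0):
            raise ValueError("require 0 <= p2_low < p2_high <= 1")
        if len(self.candidate_radii) == 0:
            raise ValueError("candidate_radii must be non-empty")


def regulate_lambdas(p: PositionProbabilities) -> tuple[float, float]:
    """Map position probabilities to the energy weights (lambda1, lambda2).

    Both outputs lie in [e^0.5, e^2] and swap under (p1 <-> p3); lambda1 >
    lambda2 exactly when p1 > p3.
    """
    if not isinstance(p, PositionProbabilities):
        p = PositionProbabilities(*p)
    num = 1.0 + p.p1 + p.p2
    den = 1.0 + p.p2 + p.p3
    lam1 = float(np.exp(num / den))
    lam2 = float(np.exp(den / num))
    return lam1, lam2


def regulate_window(p: PositionProbabilities, cfg: RegulationConfig | None = None) -> int:
    """Map position probabilities to the local-window radius in voxels.

    Near the boundary (p2_low < p2 < p2_high) the radius is ``cfg.rad_near``
    (8 voxels by default); otherwise it grows with |p1 - p3| under the
    configured rule (see :class:`RegulationConfig`).
    """
    if cfg is None:
        cfg = RegulationConfig()
    if not isinstance(p, PositionProbabilities):
        p = PositionProbabilities(*p)
    if cfg.p2_low < p.p2 < cfg.p2_high:
        return int(cfg.rad_near)
    gap = abs(p.p1 - p.p3)
    if cfg.window_rule == "literal":
        rad = int(round(25.0 * gap))
        return int(np.clip(rad, cfg.rad_min, cfg.rad_max))
    rad = int(round(5.0 + 5.0 * gap))
    return rad


# ---------------------------------------------------------------------------
# Geometric oracle


def gt_signed_distance(gt_mask: np.ndarray) -> np.ndarray:
    """Voxel-unit signed distance to the boundary of ``gt_mask`` (< 0 inside).

    Referenced to the continuous surface halfway between voxel centers: the
    discrete center-to-center EDT overshoots it by half a voxel on each side,
    so that half voxel is subtracted symmetrically.
    """
    gt = np.asarray(gt_mask, dtype=bool)
    if not gt.any():
        raise ValueError("ground-truth mask is empty")
    d_out = ndimage.distance_transform_edt(~gt)
    d_in = ndimage.distance_transform_edt(gt)
    return d_out - d_in + np.where(gt, 0.5, -0.5)


def equivalent_radius(mask: np.ndarray) -> float:
    """Radius of the sphere with the same voxel volume as ``mask``."""
    v = float(np.count_nonzero(mask))
    if v == 0:
        raise ValueError("mask is empty")
    return float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0))


def _contour_voxels(phi: np.ndarray) -> np.ndarray:
    """Boolean shell of the zero level set: border voxels of {phi < 0}."""
    interior = phi < 0
    if not interior.any() or interior.all():
        raise ValueError("zero level set is empty")
    eroded = ndimage.binary_erosion(interior, structure=_FACE_STRUCT, border_value=0)
    return interior & ~eroded


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def oracle_position_probs(
    phi: np.ndarray,
    gt_mask: np.ndarray,
    sigma_frac: float = 0.25,
    _sdf_cache: np.ndarray | None = None,
    _req_cache: float | None = None,
) -> PositionProbabilities:
    """Deterministic contour-position probabilities from the ground truth.

    Let ``s`` be the mean signed distance (voxels, negative inside) of the
    contour shell to the GT boundary, normalized by the GT equivalent radius.
    Then ``p2 = exp(-(s / sigma_frac)^2)`` and the remaining mass goes to
    ``p1`` if s < 0, to ``p3`` if s > 0 (split 50/50 exactly at s = 0).
    """
    if sigma_frac <= 0:
        raise ValueError("sigma_frac must be positive")
    shell = _contour_voxels(np.asarray(phi))
    sdf = gt_signed_distance(gt_mask) if _sdf_cache is None else _sdf_cache
    r_eq = equivalent_radius(gt_mask) if _req_cache is None else _req_cache
    # +0.5: shell voxels are interior border voxels, whose centers sit half a
    # voxel inside the continuous surface they represent
    s = (float(sdf[shell].mean()) + 0.5) / r_eq
    p2 = float(np.exp(-((s / sigma_frac) ** 2)))
    rest = 1.0 - p2
    if s < 0:
        p1, p3 = rest, 0.0
    elif s > 0:
        p1, p3 = 0.0, rest
    else:
        p1 = p3 = rest / 2.0
    # renormalize defensively against float drift
    tot = p1 + p2 + p3
    return PositionProbabilities(p1 / tot, p2 / tot, p3 / tot)


class OracleClassifier:
    """Position classifier backed by the ground-truth mask.

    Satisfies the classifier contract used by the evolution loop and by
    :func:`select_initialization`: a ``predict_position(volume, phi)`` method
    returning :class:`PositionProbabilities`.  The GT distance transform is
    cached, so repeated per-iteration queries are cheap.
    """

    def __init__(self, gt_mask: np.ndarray, sigma_frac: float = 0.25):
        self.gt_mask = np.asarray(gt_mask, dtype=bool)
        self.sigma_frac = float(sigma_frac)
        self._sdf = gt_signed_distance(self.gt_mask)
        self._req = equivalent_radius(self.gt_mask)

    def predict_position(self, volume, phi) -> PositionProbabilities:
        phi_arr = phi.phi if hasattr(phi, "phi") else np.asarray(phi)
        return oracle_position_probs(
            phi_arr, self.gt_mask, self.sigma_frac,
            _sdf_cache=self._sdf, _req_cache=self._req,
        )


class FixedClassifier:
    """Always returns the same probabilities; useful for directed tests."""

    def __init__(self, p: PositionProbabilities):
        self.p = p if isinstance(p, PositionProbabilities) else PositionProbabilities(*p)

    def predict_position(self, volume, phi) -> PositionProbabilities:
        return self.p


def select_initialization(
    volume,
    voi_center: tuple[float, float, float],
    candidate_radii,
    classifier,
):
    """Pick the initial SDF ball whose contour the classifier rates nearest
    the boundary (maximal p2); ties break toward the smaller radius.

    Returns ``(LevelSetField, records)`` where ``records`` is a list of
    ``(radius, PositionProbabilities)`` for every candidate.
    """
    from .levelset import init_sdf_ball  # local import to avoid a cycle

    radii = sorted(int(r) for r in candidate_radii)
    if not radii:
        raise ValueError("no candidate radii given")
    shape = volume.shape if hasattr(volume, "shape") else np.asarray(volume).shape
    best = None
    records = []
    for r in radii:
        try:
            field = init_sdf_ball(shape, voi_center, r)
        except ValueError:
            continue
        p = classifier.predict_position(volume, field)
        records.append((r, p))
        # strict > keeps the smaller radius on ties (radii are ascending)
        if best is None or p.p2 > best[1].p2:
            best = (field, p, r)
    if best is None:
        raise ValueError("no candidate initialization intersects the grid")
    return best[0], records
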