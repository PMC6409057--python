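"""Volume/mask readers and writers and configuration loading.

NIfTI (.nii / .nii.gz) and NRRD (.nrrd) round-trip through SimpleITK; data
arrays are index-ordered (z-fastest handled by SimpleITK internally, we keep
the array exactly as written).  Masks are stored as unsigned 8-bit {0, 1}.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from .volume import ScalarVolume

__all__ = [
    "SUPPORTED_EXTENSIONS",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "load_config",
    "save_config",
]

SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".nrrd")


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in SUPPORTED_EXTENSIONS):
        raise ValueError(
            f"unsupported volume format {path.suffix!r} for {path.name}; "
            f"supported: {', '.join(SUPPORTED_EXTENSIONS)}"
        )


def read_volume(path) -> ScalarVolume:
    path = Path(path)
    _check_extension(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"could not read volume {path}: {exc}") from exc
    data = sitk.GetArrayFromImage(img).astype(np.float64)
    # SimpleITK returns (z, y, x); transpose back to (x, y, z) index order
    data = np.transpose(data, (2, 1, 0))
    return ScalarVolume(data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_volume(volume: ScalarVolume, path) -> None:
    path = Path(path)
    _check_extension(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(np.transpose(volume.data, (2, 1, 0)))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    vol = read_volume(path)
    return vol.data > 0.5, vol.spacing


def write_mask(mask: np.ndarray, path, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    path = Path(path)
    _check_extension(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(
        np.transpose(np.asarray(mask, dtype=np.uint8), (2, 1, 0))
    )
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_config(cfg, path) -> None:
    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            obj = dataclasses.asdict(obj)
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_clean(cfg), fh, sort_keys=False)
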