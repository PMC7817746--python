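"""NIfTI input/output for binary volumes.

Loading binarises at 0.5 (values > 0.5 are foreground) and takes the voxel
spacing from the header zooms.  Saving writes a uint8 mask with a diagonal
affine built from the spacing; oblique affines encountered on load are used
only for their voxel sizes, with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import DimensionalityError
from .metrics import BinaryVolume

logger = logging.getLogger(__name__)

FOREGROUND_THRESHOLD = 0.5


@dataclass(frozen=True)
class VolumeFileRecord:
    """Provenance of a volume written to disk."""

    path: Path
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]


def load_volume(path: str | Path) -> BinaryVolume:
    """Load a 3D NIfTI image as a binary volume (intensity > 0.5 is foreground)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several format errors
        raise OSError(f"could not read NIfTI image at {path}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D volume, got {img.ndim} dimensions"
        )
    affine = img.affine
    if affine is not None and not np.allclose(
        affine[:3, :3], np.diag(np.diag(affine[:3, :3])), atol=1e-6
    ):
        logger.warning(
            "%s has an oblique affine; only voxel sizes are used", path
        )
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BinaryVolume(data > FOREGROUND_THRESHOLD, spacing)


def save_volume(volume: BinaryVolume, path: str | Path) -> VolumeFileRecord:
    """Write a binary volume as a uint8 NIfTI image (foreground 1, background 0)."""
    path = Path(path)
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(volume.mask.astype(np.uint8), affine)
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"could not write NIfTI image to {path}: {exc}") from exc
    return VolumeFileRecord(path, volume.shape, volume.spacing)
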