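"""NIfTI input/output helpers.

Volumes are float32 on disk and float64 in computation; the affine is
carried through unchanged, and all internal indexing is 0-based voxel space.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .btensor import AcquisitionProtocol, read_sidecar

__all__ = ["read_nifti", "write_nifti", "load_dwi"]


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    """Read a NIfTI volume.

    Returns ``(data, affine, voxel_size)`` with data as float64 and
    voxel_size the spatial zooms in mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except Exception as exc:  # re-raise with the offending filename
        raise ValueError(f"could not read NIfTI file {path}: {exc}") from exc
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine, dtype=float), voxel_size


def write_nifti(
    volume: np.ndarray, affine: np.ndarray, path: str | Path, dtype=np.float32
) -> None:
    """Write a volume as NIfTI with the given affine (float32 by default)."""
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
        dtype = np.uint8
    img = nib.Nifti1Image(vol.astype(dtype), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def load_dwi(
    dwi_path: str | Path, sidecar_path: str | Path
) -> tuple[np.ndarray, np.ndarray, tuple[float, ...], AcquisitionProtocol]:
    """Read a 4-D diffusion volume together with its b-tensor sidecar.

    Raises when the number of sidecar lines does not match the number of
    volumes (line order must match volume order).
    """
    data, affine, voxel_size = read_nifti(dwi_path)
    if data.ndim != 4:
        raise ValueError(f"{dwi_path}: expected a 4-D volume, got shape {data.shape}")
    protocol = read_sidecar(sidecar_path)
    if len(protocol) != data.shape[3]:
        raise ValueError(
            f"{dwi_path} has {data.shape[3]} volumes but sidecar "
            f"{sidecar_path} describes {len(protocol)}"
        )
    return data, affine, voxel_size, protocol
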