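"""Reading and writing volumes, series, displacement fields, masks and tables.

Primary on-disk format is NIfTI-1 (.nii / .nii.gz) via nibabel, with
MetaImage (.mha / .mhd) supported through SimpleITK.  Dynamic series are
4D NIfTI with time as the last axis plus a ``<stem>.times.json`` sidecar
holding the per-frame acquisition times in seconds; displacement fields
are 4D NIfTI with the 3-vector dimension last, values in mm; masks are
NIfTI with a 0/1 integer payload.  Geometry is taken from the header
(axis-aligned affine assumed); HU values pass through unscaled beyond any
header slope/intercept applied by nibabel.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import (
    DisplacementField,
    PerfusionSeries,
    ROIMask,
    ScalarVolume,
    VolumeGrid,
)

__all__ = [
    "SeriesIOError",
    "read_volume",
    "write_volume",
    "read_series",
    "write_series",
    "read_field",
    "write_field",
    "read_mask",
    "write_mask",
    "write_tdc_csv",
    "write_json",
]


class SeriesIOError(ValueError):
    """Raised for malformed or inconsistent image inputs."""


_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_SUFFIXES)


def _stem(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz",) + _NIFTI_SUFFIXES + _META_SUFFIXES:
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)])
    return path


def _times_sidecar(path: Path) -> Path:
    return _stem(path).with_name(_stem(path).name + ".times.json")


def _affine_from_grid(grid: VolumeGrid) -> np.ndarray:
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    return affine


def _grid_from_nifti(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms), origin)


def _load_nifti_data(path: Path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), _grid_from_nifti(img)


def _load_meta(path: Path) -> tuple[np.ndarray, VolumeGrid]:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # z, y, x order
    if data.ndim != 3:
        raise SeriesIOError(f"{path}: expected a 3D MetaImage, got {data.ndim}D")
    grid = VolumeGrid(
        tuple(int(n) for n in img.GetSize()),
        tuple(float(s) for s in img.GetSpacing()),
        tuple(float(o) for o in img.GetOrigin()),
    )
    return np.transpose(data, (2, 1, 0)).astype(float), grid


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a single 3D volume (NIfTI or MetaImage)."""
    path = Path(path)
    if _is_nifti(path):
        data, grid = _load_nifti_data(path)
        if data.ndim == 4 and data.shape[-1] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise SeriesIOError(
                f"{path}: expected a 3D volume, got {data.ndim}D "
                "(use read_series for dynamic data)"
            )
        return ScalarVolume(grid, data)
    if path.name.endswith(_META_SUFFIXES):
        data, grid = _load_meta(path)
        return ScalarVolume(grid, data)
    raise SeriesIOError(f"unsupported volume format: {path}")


def write_volume(volume: ScalarVolume, path: str | Path) -> None:
    path = Path(path)
    if _is_nifti(path):
        nib.save(
            nib.Nifti1Image(volume.values, _affine_from_grid(volume.grid)), str(path)
        )
        return
    if path.name.endswith(_META_SUFFIXES):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.transpose(volume.values, (2, 1, 0)))
        img.SetSpacing(volume.grid.spacing)
        img.SetOrigin(volume.grid.origin)
        sitk.WriteImage(img, str(path))
        return
    raise SeriesIOError(f"unsupported volume format: {path}")


def write_series(series: PerfusionSeries, path: str | Path) -> None:
    """Write a dynamic series as 4D NIfTI plus a times sidecar JSON."""
    path = Path(path)
    if not _is_nifti(path):
        raise SeriesIOError("series are written as 4D NIfTI (.nii/.nii.gz)")
    img = nib.Nifti1Image(series.as_array(), _affine_from_grid(series.grid))
    nib.save(img, str(path))
    _times_sidecar(path).write_text(json.dumps(list(map(float, series.times_s))))


def read_series(
    path: str | Path, times_s: np.ndarray | None = None
) -> PerfusionSeries:
    """Read a 4D NIfTI dynamic series.

    Acquisition times come from the ``times_s`` argument or a
    ``<stem>.times.json`` sidecar; frames are re-ordered by increasing
    time if needed.
    """
    path = Path(path)
    if not _is_nifti(path):
        raise SeriesIOError(f"unsupported series format: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        raise SeriesIOError(
            f"{path}: got a 3D volume where a 4D dynamic series was expected"
        )
    if data.ndim != 4:
        raise SeriesIOError(f"{path}: expected 4D data, got {data.ndim}D")
    grid = _grid_from_nifti(img)
    n = data.shape[-1]
    if times_s is None:
        sidecar = _times_sidecar(path)
        if not sidecar.exists():
            # Header TR is not trusted: writers default the 4th zoom to 1.0,
            # which is indistinguishable from a real repetition time.
            raise SeriesIOError(
                f"{path}: no acquisition times (pass times_s or provide "
                f"{sidecar.name})"
            )
        times_s = np.asarray(json.loads(sidecar.read_text()), dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if len(times_s) != n:
        raise SeriesIOError(
            f"{path}: {n} frames but {len(times_s)} acquisition times"
        )
    order = np.argsort(times_s, kind="stable")
    return PerfusionSeries.from_array(grid, data[..., order], times_s[order])


def write_field(field: DisplacementField, path: str | Path) -> None:
    """Write a displacement field as 4D NIfTI, vector dimension last, mm."""
    path = Path(path)
    if not _is_nifti(path):
        raise SeriesIOError("displacement fields are written as NIfTI")
    nib.save(nib.Nifti1Image(field.vectors, _affine_from_grid(field.grid)), str(path))


def read_field(path: str | Path) -> DisplacementField:
    path = Path(path)
    data, grid = _load_nifti_data(path)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise SeriesIOError(f"{path}: displacement field must be (nx, ny, nz, 3)")
    return DisplacementField(grid, data)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(
            mask.mask.astype(np.uint8), _affine_from_grid(mask.grid)
        ),
        str(path),
    )


def read_mask(path: str | Path, label: str | None = None) -> ROIMask:
    path = Path(path)
    data, grid = _load_nifti_data(path)
    if data.ndim != 3:
        raise SeriesIOError(f"{path}: mask must be 3D")
    return ROIMask(grid, data > 0.5, label or _stem(path).name)


def write_tdc_csv(tdc, path: str | Path) -> None:
    """Export a time-density curve as CSV (time_s, mean_hu, sd_hu, n_voxels)."""
    tdc.to_dataframe().to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
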