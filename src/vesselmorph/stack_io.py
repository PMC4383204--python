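"""Reading, writing and assembling section stacks and volumes.

Storage format is deliberately plain: multi-page TIFF for pixel data plus a
human-readable YAML sidecar carrying the physical metadata
(``spacing_z_um``, ``spacing_xy_um``, optional ``channel_names``).  Spacing
metadata is required on read — there are no silent defaults, because every
downstream morphometric quantity is in physical units.

Intensity images are stored at a chosen integer bit depth (or float32) and
rescaled to [0, 1] on load by dividing by the dtype maximum; label images
are stored as 8-bit codes without rescaling, so label round trips are
bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .containers import LabelVolume, SectionStack, Volume

__all__ = [
    "read_stack",
    "write_stack",
    "assemble_volume",
    "write_volume",
    "read_volume",
    "write_labels",
    "read_labels",
    "sidecar_path",
]

SIDECAR_SUFFIX = ".meta.yaml"


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    if path.is_dir():
        return path / ("stack" + SIDECAR_SUFFIX)
    return path.with_suffix(path.suffix + SIDECAR_SUFFIX)


def _write_sidecar(path: Path, metadata: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=True)


def _read_sidecar(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _rescale_on_load(pages: np.ndarray) -> np.ndarray:
    if np.issubdtype(pages.dtype, np.integer):
        info = np.iinfo(pages.dtype)
        return pages.astype(np.float32) / float(info.max)
    return pages.astype(np.float32)


def _load_metadata(path: Path, metadata: dict | None) -> dict:
    if metadata is None:
        sc = sidecar_path(path)
        if not sc.exists():
            raise ValueError(
                f"missing spacing metadata for {path}: provide a metadata dict or "
                f"a sidecar file {sc.name} (keys spacing_z_um, spacing_xy_um)"
            )
        metadata = _read_sidecar(sc)
    for key in ("spacing_z_um", "spacing_xy_um"):
        if key not in metadata:
            raise ValueError(f"metadata is missing required key {key!r}")
    return metadata


def read_stack(path: str | Path, metadata: dict | None = None) -> SectionStack:
    """Load a section stack from a multi-page TIFF or a directory of TIFFs.

    Directory entries must be named with a zero-padded index so lexical
    order is section order.  Pixel values are rescaled to [0, 1]; spacing
    comes from ``metadata`` or the sidecar file next to ``path``.
    """
    path = Path(path)
    metadata = _load_metadata(path, metadata)

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"no TIFF files found in directory {path}")
        pages = [tifffile.imread(f) for f in files]
        shape0 = pages[0].shape
        bad = [f.name for f, p in zip(files, pages) if p.shape != shape0]
        if bad:
            raise ValueError(
                f"sections with shapes inconsistent with {files[0].name} {shape0}: {bad}"
            )
        arr = np.stack(pages, axis=0)
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]

    arr = _rescale_on_load(arr)
    return SectionStack(
        sections=[arr[k] for k in range(arr.shape[0])],
        pixel_size_xy=float(metadata["spacing_xy_um"]),
        section_thickness=float(metadata["spacing_z_um"]),
        channel_names=metadata.get("channel_names"),
    )


def write_stack(stack: SectionStack, path: str | Path, dtype: str = "uint16") -> Path:
    """Write a stack as a multi-page TIFF plus a metadata sidecar.

    ``dtype`` is ``uint8``, ``uint16`` or ``float32``; integer depths
    quantize [0, 1] intensities to the full dtype range.
    """
    path = Path(path)
    arr = stack.as_array()
    if dtype in ("uint8", "uint16"):
        info = np.iinfo(np.dtype(dtype))
        arr = np.clip(np.round(np.clip(arr, 0.0, 1.0) * info.max), 0, info.max).astype(dtype)
    elif dtype == "float32":
        arr = arr.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {
        "spacing_z_um": float(stack.section_thickness),
        "spacing_xy_um": float(stack.pixel_size_xy),
    }
    if stack.channel_names is not None:
        meta["channel_names"] = list(stack.channel_names)
    _write_sidecar(sidecar_path(path), meta)
    return path


def assemble_volume(stack: SectionStack) -> Volume:
    """Stack aligned sections into an anisotropic volume.

    No resampling happens here: ``data[k]`` is section ``k`` and the voxel
    spacing is ``(section_thickness, pixel_size_xy, pixel_size_xy)``, so
    per-section intensity sums are preserved exactly.
    """
    return Volume(
        data=stack.as_array(),
        spacing=(stack.section_thickness, stack.pixel_size_xy, stack.pixel_size_xy),
        channel_names=stack.channel_names,
    )


def write_volume(volume: Volume, path: str | Path, dtype: str = "float32") -> Path:
    """Write an intensity volume as multi-page TIFF + sidecar."""
    path = Path(path)
    arr = volume.data
    if dtype in ("uint8", "uint16"):
        info = np.iinfo(np.dtype(dtype))
        arr = np.clip(np.round(np.clip(arr, 0.0, 1.0) * info.max), 0, info.max).astype(dtype)
    elif dtype == "float32":
        arr = arr.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {
        "spacing_z_um": volume.spacing[0],
        "spacing_xy_um": volume.spacing[1],
        "origin_um": [float(v) for v in volume.origin],
    }
    if volume.channel_names is not None:
        meta["channel_names"] = list(volume.channel_names)
    _write_sidecar(sidecar_path(path), meta)
    return path


def read_volume(path: str | Path, metadata: dict | None = None) -> Volume:
    path = Path(path)
    metadata = _load_metadata(path, metadata)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    arr = _rescale_on_load(arr)
    sz, sxy = float(metadata["spacing_z_um"]), float(metadata["spacing_xy_um"])
    origin = tuple(metadata.get("origin_um", (0.0, 0.0, 0.0)))
    return Volume(
        data=arr,
        spacing=(sz, sxy, sxy),
        origin=origin,
        channel_names=metadata.get("channel_names"),
    )


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as 8-bit multi-page TIFF (codes, no rescaling)."""
    path = Path(path)
    tifffile.imwrite(path, labels.data.astype(np.uint8), photometric="minisblack")
    _write_sidecar(
        sidecar_path(path),
        {
            "spacing_z_um": labels.spacing[0],
            "spacing_xy_um": labels.spacing[1],
            "origin_um": [float(v) for v in labels.origin],
            "content": "labels",
        },
    )
    return path


def read_labels(path: str | Path, metadata: dict | None = None) -> LabelVolume:
    path = Path(path)
    metadata = _load_metadata(path, metadata)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label file {path} does not hold integer data")
    sz, sxy = float(metadata["spacing_z_um"]), float(metadata["spacing_xy_um"])
    origin = tuple(metadata.get("origin_um", (0.0, 0.0, 0.0)))
    return LabelVolume(data=arr.astype(np.uint8), spacing=(sz, sxy, sxy), origin=origin)
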