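"""Core in-memory containers: section stacks, volumes, label volumes.

Conventions
-----------
* Array axis order is ``(z, y, x)`` (plus a trailing channel axis for
  multichannel data), with ``z`` the section order starting from the first
  (most proximal) slide.
* All physical coordinates are voxel-center positions in micrometres:
  ``position = origin + index * spacing``.
* Image intensities live in ``[0, 1]``; label codes are
  0 = background, 1 = lumen, 2 = neointima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Label codes used throughout the toolkit.
BACKGROUND = 0
LUMEN = 1
NEOINTIMA = 2
LABEL_CODES = (BACKGROUND, LUMEN, NEOINTIMA)
LABEL_NAMES = {BACKGROUND: "background", LUMEN: "lumen", NEOINTIMA: "neointima"}


@dataclass
class SectionStack:
    """An ordered stack of 2-D serial sections with physical spacing metadata.

    Parameters
    ----------
    sections:
        List of 2-D arrays ``(y, x)`` or ``(y, x, c)``; all must share shape.
    pixel_size_xy:
        In-plane pixel size in µm (isotropic in-plane).
    section_thickness:
        Physical thickness of each section in µm (the z step).
    channel_names:
        Optional channel labels for multichannel stacks.
    """

    sections: list[np.ndarray]
    pixel_size_xy: float
    section_thickness: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be positive")
        if len(self.sections) == 0:
            raise ValueError("stack must contain at least one section")
        shape0 = self.sections[0].shape
        bad = [k for k, s in enumerate(self.sections) if s.shape != shape0]
        if bad:
            raise ValueError(
                f"sections {bad} have shapes inconsistent with section 0 {shape0}"
            )

    def __len__(self) -> int:
        return len(self.sections)

    @property
    def section_shape(self) -> tuple[int, ...]:
        return self.sections[0].shape

    @property
    def n_channels(self) -> int:
        shape = self.section_shape
        return 1 if len(shape) == 2 else shape[2]

    def as_array(self) -> np.ndarray:
        """Stack the sections into one ``(z, y, x[, c])`` array."""
        return np.stack(self.sections, axis=0)


@dataclass
class Volume:
    """A reconstructed 3-D specimen: scalar or multichannel voxel data.

    ``spacing`` and ``origin`` are ``(z, y, x)`` triples in µm; z spacing
    equals the section thickness of the source stack.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.data.ndim not in (3, 4):
            raise ValueError("volume data must be 3-D or 3-D + channel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def physical_position(self, index: tuple[float, float, float]) -> np.ndarray:
        """Physical (z, y, x) µm position of a (possibly fractional) index."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def index_of(self, position: np.ndarray) -> np.ndarray:
        """Fractional (z, y, x) index of a physical position."""
        return (np.asarray(position) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class LabelVolume:
    """3-D integer class map over {background, lumen, neointima}."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.data.ndim != 3:
            raise ValueError("label data must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be an integer array")
        bad = np.setdiff1d(np.unique(self.data), np.asarray(LABEL_CODES))
        if bad.size:
            raise ValueError(f"label volume contains invalid codes {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def physical_position(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def index_of(self, position) -> np.ndarray:
        return (np.asarray(position) - np.asarray(self.origin)) / np.asarray(self.spacing)
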