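"""Core data containers shared across the package.

Coordinate conventions
----------------------
World coordinates are millimetres.  In the canonical (reoriented) frame the
index axes are, in order: labiolingual (x), mesiodistal (y) and apicocoronal
(z), with +z pointing apically.  A voxel with index ``i`` sits at world
position ``orientation @ (i * spacing_mm)``; the origin is the volume corner.

Semantic labels
---------------
``0`` background, ``1`` bone, ``2`` central-incisor root, ``3`` canine root,
``4`` enamel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

LABELS = {
    "background": 0,
    "bone": 1,
    "incisor_root": 2,
    "canine_root": 3,
    "enamel": 4,
}

BONE = LABELS["bone"]
INCISOR_ROOT = LABELS["incisor_root"]
CANINE_ROOT = LABELS["canine_root"]
ENAMEL = LABELS["enamel"]

#: the four assessment depths below the cementoenamel junction, in mm
ASSESSMENT_LEVELS_MM = (3.0, 5.0, 7.0, 9.0)


class GeometryError(ValueError):
    """Raised when a measurement cannot be made on the supplied geometry."""


class OutOfBoundsError(GeometryError):
    """A landmark or sampling plane falls outside the volume."""


class LandmarkRequiredError(GeometryError):
    """Automatic landmark detection is impossible; supply landmarks explicitly."""


@dataclass
class LabeledVolume:
    """A 3D integer label grid with isotropic spacing.

    Parameters
    ----------
    voxels
        Integer label array, axis order (x, y, z) as described in the module
        docstring.
    spacing_mm
        Isotropic voxel edge length in millimetres.
    orientation
        3x3 rotation matrix mapping index axes to world axes (defaults to
        identity, i.e. index axes == world axes).
    meta
        Free-form provenance (seed, transformed landmarks, CEJ index, ...).
    """

    voxels: np.ndarray
    spacing_mm: float
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must have an integer dtype")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 matrix")
        if not np.allclose(self.orientation @ self.orientation.T, np.eye(3), atol=1e-8):
            raise ValueError("orientation must be a rotation matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    def world_to_index(self, point_mm: np.ndarray) -> np.ndarray:
        """Continuous index coordinate of a world point."""
        return self.orientation.T @ np.asarray(point_mm, float) / self.spacing_mm

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        return self.orientation @ (np.asarray(index, float) * self.spacing_mm)

    def is_axis_canonical(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.orientation, np.eye(3), atol=atol))


@dataclass(frozen=True)
class ToothLandmarks:
    """Reference-tooth landmarks: CEJ point, apex point and apical long axis.

    ``axis_direction`` is a unit vector pointing apically from the CEJ; the
    apex must have positive projection onto it.
    """

    cej_point_mm: tuple[float, float, float]
    apex_point_mm: tuple[float, float, float]
    axis_direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis_direction, float)
        norm = float(np.linalg.norm(axis))
        if norm < 1e-12:
            raise ValueError("axis_direction must be non-degenerate")
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector (|a|=1 within 1e-9)")
        proj = float(
            (np.asarray(self.apex_point_mm) - np.asarray(self.cej_point_mm)) @ axis
        )
        if proj <= 0:
            raise ValueError("apex must lie apically of the CEJ along axis_direction")

    @property
    def cej(self) -> np.ndarray:
        return np.asarray(self.cej_point_mm, float)

    @property
    def apex(self) -> np.ndarray:
        return np.asarray(self.apex_point_mm, float)

    @property
    def axis(self) -> np.ndarray:
        return np.asarray(self.axis_direction, float)

    @property
    def root_length_mm(self) -> float:
        """Apical depth of the apex below the CEJ along the long axis."""
        return float((self.apex - self.cej) @ self.axis)

    def to_dict(self) -> dict[str, list[float]]:
        return {
            "cej_mm": list(map(float, self.cej_point_mm)),
            "apex_mm": list(map(float, self.apex_point_mm)),
            "axis": list(map(float, self.axis_direction)),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ToothLandmarks":
        return cls(tuple(d["cej_mm"]), tuple(d["apex_mm"]), tuple(d["axis"]))


@dataclass
class LevelSection:
    """A 2D cross-section perpendicular to the tooth axis at a given depth.

    ``image`` is a 2D label array; pixel (i, j) lies at
    ``origin_mm + i*spacing*u + j*spacing*v`` where (u, v, axis) is a
    right-handed orthonormal frame.
    """

    depth_mm: float
    image: np.ndarray
    spacing_mm: float
    axis: tuple[float, float, float]
    origin_mm: tuple[float, float, float] | None = None
    basis_u: tuple[float, float, float] | None = None
    basis_v: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.depth_mm > 0:
            raise ValueError("depth_mm must be positive")
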