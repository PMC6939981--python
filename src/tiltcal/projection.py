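"""Tilt application and AP radiographic projection of pelvic landmarks.

``apply_tilt`` rotates the whole pelvis rigidly about the mediolateral axis
through the centroid of the three anterior-pelvic-plane landmarks; positive
angles are anterior tilt.  ``project`` maps 3D landmarks to detector-plane
coordinates (u horizontal toward patient left, v vertical superior) either
by orthographic (parallel-beam) projection or by central projection from a
point source anterior to the patient, which introduces the depth-dependent
magnification of real AP radiography.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .anatomy import PelvisLandmarks3D
from .geometry import rotate_about_x

MAX_TILT_DEG = 89.0


@dataclass(frozen=True)
class ProjectionGeometry:
    """Source/detector arrangement governing magnification.

    Parameters
    ----------
    mode : {"perspective", "parallel"}
        Parallel-beam projection maps (x, y, z) -> (x, z) exactly.
        Perspective projection places a point source on the +y axis at
        ``source_image_distance - object_image_distance`` and the detector
        plane at y = -object_image_distance, so a point in the rotation
        center's plane (y = 0) is magnified by
        SID / (SID - OID).
    source_image_distance : float
        Source-to-detector distance (SID), mm.  Perspective only.
    object_image_distance : float
        Distance of the rotation-center plane from the detector (OID), mm.
    """

    mode: str = "perspective"
    source_image_distance: float = 1000.0
    object_image_distance: float = 150.0

    def __post_init__(self) -> None:
        if self.mode not in ("perspective", "parallel"):
            raise ValueError(f"unknown projection mode {self.mode!r}")
        if self.mode == "perspective":
            if not self.object_image_distance >= 0:
                raise ValueError("object_image_distance must be >= 0")
            if not self.source_image_distance > self.object_image_distance:
                raise ValueError(
                    "source_image_distance must exceed object_image_distance"
                )

    @classmethod
    def parallel(cls) -> "ProjectionGeometry":
        return cls(mode="parallel")

    @classmethod
    def perspective(cls, source_image_distance: float = 1000.0,
                    object_image_distance: float = 150.0) -> "ProjectionGeometry":
        return cls("perspective", source_image_distance, object_image_distance)

    @property
    def source_y(self) -> float:
        return self.source_image_distance - self.object_image_distance

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "source_image_distance": self.source_image_distance,
            "object_image_distance": self.object_image_distance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionGeometry":
        return cls(**d)


@dataclass
class ImageLandmarks2D:
    """Detector-plane (u, v) coordinates of the projected landmarks."""

    subject_id: str
    points: dict[str, np.ndarray]
    foramen_L: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    foramen_R: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    true_tilt_deg: float | None = None
    sex: str | None = None
    geometry: ProjectionGeometry | None = None

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        self.foramen_L = np.asarray(self.foramen_L, dtype=float).reshape(-1, 2)
        self.foramen_R = np.asarray(self.foramen_R, dtype=float).reshape(-1, 2)

    def copy(self) -> "ImageLandmarks2D":
        return ImageLandmarks2D(
            subject_id=self.subject_id,
            points={k: v.copy() for k, v in self.points.items()},
            foramen_L=self.foramen_L.copy(),
            foramen_R=self.foramen_R.copy(),
            true_tilt_deg=self.true_tilt_deg,
            sex=self.sex,
            geometry=self.geometry,
        )

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "sex": self.sex,
            "true_tilt_deg": self.true_tilt_deg,
            "geometry": self.geometry.to_dict() if self.geometry else None,
            "points": {k: [float(u) for u in v] for k, v in self.points.items()},
            "foramen_L": self.foramen_L.tolist(),
            "foramen_R": self.foramen_R.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageLandmarks2D":
        return cls(
            subject_id=d["subject_id"],
            points=d["points"],
            foramen_L=np.asarray(d.get("foramen_L", []), float).reshape(-1, 2),
            foramen_R=np.asarray(d.get("foramen_R", []), float).reshape(-1, 2),
            true_tilt_deg=d.get("true_tilt_deg"),
            sex=d.get("sex"),
            geometry=ProjectionGeometry.from_dict(d["geometry"]) if d.get("geometry") else None,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ImageLandmarks2D":
        return cls.from_dict(json.loads(Path(path).read_text()))


def apply_tilt(lm: PelvisLandmarks3D, tilt_deg: float) -> PelvisLandmarks3D:
    """Rigidly tilt the pelvis about the mediolateral axis through the APP centroid.

    Positive angles move the ASIS anteriorly relative to the symphysis
    (anterior tilt).  All pairwise 3D distances are preserved.
    """
    if abs(tilt_deg) > MAX_TILT_DEG:
        raise ValueError(
            f"|tilt| = {abs(tilt_deg)} deg exceeds {MAX_TILT_DEG} deg; "
            "the AP projection degenerates"
        )
    out = lm.copy()
    center = lm.app_centroid()
    for k in out.points:
        out.points[k] = rotate_about_x(out.points[k][None, :], tilt_deg, center)[0]
    out.foramen_L = rotate_about_x(out.foramen_L, tilt_deg, center)
    out.foramen_R = rotate_about_x(out.foramen_R, tilt_deg, center)
    return out


def _project_array(pts: np.ndarray, geom: ProjectionGeometry) -> np.ndarray:
    pts = np.asarray(pts, float).reshape(-1, 3)
    if geom.mode == "parallel":
        return pts[:, [0, 2]].copy()
    depth = geom.source_y - pts[:, 1]
    if np.any(depth <= 1e-9):
        raise ValueError("landmark at or behind the X-ray source plane")
    mag = geom.source_image_distance / depth
    return pts[:, [0, 2]] * mag[:, None]


def project(
    lm: PelvisLandmarks3D,
    geom: ProjectionGeometry,
    true_tilt_deg: float | None = None,
) -> ImageLandmarks2D:
    """Project 3D landmarks onto the detector plane."""
    names = list(lm.points)
    uv = _project_array(np.stack([lm.points[n] for n in names]), geom)
    return ImageLandmarks2D(
        subject_id=lm.subject_id,
        points=dict(zip(names, uv)),
        foramen_L=_project_array(lm.foramen_L, geom) if len(lm.foramen_L) else np.empty((0, 2)),
        foramen_R=_project_array(lm.foramen_R, geom) if len(lm.foramen_R) else np.empty((0, 2)),
        true_tilt_deg=true_tilt_deg,
        sex=lm.sex,
        geometry=geom,
    )


def synthesize_image(
    lm: PelvisLandmarks3D, tilt_deg: float, geom: ProjectionGeometry
) -> ImageLandmarks2D:
    """Tilt the pelvis then project it: one synthetic AP image at known APPt."""
    return project(apply_tilt(lm, tilt_deg), geom, true_tilt_deg=float(tilt_deg))
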