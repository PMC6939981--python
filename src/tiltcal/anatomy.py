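"""Parametric, gender-dimorphic 3D pelvis landmark model.

The package operates purely on named bony landmarks, so the anatomy module
ships one hand-placed landmark template per sex (in the canonical supine
pose: anterior pelvic plane vertical, APPt = 0) and a seeded generator that
emulates inter-subject variation with a global isotropic scale factor and
mirrored per-landmark shape noise.  Obturator foramina are modelled as
planar ellipse rims sampled densely along the boundary, because the
projected height/width extremes travel along the rim as the pelvis tilts.

Landmark names
--------------
ASIS_L / ASIS_R   anterior superior iliac spines
PS_ANT            anterior border of the pubic symphysis (on the APP)
PS_SUP            superior margin of the pubic symphysis
ISCH_L / ISCH_R   inferior ischial margins (transischial line)
SIJ_L / SIJ_R     inferior borders of the sacroiliac joints (trans-SI line)
OUTLET_L / OUTLET_R  lateral extremes of the pelvic outlet brim (POD)

Coordinates are mm in the frame x = patient left (+), y = anterior (+),
z = superior (+).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .geometry import APP_LANDMARKS, app_centroid, app_tilt_deg, rotate_about_x

REQUIRED_LANDMARKS = (
    "ASIS_L",
    "ASIS_R",
    "PS_SUP",
    "PS_ANT",
    "ISCH_L",
    "ISCH_R",
    "SIJ_L",
    "SIJ_R",
    "OUTLET_L",
    "OUTLET_R",
)

#: landmark pairs mirrored across the midsagittal (x = 0) plane
MIRROR_PAIRS = (
    ("ASIS_L", "ASIS_R"),
    ("ISCH_L", "ISCH_R"),
    ("SIJ_L", "SIJ_R"),
    ("OUTLET_L", "OUTLET_R"),
)

MIDLINE_LANDMARKS = ("PS_ANT", "PS_SUP")

SEXES = ("male", "female")

MIN_FORAMEN_POINTS = 16


def _mirror(p: np.ndarray) -> np.ndarray:
    """Reflect across the midsagittal plane (x -> -x)."""
    out = np.array(p, dtype=float)
    out[..., 0] = -out[..., 0]
    return out


def _ellipse_rim(center, p_axis, q_axis, n: int = 24) -> np.ndarray:
    """Sample n points on a planar ellipse rim: c + p cos t + q sin t."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    c = np.asarray(center, float)
    p = np.asarray(p_axis, float)
    q = np.asarray(q_axis, float)
    return c + np.outer(np.cos(t), p) + np.outer(np.sin(t), q)


# ---------------------------------------------------------------------------
# Sex-specific templates (fixture constants, canonical pose, APPt = 0).
#
# The female template is wider mediolaterally (larger ASIS and outlet
# separations, broader obturator foramina) and slightly deeper/taller in
# proportion, encoding the familiar sexual dimorphism of the pelvis.  The
# obturator foramen rim plane contains the mediolateral axis and an oblique
# anteroinferior-posterosuperior axis, so its projected height grows as the
# pelvis tilts anteriorly while its projected width stays near-constant.
# ---------------------------------------------------------------------------

_SQ2 = np.sqrt(2.0) / 2.0

_TEMPLATE_SPECS = {
    "male": {
        "points": {
            "ASIS_L": (114.0, 0.0, 92.0),
            "ASIS_R": (-114.0, 0.0, 92.0),
            "PS_ANT": (0.0, 0.0, 0.0),
            "PS_SUP": (0.0, -10.0, 8.0),
            "ISCH_L": (42.0, -110.0, -30.0),
            "ISCH_R": (-42.0, -110.0, -30.0),
            "SIJ_L": (40.0, -150.0, 70.0),
            "SIJ_R": (-40.0, -150.0, 70.0),
            "OUTLET_L": (62.0, -80.0, -25.0),
            "OUTLET_R": (-62.0, -80.0, -25.0),
        },
        "foramen_center": (55.0, -35.0, -45.0),
        "foramen_semi_major": 25.0,
        "foramen_semi_minor": 15.0,
    },
    "female": {
        "points": {
            "ASIS_L": (129.0, 0.0, 97.0),
            "ASIS_R": (-129.0, 0.0, 97.0),
            "PS_ANT": (0.0, 0.0, 0.0),
            "PS_SUP": (0.0, -10.0, 8.0),
            "ISCH_L": (47.0, -116.0, -32.0),
            "ISCH_R": (-47.0, -116.0, -32.0),
            "SIJ_L": (45.0, -158.0, 74.0),
            "SIJ_R": (-45.0, -158.0, 74.0),
            "OUTLET_L": (70.0, -84.0, -26.0),
            "OUTLET_R": (-70.0, -84.0, -26.0),
        },
        "foramen_center": (61.0, -36.0, -47.0),
        "foramen_semi_major": 25.0,
        "foramen_semi_minor": 17.0,
    },
}

#: in-plane axes of the foramen rim ellipse (unit): the major axis runs
#: obliquely from anteroinferior to posterosuperior, the minor axis is
#: mediolateral.
_FORAMEN_P_AXIS = np.array([0.0, -_SQ2, _SQ2])
_FORAMEN_Q_AXIS = np.array([1.0, 0.0, 0.0])

_FORAMEN_N_POINTS = 24


@dataclass
class PelvisLandmarks3D:
    """Named 3D anatomical landmarks (+ obturator rim samples) for one subject."""

    subject_id: str
    sex: str
    points: dict[str, np.ndarray]
    foramen_L: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    foramen_R: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        self.foramen_L = np.asarray(self.foramen_L, dtype=float).reshape(-1, 3)
        self.foramen_R = np.asarray(self.foramen_R, dtype=float).reshape(-1, 3)

    # -- invariants ---------------------------------------------------------

    def validate(self, asymmetry_tol_mm: float = 2.0, require_canonical: bool = False) -> None:
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.points]
        if missing:
            raise ValueError(f"missing required landmarks: {missing}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        for name, p in self.points.items():
            if not np.all(np.isfinite(p)):
                raise ValueError(f"non-finite coordinates for landmark {name!r}")
        for rim, side in ((self.foramen_L, "L"), (self.foramen_R, "R")):
            if len(rim) < MIN_FORAMEN_POINTS:
                raise ValueError(
                    f"foramen_{side} has {len(rim)} rim samples; "
                    f"need at least {MIN_FORAMEN_POINTS}"
                )
            if not np.all(np.isfinite(rim)):
                raise ValueError(f"non-finite coordinates in foramen_{side}")
        for left, right in MIRROR_PAIRS:
            err = np.max(np.abs(_mirror(self.points[left]) - self.points[right]))
            if err > asymmetry_tol_mm:
                raise ValueError(
                    f"{left}/{right} asymmetry {err:.3f} mm exceeds {asymmetry_tol_mm} mm"
                )
        if require_canonical and abs(self.app_tilt_deg()) > 1e-9:
            raise ValueError(f"not in canonical pose: APPt = {self.app_tilt_deg():.3e} deg")

    # -- derived quantities -------------------------------------------------

    def app_tilt_deg(self) -> float:
        return app_tilt_deg(*(self.points[n] for n in APP_LANDMARKS))

    def app_centroid(self) -> np.ndarray:
        return app_centroid(*(self.points[n] for n in APP_LANDMARKS))

    def all_coordinates(self) -> np.ndarray:
        """All landmark + rim coordinates stacked into one (n, 3) array."""
        pts = [self.points[n] for n in sorted(self.points)]
        return np.vstack([np.stack(pts), self.foramen_L, self.foramen_R])

    def copy(self) -> "PelvisLandmarks3D":
        return PelvisLandmarks3D(
            subject_id=self.subject_id,
            sex=self.sex,
            points={k: v.copy() for k, v in self.points.items()},
            foramen_L=self.foramen_L.copy(),
            foramen_R=self.foramen_R.copy(),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "sex": self.sex,
            "points": {k: [float(x) for x in v] for k, v in self.points.items()},
            "foramen_L": self.foramen_L.tolist(),
            "foramen_R": self.foramen_R.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PelvisLandmarks3D":
        return cls(
            subject_id=d["subject_id"],
            sex=d["sex"],
            points=d["points"],
            foramen_L=np.asarray(d.get("foramen_L", []), float).reshape(-1, 3),
            foramen_R=np.asarray(d.get("foramen_R", []), float).reshape(-1, 3),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PelvisLandmarks3D":
        return cls.from_dict(json.loads(Path(path).read_text()))


def write_landmarks_csv(subjects: Iterable[PelvisLandmarks3D], path: str | Path) -> None:
    """Flat CSV: one row per landmark (rim samples as foramen_S_ii)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "sex", "landmark", "x", "y", "z"])
        for lm in subjects:
            for name in sorted(lm.points):
                x, y, z = (float(v) for v in lm.points[name])
                w.writerow([lm.subject_id, lm.sex, name, repr(x), repr(y), repr(z)])
            for side, rim in (("L", lm.foramen_L), ("R", lm.foramen_R)):
                for i, (x, y, z) in enumerate(rim.astype(float)):
                    w.writerow(
                        [lm.subject_id, lm.sex, f"foramen_{side}_{i:02d}",
                         repr(float(x)), repr(float(y)), repr(float(z))]
                    )


def read_landmarks_csv(path: str | Path) -> list[PelvisLandmarks3D]:
    rows: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            d = rows.setdefault(
                rec["subject_id"],
                {"sex": rec["sex"], "points": {}, "foramen_L": [], "foramen_R": []},
            )
            xyz = [float(rec["x"]), float(rec["y"]), float(rec["z"])]
            name = rec["landmark"]
            if name.startswith("foramen_L_"):
                d["foramen_L"].append(xyz)
            elif name.startswith("foramen_R_"):
                d["foramen_R"].append(xyz)
            else:
                d["points"][name] = xyz
    return [
        PelvisLandmarks3D(subject_id=sid, sex=d["sex"], points=d["points"],
                          foramen_L=d["foramen_L"], foramen_R=d["foramen_R"])
        for sid, d in rows.items()
    ]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def template_landmarks(sex: str) -> PelvisLandmarks3D:
    """Fixed canonical landmark template for one sex (APPt = 0).

    The templates are package constants; repeated calls return identical
    coordinate sets.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
    spec = _TEMPLATE_SPECS[sex]
    center_l = np.asarray(spec["foramen_center"], float)
    p = spec["foramen_semi_major"] * _FORAMEN_P_AXIS
    q = spec["foramen_semi_minor"] * _FORAMEN_Q_AXIS
    rim_l = _ellipse_rim(center_l, p, q, _FORAMEN_N_POINTS)
    lm = PelvisLandmarks3D(
        subject_id=f"template_{sex}",
        sex=sex,
        points={k: np.asarray(v, float) for k, v in spec["points"].items()},
        foramen_L=rim_l,
        foramen_R=_mirror(rim_l),
    )
    lm.validate(asymmetry_tol_mm=1e-9, require_canonical=True)
    return lm


def _truncated_scale(rng: np.random.Generator, scale_sd: float) -> float:
    """Global scale ~ N(1, scale_sd) truncated to [0.8, 1.2] (rejection)."""
    if scale_sd == 0.0:
        return 1.0
    while True:
        s = rng.normal(1.0, scale_sd)
        if 0.8 <= s <= 1.2:
            return float(s)


def generate_pelvis(
    sex: str,
    seed: int,
    scale_sd: float = 0.05,
    shape_sd_mm: float = 1.5,
    subject_id: str | None = None,
) -> PelvisLandmarks3D:
    """Draw one synthetic pelvis from the sex template.

    A single isotropic scale factor (N(1, scale_sd), truncated to
    [0.8, 1.2]) emulates size variation; independent per-landmark Gaussian
    perturbations (sd ``shape_sd_mm``), mirrored across the midsagittal
    plane so no pelvic obliquity is introduced, emulate shape variation.
    The result is re-normalized to the canonical pose (APPt = 0).
    Deterministic for a given seed.
    """
    if scale_sd < 0 or shape_sd_mm < 0:
        raise ValueError("scale_sd and shape_sd_mm must be non-negative")
    lm = template_landmarks(sex)
    lm.subject_id = subject_id if subject_id is not None else f"{sex}_{seed}"
    rng = np.random.default_rng(seed)
    s = _truncated_scale(rng, scale_sd)
    for k in lm.points:
        lm.points[k] = lm.points[k] * s
    lm.foramen_L = lm.foramen_L * s
    lm.foramen_R = lm.foramen_R * s

    if shape_sd_mm > 0.0:
        for name in MIDLINE_LANDMARKS:
            d = rng.normal(0.0, shape_sd_mm, size=3)
            d[0] = 0.0  # midline landmarks stay on the midsagittal plane
            lm.points[name] = lm.points[name] + d
        for left, right in MIRROR_PAIRS:
            d = rng.normal(0.0, shape_sd_mm, size=3)
            lm.points[left] = lm.points[left] + d
            lm.points[right] = lm.points[right] + _mirror(d)
        d_rim = rng.normal(0.0, shape_sd_mm, size=lm.foramen_L.shape)
        lm.foramen_L = lm.foramen_L + d_rim
        lm.foramen_R = lm.foramen_R + _mirror(d_rim)

    # re-normalize: one rotation about x restores APP verticality exactly,
    # because mirrored noise keeps the ASIS axis parallel to x
    residual = lm.app_tilt_deg()
    if residual != 0.0:
        center = lm.app_centroid()
        for k in lm.points:
            lm.points[k] = rotate_about_x(lm.points[k][None, :], -residual, center)[0]
        lm.foramen_L = rotate_about_x(lm.foramen_L, -residual, center)
        lm.foramen_R = rotate_about_x(lm.foramen_R, -residual, center)
    lm.validate(asymmetry_tol_mm=2.0 if shape_sd_mm <= 2.0 else 4 * shape_sd_mm)
    return lm


def generate_cohort(
    n_male: int,
    n_female: int,
    seed: int,
    scale_sd: float = 0.05,
    shape_sd_mm: float = 1.5,
) -> list[PelvisLandmarks3D]:
    """Seeded cohort of n_male + n_female subjects with unique ids.

    Per-subject sub-seeds are derived from ``seed`` via a SeedSequence so
    each subject's anatomy is independent yet fully reproducible.
    """
    if n_male < 0 or n_female < 0:
        raise ValueError("subject counts must be non-negative")
    n = n_male + n_female
    sub_seeds = np.random.SeedSequence(seed).generate_state(max(n, 1), dtype=np.uint32)
    cohort = []
    for i in range(n):
        sex = "male" if i < n_male else "female"
        idx = i if i < n_male else i - n_male
        cohort.append(
            generate_pelvis(
                sex,
                int(sub_seeds[i]),
                scale_sd=scale_sd,
                shape_sd_mm=shape_sd_mm,
                subject_id=f"{sex[0].upper()}{idx + 1:02d}",
            )
        )
    return cohort
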