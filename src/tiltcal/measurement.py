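"""The eight candidate radiographic parameters plus the POD scaling distance.

All reference lines are straight lines through a landmark pair on the AP
image: the transischial line (ISCH_L-ISCH_R), the trans-SI line
(SIJ_L-SIJ_R) and the trans-ASIS line (ASIS_L-ASIS_R).  Each distance is
the *signed* vertical (v-axis) separation evaluated at a stated horizontal
position:

====  =====================================================================
PSTI  v(PS_SUP) - v(transischial line)            at u(PS_SUP)
PSSI  v(trans-SI line) - v(PS_SUP)                at u(PS_SUP)
OFH   mean over sides of the projected foramen rim's vertical extent
OFR   OFH / mean projected foramen width (dimensionless)
TISI  v(trans-SI line) - v(transischial line)     at the midline u
PSTA  v(trans-ASIS line) - v(PS_SUP)              at u(PS_SUP)
TITA  v(trans-ASIS line) - v(transischial line)   at the midline u
SITA  v(trans-SI line) - v(trans-ASIS line)       at the midline u
POD   separation of the two outlet extremes parallel to the transischial line
====  =====================================================================

Signed values matter: with enough tilt the symphysis can cross the
transischial line, and clamping at zero would destroy the monotone
tilt-parameter relationship the nomogram inverts.  SITA is oriented so that
anterior tilt, which elevates the deep posterior SI joints on the image
much faster than the ASIS, *increases* it.

A parameter whose defining landmarks are absent from the image is flagged
(not silently zeroed); the others are still computed, mirroring the missed
measurements of manual radiograph reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import math

import numpy as np

from .projection import ImageLandmarks2D

PARAMETER_NAMES = ("psti", "pssi", "ofh", "ofr", "tisi", "psta", "tita", "sita", "pod")

#: parameters measured in mm (everything except the dimensionless OFR)
MM_PARAMETERS = tuple(p for p in PARAMETER_NAMES if p != "ofr")

_LINE_LANDMARKS = {
    "transischial": ("ISCH_L", "ISCH_R"),
    "trans_si": ("SIJ_L", "SIJ_R"),
    "trans_asis": ("ASIS_L", "ASIS_R"),
}

#: landmarks required by each parameter (rims handled separately)
PARAMETER_REQUIREMENTS = {
    "psti": ("PS_SUP", "ISCH_L", "ISCH_R"),
    "pssi": ("PS_SUP", "SIJ_L", "SIJ_R"),
    "ofh": (),
    "ofr": (),
    "tisi": ("ISCH_L", "ISCH_R", "SIJ_L", "SIJ_R"),
    "psta": ("PS_SUP", "ASIS_L", "ASIS_R"),
    "tita": ("ISCH_L", "ISCH_R", "ASIS_L", "ASIS_R"),
    "sita": ("SIJ_L", "SIJ_R", "ASIS_L", "ASIS_R"),
    "pod": ("OUTLET_L", "OUTLET_R", "ISCH_L", "ISCH_R"),
}


@dataclass
class ParameterSet:
    """One image's candidate parameters; flagged entries are NaN."""

    psti: float = math.nan
    pssi: float = math.nan
    ofh: float = math.nan
    ofr: float = math.nan
    tisi: float = math.nan
    psta: float = math.nan
    tita: float = math.nan
    sita: float = math.nan
    pod: float = math.nan
    of_height_mm: float = math.nan
    of_width_mm: float = math.nan
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.flags = frozenset(self.flags)
        for name in self.flags:
            if name not in PARAMETER_NAMES:
                raise ValueError(f"unknown flagged parameter {name!r}")
        for name in PARAMETER_NAMES:
            v = getattr(self, name)
            if name in self.flags:
                if not math.isnan(v):
                    raise ValueError(f"flagged parameter {name!r} must carry no value")
            elif not math.isfinite(v):
                raise ValueError(f"parameter {name!r} is not finite and not flagged")

    def value(self, name: str) -> float:
        if name not in PARAMETER_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in PARAMETER_NAMES}
        d["of_height_mm"] = self.of_height_mm
        d["of_width_mm"] = self.of_width_mm
        return d

    @property
    def psti_pod_ratio(self) -> float:
        """PSTI normalized by POD: the scale-free quantity the nomogram uses."""
        if "psti" in self.flags or "pod" in self.flags:
            return math.nan
        return self.psti / self.pod


@dataclass(frozen=True)
class MeasurementNoiseModel:
    """Gaussian landmark-digitization noise with triplicate averaging.

    ``landmark_sd_mm`` is the isotropic standard deviation added to every
    landmark's (u, v); ``replicates`` independent noisy readings are
    averaged, emulating manual measurement completed in triplicate.
    """

    landmark_sd_mm: float = 0.5
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.landmark_sd_mm < 0:
            raise ValueError("landmark_sd_mm must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _line_v_at(p1: np.ndarray, p2: np.ndarray, u: float) -> float:
    """v of the straight line through p1, p2 evaluated at horizontal u."""
    du = p2[0] - p1[0]
    if abs(du) < 1e-12:
        raise ValueError("degenerate (vertical) reference line")
    return float(p1[1] + (p2[1] - p1[1]) * (u - p1[0]) / du)


def measure_parameters(img: ImageLandmarks2D) -> ParameterSet:
    """Compute all candidate parameters from one image's landmarks.

    Missing landmarks flag only the parameters that need them; if every
    parameter would be flagged the image is rejected.
    """
    pts = img.points
    flags: set[str] = set()
    values: dict[str, float] = {}

    def have(names: Iterable[str]) -> bool:
        return all(n in pts for n in names)

    def line_v(line: str, u: float) -> float:
        a, b = _LINE_LANDMARKS[line]
        return _line_v_at(pts[a], pts[b], u)

    def midline_u(*lines: str) -> float:
        names = [n for line in lines for n in _LINE_LANDMARKS[line]]
        return float(np.mean([pts[n][0] for n in names]))

    for name in ("psti", "pssi", "tisi", "psta", "tita", "sita", "pod"):
        if not have(PARAMETER_REQUIREMENTS[name]):
            flags.add(name)

    if "psti" not in flags:
        u = pts["PS_SUP"][0]
        values["psti"] = pts["PS_SUP"][1] - line_v("transischial", u)
    if "pssi" not in flags:
        u = pts["PS_SUP"][0]
        values["pssi"] = line_v("trans_si", u) - pts["PS_SUP"][1]
    if "tisi" not in flags:
        u = midline_u("transischial", "trans_si")
        values["tisi"] = line_v("trans_si", u) - line_v("transischial", u)
    if "psta" not in flags:
        u = pts["PS_SUP"][0]
        values["psta"] = line_v("trans_asis", u) - pts["PS_SUP"][1]
    if "tita" not in flags:
        u = midline_u("transischial", "trans_asis")
        values["tita"] = line_v("trans_asis", u) - line_v("transischial", u)
    if "sita" not in flags:
        u = midline_u("trans_si", "trans_asis")
        values["sita"] = line_v("trans_si", u) - line_v("trans_asis", u)
    if "pod" not in flags:
        d = pts["ISCH_L"] - pts["ISCH_R"]
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            flags.add("pod")
        else:
            values["pod"] = float(abs(np.dot(pts["OUTLET_L"] - pts["OUTLET_R"], d / norm)))

    of_height = of_width = math.nan
    if len(img.foramen_L) and len(img.foramen_R):
        heights, widths = [], []
        for rim in (img.foramen_L, img.foramen_R):
            heights.append(float(rim[:, 1].max() - rim[:, 1].min()))
            widths.append(float(rim[:, 0].max() - rim[:, 0].min()))
        of_height = float(np.mean(heights))
        of_width = float(np.mean(widths))
        values["ofh"] = of_height
        if of_width > 1e-12:
            values["ofr"] = of_height / of_width
        else:
            flags.add("ofr")
    else:
        flags.update(("ofh", "ofr"))

    if len(flags) == len(PARAMETER_NAMES):
        raise ValueError("no parameter could be measured: all landmarks missing")

    return ParameterSet(
        **{n: values.get(n, math.nan) for n in PARAMETER_NAMES},
        of_height_mm=of_height,
        of_width_mm=of_width,
        flags=frozenset(flags),
    )


def _perturbed(img: ImageLandmarks2D, rng: np.random.Generator, sd: float) -> ImageLandmarks2D:
    out = img.copy()
    for k in out.points:
        out.points[k] = out.points[k] + rng.normal(0.0, sd, size=2)
    if len(out.foramen_L):
        out.foramen_L = out.foramen_L + rng.normal(0.0, sd, size=out.foramen_L.shape)
    if len(out.foramen_R):
        out.foramen_R = out.foramen_R + rng.normal(0.0, sd, size=out.foramen_R.shape)
    return out


def perturb_and_average(
    img: ImageLandmarks2D, noise: MeasurementNoiseModel
) -> ParameterSet:
    """Noisy replicate measurements of one image, averaged per parameter.

    Each replicate adds independent isotropic Gaussian noise to every
    landmark and rim sample, re-measures, and the replicate values are
    averaged.  Deterministic given ``noise.seed``; with zero noise this
    reduces exactly to :func:`measure_parameters`.
    """
    if noise.landmark_sd_mm == 0.0:
        base = measure_parameters(img)
        return base
    rng = np.random.default_rng(noise.seed)
    reps = [
        measure_parameters(_perturbed(img, rng, noise.landmark_sd_mm))
        for _ in range(noise.replicates)
    ]
    flags = reps[0].flags
    mean = {
        n: (float(np.mean([r.value(n) for r in reps])) if n not in flags else math.nan)
        for n in PARAMETER_NAMES
    }
    return ParameterSet(
        **mean,
        of_height_mm=float(np.mean([r.of_height_mm for r in reps])),
        of_width_mm=float(np.mean([r.of_width_mm for r in reps])),
        flags=flags,
    )
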