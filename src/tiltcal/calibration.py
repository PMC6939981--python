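"""Calibration sweep, parameter screening and the PSTI/POD tilt nomogram.

The nomogram is the package's core fitted object: per sex, true APP tilt is
regressed on the scale-free ratio PSTI/POD over a calibration sweep of
synthetic images (-30..+30 deg in 5 deg steps by default).  Dividing by the
pelvic outlet distance removes radiographic magnification, so the fitted
curve transfers between imaging geometries.  The model/results split
follows the statsmodels convention: :class:`NomogramModel` holds the data,
``fit()`` returns a :class:`NomogramResults` carrying coefficients,
diagnostics, the valid ratio range, ``summary()`` and tilt estimation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .anatomy import PelvisLandmarks3D, SEXES
from .measurement import (
    MM_PARAMETERS,
    PARAMETER_NAMES,
    PARAMETER_REQUIREMENTS,
    MeasurementNoiseModel,
    ParameterSet,
    measure_parameters,
    perturb_and_average,
)
from .projection import ImageLandmarks2D, ProjectionGeometry, synthesize_image
from . import stats as tstats

DEFAULT_TILTS_DEG = tuple(range(-30, 31, 5))  # 13 calibration orientations
TILT_RANGE_DEG = (-30.0, 30.0)
MAX_CALIBRATION_TILT = 89.0

_TABLE_COLUMNS = ["subject_id", "sex", "true_tilt_deg", *PARAMETER_NAMES, "flags"]


@dataclass
class CalibrationTable:
    """Rows of (subject, sex, true tilt, parameters) plus provenance.

    The synthesized images are retained so screening can re-measure them
    under replicate noise (repeatability ICC) without re-running the
    projection step.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    images: list[ImageLandmarks2D] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df):
            dup = self.df.duplicated(subset=["subject_id", "true_tilt_deg"])
            if dup.any():
                raise ValueError("duplicate (subject_id, true_tilt_deg) rows")

    def __len__(self) -> int:
        return len(self.df)

    def for_sex(self, sex: str) -> pd.DataFrame:
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        return self.df[self.df["sex"] == sex]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: dict | None = None) -> "CalibrationTable":
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
        if "flags" in df.columns:
            df["flags"] = df["flags"].fillna("").astype(str)
        return cls(df=df, provenance=provenance or {})


def build_calibration_table(
    cohort: Sequence[PelvisLandmarks3D],
    tilts_deg: Sequence[float] = DEFAULT_TILTS_DEG,
    geom: ProjectionGeometry | None = None,
    noise: MeasurementNoiseModel | None = None,
) -> CalibrationTable:
    """One row per subject x tilt: synthesize, (optionally noisily) measure.

    With ``noise`` given, each image is measured through replicate
    perturbation and averaging with a per-row sub-seed derived from
    ``noise.seed``; otherwise measurement is exact.
    """
    tilts = [float(t) for t in tilts_deg]
    if len(cohort) and not tilts:
        raise ValueError("tilts_deg must be non-empty")
    if any(abs(t) > MAX_CALIBRATION_TILT for t in tilts):
        raise ValueError(f"calibration tilts must lie within +/-{MAX_CALIBRATION_TILT} deg")
    geom = geom or ProjectionGeometry()
    rows, images = [], []
    if noise is not None:
        sub_seeds = np.random.SeedSequence(noise.seed).generate_state(
            max(len(cohort) * len(tilts), 1), dtype=np.uint32
        )
    for i, lm in enumerate(cohort):
        for j, tilt in enumerate(tilts):
            img = synthesize_image(lm, tilt, geom)
            if noise is None:
                ps = measure_parameters(img)
            else:
                row_noise = MeasurementNoiseModel(
                    noise.landmark_sd_mm, noise.replicates,
                    int(sub_seeds[i * len(tilts) + j]),
                )
                ps = perturb_and_average(img, row_noise)
            rows.append(
                {
                    "subject_id": lm.subject_id,
                    "sex": lm.sex,
                    "true_tilt_deg": tilt,
                    **{n: ps.value(n) for n in PARAMETER_NAMES},
                    "flags": ";".join(sorted(ps.flags)),
                }
            )
            images.append(img)
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    provenance = {
        "geometry": geom.to_dict(),
        "tilts_deg": tilts,
        "noise": None
        if noise is None
        else {"landmark_sd_mm": noise.landmark_sd_mm, "replicates": noise.replicates,
              "seed": noise.seed},
        "n_subjects": len(cohort),
    }
    return CalibrationTable(df=df, provenance=provenance, images=images)


# ---------------------------------------------------------------------------
# Parameter screening
# ---------------------------------------------------------------------------


def evaluate_parameters(
    table: CalibrationTable,
    noise: MeasurementNoiseModel | None = None,
    miss_probabilities: dict[str, float] | None = None,
    miss_seed: int = 0,
) -> pd.DataFrame:
    """Screen each candidate parameter for tilt sensitivity and repeatability.

    Returns one row per parameter with

    - ``r``: pooled Pearson correlation between true tilt and the
      POD-normalized parameter (OFR, already dimensionless, is used raw);
      undefined (constant) columns are reported as NaN with a note, never
      silently as zero;
    - ``r_p_value``: two-sided p of the correlation test;
    - ``icc``: ICC(2,1) repeatability across ``noise.replicates`` noisy
      re-measurements of the same stored images (1.0 exactly when the noise
      is zero);
    - ``miss_rate``: fraction of images in which the parameter could not be
      measured under the caller-supplied landmark-availability scenario
      (``miss_probabilities``: landmark name -> independent miss chance).

    Rows are sorted by |r| (descending), ties by ICC.
    """
    if not len(table.df):
        raise ValueError("calibration table is empty")
    noise = noise or MeasurementNoiseModel(landmark_sd_mm=0.0, replicates=3, seed=0)
    df = table.df
    out = []

    # repeatability: replicate noisy readings of every stored image
    icc_values: dict[str, float] = {}
    if table.images:
        k = noise.replicates
        seeds = np.random.SeedSequence(noise.seed).generate_state(
            len(table.images) * k, dtype=np.uint32
        )
        readings = {n: np.empty((len(table.images), k)) for n in PARAMETER_NAMES}
        from .measurement import _perturbed  # replicate = one noisy reading

        for i, img in enumerate(table.images):
            for j in range(k):
                rng = np.random.default_rng(int(seeds[i * k + j]))
                noisy = img if noise.landmark_sd_mm == 0.0 else _perturbed(img, rng, noise.landmark_sd_mm)
                ps = measure_parameters(noisy)
                for n in PARAMETER_NAMES:
                    readings[n][i, j] = ps.value(n)
        for n in PARAMETER_NAMES:
            mat = readings[n]
            ok = ~np.isnan(mat).any(axis=1)
            if ok.sum() >= 2 and np.ptp(mat[ok]) > 0:
                icc_values[n] = tstats.icc_2_1(mat[ok])
            elif ok.sum() >= 2:
                icc_values[n] = 1.0  # identical replicates everywhere
            else:
                icc_values[n] = math.nan

    # availability scenario
    miss_rates = {n: 0.0 for n in PARAMETER_NAMES}
    if miss_probabilities:
        rng = np.random.default_rng(miss_seed)
        n_img = len(df)
        lost = {
            lmk: rng.random(n_img) < p for lmk, p in miss_probabilities.items()
        }
        for n in PARAMETER_NAMES:
            req = PARAMETER_REQUIREMENTS.get(n, ())
            if n in ("ofh", "ofr"):
                # scenario keys FORAMEN_L / FORAMEN_R stand for a whole rim
                req = ("FORAMEN_L", "FORAMEN_R")
            if not req:
                continue
            missed = np.zeros(n_img, dtype=bool)
            for lmk in req:
                if lmk in lost:
                    missed |= lost[lmk]
            miss_rates[n] = float(missed.mean())

    tilt = df["true_tilt_deg"].to_numpy(float)
    for n in (p for p in PARAMETER_NAMES if p != "pod"):
        vals = df[n].to_numpy(float)
        if n in MM_PARAMETERS:
            vals = vals / df["pod"].to_numpy(float)
        ok = np.isfinite(vals) & np.isfinite(tilt)
        note = ""
        if ok.sum() < 3:
            r = p = math.nan
            note = "insufficient data"
        elif np.ptp(vals[ok]) == 0.0 or np.ptp(tilt[ok]) == 0.0:
            r = p = math.nan
            note = "undefined: constant input"
        else:
            r, p = tstats.pearson_r(tilt[ok], vals[ok], return_p=True)
        out.append(
            {
                "parameter": n,
                "r": r,
                "r_p_value": p,
                "icc": icc_values.get(n, math.nan),
                "miss_rate": miss_rates[n],
                "n": int(ok.sum()),
                "note": note,
            }
        )
    report = pd.DataFrame(out)
    report = report.reindex(
        report.assign(abs_r=report["r"].abs())
        .sort_values(["abs_r", "icc"], ascending=[False, False])
        .index
    ).reset_index(drop=True)
    return report


# ---------------------------------------------------------------------------
# Nomogram model / results
# ---------------------------------------------------------------------------

NOMOGRAM_FORMS = ("linear", "quadratic")


@dataclass
class TiltEstimate:
    """A single APP-tilt estimate from one (PSTI, POD) pair."""

    appt_deg: float
    extrapolated: bool
    nomogram_id: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.appt_deg):
            raise ValueError("tilt estimate is not finite")


class NomogramModel:
    """Regression of true APP tilt on the PSTI/POD ratio for one sex.

    Parameters
    ----------
    tilt_deg, ratio : array-like
        Calibration observations (true tilt, PSTI/POD).
    sex : {"male", "female"}
    form : {"linear", "quadratic"}
        Polynomial degree of tilt = f(ratio).  The exact relationship is
        trigonometric; over +/-30 deg a line captures most of it and the
        quadratic removes the residual even (cos) component.
    """

    def __init__(self, tilt_deg, ratio, sex: str, form: str = "linear") -> None:
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        if form not in NOMOGRAM_FORMS:
            raise ValueError(f"unknown nomogram form {form!r}")
        tilt = np.asarray(tilt_deg, float)
        r = np.asarray(ratio, float)
        if tilt.shape != r.shape or tilt.ndim != 1:
            raise ValueError("tilt_deg and ratio must be 1-D arrays of equal length")
        ok = np.isfinite(tilt) & np.isfinite(r)
        self.tilt_deg = tilt[ok]
        self.ratio = r[ok]
        self.sex = sex
        self.form = form
        if len(np.unique(self.tilt_deg)) < 2:
            raise ValueError("need at least 2 distinct tilt values to fit a nomogram")
        if np.ptp(self.ratio) == 0.0:
            raise ValueError("degenerate design: PSTI/POD ratio is constant")

    @classmethod
    def from_calibration_table(
        cls, table: CalibrationTable, sex: str, form: str = "linear"
    ) -> "NomogramModel":
        df = table.for_sex(sex)
        flagged = df["flags"].fillna("").str.contains("psti|pod", regex=True)
        df = df[~flagged]
        if not len(df):
            raise ValueError(f"no usable rows for sex {sex!r} (PSTI/POD flagged or absent)")
        return cls(
            df["true_tilt_deg"].to_numpy(float),
            (df["psti"] / df["pod"]).to_numpy(float),
            sex=sex,
            form=form,
        )

    def fit(self) -> "NomogramResults":
        """Least-squares fit; a non-monotone quadratic is rejected."""
        deg = 1 if self.form == "linear" else 2
        coef = np.polyfit(self.ratio, self.tilt_deg, deg)
        lo, hi = float(self.ratio.min()), float(self.ratio.max())
        if self.form == "quadratic":
            # f'(r) = 2 a r + b must not change sign on [lo, hi]
            d_lo = 2 * coef[0] * lo + coef[1]
            d_hi = 2 * coef[0] * hi + coef[1]
            if d_lo * d_hi <= 0:
                raise ValueError(
                    "quadratic nomogram is not monotone over the calibrated ratio range"
                )
        resid = self.tilt_deg - np.polyval(coef, self.ratio)
        dof = max(len(resid) - (deg + 1), 1)
        residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
        r = tstats.pearson_r(self.ratio, self.tilt_deg)
        return NomogramResults(
            sex=self.sex,
            form=self.form,
            coefficients=[float(c) for c in coef],
            ratio_range=(lo, hi),
            tilt_range=TILT_RANGE_DEG,
            pearson_r=float(r),
            residual_sd_deg=residual_sd,
            n_images=int(len(self.tilt_deg)),
            model=self,
        )


@dataclass
class NomogramResults:
    """Fitted sex-specific mapping from PSTI/POD ratio to APP tilt.

    ``coefficients`` are polynomial coefficients, highest degree first
    (numpy convention).  Estimates outside the calibrated ratio range are
    flagged as extrapolated, never clamped.
    """

    sex: str
    form: str
    coefficients: list[float]
    ratio_range: tuple[float, float]
    tilt_range: tuple[float, float]
    pearson_r: float
    residual_sd_deg: float
    n_images: int
    provenance: dict = field(default_factory=dict)
    model: NomogramModel | None = field(default=None, repr=False, compare=False)

    @property
    def nomogram_id(self) -> str:
        return f"{self.sex}-{self.form}"

    def predict(self, ratio) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(ratio, float))

    def estimate_tilt(self, psti: float, pod: float) -> TiltEstimate:
        """Estimate APP tilt from one image's averaged PSTI and POD (mm)."""
        if not math.isfinite(pod) or pod <= 0:
            raise ValueError("POD must be a positive, finite length")
        if not math.isfinite(psti):
            raise ValueError("PSTI is missing or flagged; cannot estimate tilt")
        ratio = psti / pod
        lo, hi = self.ratio_range
        return TiltEstimate(
            appt_deg=float(self.predict(ratio)),
            extrapolated=bool(ratio < lo or ratio > hi),
            nomogram_id=self.nomogram_id,
        )

    def summary(self) -> str:
        lo, hi = self.ratio_range
        lines = [
            "PSTI/POD tilt nomogram",
            "=" * 44,
            f"sex:              {self.sex}",
            f"form:             {self.form}",
            f"n images:         {self.n_images}",
            "coefficients:     "
            + ", ".join(f"{c:.6g}" for c in self.coefficients)
            + "  (highest degree first)",
            f"ratio range:      [{lo:.4f}, {hi:.4f}]",
            f"tilt range (deg): [{self.tilt_range[0]:g}, {self.tilt_range[1]:g}]",
            f"Pearson r:        {self.pearson_r:+.4f}",
            f"residual sd:      {self.residual_sd_deg:.3f} deg",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: calibration scatter and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.plot(self.model.ratio, self.model.tilt_deg, "o", ms=3, alpha=0.6,
                    label="calibration images")
        grid = np.linspace(*self.ratio_range, 200)
        ax.plot(grid, self.predict(grid), "-", label=f"{self.form} fit")
        ax.set_xlabel("PSTI / POD")
        ax.set_ylabel("APP tilt (deg)")
        ax.set_title(f"{self.sex} nomogram (r = {self.pearson_r:+.2f})")
        ax.legend()
        return ax

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "form": self.form,
            "coefficients": self.coefficients,
            "ratio_range": list(self.ratio_range),
            "tilt_range": list(self.tilt_range),
            "diagnostics": {
                "r": self.pearson_r,
                "residual_sd_deg": self.residual_sd_deg,
                "n_images": self.n_images,
            },
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "NomogramResults":
        diag = d.get("diagnostics", {})
        return cls(
            sex=d["sex"],
            form=d["form"],
            coefficients=[float(c) for c in d["coefficients"]],
            ratio_range=tuple(d["ratio_range"]),
            tilt_range=tuple(d.get("tilt_range", TILT_RANGE_DEG)),
            pearson_r=float(diag.get("r", math.nan)),
            residual_sd_deg=float(diag.get("residual_sd_deg", math.nan)),
            n_images=int(diag.get("n_images", 0)),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NomogramResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_nomogram(
    table: CalibrationTable, sex: str, form: str = "linear"
) -> NomogramResults:
    """Fit the sex-specific nomogram from a calibration table."""
    res = NomogramModel.from_calibration_table(table, sex, form).fit()
    res.provenance = dict(table.provenance)
    return res


def estimate_tilt(nom: NomogramResults, psti: float, pod: float) -> TiltEstimate:
    """Functional alias for :meth:`NomogramResults.estimate_tilt`."""
    return nom.estimate_tilt(psti, pod)
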