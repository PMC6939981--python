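"""End-to-end workflows: configuration, generation, calibration, validation.

Every stochastic stage carries its own explicit seed so that a single
configuration reproduces the whole pipeline byte-for-byte.  The default
configuration mirrors the reference study design: a cohort of 10 male and
10 female pelvises, 13 calibration orientations from -30 to +30 degrees in
5-degree steps (260 pooled calibration images), and a validation set of 50
synthetic images (5 each from 10 pelvises) at random tilts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anatomy import PelvisLandmarks3D, generate_cohort, write_landmarks_csv
from .calibration import (
    DEFAULT_TILTS_DEG,
    CalibrationTable,
    NomogramResults,
    build_calibration_table,
    evaluate_parameters,
    fit_nomogram,
)
from .measurement import MeasurementNoiseModel, measure_parameters, perturb_and_average
from .projection import ProjectionGeometry, synthesize_image
from .stats import DIRECTION_THRESHOLD_DEG, validation_table, write_report


@dataclass
class CohortConfig:
    n_male: int = 10
    n_female: int = 10
    scale_sd: float = 0.05
    shape_sd_mm: float = 1.5
    seed: int = 1


@dataclass
class NoiseConfig:
    landmark_sd_mm: float = 0.5
    replicates: int = 3
    seed: int = 11

    def model(self) -> MeasurementNoiseModel | None:
        if self.landmark_sd_mm == 0.0:
            return None
        return MeasurementNoiseModel(self.landmark_sd_mm, self.replicates, self.seed)


@dataclass
class ValidationConfig:
    n_pelvises: int = 10
    n_per_pelvis: int = 5
    tilt_low_deg: float = -30.0
    tilt_high_deg: float = 30.0
    min_abs_tilt_deg: float = 0.0
    integer_tilts: bool = False
    seed: int = 17


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    geometry: ProjectionGeometry = field(default_factory=ProjectionGeometry)
    tilts_deg: list[float] = field(default_factory=lambda: list(DEFAULT_TILTS_DEG))
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    #: functional form of the fitted nomogram used by the pipeline.  The
    #: quadratic captures the small even (cos) component of the exact
    #: trigonometric ratio-tilt relation that a straight line cannot.
    nomogram_form: str = "quadratic"

    # -- round-trippable serialization --------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = self.geometry.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        return cls(
            cohort=CohortConfig(**d.get("cohort", {})),
            geometry=ProjectionGeometry.from_dict(
                d.get("geometry", ProjectionGeometry().to_dict())
            ),
            tilts_deg=[float(t) for t in d.get("tilts_deg", DEFAULT_TILTS_DEG)],
            noise=NoiseConfig(**d.get("noise", {})),
            validation=ValidationConfig(**d.get("validation", {})),
            nomogram_form=d.get("nomogram_form", "quadratic"),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data or {})


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def build_cohort(config: RunConfig) -> list[PelvisLandmarks3D]:
    c = config.cohort
    return generate_cohort(c.n_male, c.n_female, c.seed, c.scale_sd, c.shape_sd_mm)


def calibrate(config: RunConfig, cohort=None):
    """Calibration table + fitted per-sex nomograms for a configuration."""
    cohort = cohort if cohort is not None else build_cohort(config)
    table = build_calibration_table(
        cohort, config.tilts_deg, config.geometry, config.noise.model()
    )
    nomograms: dict[str, NomogramResults] = {}
    for sex in ("male", "female"):
        if (table.df["sex"] == sex).any():
            nomograms[sex] = fit_nomogram(table, sex, form=config.nomogram_form)
        else:
            warnings.warn(f"no {sex} subjects in cohort; skipping {sex} nomogram")
    return table, nomograms, cohort


def sample_validation_tilts(config: ValidationConfig, n: int, rng: np.random.Generator):
    """Random tilts, uniform (or integer-uniform) on the configured range,
    optionally resampled to respect a minimum magnitude."""
    out = np.empty(n)
    for i in range(n):
        while True:
            if config.integer_tilts:
                t = float(rng.integers(int(config.tilt_low_deg), int(config.tilt_high_deg) + 1))
            else:
                t = float(rng.uniform(config.tilt_low_deg, config.tilt_high_deg))
            if abs(t) >= config.min_abs_tilt_deg:
                out[i] = t
                break
    return out


def run_validation(
    config: RunConfig,
    cohort: list[PelvisLandmarks3D],
    nomograms: dict[str, NomogramResults],
) -> pd.DataFrame:
    """Fresh random-tilt images, measured and estimated per image.

    Returns one row per validation image: subject, sex, true tilt,
    measured PSTI/POD, estimated tilt, extrapolation flag.
    """
    v = config.validation
    rng = np.random.default_rng(v.seed)
    if v.n_pelvises > len(cohort):
        raise ValueError("validation requests more pelvises than the cohort holds")
    idx = rng.choice(len(cohort), size=v.n_pelvises, replace=False)
    subjects = [cohort[i] for i in idx]
    noise_seeds = np.random.SeedSequence(config.noise.seed + 1).generate_state(
        max(v.n_pelvises * v.n_per_pelvis, 1), dtype=np.uint32
    )
    rows = []
    k = 0
    for lm in subjects:
        tilts = sample_validation_tilts(v, v.n_per_pelvis, rng)
        for tilt in tilts:
            img = synthesize_image(lm, float(tilt), config.geometry)
            if config.noise.landmark_sd_mm == 0.0:
                ps = measure_parameters(img)
            else:
                ps = perturb_and_average(
                    img,
                    MeasurementNoiseModel(
                        config.noise.landmark_sd_mm,
                        config.noise.replicates,
                        int(noise_seeds[k]),
                    ),
                )
            est = nomograms[lm.sex].estimate_tilt(ps.psti, ps.pod)
            rows.append(
                {
                    "subject_id": lm.subject_id,
                    "sex": lm.sex,
                    "true_tilt_deg": float(tilt),
                    "psti": ps.psti,
                    "pod": ps.pod,
                    "estimated_tilt_deg": est.appt_deg,
                    "extrapolated": est.extrapolated,
                }
            )
            k += 1
    return pd.DataFrame(rows)


def synthetic_validation_study(
    seed: int = 1,
    n_male: int = 5,
    n_female: int = 5,
    n_per_pelvis: int = 5,
    min_abs_tilt_deg: float = 2.0,
    nomogram_form: str = "quadratic",
    geometry: ProjectionGeometry | None = None,
) -> pd.DataFrame:
    """The standard noiseless round-trip experiment.

    Calibrates per-sex nomograms on a seeded cohort over the 13-orientation
    sweep, then synthesizes ``n_per_pelvis`` fresh images per pelvis at
    uniform-random tilts in [-30, 30] deg (magnitude at least
    ``min_abs_tilt_deg``), measures them exactly and estimates tilt.  All
    randomness derives from ``seed``.  Returns the per-image validation rows.
    """
    ss = np.random.SeedSequence(seed)
    cohort_seed, val_seed = (int(s) for s in ss.generate_state(2, dtype=np.uint32) >> np.uint32(1))
    cfg = RunConfig(
        cohort=CohortConfig(n_male=n_male, n_female=n_female, seed=cohort_seed),
        geometry=geometry or ProjectionGeometry(),
        noise=NoiseConfig(landmark_sd_mm=0.0),
        validation=ValidationConfig(
            n_pelvises=n_male + n_female,
            n_per_pelvis=n_per_pelvis,
            min_abs_tilt_deg=min_abs_tilt_deg,
            seed=val_seed,
        ),
        nomogram_form=nomogram_form,
    )
    _, nomograms, cohort = calibrate(cfg)
    return run_validation(cfg, cohort, nomograms)


# ---------------------------------------------------------------------------
# Command implementations (the CLI wraps these thinly)
# ---------------------------------------------------------------------------


def cmd_generate(config: RunConfig, out_dir: str | Path) -> dict:
    """Write per-subject landmark JSON files, a flat CSV and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(config)
    files = []
    for lm in cohort:
        path = out / f"landmarks_{lm.subject_id}.json"
        lm.to_json(path)
        files.append(path.name)
    write_landmarks_csv(cohort, out / "landmarks.csv")
    manifest = {
        "config": config.to_dict(),
        "n_subjects": len(cohort),
        "subjects": [{"subject_id": lm.subject_id, "sex": lm.sex} for lm in cohort],
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def cmd_calibrate(config: RunConfig, out_dir: str | Path) -> dict:
    """Write the calibration table, screening report and per-sex nomograms."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, nomograms, _ = calibrate(config)
    table.to_csv(out / "calibration_table.csv")
    screening = evaluate_parameters(
        table,
        MeasurementNoiseModel(
            config.noise.landmark_sd_mm, config.noise.replicates, config.noise.seed
        ),
    )
    screening.to_csv(out / "parameter_screening.csv", index=False)
    written = {}
    for sex, nom in nomograms.items():
        path = out / f"nomogram_{sex}.json"
        nom.to_json(path)
        written[sex] = path.name
    return {"rows": len(table), "nomograms": written}


def cmd_estimate(
    nomogram_file: str | Path, measurements_file: str | Path, out_file: str | Path
) -> pd.DataFrame:
    """Apply a stored nomogram to a CSV of (psti, pod) measurements.

    Rows that cannot be estimated (e.g. non-positive POD) are kept with an
    ``error`` message; the remaining rows are still processed.
    """
    nom = NomogramResults.from_json(nomogram_file)
    meas = pd.read_csv(measurements_file)
    if not {"psti", "pod"}.issubset(meas.columns):
        raise ValueError("measurements file needs 'psti' and 'pod' columns")
    out_rows = []
    for _, row in meas.iterrows():
        rec = dict(row)
        try:
            est = nom.estimate_tilt(float(row["psti"]), float(row["pod"]))
            rec.update(
                appt_deg=est.appt_deg, extrapolated=est.extrapolated, error=""
            )
        except (ValueError, TypeError) as exc:
            rec.update(appt_deg=np.nan, extrapolated=False, error=str(exc))
        out_rows.append(rec)
    result = pd.DataFrame(out_rows)
    result.to_csv(out_file, index=False)
    return result


def cmd_validate(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Calibrate, run the random-tilt validation and write the reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, nomograms, cohort = calibrate(config)
    rows = run_validation(config, cohort, nomograms)
    rows.to_csv(out / "validation_rows.csv", index=False)
    report = validation_table(rows, direction_threshold_deg=DIRECTION_THRESHOLD_DEG)
    write_report(report, out / "validation_report.tsv")
    write_report(report, out / "validation_report.json")
    for sex, nom in nomograms.items():
        nom.to_json(out / f"nomogram_{sex}.json")
    return report
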