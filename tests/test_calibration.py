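"""Calibration table, screening, nomogram fit/inversion and robustness."""

import math

import numpy as np
import pytest

from tiltcal import (
    MeasurementNoiseModel,
    NomogramModel,
    NomogramResults,
    ProjectionGeometry,
    build_calibration_table,
    estimate_tilt,
    evaluate_parameters,
    fit_nomogram,
    generate_cohort,
    measure_parameters,
    synthesize_image,
    template_landmarks,
)

#: Table-1-style expected association signs for the strong parameters
EXPECTED_SIGNS = {
    "psti": -1, "pssi": +1, "ofh": +1, "ofr": +1, "tisi": +1, "tita": -1, "sita": +1,
}


def test_default_sweep_row_counts(small_cohort):
    table = build_calibration_table(small_cohort)
    assert len(table) == len(small_cohort) * 13
    one = build_calibration_table([template_landmarks("male")])
    assert len(one) == 13
    assert len(build_calibration_table([])) == 0


def test_rows_are_unique_per_subject_and_tilt(small_calibration_table):
    df = small_calibration_table.df
    assert not df.duplicated(subset=["subject_id", "true_tilt_deg"]).any()
    assert df["true_tilt_deg"].between(-30, 30).all()


def test_calibration_table_csv_round_trip(small_calibration_table, tmp_path):
    p = tmp_path / "table.csv"
    small_calibration_table.to_csv(p)
    from tiltcal import CalibrationTable

    back = CalibrationTable.from_csv(p)
    np.testing.assert_allclose(
        back.df["psti"].to_numpy(), small_calibration_table.df["psti"].to_numpy()
    )
    assert list(back.df["subject_id"]) == list(small_calibration_table.df["subject_id"])


def test_screening_sign_pattern_and_strength(small_calibration_table):
    rep = evaluate_parameters(small_calibration_table).set_index("parameter")
    for name, sign in EXPECTED_SIGNS.items():
        r = rep.loc[name, "r"]
        assert abs(r) >= 0.8, f"{name}: |r| = {abs(r):.3f}"
        assert np.sign(r) == sign, f"{name}: r = {r:+.3f}"
    # PSTI is the most tilt-sensitive reliable parameter and its r is negative
    assert rep.loc["psti", "r"] <= -0.9


def test_screening_zero_noise_gives_perfect_icc(small_calibration_table):
    rep = evaluate_parameters(
        small_calibration_table, MeasurementNoiseModel(0.0, 3, seed=0)
    ).set_index("parameter")
    for name in EXPECTED_SIGNS:
        assert rep.loc[name, "icc"] == pytest.approx(1.0, abs=1e-12)


def test_screening_noise_degrades_icc(small_calibration_table):
    rep = evaluate_parameters(
        small_calibration_table, MeasurementNoiseModel(2.0, 3, seed=3)
    ).set_index("parameter")
    assert rep["icc"].between(0, 1.0000001).all()
    assert rep.loc["psti", "icc"] < 1.0


def test_screening_constant_column_reported_not_zero(small_calibration_table):
    table = small_calibration_table
    df = table.df.copy()
    df["ofr"] = 1.0
    from tiltcal import CalibrationTable

    rep = evaluate_parameters(
        CalibrationTable(df=df, provenance=table.provenance, images=table.images)
    ).set_index("parameter")
    assert math.isnan(rep.loc["ofr", "r"])
    assert "constant" in rep.loc["ofr", "note"]


def test_screening_miss_rate_scenario(small_calibration_table):
    rep = evaluate_parameters(
        small_calibration_table,
        miss_probabilities={"SIJ_L": 1.0},
        miss_seed=0,
    ).set_index("parameter")
    for name in ("pssi", "tisi", "sita"):
        assert rep.loc[name, "miss_rate"] == 1.0
    assert rep.loc["psti", "miss_rate"] == 0.0


def test_single_pelvis_linear_fit_residual_below_2deg():
    """The exact ratio-tilt curve is near-linear over +/-30 deg: a linear fit
    on a 1-degree sweep of one template leaves residual sd below 2 deg."""
    for sex in ("male", "female"):
        table = build_calibration_table([template_landmarks(sex)], tilts_deg=range(-30, 31, 1))
        nom = fit_nomogram(table, sex, form="linear")
        assert nom.residual_sd_deg <= 2.0
        assert nom.pearson_r < -0.98  # strongly monotone decreasing


def test_negating_tilts_flips_slope_keeps_abs_r(small_calibration_table):
    from tiltcal import CalibrationTable

    nom = fit_nomogram(small_calibration_table, "male", form="linear")
    df = small_calibration_table.df.copy()
    df["true_tilt_deg"] = -df["true_tilt_deg"]
    flipped = fit_nomogram(CalibrationTable(df=df), "male", form="linear")
    assert flipped.coefficients[0] == pytest.approx(-nom.coefficients[0], rel=1e-9)
    assert abs(flipped.pearson_r) == pytest.approx(abs(nom.pearson_r), rel=1e-9)


def test_nomogram_bookkeeping_counts_only_that_sex(small_calibration_table):
    nom = fit_nomogram(small_calibration_table, "female", form="linear")
    assert nom.n_images == int((small_calibration_table.df["sex"] == "female").sum())
    assert nom.sex == "female"


def test_linear_fit_matches_normal_equations_oracle(small_calibration_table):
    """Fitted coefficients equal an explicit normal-equations solve to 1e-9."""
    df = small_calibration_table.for_sex("male")
    x = (df["psti"] / df["pod"]).to_numpy()
    y = df["true_tilt_deg"].to_numpy()
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    nom = fit_nomogram(small_calibration_table, "male", form="linear")
    assert nom.coefficients[0] == pytest.approx(slope, rel=1e-9)
    assert nom.coefficients[1] == pytest.approx(intercept, rel=1e-9)


def test_insufficient_or_degenerate_fit_rejected():
    with pytest.raises(ValueError, match="distinct tilt"):
        NomogramModel([5.0, 5.0], [0.3, 0.4], sex="male")
    with pytest.raises(ValueError, match="degenerate"):
        NomogramModel([0.0, 10.0], [0.3, 0.3], sex="male")
    with pytest.raises(ValueError, match="unknown sex"):
        NomogramModel([0.0, 10.0], [0.3, 0.2], sex="x")


def test_non_monotone_quadratic_rejected():
    rng = np.random.default_rng(0)
    ratio = np.linspace(-1, 1, 41)
    tilt = ratio**2 * 30 + rng.normal(0, 0.01, ratio.size)  # a parabola
    with pytest.raises(ValueError, match="monotone"):
        NomogramModel(tilt, ratio, sex="male", form="quadratic").fit()


def test_estimate_matches_published_worked_example():
    """A female nomogram whose line maps ratio 40/120 to +7.5 deg returns
    +7.5 deg for PSTI 40 mm, POD 120 mm, and is invariant to magnification."""
    nom = NomogramResults(
        sex="female", form="linear", coefficients=[-150.0, 57.5],
        ratio_range=(-0.2, 0.7), tilt_range=(-30, 30),
        pearson_r=-0.99, residual_sd_deg=1.0, n_images=130,
    )
    est = estimate_tilt(nom, 40.0, 120.0)
    assert est.appt_deg == pytest.approx(7.5, abs=1e-9)
    assert not est.extrapolated
    for k in (0.5, 2.0, 13.7):
        scaled = estimate_tilt(nom, 40.0 * k, 120.0 * k)
        assert scaled.appt_deg == pytest.approx(est.appt_deg, abs=1e-9)


def test_estimate_rejects_bad_inputs_and_flags_extrapolation(small_calibration_table):
    nom = fit_nomogram(small_calibration_table, "male")
    with pytest.raises(ValueError, match="POD"):
        nom.estimate_tilt(40.0, 0.0)
    with pytest.raises(ValueError, match="PSTI"):
        nom.estimate_tilt(float("nan"), 120.0)
    lo, hi = nom.ratio_range
    assert nom.estimate_tilt(hi * 2 * 100.0, 100.0).extrapolated
    mid = 0.5 * (lo + hi)
    assert not nom.estimate_tilt(mid * 100.0, 100.0).extrapolated


def test_noiseless_round_trip_single_subject(default_geom):
    """Calibrate on one pelvis, estimate a fresh +12 deg image within 2 deg."""
    lm = template_landmarks("male")
    nom = fit_nomogram(build_calibration_table([lm]), "male", form="linear")
    ps = measure_parameters(synthesize_image(lm, 12.0, default_geom))
    est = nom.estimate_tilt(ps.psti, ps.pod)
    assert est.appt_deg == pytest.approx(12.0, abs=2.0)


def test_magnification_robustness_between_calibration_and_estimation(small_cohort):
    """POD normalization absorbs a SID change from 1000 to 1200 mm: estimates
    move by less than 1 degree."""
    table = build_calibration_table(small_cohort, geom=ProjectionGeometry.perspective(1000, 150))
    nom = {s: fit_nomogram(table, s, form="quadratic") for s in ("male", "female")}
    for lm in small_cohort[:2] + small_cohort[-2:]:
        for tilt in (-20.0, 5.0, 25.0):
            ests = []
            for sid in (1000.0, 1200.0):
                img = synthesize_image(lm, tilt, ProjectionGeometry.perspective(sid, 150))
                ps = measure_parameters(img)
                ests.append(nom[lm.sex].estimate_tilt(ps.psti, ps.pod).appt_deg)
            assert abs(ests[1] - ests[0]) < 1.0


def test_nomogram_json_round_trip(small_calibration_table, tmp_path):
    nom = fit_nomogram(small_calibration_table, "male", form="quadratic")
    p = tmp_path / "nomogram.json"
    nom.to_json(p)
    back = NomogramResults.from_json(p)
    assert back.sex == "male" and back.form == "quadratic"
    np.testing.assert_allclose(back.coefficients, nom.coefficients)
    assert back.ratio_range == nom.ratio_range
    assert back.pearson_r == nom.pearson_r
    assert back.n_images == nom.n_images
    # diagnostics recomputable: prediction agrees everywhere
    grid = np.linspace(*nom.ratio_range, 7)
    np.testing.assert_allclose(back.predict(grid), nom.predict(grid))


def test_summary_mentions_fit_quality(small_calibration_table):
    nom = fit_nomogram(small_calibration_table, "female")
    text = nom.summary()
    assert "female" in text and "Pearson r" in text and "residual sd" in text
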