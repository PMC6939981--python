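"""Rigid-rotation helpers shared by the anatomy and projection modules.

World frame: x = patient left (+, mediolateral), y = anterior (+),
z = superior (+); all lengths in mm.  The anterior pelvic plane (APP) is
the plane through ASIS_L, ASIS_R and the anterior symphysis border; its
tilt (APPt) is the signed angle of the APP normal away from the anterior
(y) axis, positive when the ASIS move anteriorly relative to the symphysis.
"""

from __future__ import annotations

import numpy as np

APP_LANDMARKS = ("ASIS_L", "ASIS_R", "PS_ANT")


def tilt_rotation_matrix(tilt_deg: float) -> np.ndarray:
    """Rotation about the mediolateral (x) axis that tilts the pelvis.

    Positive angles move superior structures (the ASIS) anteriorly:
    y' = y cos t + z sin t, z' = -y sin t + z cos t.
    """
    t = np.deg2rad(tilt_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])


def rotate_about_x(points: np.ndarray, tilt_deg: float, center: np.ndarray) -> np.ndarray:
    """Rotate an (n, 3) array about the x-axis line through ``center``."""
    pts = np.asarray(points, dtype=float)
    c = np.asarray(center, dtype=float)
    return (pts - c) @ tilt_rotation_matrix(tilt_deg).T + c


def app_normal(asis_l: np.ndarray, asis_r: np.ndarray, ps_ant: np.ndarray) -> np.ndarray:
    """Unit normal of the anterior pelvic plane, oriented anteriorly."""
    v_lat = np.asarray(asis_l, float) - np.asarray(asis_r, float)
    mid = 0.5 * (np.asarray(asis_l, float) + np.asarray(asis_r, float))
    v_sup = mid - np.asarray(ps_ant, float)
    n = np.cross(v_sup, v_lat)
    norm = np.linalg.norm(n)
    if norm == 0.0:
        raise ValueError("degenerate APP landmarks: normal undefined")
    n = n / norm
    # orient toward +y so that the sign of the tilt is well defined
    if n[1] < 0:
        n = -n
    return n


def app_tilt_deg(asis_l, asis_r, ps_ant) -> float:
    """Signed APP tilt in degrees (positive = anterior tilt)."""
    n = app_normal(asis_l, asis_r, ps_ant)
    # canonical pose normal is +y; a tilt t maps it to (0, cos t, -sin t)
    return float(np.degrees(np.arctan2(-n[2], n[1])))


def app_centroid(asis_l, asis_r, ps_ant) -> np.ndarray:
    return np.mean(np.stack([asis_l, asis_r, ps_ant]).astype(float), axis=0)
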