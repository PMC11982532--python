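"""Standardization of a tilted, variable-thickness cortical volume.

Electron-microscopy volumes are not aligned with anatomical axes: the pial
surface is tilted relative to the (x, z) plane and cortical thickness varies
across the volume.  Depth-dependent analyses therefore first rotate the
volume about the z-axis to remove the systematic tilt and then, per (x, z)
column, map the y-axis affinely so that the local pia depth goes to the mean
pia depth and the local white-matter depth to the mean white-matter depth.
After this transformation pia and white matter are horizontal planes; depth
relative to the pia is ``y - mean_pia_depth``.

The surfaces are estimated as least-squares planes ``y = a*x + b*z + c``
from landmark points placed on a regular (x, z) grid (25 μm spacing by
convention).  Depth (y) increases downward; the white matter is deeper than
the pia everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VolumeFrame", "fit_volume_frame", "standardize_points", "rotate_z"]


def rotate_z(points: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate points about the z-axis (mixes x and y; z untouched)."""
    points = np.asarray(points, dtype=float)
    th = np.deg2rad(degrees)
    c, s = np.cos(th), np.sin(th)
    out = points.copy()
    out[..., 0] = c * points[..., 0] - s * points[..., 1]
    out[..., 1] = s * points[..., 0] + c * points[..., 1]
    return out


@dataclass
class VolumeFrame:
    """Fitted rotation + pia / white-matter planes in the rotated frame."""

    rotation_degrees: float
    pia_fit: np.ndarray       # (a, b, c): y = a x + b z + c
    wm_fit: np.ndarray
    mean_pia_depth: float
    mean_wm_depth: float

    def pia_depth_at(self, x, z):
        a, b, c = self.pia_fit
        return a * x + b * z + c

    def wm_depth_at(self, x, z):
        a, b, c = self.wm_fit
        return a * x + b * z + c

    def to_dict(self) -> dict:
        return {
            "rotation_degrees": float(self.rotation_degrees),
            "pia_fit": [float(v) for v in self.pia_fit],
            "wm_fit": [float(v) for v in self.wm_fit],
            "mean_pia_depth": float(self.mean_pia_depth),
            "mean_wm_depth": float(self.mean_wm_depth),
        }

    @classmethod
    def from_dict(cls, d) -> "VolumeFrame":
        return cls(
            d["rotation_degrees"],
            np.asarray(d["pia_fit"], float),
            np.asarray(d["wm_fit"], float),
            d["mean_pia_depth"],
            d["mean_wm_depth"],
        )


def _fit_plane(x, z, y):
    A = np.column_stack([x, z, np.ones_like(x)])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("landmarks are collinear; plane fit is rank-deficient")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


def fit_volume_frame(landmarks, rotation_degrees: float) -> VolumeFrame:
    """Fit pia and white-matter planes from landmark rows.

    ``landmarks`` is a DataFrame (or array-convertible) with columns
    ``x, z, y_pia, y_wm``: at grid position (x, z) the pia surface lies at
    depth ``y_pia`` and the white matter at ``y_wm`` (raw, un-rotated
    coordinates).  The tilt rotation is applied to the landmark points before
    the planes are fit, so the fitted frame lives in the rotated coordinates.
    """
    if not isinstance(landmarks, pd.DataFrame):
        landmarks = pd.DataFrame(
            np.asarray(landmarks, float), columns=["x", "z", "y_pia", "y_wm"]
        )
    if len(landmarks) < 3:
        raise ValueError("need at least 3 landmarks per surface")
    if np.any(landmarks["y_wm"].to_numpy() <= landmarks["y_pia"].to_numpy()):
        bad = landmarks[landmarks.y_wm <= landmarks.y_pia].iloc[0]
        raise ValueError(
            f"white matter not deeper than pia at (x={bad.x}, z={bad.z})"
        )
    pia_pts = rotate_z(
        landmarks[["x", "y_pia", "z"]].to_numpy(float), rotation_degrees
    )
    wm_pts = rotate_z(
        landmarks[["x", "y_wm", "z"]].to_numpy(float), rotation_degrees
    )
    pia_fit = _fit_plane(pia_pts[:, 0], pia_pts[:, 2], pia_pts[:, 1])
    wm_fit = _fit_plane(wm_pts[:, 0], wm_pts[:, 2], wm_pts[:, 1])
    return VolumeFrame(
        rotation_degrees=rotation_degrees,
        pia_fit=pia_fit,
        wm_fit=wm_fit,
        mean_pia_depth=float(pia_pts[:, 1].mean()),
        mean_wm_depth=float(wm_pts[:, 1].mean()),
    )


def standardize_points(points: np.ndarray, frame: VolumeFrame) -> np.ndarray:
    """Rotate, then affinely map y per (x, z) column onto the mean surfaces.

    A point on the fitted pia surface maps to depth ``mean_pia_depth``; a
    point on the white matter to ``mean_wm_depth``; in between (and beyond)
    the map is linear in y.  x and z are unchanged after the rotation.
    """
    pts = rotate_z(np.atleast_2d(np.asarray(points, dtype=float)), frame.rotation_degrees)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    y_p = frame.pia_depth_at(x, z)
    y_w = frame.wm_depth_at(x, z)
    thick = y_w - y_p
    if np.any(thick <= 0):
        k = int(np.argmax(thick <= 0))
        raise ValueError(
            f"degenerate column at (x={x[k]:.1f}, z={z[k]:.1f}): local white "
            "matter not deeper than local pia"
        )
    frac = (y - y_p) / thick
    out = pts.copy()
    out[:, 1] = frame.mean_pia_depth + frac * (
        frame.mean_wm_depth - frame.mean_pia_depth
    )
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


def standardized_depth(points: np.ndarray, frame: VolumeFrame) -> np.ndarray:
    """Depth relative to the pia (pia = 0) after standardization."""
    pts = standardize_points(points, frame)
    return np.atleast_2d(pts)[:, 1] - frame.mean_pia_depth
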