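"""Rigid+scale mapping between the confocal frame (um) and the MSI pixel grid.

The registration search rotates about the image centers, so the transform is
parameterized as

    p_msi_px = C_msi + R(theta) * (scale / msi_pitch) * (p_conf_um - C_conf) + t_px

with ``t_px = (dx_um, dy_um) / msi_pitch``.  ``scale`` is the residual scale
relative to the nominal pitch ratio, so scale = 1 means the two images agree
with their stated calibrations.  Points are (x, y); the MSI grid indexes
pixels as (row, col) = (y, x) with pixel centers at integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class AffineTransform2D:
    rotation_deg: float
    dx_um: float
    dy_um: float
    scale: float
    msi_pitch: float  # um per MSI pixel
    center_conf_um: tuple[float, float] = (0.0, 0.0)
    center_msi_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.msi_pitch <= 0:
            raise ValueError("msi_pitch must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix mapping confocal (x, y) um -> MSI (x, y) px."""
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        k = self.scale / self.msi_pitch
        rot_scale = np.array([[c * k, -s * k], [s * k, c * k]])
        cx, cy = self.center_conf_um
        mx, my = self.center_msi_px
        t = np.array([mx, my]) + np.array([self.dx_um, self.dy_um]) / self.msi_pitch
        offset = t - rot_scale @ np.array([cx, cy])
        m = np.eye(3)
        m[:2, :2] = rot_scale
        m[:2, 2] = offset
        return m

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        """Map (n, 2) confocal um points to MSI pixel (x, y) coordinates."""
        pts = np.atleast_2d(np.asarray(points_um, float))
        m = self.matrix
        out = pts @ m[:2, :2].T + m[:2, 2]
        return out

    def inverse_apply(self, points_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_px, float))
        m = np.linalg.inv(self.matrix)
        return pts @ m[:2, :2].T + m[:2, 2]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg,
            "dx_um": self.dx_um,
            "dy_um": self.dy_um,
            "scale": self.scale,
            "msi_pitch": self.msi_pitch,
            "center_conf_um": list(self.center_conf_um),
            "center_msi_px": list(self.center_msi_px),
            "matrix": self.matrix.ravel().tolist(),  # row-major, derived
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(
            rotation_deg=float(d["rotation_deg"]),
            dx_um=float(d["dx_um"]),
            dy_um=float(d["dy_um"]),
            scale=float(d["scale"]),
            msi_pitch=float(d["msi_pitch"]),
            center_conf_um=tuple(d.get("center_conf_um", (0.0, 0.0))),
            center_msi_px=tuple(d.get("center_msi_px", (0.0, 0.0))),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform2D":
        return cls.from_dict(json.loads(Path(path).read_text()))
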