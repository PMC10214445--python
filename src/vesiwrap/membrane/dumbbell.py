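"""Rigid dumbbell body: two tangent spheres, quaternion orientation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DumbbellBody", "quat_to_matrix", "quat_multiply", "quat_from_axis_angle"]


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@dataclass
class DumbbellBody:
    """Rigid colloid of two tangent spheres of radius ``lobe_radius``.

    The long axis is the body-frame z direction; lobe centres sit at
    ``center +- lobe_radius * axis`` so their separation is exactly two
    lobe radii (tangent spheres: long axis 2 d_s, short axis d_s for
    lobes of diameter d_s).  Orientation is stored as a unit quaternion;
    ``axis`` is derived from it.
    """

    center: np.ndarray
    quat: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    lobe_radius: float = 3.0
    mass_density: float = 1.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        self.quat = self.quat / np.linalg.norm(self.quat)
        if self.lobe_radius <= 0:
            raise ValueError("lobe radius must be positive")

    @classmethod
    def from_axis(cls, center, axis, lobe_radius: float) -> "DumbbellBody":
        """Build with the long axis along ``axis`` (any non-zero vector)."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, axis)
        s = np.linalg.norm(v)
        if s < 1e-12:
            q = (np.array([1.0, 0.0, 0.0, 0.0]) if axis[2] > 0
                 else quat_from_axis_angle([1.0, 0.0, 0.0], np.pi))
        else:
            q = quat_from_axis_angle(v / s, float(np.arctan2(s, axis[2])))
        return cls(center=np.asarray(center, dtype=float), quat=q,
                   lobe_radius=lobe_radius)

    @property
    def axis(self) -> np.ndarray:
        return quat_to_matrix(self.quat)[:, 2]

    def lobe_centers(self) -> tuple[np.ndarray, np.ndarray]:
        u = self.axis
        return (self.center + self.lobe_radius * u,
                self.center - self.lobe_radius * u)

    @property
    def mass(self) -> float:
        return 2.0 * self.mass_density * 4.0 / 3.0 * np.pi * self.lobe_radius ** 3

    def inertia_body(self) -> np.ndarray:
        """Principal moments (Ixx, Iyy, Izz) in the body frame."""
        a = self.lobe_radius
        m_lobe = 0.5 * self.mass
        i_sphere = 0.4 * m_lobe * a * a
        i_perp = 2.0 * (i_sphere + m_lobe * a * a)
        i_par = 2.0 * i_sphere
        return np.array([i_perp, i_perp, i_par])
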