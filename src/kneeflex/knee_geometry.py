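"""Knee moment arms and musculotendon lengths versus knee angle.

Each muscle's knee moment arm is a cubic polynomial in knee angle (degrees,
0 = full extension, valid on [0, 90]) with the hip and ankle locked.  The
musculotendon length follows from the tendon-excursion relation
``dL/dtheta = -r(theta)`` (flexors shorten as the knee flexes; extensors
lengthen), with the polynomial integrated in closed form.  Biarticular
muscles carry a constant hip moment arm so a flexed-hip posture can be
represented as a linear length offset.  A single multiplicative segment
scale maps the reference skeleton to a participant's thigh length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, ParameterError

__all__ = [
    "MusclePath",
    "KneeGeometry",
    "PoseConfig",
    "moment_arm",
    "mtu_length",
    "scale_geometry",
    "load_geometry",
    "save_geometry",
]

#: Group-mean greater-trochanter to lateral-femoral-condyle distance, m.
REFERENCE_THIGH_LENGTH_M = 0.413

KNEE_RANGE_DEG = (0.0, 90.0)


@dataclass(frozen=True)
class PoseConfig:
    """A static lower-limb posture.

    ``knee_angle_deg`` in [0, 90] with 0 = full extension; ``hip_angle_deg``
    0 (prone/neutral) or 90 (flexed hip).  The ankle is locked at neutral
    and is not a variable.
    """

    knee_angle_deg: float
    hip_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = KNEE_RANGE_DEG
        if not (lo <= self.knee_angle_deg <= hi):
            raise ParameterError(
                f"knee angle {self.knee_angle_deg} outside [{lo}, {hi}] deg")
        if not (0.0 <= self.hip_angle_deg <= 90.0):
            raise ParameterError(
                f"hip angle {self.hip_angle_deg} outside [0, 90] deg")


@dataclass(frozen=True)
class MusclePath:
    """Geometric description of one muscle's path over the knee.

    ``arm_coeffs`` are polynomial coefficients (m, ascending powers of the
    knee angle in degrees) of the magnitude of the knee moment arm: a
    flexion arm for flexors, an extension arm for extensors.  ``l_mtu_ref``
    is the musculotendon length at knee 0 deg / hip 0 deg before scaling.
    ``hip_arm`` is a constant, signed hip moment arm (m): positive if hip
    flexion lengthens the muscle (hamstrings), negative if it shortens it
    (rectus femoris, sartorius), zero for uniarticular muscles.
    """

    arm_coeffs: tuple[float, ...]
    l_mtu_ref: float
    hip_arm: float = 0.0
    action: str = "flexor"  # "flexor" | "extensor"

    def __post_init__(self) -> None:
        if self.action not in ("flexor", "extensor"):
            raise ConfigError(f"unknown action {self.action!r}")
        if not (self.l_mtu_ref > 0):
            raise ParameterError("l_mtu_ref must be positive")


@dataclass(frozen=True)
class KneeGeometry:
    """Per-muscle knee geometry plus a global segment scale factor."""

    muscles: dict[str, MusclePath] = field(default_factory=dict)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ParameterError("scale must be positive")

    def path(self, muscle: str) -> MusclePath:
        try:
            return self.muscles[muscle]
        except KeyError:
            raise ConfigError(f"unknown muscle {muscle!r}") from None


def _poly_eval(coeffs: tuple[float, ...], theta_deg) -> np.ndarray | float:
    out = np.polynomial.polynomial.polyval(np.asarray(theta_deg, float),
                                           np.asarray(coeffs, float))
    return out if np.ndim(out) else float(out)


def moment_arm(geometry: KneeGeometry, muscle: str, pose: PoseConfig) -> float:
    """Knee moment arm magnitude (m) of ``muscle`` at ``pose``.

    Positive values are flexion moment arms for flexors and extension
    moment arms for extensors; the segment scale applies multiplicatively.
    """
    path = geometry.path(muscle)
    return geometry.scale * _poly_eval(path.arm_coeffs, pose.knee_angle_deg)


def _arm_integral_m_rad(path: MusclePath, theta_deg: float) -> float:
    """Closed-form integral of the arm polynomial from 0 to theta, m*rad."""
    coeffs = np.asarray(path.arm_coeffs, float)
    powers = np.arange(1, coeffs.size + 1)
    return float(np.sum(coeffs * theta_deg ** powers / powers) * np.pi / 180.0)


def mtu_length(geometry: KneeGeometry, muscle: str, pose: PoseConfig) -> float:
    """Musculotendon length (m) at ``pose``.

    Tendon-excursion relation: flexors shorten by the integral of their
    flexion arm as the knee flexes, extensors lengthen by the integral of
    their extension arm.  Hip flexion adds ``hip_arm * hip_angle`` (rad).
    """
    path = geometry.path(muscle)
    excursion = _arm_integral_m_rad(path, pose.knee_angle_deg)
    sign = -1.0 if path.action == "flexor" else 1.0
    hip_term = path.hip_arm * np.deg2rad(pose.hip_angle_deg)
    return geometry.scale * (path.l_mtu_ref + sign * excursion + hip_term)


def scale_geometry(geometry: KneeGeometry, measured_thigh_length_m: float,
                   reference_thigh_length_m: float = REFERENCE_THIGH_LENGTH_M
                   ) -> KneeGeometry:
    """Geometry scaled by the ratio of measured to reference thigh length."""
    if not (measured_thigh_length_m > 0 and reference_thigh_length_m > 0):
        raise ParameterError("thigh lengths must be positive")
    s = measured_thigh_length_m / reference_thigh_length_m
    return replace(geometry, scale=geometry.scale * s)


# ---------------------------------------------------------------------------
# Config round-trip

def geometry_to_dict(geometry: KneeGeometry) -> dict:
    return {
        "scale": geometry.scale,
        "muscles": {
            name: {
                "arm_coeffs_m_per_deg": list(path.arm_coeffs),
                "l_mtu_ref_m": path.l_mtu_ref,
                "hip_arm_m": path.hip_arm,
                "action": path.action,
            }
            for name, path in geometry.muscles.items()
        },
    }


def geometry_from_dict(payload: dict) -> KneeGeometry:
    try:
        muscles = {
            name: MusclePath(
                arm_coeffs=tuple(entry["arm_coeffs_m_per_deg"]),
                l_mtu_ref=float(entry["l_mtu_ref_m"]),
                hip_arm=float(entry.get("hip_arm_m", 0.0)),
                action=entry.get("action", "flexor"),
            )
            for name, entry in payload["muscles"].items()
        }
    except KeyError as exc:
        raise ConfigError(f"geometry config missing key {exc}") from None
    geometry = KneeGeometry(muscles=muscles, scale=float(payload.get("scale", 1.0)))
    _validate_arms(geometry)
    return geometry


def _validate_arms(geometry: KneeGeometry) -> None:
    """Moment arms must stay positive over the supported knee range."""
    thetas = np.linspace(*KNEE_RANGE_DEG, 91)
    for name, path in geometry.muscles.items():
        arms = _poly_eval(path.arm_coeffs, thetas) * geometry.scale
        if np.any(np.asarray(arms) <= 0):
            raise ConfigError(f"{name}: moment arm non-positive on [0, 90] deg")


def load_geometry(path: str | Path) -> KneeGeometry:
    """Read a geometry config (JSON or YAML by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return geometry_from_dict(payload)


def save_geometry(geometry: KneeGeometry, path: str | Path) -> None:
    """Write a geometry config (JSON or YAML by extension)."""
    path = Path(path)
    payload = geometry_to_dict(geometry)
    if path.suffix in (".yaml", ".yml"):
        import yaml
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
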