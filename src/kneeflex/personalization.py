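"""Build the baseline ("contralateral") knee model from anthropometry.

The baseline model represents the intact leg of the group: segment geometry
scaled by thigh length, maximal isometric forces from muscle volumes
(``F_max = sigma_m * volume / lf_o``) estimated by linear mass*height
regressions, and the semitendinosus personalized from imaging-derived
morphology: its optimal fiber length from the measured anatomical fiber and
sarcomere lengths (``lf_o = lf_anat * 2.7um / l_sarc``) and its maximal
force from the maximal anatomical cross-sectional area
(``F_max = sigma_m * ACSA_max``).  Every muscle's tendon slack length is
then calibrated so that, at a near-passive activation of 0.01 in the
anatomical pose (knee 0 deg, hip 0 deg), the equilibrium fiber length
matches its anatomical target.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, ConfigError, ParameterError
from .knee_geometry import (KneeGeometry, PoseConfig, geometry_from_dict,
                            mtu_length, scale_geometry)
from .mtu_model import MuscleTendonParams, solve_isometric_equilibrium

__all__ = [
    "MorphologyRecord",
    "KneeModel",
    "fmax_from_volume",
    "volume_from_regression",
    "lfo_from_sarcomere",
    "fmax_from_acsa",
    "calibrate_tendon_slack",
    "rescale_fiber_tendon",
    "default_config",
    "build_baseline_model",
]

#: Sarcomere length at which actin-myosin overlap is optimal, micrometres.
OPTIMAL_SARCOMERE_UM = 2.7

#: Muscle specific tension, N/cm^2.
DEFAULT_SPECIFIC_TENSION = 60.0

#: Activation used during tendon-slack-length calibration.
CALIBRATION_ACTIVATION = 0.01

ANATOMICAL_POSE = PoseConfig(knee_angle_deg=0.0, hip_angle_deg=0.0)


@dataclass(frozen=True)
class MorphologyRecord:
    """Imaging-derived semitendinosus morphology (one leg).

    ``acsa_max`` maximal anatomical cross-sectional area (cm^2), ``lf_anat``
    fiber length in the anatomical position (cm), ``l_sarc`` sarcomere
    length in the anatomical position (um), ``sigma_m`` specific tension
    (N/cm^2).
    """

    acsa_max: float
    lf_anat: float
    l_sarc: float
    sigma_m: float = DEFAULT_SPECIFIC_TENSION
    optimal_sarcomere: float = OPTIMAL_SARCOMERE_UM

    def __post_init__(self) -> None:
        for name in ("acsa_max", "lf_anat", "l_sarc", "sigma_m"):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be positive")


def fmax_from_volume(volume_cm3: float, lf_o_cm: float,
                     sigma_m: float = DEFAULT_SPECIFIC_TENSION) -> float:
    """Maximal isometric force (N) from muscle volume and optimal fiber length.

    ``F_max = sigma_m * volume / lf_o`` with volume in cm^3, lengths in cm.
    """
    if not (volume_cm3 > 0 and lf_o_cm > 0 and sigma_m > 0):
        raise ParameterError("volume, lf_o and sigma_m must be positive")
    return sigma_m * volume_cm3 / lf_o_cm


def volume_from_regression(mass_kg: float, height_m: float,
                           coeffs: tuple[float, float]) -> float:
    """Muscle volume (cm^3) from the linear fit ``b1 * mass * height + b2``."""
    if not (mass_kg > 0 and height_m > 0):
        raise ParameterError("mass and height must be positive")
    try:
        b1, b2 = coeffs
    except (TypeError, ValueError):
        raise ConfigError("regression coefficients must be a (b1, b2) pair") from None
    return b1 * mass_kg * height_m + b2


def lfo_from_sarcomere(lf_anat_cm: float, l_sarc_um: float,
                       optimal_sarcomere_um: float = OPTIMAL_SARCOMERE_UM) -> float:
    """Optimal fiber length (cm) from the anatomical fiber/sarcomere lengths.

    Scales the measured fiber length to the length at which sarcomeres sit
    at their optimum: ``lf_o = lf_anat * (2.7 um / l_sarc)``.
    """
    if not (lf_anat_cm > 0 and l_sarc_um > 0):
        raise ParameterError("fiber and sarcomere lengths must be positive")
    return lf_anat_cm * (optimal_sarcomere_um / l_sarc_um)


def fmax_from_acsa(acsa_max_cm2: float,
                   sigma_m: float = DEFAULT_SPECIFIC_TENSION) -> float:
    """Maximal isometric force (N) from maximal anatomical cross-section."""
    if not (acsa_max_cm2 > 0 and sigma_m > 0):
        raise ParameterError("ACSA and sigma_m must be positive")
    return sigma_m * acsa_max_cm2


def calibrate_tendon_slack(params: MuscleTendonParams, geometry: KneeGeometry,
                           target_lf_anat_m: float,
                           a: float = CALIBRATION_ACTIVATION) -> float:
    """Tendon slack length (m) placing the fiber at its anatomical target.

    Root-finds ``lt_s`` such that the equilibrium fiber length at the
    anatomical pose (knee 0 deg, hip 0 deg) with activation ``a`` equals
    ``target_lf_anat_m``.  The fiber-length residual is monotone in
    ``lt_s``, so the root is unique on the bracket.
    """
    if not (target_lf_anat_m > 0):
        raise ParameterError("target fiber length must be positive")
    l_mtu = mtu_length(geometry, params.name, ANATOMICAL_POSE)
    if target_lf_anat_m >= l_mtu:
        raise CalibrationError(
            f"{params.name}: target fiber length {target_lf_anat_m:.4f} m "
            f"not shorter than the musculotendon length {l_mtu:.4f} m")

    def residual(lt_s: float) -> float:
        trial = replace(params, lt_s=lt_s)
        return solve_isometric_equilibrium(trial, l_mtu, a).l_fiber - target_lf_anat_m

    lo, hi = 1e-3, 0.95 * l_mtu
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise CalibrationError(
            f"{params.name}: calibration target unreachable on "
            f"[{lo:.4g}, {hi:.4g}] m (residuals {r_lo:.3g}, {r_hi:.3g})")
    return brentq(residual, lo, hi, xtol=1e-10, maxiter=200)


def rescale_fiber_tendon(params: MuscleTendonParams, old_geometry: KneeGeometry,
                         new_geometry: KneeGeometry,
                         reference_pose: PoseConfig = ANATOMICAL_POSE
                         ) -> MuscleTendonParams:
    """Re-optimize fiber/tendon lengths after a geometry change.

    Both ``lf_o`` and ``lt_s`` are multiplied by the ratio of musculotendon
    lengths at the reference pose, which preserves normalized fiber length
    and tendon strain at every pose of a pure uniform scaling.
    """
    l_old = mtu_length(old_geometry, params.name, reference_pose)
    l_new = mtu_length(new_geometry, params.name, reference_pose)
    if l_old <= 0:
        raise ParameterError("old geometry yields non-positive length")
    ratio = l_new / l_old
    return replace(params, lf_o=params.lf_o * ratio, lt_s=params.lt_s * ratio)


# ---------------------------------------------------------------------------
# Model container and baseline build

@dataclass
class KneeModel:
    """A complete knee muscle model: parameters, geometry, morphology.

    ``st_morphology`` records the semitendinosus imaging inputs so that
    perturbation scenarios can rebuild its Hill parameters from first
    principles (force from ACSA, optimal fiber length from sarcomere
    geometry) rather than mutating opaque numbers.
    """

    params: dict[str, MuscleTendonParams]
    geometry: KneeGeometry
    st_morphology: MorphologyRecord
    st_name: str = "semitendinosus"
    quad_coactivation: float = 0.075
    sigma_m: float = DEFAULT_SPECIFIC_TENSION
    meta: dict = field(default_factory=dict)

    @property
    def flexors(self) -> list[str]:
        return [n for n, p in self.params.items() if p.is_flexor]

    @property
    def extensors(self) -> list[str]:
        return [n for n, p in self.params.items() if not p.is_flexor]

    @property
    def synergists(self) -> list[str]:
        return [n for n in self.flexors if n != self.st_name]

    def copy(self) -> "KneeModel":
        return KneeModel(params=dict(self.params), geometry=self.geometry,
                         st_morphology=self.st_morphology, st_name=self.st_name,
                         quad_coactivation=self.quad_coactivation,
                         sigma_m=self.sigma_m, meta=copy.deepcopy(self.meta))


def default_config() -> dict:
    """The packaged baseline model configuration (deep copy)."""
    text = resources.files("kneeflex.data").joinpath("default_model.json").read_text()
    return json.loads(text)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def build_baseline_model(config: dict | str | Path | None = None) -> KneeModel:
    """Construct and calibrate the baseline model.

    Deterministic: geometry scaling, volume regressions, semitendinosus
    personalization and per-muscle tendon-slack calibration, in that order.
    """
    if config is None:
        config = default_config()
    elif isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())

    try:
        anthro = config["anthropometry"]
        sigma_m = float(config["sigma_m_n_per_cm2"])
        gamma = float(config["gamma"])
        eps_t0 = float(config["eps_t0"])
        quad_coactivation = float(config["quad_coactivation"])
        st_cfg = config["st_morphology"]
        muscles_cfg = config["muscles"]
        geometry = geometry_from_dict(config["geometry"])
    except KeyError as exc:
        raise ConfigError(f"model config missing key {exc}") from None

    geometry = scale_geometry(
        geometry, float(anthro["thigh_length_m"]),
        float(config.get("reference_thigh_length_m", 0.413)))

    lf_anat_st_cm = float(np.mean(st_cfg["compartment_lengths_cm"]))
    morphology = MorphologyRecord(
        acsa_max=float(st_cfg["acsa_max_cm2"]),
        lf_anat=lf_anat_st_cm,
        l_sarc=float(st_cfg["l_sarc_um"]),
        sigma_m=sigma_m)

    st_name = config.get("st_name", "semitendinosus")
    params: dict[str, MuscleTendonParams] = {}
    for name, cfg in muscles_cfg.items():
        is_flexor = geometry.path(name).action == "flexor"
        if name == st_name:
            lf_o_m = lfo_from_sarcomere(morphology.lf_anat, morphology.l_sarc) / 100.0
            f_max = fmax_from_acsa(morphology.acsa_max, sigma_m)
            target_m = morphology.lf_anat / 100.0
            alpha_o = 0.0
        else:
            lf_o_m = float(cfg["lf_o_m"]) * geometry.scale
            if "volume_cm3" in cfg:
                volume = float(cfg["volume_cm3"])
            else:
                volume = volume_from_regression(
                    float(anthro["mass_kg"]), float(anthro["height_m"]),
                    tuple(cfg["volume_regression"]))
            f_max = fmax_from_volume(volume, lf_o_m * 100.0, sigma_m)
            target_m = float(cfg["anatomical_norm_length"]) * lf_o_m
            alpha_o = float(cfg.get("alpha_o_rad", 0.0))
        base = MuscleTendonParams(
            name=name, f_max=f_max, lf_o=lf_o_m, lt_s=0.1,
            alpha_o=alpha_o, gamma=gamma, eps_t0=eps_t0, is_flexor=is_flexor)
        lt_s = calibrate_tendon_slack(base, geometry, target_m)
        params[name] = replace(base, lt_s=lt_s)

    return KneeModel(
        params=params, geometry=geometry, st_morphology=morphology,
        st_name=st_name, quad_coactivation=quad_coactivation, sigma_m=sigma_m,
        meta={"config_hash": config_hash(config),
              "anthropometry": dict(anthro)})
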