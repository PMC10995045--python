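"""Morphology-perturbation simulations and the synergist-compensation search.

Baseline joint moments are computed with every knee flexor maximally
activated and the quadriceps at a fixed co-activation level; the resultant
flexion moment is the agonist (flexor) moment minus the antagonist
(quadriceps) extension moment.  Reconstructed-leg conditions perturb the
semitendinosus morphology:

* radial atrophy — smaller ACSA_max, hence smaller F_max;
* serial sarcomere loss — shorter anatomical fiber length at unchanged
  sarcomere length, hence a proportionally shorter optimal fiber length;
* sarcomere shortening — anatomical fiber and sarcomere lengths reduced by
  the same fraction, leaving the optimal fiber length unchanged but moving
  the anatomical operating point to shorter normalized lengths.

Both sarcomere-level mechanisms re-calibrate the tendon slack length to the
new anatomical fiber length.  All reconstructed-leg conditions also reduce
quadriceps F_max by 10% (known quadriceps atrophy), so the resultant moment
can exceed baseline.  Sweeps step morphology deltas in exact 1% intervals
between the +/-1 SD bounds of the measured between-leg differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, ScenarioError, SolverError
from .knee_geometry import PoseConfig, moment_arm, mtu_length
from .mtu_model import MuscleTendonParams, solve_isometric_equilibrium
from .personalization import (KneeModel, MorphologyRecord,
                              calibrate_tendon_slack, fmax_from_acsa,
                              lfo_from_sarcomere)

__all__ = [
    "ScenarioSpec",
    "MomentResult",
    "SweepResult",
    "ImpairmentResult",
    "CompensationResult",
    "DEFAULT_ANGLES",
    "QUAD_ATROPHY_DELTA",
    "ACSA_SWEEP_BOUNDS_PCT",
    "LENGTH_SWEEP_BOUNDS_PCT",
    "SWEEP_CONDITIONS",
    "joint_moment",
    "baseline_moments",
    "apply_radial_atrophy",
    "apply_sarcomere_loss",
    "apply_sarcomere_shortening",
    "apply_quad_atrophy",
    "percent_grid",
    "run_sweep",
    "impair_st_to_match",
    "synergist_compensation",
]

DEFAULT_ANGLES = (15.0, 45.0, 60.0, 90.0)

#: Quadriceps F_max change applied in all reconstructed-leg conditions.
QUAD_ATROPHY_DELTA = -0.10

#: ACSA_max between-leg difference sweep bounds, integer percent.
ACSA_SWEEP_BOUNDS_PCT = (8, -22)
#: Muscle-length between-leg difference sweep bounds, integer percent.
LENGTH_SWEEP_BOUNDS_PCT = (-6, -17)

#: The five simulated conditions: radial alone, each sarcomere mechanism
#: alone, and radial combined with each mechanism (Cartesian product).
SWEEP_CONDITIONS = ("acsa", "sarcomere_number", "sarcomere_length",
                    "acsa_number", "acsa_length")


@dataclass(frozen=True)
class ScenarioSpec:
    """One morphology/compensation perturbation."""

    acsa_delta: float = 0.0
    length_delta: float = 0.0
    mechanism: str = "none"  # none | serial_sarcomere_loss | sarcomere_shortening
    synergist_fmax_delta: float = 0.0
    quad_fmax_delta: float = 0.0
    knee_angles: tuple[float, ...] = DEFAULT_ANGLES
    hip_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("none", "serial_sarcomere_loss",
                                  "sarcomere_shortening"):
            raise ParameterError(f"unknown mechanism {self.mechanism!r}")
        if (self.mechanism == "none") != (self.length_delta == 0.0):
            raise ParameterError("mechanism 'none' requires length_delta == 0 "
                                 "and vice versa")


@dataclass
class MomentResult:
    """Joint moments (Nm) at a set of knee angles."""

    angles_deg: tuple[float, ...]
    flexor_nm: np.ndarray
    extensor_nm: np.ndarray
    per_muscle_nm: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def resultant_nm(self) -> np.ndarray:
        return self.flexor_nm - self.extensor_nm

    def relative_to(self, baseline: "MomentResult") -> np.ndarray:
        """(condition - baseline) / baseline, per angle."""
        return (self.resultant_nm - baseline.resultant_nm) / baseline.resultant_nm


def _muscle_moment(model: KneeModel, name: str, pose: PoseConfig,
                   activation: float,
                   params: MuscleTendonParams | None = None) -> float:
    """Active-force moment contribution (Nm) of one muscle at one pose."""
    p = params if params is not None else model.params[name]
    l_mtu = mtu_length(model.geometry, name, pose)
    try:
        f_active = solve_isometric_equilibrium(p, l_mtu, activation).f_active
    except SolverError as exc:
        raise ScenarioError(
            f"equilibrium failed for {name} at knee {pose.knee_angle_deg} deg: "
            f"{exc}") from exc
    return f_active * moment_arm(model.geometry, name, pose)


def joint_moment(model: KneeModel, pose: PoseConfig,
                 activations: dict[str, float] | None = None) -> MomentResult:
    """Flexor, extensor and per-muscle active moments at one pose.

    Defaults: flexors fully activated (1.0), quadriceps at the model's
    co-activation level.  The moment-generating force is the *active* fiber
    force along the tendon; passive forces only shape the equilibrium.
    """
    acts = {}
    for name, p in model.params.items():
        acts[name] = 1.0 if p.is_flexor else model.quad_coactivation
    if activations:
        for name, a in activations.items():
            if name not in model.params:
                raise ParameterError(f"unknown muscle {name!r}")
            if not (0.0 <= a <= 1.0):
                raise ParameterError(f"{name}: activation outside [0, 1]")
            acts[name] = a

    per_muscle: dict[str, np.ndarray] = {}
    flexor = extensor = 0.0
    for name, p in model.params.items():
        if acts[name] == 0.0:
            m = 0.0
        else:
            m = _muscle_moment(model, name, pose, acts[name])
        per_muscle[name] = np.array([m])
        if p.is_flexor:
            flexor += m
        else:
            extensor += m
    return MomentResult(angles_deg=(pose.knee_angle_deg,),
                        flexor_nm=np.array([flexor]),
                        extensor_nm=np.array([extensor]),
                        per_muscle_nm=per_muscle)


def baseline_moments(model: KneeModel,
                     angles_deg: tuple[float, ...] = DEFAULT_ANGLES,
                     hip_angle_deg: float = 0.0) -> MomentResult:
    """Resultant moments of the calibrated baseline model (the reference)."""
    flexor, extensor = [], []
    per_muscle: dict[str, list[float]] = {n: [] for n in model.params}
    for theta in angles_deg:
        res = joint_moment(model, PoseConfig(theta, hip_angle_deg))
        flexor.append(res.flexor_nm[0])
        extensor.append(res.extensor_nm[0])
        for n in model.params:
            per_muscle[n].append(res.per_muscle_nm[n][0])
    return MomentResult(angles_deg=tuple(angles_deg),
                        flexor_nm=np.array(flexor),
                        extensor_nm=np.array(extensor),
                        per_muscle_nm={n: np.array(v) for n, v in per_muscle.items()})


# ---------------------------------------------------------------------------
# Morphology perturbations

def _rebuild_st(model: KneeModel, morphology: MorphologyRecord,
                lf_o_m: float, recalibrate: bool) -> KneeModel:
    st = model.params[model.st_name]
    f_max = fmax_from_acsa(morphology.acsa_max, morphology.sigma_m)
    new_st = replace(st, f_max=f_max, lf_o=lf_o_m)
    if recalibrate:
        lt_s = calibrate_tendon_slack(new_st, model.geometry,
                                      morphology.lf_anat / 100.0)
        new_st = replace(new_st, lt_s=lt_s)
    out = model.copy()
    out.params[model.st_name] = new_st
    out.st_morphology = morphology
    return out


def apply_radial_atrophy(model: KneeModel, acsa_delta: float,
                         allow_out_of_bounds: bool = False) -> KneeModel:
    """Scale semitendinosus ACSA_max by (1 + acsa_delta); F_max follows.

    The fiber/tendon lengths are untouched: radial atrophy changes how much
    force the muscle can produce, not where it operates.
    """
    lo, hi = ACSA_SWEEP_BOUNDS_PCT[1] / 100.0, ACSA_SWEEP_BOUNDS_PCT[0] / 100.0
    if not allow_out_of_bounds and not (lo <= acsa_delta <= hi):
        raise ParameterError(
            f"acsa_delta {acsa_delta} outside [{lo}, {hi}] "
            "(pass allow_out_of_bounds=True to override)")
    morph = replace(model.st_morphology,
                    acsa_max=model.st_morphology.acsa_max * (1.0 + acsa_delta))
    st = model.params[model.st_name]
    return _rebuild_st(model, morph, st.lf_o, recalibrate=False)


def _check_length_delta(length_delta: float, allow_out_of_bounds: bool) -> None:
    lo, hi = LENGTH_SWEEP_BOUNDS_PCT[1] / 100.0, LENGTH_SWEEP_BOUNDS_PCT[0] / 100.0
    if not allow_out_of_bounds and not (lo <= length_delta <= hi):
        raise ParameterError(
            f"length_delta {length_delta} outside [{lo}, {hi}] "
            "(pass allow_out_of_bounds=True to override)")


def apply_sarcomere_loss(model: KneeModel, length_delta: float,
                         allow_out_of_bounds: bool = False) -> KneeModel:
    """Remove serial sarcomeres: shorter anatomical fiber, same sarcomeres.

    ``lf_anat`` scales by (1 + length_delta) at unchanged sarcomere length,
    so the optimal fiber length scales by the same factor and the
    anatomical normalized fiber length is preserved.  The tendon slack
    length is re-calibrated to the new anatomical fiber length.
    """
    _check_length_delta(length_delta, allow_out_of_bounds)
    morph = replace(model.st_morphology,
                    lf_anat=model.st_morphology.lf_anat * (1.0 + length_delta))
    lf_o_cm = lfo_from_sarcomere(morph.lf_anat, morph.l_sarc)
    return _rebuild_st(model, morph, lf_o_cm / 100.0, recalibrate=True)


def apply_sarcomere_shortening(model: KneeModel, length_delta: float,
                               allow_out_of_bounds: bool = False) -> KneeModel:
    """Shorten sarcomeres: fiber and sarcomere lengths scale together.

    The scaling cancels exactly in the optimal-fiber-length relation, so
    ``lf_o`` is carried over bit-identically; only the anatomical operating
    point moves (to shorter normalized lengths).  The tendon slack length
    is re-calibrated to the new anatomical fiber length.
    """
    _check_length_delta(length_delta, allow_out_of_bounds)
    morph = replace(model.st_morphology,
                    lf_anat=model.st_morphology.lf_anat * (1.0 + length_delta),
                    l_sarc=model.st_morphology.l_sarc * (1.0 + length_delta))
    # exact algebraic cancellation: lf_o unchanged
    lf_o_m = model.params[model.st_name].lf_o
    return _rebuild_st(model, morph, lf_o_m, recalibrate=True)


def apply_quad_atrophy(model: KneeModel,
                       delta: float = QUAD_ATROPHY_DELTA) -> KneeModel:
    """Scale every quadriceps F_max by (1 + delta); co-activation unchanged."""
    out = model.copy()
    for name in model.extensors:
        p = out.params[name]
        out.params[name] = replace(p, f_max=p.f_max * (1.0 + delta))
    return out


def apply_synergist_boost(model: KneeModel, delta: float) -> KneeModel:
    """Scale every non-semitendinosus flexor F_max by (1 + delta)."""
    out = model.copy()
    for name in model.synergists:
        p = out.params[name]
        out.params[name] = replace(p, f_max=p.f_max * (1.0 + delta))
    return out


# ---------------------------------------------------------------------------
# Sweeps

def percent_grid(upper_pct: int, lower_pct: int) -> np.ndarray:
    """Integer-percent grid from upper to lower bound, 1% steps, inclusive."""
    if upper_pct < lower_pct:
        raise ParameterError("upper bound must not be below lower bound")
    return np.arange(upper_pct, lower_pct - 1, -1)


@dataclass
class SweepResult:
    """Relative resultant-moment differences of one sweep condition."""

    condition: str
    angles_deg: tuple[float, ...]
    #: acsa/length percent deltas of each iteration (NaN where not swept)
    acsa_pct: np.ndarray
    length_pct: np.ndarray
    #: (n_iterations, n_angles) relative differences vs baseline
    rel_diff: np.ndarray

    @property
    def median(self) -> np.ndarray:
        return np.median(self.rel_diff, axis=0)

    @property
    def min(self) -> np.ndarray:
        return np.min(self.rel_diff, axis=0)

    @property
    def max(self) -> np.ndarray:
        return np.max(self.rel_diff, axis=0)

    def summary(self) -> dict:
        return {
            "condition": self.condition,
            "angles_deg": list(self.angles_deg),
            "median": self.median.tolist(),
            "min": self.min.tolist(),
            "max": self.max.tolist(),
            "n_iterations": int(self.rel_diff.shape[0]),
        }


def _condition_grids(condition: str) -> tuple[np.ndarray, np.ndarray, str]:
    """ACSA grid, length grid and mechanism for a named sweep condition."""
    acsa = percent_grid(*ACSA_SWEEP_BOUNDS_PCT)
    length = percent_grid(*LENGTH_SWEEP_BOUNDS_PCT)
    if condition == "acsa":
        return acsa, np.array([0]), "none"
    if condition == "sarcomere_number":
        return np.array([0]), length, "serial_sarcomere_loss"
    if condition == "sarcomere_length":
        return np.array([0]), length, "sarcomere_shortening"
    if condition == "acsa_number":
        return acsa, length, "serial_sarcomere_loss"
    if condition == "acsa_length":
        return acsa, length, "sarcomere_shortening"
    raise ParameterError(f"unknown sweep condition {condition!r}")


def _st_active_moments(model: KneeModel, st_params: MuscleTendonParams,
                       poses: list[PoseConfig]) -> np.ndarray:
    return np.array([
        _muscle_moment(model, model.st_name, pose, 1.0, params=st_params)
        for pose in poses])


def run_sweep(model: KneeModel, condition: str,
              angles_deg: tuple[float, ...] = DEFAULT_ANGLES,
              hip_angle_deg: float = 0.0,
              quad_delta: float = QUAD_ATROPHY_DELTA,
              baseline: MomentResult | None = None) -> SweepResult:
    """Run one morphology sweep condition against the baseline model.

    Combined conditions take the Cartesian product of the ACSA and length
    grids.  Quadriceps atrophy applies to every iteration.  Synergist and
    quadriceps moments do not depend on the semitendinosus deltas and are
    computed once per angle.
    """
    acsa_grid, length_grid, mechanism = _condition_grids(condition)
    if acsa_grid.size == 0 or length_grid.size == 0:
        raise ParameterError("empty sweep grid")
    if baseline is None:
        baseline = baseline_moments(model, angles_deg, hip_angle_deg)
    poses = [PoseConfig(t, hip_angle_deg) for t in angles_deg]

    atrophied = apply_quad_atrophy(model, quad_delta)
    synergist_nm = np.zeros(len(poses))
    extensor_nm = np.zeros(len(poses))
    for i, pose in enumerate(poses):
        synergist_nm[i] = sum(_muscle_moment(atrophied, n, pose, 1.0)
                              for n in model.synergists)
        extensor_nm[i] = sum(
            _muscle_moment(atrophied, n, pose, model.quad_coactivation)
            for n in model.extensors)

    # ST normalized equilibrium is independent of F_max, so length
    # calibration is shared across all ACSA deltas of a combined sweep.
    st_by_length: dict[int, MuscleTendonParams] = {}
    for lp in length_grid:
        if lp == 0:
            st_by_length[0] = model.params[model.st_name]
        elif mechanism == "serial_sarcomere_loss":
            st_by_length[int(lp)] = apply_sarcomere_loss(
                model, lp / 100.0).params[model.st_name]
        else:
            st_by_length[int(lp)] = apply_sarcomere_shortening(
                model, lp / 100.0).params[model.st_name]

    rows, acsa_col, length_col = [], [], []
    base_res = baseline.resultant_nm
    for lp in length_grid:
        st_len = st_by_length[int(lp)]
        st_unit = _st_active_moments(model, replace(st_len, f_max=1.0), poses)
        for ap in acsa_grid:
            f_max = fmax_from_acsa(
                model.st_morphology.acsa_max * (1.0 + ap / 100.0),
                model.st_morphology.sigma_m)
            # active force is proportional to F_max at fixed normalized
            # state; the normalized state itself is F_max-invariant
            st_nm = st_unit * f_max
            resultant = synergist_nm + st_nm - extensor_nm
            rows.append((resultant - base_res) / base_res)
            acsa_col.append(float(ap))
            length_col.append(float(lp))

    return SweepResult(condition=condition, angles_deg=tuple(angles_deg),
                       acsa_pct=np.array(acsa_col),
                       length_pct=np.array(length_col),
                       rel_diff=np.array(rows))


# ---------------------------------------------------------------------------
# Artificial impairment and synergist compensation

@dataclass
class ImpairmentResult:
    """Outcome of matching a target between-leg difference by impairing ST."""

    angle_deg: float
    target_rel_diff: float
    st_fmax_scale: float
    achieved_rel_diff: float
    achieved: bool
    floor_rel_diff: float
    model: KneeModel


def impair_st_to_match(model: KneeModel, angle_deg: float,
                       experimental_rel_diff: float,
                       quad_delta: float = QUAD_ATROPHY_DELTA,
                       tol: float = 1e-4,
                       mechanism: str = "fmax") -> ImpairmentResult:
    """Scale down semitendinosus until the model reproduces a measured deficit.

    Root-finds the ST F_max scale (or, with ``mechanism='activation'``, the
    ST activation) at which the resultant moment relative to baseline, with
    quadriceps atrophy applied, equals ``experimental_rel_diff``.  If even
    complete ST removal cannot reach the target, the floor difference is
    reported with ``achieved=False``.
    """
    if not (experimental_rel_diff < 0):
        raise ParameterError("experimental relative difference must be negative")
    if mechanism not in ("fmax", "activation"):
        raise ParameterError(f"unknown impairment mechanism {mechanism!r}")
    pose = PoseConfig(angle_deg)
    base = joint_moment(model, pose).resultant_nm[0]

    atrophied = apply_quad_atrophy(model, quad_delta)
    other_nm = (sum(_muscle_moment(atrophied, n, pose, 1.0)
                    for n in model.synergists)
                - sum(_muscle_moment(atrophied, n, pose, model.quad_coactivation)
                      for n in model.extensors))
    st = model.params[model.st_name]

    def rel_diff(scale: float) -> float:
        if scale == 0.0:
            st_nm = 0.0
        elif mechanism == "fmax":
            st_nm = _muscle_moment(model, model.st_name, pose, 1.0,
                                   params=replace(st, f_max=st.f_max * scale))
        else:
            st_nm = _muscle_moment(model, model.st_name, pose, scale)
        return (other_nm + st_nm - base) / base

    floor = rel_diff(0.0)
    target = experimental_rel_diff
    if floor > target:
        out = apply_quad_atrophy(model, quad_delta)
        st_zeroed = replace(st, f_max=st.f_max * 1e-12)
        out.params[model.st_name] = st_zeroed
        return ImpairmentResult(angle_deg=angle_deg, target_rel_diff=target,
                                st_fmax_scale=0.0, achieved_rel_diff=floor,
                                achieved=False, floor_rel_diff=floor, model=out)

    from scipy.optimize import brentq
    scale = brentq(lambda s: rel_diff(s) - target, 0.0, 1.0, xtol=1e-8)
    achieved = rel_diff(scale)
    if abs(achieved - target) > tol:
        raise ScenarioError(
            f"impairment at {angle_deg} deg missed target: "
            f"{achieved:.6f} vs {target:.6f}")
    out = apply_quad_atrophy(model, quad_delta)
    if mechanism == "fmax":
        out.params[model.st_name] = replace(st, f_max=st.f_max * scale)
        out.meta["st_activation"] = 1.0
    else:
        out.meta["st_activation"] = scale
    return ImpairmentResult(angle_deg=angle_deg, target_rel_diff=target,
                            st_fmax_scale=scale, achieved_rel_diff=achieved,
                            achieved=True, floor_rel_diff=floor, model=out)


@dataclass
class CompensationResult:
    """Outcome of the synergist F_max sweep on an impaired model."""

    angle_deg: float
    steps_pct: np.ndarray
    rel_diff: np.ndarray
    required_pct: int | None  # None = "insufficient"
    residual_at_max: float

    @property
    def sufficient(self) -> bool:
        return self.required_pct is not None


def synergist_compensation(impairment: ImpairmentResult, model: KneeModel,
                           max_pct: int = 20) -> CompensationResult:
    """Find the minimal synergist F_max increase restoring baseline moment.

    Increases the F_max of all synergists simultaneously in 1% steps up to
    ``max_pct``; the first step at which the resultant moment reaches or
    surpasses the baseline (relative difference >= 0) compensates.  Returns
    ``required_pct=None`` with the residual deficit if +``max_pct``% is
    insufficient.
    """
    pose = PoseConfig(impairment.angle_deg)
    base = joint_moment(model, pose).resultant_nm[0]
    impaired = impairment.model
    st_activation = impaired.meta.get("st_activation", 1.0)
    extensor_nm = sum(
        _muscle_moment(impaired, n, pose, impaired.quad_coactivation)
        for n in impaired.extensors)
    if impairment.st_fmax_scale > 0 or st_activation < 1.0:
        st_nm = _muscle_moment(impaired, impaired.st_name, pose, st_activation)
    else:
        st_nm = 0.0

    steps = np.arange(1, max_pct + 1)
    rel = np.empty(steps.size)
    required: int | None = None
    for i, k in enumerate(steps):
        syn_nm = sum(
            _muscle_moment(impaired, n, pose, 1.0,
                           params=replace(impaired.params[n],
                                          f_max=impaired.params[n].f_max
                                          * (1.0 + k / 100.0)))
            for n in impaired.synergists)
        rel[i] = (syn_nm + st_nm - extensor_nm - base) / base
        if required is None and rel[i] >= 0.0:
            required = int(k)
    return CompensationResult(angle_deg=impairment.angle_deg,
                              steps_pct=steps, rel_diff=rel,
                              required_pct=required,
                              residual_at_max=float(rel[-1]))
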