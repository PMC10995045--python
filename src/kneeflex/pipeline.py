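"""Full-analysis orchestration and model-vs-experiment decision rules.

The workflow: build the calibrated baseline model, run the five morphology
sweep conditions at the four test angles, compare each condition's range of
relative moment differences with the experimental 95% confidence interval
(closed-interval overlap = "this condition can fully induce the observed
weakness"), then artificially impair the semitendinosus to the measured
deficit at each angle and search the synergist F_max sweep for the minimal
compensating increase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamometry import ci95_from_stats
from .errors import ConfigError, ParameterError
from .personalization import KneeModel, build_baseline_model, config_hash, \
    default_config
from .scenarios import (DEFAULT_ANGLES, SWEEP_CONDITIONS, SweepResult,
                        baseline_moments, impair_st_to_match, run_sweep,
                        synergist_compensation)

__all__ = [
    "ExperimentalStats",
    "ComparisonVerdict",
    "load_experimental_stats",
    "compare_model_to_experiment",
    "run_full_analysis",
]


@dataclass(frozen=True)
class ExperimentalStats:
    """Experimental group statistics at one knee angle."""

    angle_deg: float
    n: int
    contra_mean_nm: float
    contra_sd_nm: float
    diff_mean: float
    diff_sd: float

    @property
    def diff_ci95(self) -> tuple[float, float]:
        return ci95_from_stats(self.diff_mean, self.diff_sd, self.n)

    @property
    def contra_window(self) -> tuple[float, float]:
        """Mean +/- 1 SD window used to validate the baseline model."""
        return (self.contra_mean_nm - self.contra_sd_nm,
                self.contra_mean_nm + self.contra_sd_nm)


@dataclass(frozen=True)
class ComparisonVerdict:
    """Interval-overlap verdict for one condition at one angle."""

    condition: str
    angle_deg: float
    model_min: float
    model_max: float
    exp_mean: float
    ci_low: float
    ci_high: float
    overlaps: bool


def load_experimental_stats(path: str | Path | None = None,
                            subgroup: str = "regenerated"
                            ) -> dict[float, ExperimentalStats]:
    """Per-angle experimental statistics (packaged defaults or a JSON file)."""
    if path is None:
        text = resources.files("kneeflex.data").joinpath(
            "experimental_stats.json").read_text()
    else:
        text = Path(path).read_text()
    payload = json.loads(text)
    if subgroup not in payload:
        raise ConfigError(f"no subgroup {subgroup!r} in experimental stats")
    block = payload[subgroup]
    out = {}
    for angle_str, entry in block["angles"].items():
        angle = float(angle_str)
        out[angle] = ExperimentalStats(
            angle_deg=angle, n=int(block["n"]),
            contra_mean_nm=float(entry["contra_mean_nm"]),
            contra_sd_nm=float(entry["contra_sd_nm"]),
            diff_mean=float(entry["diff_mean"]),
            diff_sd=float(entry["diff_sd"]))
    return out


def compare_model_to_experiment(sweep: SweepResult,
                                stats: dict[float, ExperimentalStats]
                                ) -> list[ComparisonVerdict]:
    """Closed-interval overlap between sweep ranges and experimental CIs."""
    verdicts = []
    for j, angle in enumerate(sweep.angles_deg):
        if angle not in stats:
            raise ParameterError(f"no experimental stats at {angle} deg")
        st = stats[angle]
        lo, hi = st.diff_ci95
        m_min, m_max = float(sweep.min[j]), float(sweep.max[j])
        overlaps = (m_min <= hi) and (m_max >= lo)
        verdicts.append(ComparisonVerdict(
            condition=sweep.condition, angle_deg=angle,
            model_min=m_min, model_max=m_max, exp_mean=st.diff_mean,
            ci_low=lo, ci_high=hi, overlaps=overlaps))
    return verdicts


def run_full_analysis(out_dir: str | Path | None = None,
                      config: dict | None = None,
                      experimental_stats_path: str | Path | None = None,
                      subgroup: str = "regenerated",
                      angles: tuple[float, ...] = DEFAULT_ANGLES,
                      model: KneeModel | None = None) -> dict:
    """Run the whole simulation analysis; optionally write a report bundle.

    Returns a dict with the baseline moments, per-condition sweep summaries
    and verdicts, and per-angle impairment/compensation results.  The
    pipeline is fully deterministic; the returned ``config_hash`` ties
    outputs to their configuration.
    """
    cfg = default_config() if config is None else config
    if model is None:
        model = build_baseline_model(cfg)
    stats = load_experimental_stats(experimental_stats_path, subgroup)

    base = baseline_moments(model, angles)
    baseline_rows = [
        {"angle_deg": a,
         "flexor_nm": float(base.flexor_nm[i]),
         "extensor_nm": float(base.extensor_nm[i]),
         "resultant_nm": float(base.resultant_nm[i]),
         "exp_contra_mean_nm": stats[a].contra_mean_nm,
         "exp_contra_sd_nm": stats[a].contra_sd_nm,
         "within_1sd": bool(stats[a].contra_window[0]
                            <= base.resultant_nm[i]
                            <= stats[a].contra_window[1])}
        for i, a in enumerate(angles)]

    sweep_rows, verdicts = [], []
    for condition in SWEEP_CONDITIONS:
        sweep = run_sweep(model, condition, angles, baseline=base)
        for i in range(sweep.rel_diff.shape[0]):
            for j, a in enumerate(angles):
                sweep_rows.append({
                    "condition": condition, "angle_deg": a,
                    "acsa_pct": sweep.acsa_pct[i],
                    "length_pct": sweep.length_pct[i],
                    "rel_diff": sweep.rel_diff[i, j]})
        verdicts.extend(compare_model_to_experiment(sweep, stats))

    compensation = []
    for a in angles:
        imp = impair_st_to_match(model, a, stats[a].diff_mean)
        comp = synergist_compensation(imp, model)
        compensation.append({
            "angle_deg": a,
            "target_rel_diff": stats[a].diff_mean,
            "impairment_achieved": imp.achieved,
            "st_fmax_scale": imp.st_fmax_scale,
            "floor_rel_diff": imp.floor_rel_diff,
            "required_pct": comp.required_pct,
            "sufficient": comp.sufficient,
            "residual_at_max": comp.residual_at_max})

    report = {
        "config_hash": config_hash(cfg),
        "subgroup": subgroup,
        "baseline": baseline_rows,
        "verdicts": [asdict(v) for v in verdicts],
        "compensation": compensation,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(baseline_rows).to_csv(out_dir / "baseline_moments.csv",
                                           index=False)
        pd.DataFrame(sweep_rows).to_csv(out_dir / "sweep_results.csv",
                                        index=False)
        pd.DataFrame([asdict(v) for v in verdicts]).to_csv(
            out_dir / "verdicts.csv", index=False)
        (out_dir / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
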