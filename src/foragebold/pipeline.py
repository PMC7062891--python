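"""End-to-end scenarios: schedule -> TD curves -> design -> cohort -> GLM ->
permutation report.

Each of the three experiment variants is encoded as a preset:

=============  ========  =====  ========  ===========  ============
experiment     subjects  TR s   FWHM mm   alternation  targets
=============  ========  =====  ========  ===========  ============
1              35        2.46   8         random       irregular
2              17        2.85   6         regular      irregular
3              20        2.85   6         random       regular
=============  ========  =====  ========  ===========  ============

The planted group effects mirror the design logic: the cue contrast carries a
high-vs-low difference in the ventral-striatum phantom region only where the
cue is informative (experiments 1 and 3), while the foraging-patch contrast
carries a difference in the VTA/SN phantom region in every experiment.  The
cue contrast is corrected within the ventral-striatum ROI box; the patch
contrast whole-volume in experiment 1 and within the midbrain surrogate box
in experiments 2 and 3 (cluster-defining p: 0.001 whole volume, 0.01 ROI).

A master seed deterministically derives every stage's stream, so identical
configurations reproduce identical cluster tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import design_matrix, glm, inference, synth_bold, td_model
from .design_matrix import DesignMatrix, HRFSpec, build_block_design
from .inference import PermutationResult, builtin_roi, cluster_report, \
    permutation_correct
from .synth_bold import (Amplitudes, CohortSpec, NoiseSpec, Phantom,
                         default_phantom, draw_subject_amplitudes,
                         gaussian_smooth, simulate_subject)
from .task_schedule import (TaskConfig, TrialSchedule, experiment_task_config,
                            generate_schedule, write_events)
from .td_model import TDConfig

log = logging.getLogger("foragebold.pipeline")

CONTRASTS: dict[str, dict[str, float]] = {
    "cue_high_gt_low": {"cue_high": 1.0, "cue_low": -1.0},
    "patch_high_gt_low": {"patch_high": 1.0, "patch_low": -1.0},
}


@dataclass
class ScenarioConfig:
    """Complete description of one simulated experiment run."""

    experiment: int
    task: TaskConfig
    td: TDConfig
    hrf: HRFSpec
    noise: NoiseSpec
    cohort: CohortSpec
    amplitudes: Amplitudes
    tr: float
    fwhm: float
    n_perm: int = 6000
    cdt_whole: float = 0.001
    cdt_roi: float = 0.01
    connectivity: int = 18
    run_td: bool = True
    seed: int = 0

    @property
    def n_scans(self) -> int:
        return int(np.ceil(self.task.n_trials * self.task.trial_duration
                           / self.tr))


@dataclass
class RunReport:
    """Artefacts of one scenario run."""

    experiment: int
    config: ScenarioConfig
    schedule: TrialSchedule
    design_names: list[str]
    affine: np.ndarray
    td_summary: dict | None
    contrast_maps: dict[str, np.ndarray]       # {contrast: (n_subj, x, y, z)}
    results: dict[str, PermutationResult]
    tables: dict[str, pd.DataFrame]
    detected: dict[str, bool]
    paths: dict[str, str] = field(default_factory=dict)


# planted group-mean amplitudes (% signal) per experiment: the cue effect
# lives in "VS" only when the cue is informative; the patch effect lives in
# "VTA_SN" in every experiment.
def _preset_amplitudes(experiment: int) -> Amplitudes:
    cue_effect = experiment != 2
    return {
        "VS": {"cue_high": 0.75 if cue_effect else 0.5,
               "cue_low": 0.25 if cue_effect else 0.5},
        "VTA_SN": {"patch_high": 0.5, "patch_low": 0.0},
    }


def experiment_preset(experiment: int, *, n_subjects: int | None = None,
                      n_perm: int = 6000, seed: int = 0,
                      noise: NoiseSpec | None = None,
                      between_sd: float = 0.15,
                      run_td: bool = True) -> ScenarioConfig:
    """Scenario preset for experiment 1, 2 or 3 (see module table)."""
    presets = {1: (35, 2.46, 8.0), 2: (17, 2.85, 6.0), 3: (20, 2.85, 6.0)}
    if experiment not in presets:
        raise ValueError(f"unknown experiment {experiment!r}")
    n_default, tr, fwhm = presets[experiment]
    n = n_default if n_subjects is None else n_subjects
    return ScenarioConfig(
        experiment=experiment,
        task=experiment_task_config(experiment),
        td=TDConfig(seed=seed),
        hrf=HRFSpec(),
        noise=noise or NoiseSpec(),
        cohort=CohortSpec(n_subjects=n, between_sd=between_sd, seed=seed),
        amplitudes=_preset_amplitudes(experiment),
        tr=tr, fwhm=fwhm, n_perm=n_perm, run_td=run_td, seed=seed)


def _roi_for_contrast(config: ScenarioConfig, contrast: str,
                      phantom: Phantom) -> tuple[np.ndarray | None, float]:
    """Search mask and cluster-defining p for one contrast."""
    if contrast.startswith("cue"):
        roi = builtin_roi("ventral_striatum", phantom.shape, phantom.affine)
        return roi.mask, config.cdt_roi
    if config.experiment == 1:
        return None, config.cdt_whole
    roi = builtin_roi("midbrain", phantom.shape, phantom.affine)
    return roi.mask, config.cdt_roi


def _td_summary(config: ScenarioConfig) -> dict:
    values, trace, curves = td_model.simulate_experiment(
        config.experiment, config.task, config.td)
    patch = td_model.consistency_residual(trace)
    cue = trace.frame[trace.frame.kind_to == "cue"]
    summary = {
        "converged": bool(values.converged),
        "training_trials": int(values.sweeps_used),
        "patch_mean_delta": patch.mean,
        "patch_max_abs_delta": patch.max_abs,
        "cue_mean_delta_high": float(
            cue[cue.trial_type == "high"].delta.mean()),
        "cue_mean_delta_low": float(
            cue[cue.trial_type == "low"].delta.mean()),
    }
    try:
        summary["reward_rate_ratio"] = td_model.reward_rate_ratio(
            curves, config.task)
    except (ValueError, KeyError):
        pass
    return summary


def run_scenario(config: ScenarioConfig,
                 out_dir: str | Path | None = None) -> RunReport:
    """Execute all stages of one experiment scenario.

    Deterministic given the master seed.  Any stage failure propagates with
    the stage name attached.
    """
    ss = np.random.SeedSequence(config.seed)
    s_sched, s_cohort, s_perm = ss.spawn(3)
    stage = "setup"
    try:
        stage = "schedule"
        log.info("stage=%s seed=%s", stage, config.seed)
        task = replace(config.task,
                       seed=int(s_sched.generate_state(1)[0] % 2 ** 31))
        schedule = generate_schedule(task)

        td_summary = None
        if config.run_td:
            stage = "td_model"
            log.info("stage=%s", stage)
            td_summary = _td_summary(config)

        stage = "design"
        design = build_block_design(schedule, config.tr, config.n_scans,
                                    config.hrf)
        for name, weights in CONTRASTS.items():
            missing = [c for c in weights if c not in design.frame.columns]
            if missing:
                raise ValueError(
                    f"contrast {name!r} references missing column(s) "
                    f"{missing}")

        stage = "synthesis"
        phantom = default_phantom()
        log.info("stage=%s n_subjects=%d", stage, config.cohort.n_subjects)
        contrast_maps: dict[str, list[np.ndarray]] = {
            name: [] for name in CONTRASTS}
        children = s_cohort.spawn(config.cohort.n_subjects)
        for i, child in enumerate(children):
            amp_seed, noise_seed = child.spawn(2)
            amps = draw_subject_amplitudes(
                config.amplitudes, config.cohort.between_sd,
                np.random.default_rng(amp_seed))
            series = simulate_subject(phantom, design, config.noise, amps,
                                      seed=noise_seed,
                                      subject_id=f"sub-{i:02d}")
            series = gaussian_smooth(series, config.fwhm)
            fit = glm.fit_first_level(series, design)
            for name, weights in CONTRASTS.items():
                contrast_maps[name].append(
                    glm.contrast_map(fit, weights).effect)

        stage = "inference"
        results: dict[str, PermutationResult] = {}
        tables: dict[str, pd.DataFrame] = {}
        detected: dict[str, bool] = {}
        for j, (name, _) in enumerate(CONTRASTS.items()):
            mask, cdt = _roi_for_contrast(config, name, phantom)
            res = permutation_correct(
                np.asarray(contrast_maps[name]), mask=mask,
                n_perm=config.n_perm, cdt_p=cdt,
                connectivity=config.connectivity,
                seed=int(s_perm.generate_state(1)[0] % 2 ** 31) + j)
            results[name] = res
            tables[name] = cluster_report(res, phantom.affine)
            detected[name] = any(
                c.p_cluster <= 0.05 or c.p_peak <= 0.05
                for c in res.clusters)
            log.info("contrast=%s clusters=%d detected=%s", name,
                     len(res.clusters), detected[name])
    except Exception as err:
        raise RuntimeError(f"scenario stage {stage!r} failed: {err}") from err

    report = RunReport(
        experiment=config.experiment, config=config, schedule=schedule,
        design_names=design.names, affine=phantom.affine,
        td_summary=td_summary,
        contrast_maps={k: np.asarray(v) for k, v in contrast_maps.items()},
        results=results, tables=tables, detected=detected)
    if out_dir is not None:
        _write_report(report, design, Path(out_dir))
    return report


def _write_report(report: RunReport, design: DesignMatrix,
                  out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.paths["events"] = str(write_events(report.schedule,
                                              out_dir / "events.tsv"))
    report.paths["design"] = str(design.to_tsv(out_dir / "design.tsv"))
    for name, table in report.tables.items():
        p = out_dir / f"clusters_{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        report.paths[f"clusters_{name}"] = str(p)
    summary = {
        "experiment": report.experiment,
        "seed": report.config.seed,
        "n_subjects": report.config.cohort.n_subjects,
        "tr": report.config.tr,
        "fwhm": report.config.fwhm,
        "n_perm": report.config.n_perm,
        "detected": {k: bool(v) for k, v in report.detected.items()},
        "td_summary": report.td_summary,
        "paths": report.paths,
    }
    path = out_dir / "report.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    report.paths["report"] = str(path)


def compare_experiments(report_a: RunReport, report_b: RunReport,
                        contrast: str, n_perm: int = 6000,
                        roi: str = "ventral_striatum",
                        cdt_p: float = 0.01, seed: int = 0
                        ) -> tuple[glm.GroupResult, pd.DataFrame]:
    """Between-experiments interaction on a shared contrast.

    Two-sample second level (B minus A) with group-label permutation
    correction over the named ROI.  Both runs must share grid and contrast
    definitions.
    """
    if contrast not in report_a.contrast_maps or \
            contrast not in report_b.contrast_maps:
        raise ValueError(f"contrast {contrast!r} missing from a run")
    a = report_a.contrast_maps[contrast]
    b = report_b.contrast_maps[contrast]
    if a.shape[1:] != b.shape[1:] or not np.allclose(report_a.affine,
                                                     report_b.affine):
        raise ValueError("runs are on different grids; cannot compare")
    maps = np.concatenate([a, b], axis=0)
    labels = np.r_[np.zeros(a.shape[0], dtype=int),
                   np.ones(b.shape[0], dtype=int)]
    mask = builtin_roi(roi, a.shape[1:], report_a.affine).mask
    group = glm.second_level(maps, "two_sample", labels)
    res = permutation_correct(maps, mask=mask, n_perm=n_perm, cdt_p=cdt_p,
                              analysis_type="two_sample", labels=labels,
                              seed=seed)
    return group, cluster_report(res, report_a.affine)


def load_scenario_yaml(path: str | Path) -> ScenarioConfig:
    """Build a scenario from a small YAML file of preset overrides.

    Recognised keys: experiment (required), n_subjects, n_perm, seed,
    fwhm, run_td, between_sd, and a ``noise`` mapping with NoiseSpec fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "experiment" not in raw:
        raise ValueError("scenario file must name an experiment (1, 2 or 3)")
    noise = NoiseSpec(**raw["noise"]) if "noise" in raw else None
    cfg = experiment_preset(
        int(raw["experiment"]),
        n_subjects=raw.get("n_subjects"),
        n_perm=int(raw.get("n_perm", 6000)),
        seed=int(raw.get("seed", 0)),
        noise=noise,
        between_sd=float(raw.get("between_sd", 0.15)),
        run_td=bool(raw.get("run_td", True)))
    if "fwhm" in raw:
        cfg = replace(cfg, fwhm=float(raw["fwhm"]))
    return cfg
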