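"""End-to-end pipeline: simulate -> V1 GLM analysis -> model fitting ->
hippocampal decoding -> tuning comparison -> group statistics -> JSON report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import decoding, geometry, glm, io, sr_models, tuning
from . import stats as group_stats
from .synth import GroundTruth, SubjectData, make_cohort

__version__ = "0.1.0"

log = logging.getLogger("srmap")

_CONFIG_KEYS = {"seed", "n_subjects", "n_runs", "truth", "analyze_v1",
                "analyze_decoding", "analyze_tuning", "out_dir", "verbosity"}


@dataclass
class RunConfig:
    seed: int
    n_subjects: int = 8
    n_runs: int = 3
    truth: GroundTruth = field(default_factory=GroundTruth)
    analyze_v1: bool = True
    analyze_decoding: bool = True
    analyze_tuning: bool = True
    out_dir: str | None = None
    verbosity: int = 1

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        unknown = set(payload) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in payload or payload["seed"] is None:
            raise ValueError("config must set a seed before any computation")
        payload = dict(payload)
        truth = payload.pop("truth", {})
        if isinstance(truth, dict):
            truth = GroundTruth(**truth)
        return cls(truth=truth, **payload)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def load_config(path, **overrides) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    payload.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(payload)


def subject_gamma_and_contrast(profile: np.ndarray) -> dict:
    """Per-subject successor/predecessor means, lag profile, fitted decay."""
    succ, pred, by_lag = glm.successor_predecessor_average(profile)
    lag_profile = np.array([by_lag[1], by_lag[2], by_lag[3]])
    try:
        gamma, amp = sr_models.fit_gamma_decay(lag_profile)
    except ValueError:
        gamma, amp = np.nan, np.nan
    return {"successor_mean": succ, "predecessor_mean": pred,
            "by_lag": by_lag, "gamma_decay": gamma, "decay_amplitude": amp}


def analyze_v1_cohort(subjects: list[SubjectData],
                      use_true_labels: bool = False) -> dict:
    """Activity profiles, SR/CO/H0 comparison, and the group contrast."""
    profiles, per_subject = [], []
    for sub in subjects:
        n_top = sub.truth.voxels_per_location
        profile = glm.activity_profile(sub, n_top=n_top,
                                       use_true_labels=use_true_labels)
        profiles.append(profile)
        per_subject.append(subject_gamma_and_contrast(profile))
    succ = np.array([d["successor_mean"] for d in per_subject])
    pred = np.array([d["predecessor_mean"] for d in per_subject])
    gammas = np.array([d["gamma_decay"] for d in per_subject])
    comparison = sr_models.model_comparison(profiles)
    sr_gamma = comparison["fits"].query("model == 'SR'")["gamma"].to_numpy()
    return {
        "profiles": profiles,
        "per_subject": per_subject,
        "successor_vs_predecessor": group_stats.paired_t(succ, pred),
        "gamma_decay_mean": float(np.nanmean(gammas)),
        "gamma_decay_sem": float(np.nanstd(gammas, ddof=1)
                                 / np.sqrt(np.sum(np.isfinite(gammas)))),
        "gamma_vs_one": group_stats.one_sample_t(gammas[np.isfinite(gammas)], 1.0),
        "sr_gamma_fits": sr_gamma,
        "model_comparison": comparison,
    }


def decode_subject(sub: SubjectData, compute_accuracy: bool = True,
                   main_task: bool = True) -> dict:
    """Localizer training, LOO accuracy, and the main-task evidence contrast.

    The expensive stages are optional: leave-one-out accuracy retrains the
    decoder once per localizer trial, and the main-task contrast needs the
    main runs simulated; tuning-only analyses can skip both.
    """
    loc = decoding.preprocess(sub.localizer["hippocampus"])
    onsets, labels = [], []
    for block in sub.design.localizer:
        if not block.rest:
            onsets.append(block.onset)
            labels.append(block.location)
    samples = decoding.extract_trial_samples(
        loc, onsets, labels, decoding.LOCALIZER_WINDOW)
    model = decoding.train_decoder(samples)
    cv_probs = decoding.crossvalidated_evidence(samples, seed=sub.truth.seed)
    out = {"model": model, "localizer_samples": samples,
           "localizer_labels": np.asarray(labels),
           "localizer_cv_evidence": cv_probs}
    if compute_accuracy:
        out["accuracy"] = decoding.loo_cross_validate(samples)
    if main_task:
        main = decoding.preprocess(sub.main["hippocampus"])
        t_onsets, t_runs, t_pos = decoding.partial_trial_info(sub.design)
        main_samples = decoding.extract_trial_samples(
            main, t_onsets, t_pos, decoding.MAIN_TASK_WINDOW, run_index=t_runs)
        probs = decoding.evidence(model, main_samples)
        succ, pred = decoding.evidence_contrast(probs, t_pos, sub.spec)
        out.update({"successor": succ, "predecessor": pred,
                    "preprocessed_main": main})
    return out


def analyze_decoding_cohort(subjects: list[SubjectData],
                            time_resolved: bool = False) -> dict:
    results = [decode_subject(sub) for sub in subjects]
    succ = np.array([r["successor"] for r in results])
    pred = np.array([r["predecessor"] for r in results])
    out = {
        "per_subject": results,
        "accuracy_mean": float(np.mean([r["accuracy"] for r in results])),
        "accuracy_vs_chance": group_stats.one_sample_t(
            [r["accuracy"] for r in results], 1.0 / 8.0),
        "successor_vs_predecessor": group_stats.paired_t(succ, pred),
    }
    if time_resolved:
        curves = []
        for sub, r in zip(subjects, results):
            offsets, diff = decoding.time_resolved_evidence(
                r["model"], r["preprocessed_main"], sub.design, sub.spec)
            curves.append(diff)
        mean_curve = np.mean(curves, axis=0)
        out["time_resolved"] = {
            "offsets": offsets, "mean_curve": mean_curve,
            "peak_s": decoding.fit_hrf_peak(offsets, mean_curve),
        }
    return out


def analyze_tuning_cohort(subjects: list[SubjectData],
                          decode_results: list[dict]) -> dict:
    coacts, specs = [], []
    for sub, r in zip(subjects, decode_results):
        coact = tuning.build_coactivation(
            r["localizer_cv_evidence"], r["localizer_labels"], sub.spec)
        coacts.append(coact)
        specs.append(sub.spec)
    comparison = tuning.compare_tuning(coacts, specs)
    return {"coactivation": coacts, "comparison": comparison}


def tuning_cohort_winner(hippocampus_tuning: str, n_subjects: int,
                         seed: int, truth: GroundTruth | None = None) -> str:
    """Winning tuning model for a localizer-only cohort with the given
    ground-truth coactivation structure (fast path: no main-task simulation,
    no leave-one-out accuracy)."""
    truth = dataclasses.replace(truth or GroundTruth(),
                                hippocampus_tuning=hippocampus_tuning)
    cohort = make_cohort(n_subjects, truth, seed, n_runs=0,
                         rois=("hippocampus",))
    results = [decode_subject(s, compute_accuracy=False, main_task=False)
               for s in cohort.subjects]
    return analyze_tuning_cohort(cohort.subjects, results)["comparison"]["winner"]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage on a synthetic cohort and build the report."""
    if config.seed is None:
        raise ValueError("seed is mandatory")
    rois = []
    if config.analyze_v1:
        rois.append("V1")
    if config.analyze_decoding or config.analyze_tuning:
        rois.append("hippocampus")
    log.info("simulating cohort: n=%d seed=%d", config.n_subjects, config.seed)
    cohort = make_cohort(config.n_subjects, config.truth, config.seed,
                         n_runs=config.n_runs, rois=tuple(rois))
    hashed = {k: v for k, v in config.to_dict().items()
              if k not in ("out_dir", "verbosity")}  # science only, not paths
    report = {
        "provenance": {
            "seed": config.seed,
            "version": __version__,
            "config_hash": io.config_hash(hashed),
            "n_subjects": config.n_subjects,
        }
    }
    decode_results = None
    try:
        if config.analyze_v1:
            v1 = analyze_v1_cohort(cohort.subjects)
            t = v1["successor_vs_predecessor"]
            report["v1"] = {
                "gamma_decay_mean": v1["gamma_decay_mean"],
                "gamma_decay_sem": v1["gamma_decay_sem"],
                "gamma_fits_sr": [float(g) for g in v1["sr_gamma_fits"]],
                "successor_vs_predecessor_t": t.statistic,
                "successor_vs_predecessor_p": t.p_value,
                "model_winner": v1["model_comparison"]["winner"],
                "mean_bic": v1["model_comparison"]["mean_bic"],
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'analyze_v1' failed: {exc}") from exc
    try:
        if config.analyze_decoding:
            dec = analyze_decoding_cohort(cohort.subjects, time_resolved=True)
            decode_results = dec["per_subject"]
            t = dec["successor_vs_predecessor"]
            report["decoding"] = {
                "localizer_accuracy_mean": dec["accuracy_mean"],
                "successor_vs_predecessor_t": t.statistic,
                "successor_vs_predecessor_p": t.p_value,
                "evidence_peak_s": dec["time_resolved"]["peak_s"],
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'decode' failed: {exc}") from exc
    try:
        if config.analyze_tuning:
            if decode_results is None:
                decode_results = [decode_subject(s) for s in cohort.subjects]
            tun = analyze_tuning_cohort(cohort.subjects, decode_results)
            report["tuning"] = {
                "winner": tun["comparison"]["winner"],
                "mean_bic": tun["comparison"]["mean_bic"],
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'tuning' failed: {exc}") from exc
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_report(report, out / "report.json")
        for s, sub in enumerate(cohort.subjects):
            io.write_events(sub.design, out / f"sub-{s:02d}_events.tsv")
    return report
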