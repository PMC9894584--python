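"""Seeded synthetic fMRI cohorts with known predictive-map ground truth.

The generator emulates the study conditions: eight retinotopic V1
subpopulations with Gaussian spatial bleed over chord distance, per-trial
amplitudes at omitted sequence locations produced by an SR (gamma), CO
(omega) or null generative model, hippocampal voxel patterns with
configurable temporal- or spatial-distance coactivation during the localizer,
full/partial/localizer trial structure, HRF convolution at TR = 1.5 s, and
white Gaussian noise at the volume level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry, hemo, sr_models
from .geometry import SequenceSpec, SessionDesign, StimulusLayout

DOT_STEP = geometry.DOT_DURATION + geometry.ISI  # nominal within-sequence lag


@dataclass
class GroundTruth:
    """All simulator knobs for one synthetic subject or cohort template."""

    generative_model: str = "SR"       # SR | CO | H0
    gamma: float = 0.3
    omega: float = 0.2
    predecessor_amplitude: float = 0.0
    stimulus_amplitude: float = 1.0    # beta units
    noise_sd: float = 1.0              # volume-level white noise, beta units
    spatial_spread: float = 1.5        # dva scale of V1 cross-location bleed
    hippocampus_tuning: str = "temporal"   # temporal | spatial | none
    tuning_slope: float = -0.25        # per |lag| step (temporal tuning)
    spatial_tuning_slope: float = -0.06  # per dva (spatial tuning)
    voxels_per_location: int = 8
    hippocampus_voxels: int = 50
    pattern_amplitude: float = 0.05    # hippocampal pattern strength (beta units)
    hrf_kind: str = "single"           # basis used for neural-event convolution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.voxels_per_location < 1 or self.hippocampus_voxels < 1:
            raise ValueError("voxel counts must be >= 1")
        if self.generative_model not in sr_models.MODELS:
            raise ValueError(f"unknown generative model {self.generative_model!r}")
        if self.hippocampus_tuning not in ("temporal", "spatial", "none"):
            raise ValueError(f"unknown tuning {self.hippocampus_tuning!r}")
        if not np.isfinite(self.stimulus_amplitude):
            raise ValueError("stimulus amplitude must be finite")


@dataclass
class VoxelTimeSeries:
    values: np.ndarray                 # voxels x volumes
    tr: float
    run_volumes: list[int]             # volumes per run, in order
    roi: str
    preferred_location: np.ndarray | None = None  # per-voxel label, V1 only

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    def run_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.run_volumes)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class SubjectData:
    spec: SequenceSpec
    design: SessionDesign
    truth: GroundTruth
    main: dict[str, VoxelTimeSeries]
    localizer: dict[str, VoxelTimeSeries]
    patterns: np.ndarray               # hippocampal patterns, 8 x voxels


@dataclass
class SyntheticCohort:
    subjects: list[SubjectData]
    cohort_seed: int


def generative_row(truth: GroundTruth, position: int) -> np.ndarray:
    """Amplitude weights over sequence positions after showing item ``position``."""
    w = np.zeros(4)
    w[position] = 1.0
    for j in range(4):
        if j == position:
            continue
        if truth.generative_model == "SR":
            if j > position:
                w[j] = truth.gamma ** (j - position)
            else:
                w[j] = truth.predecessor_amplitude
        elif truth.generative_model == "CO":
            w[j] = truth.omega
    return w


def canonical_hrf(t, kind: str = "double") -> np.ndarray:
    """Unit-peak canonical HRF (double gamma; single-gamma GLM basis selectable)."""
    return hemo.canonical_hrf(t, kind)


def bleed_matrix(layout: StimulusLayout, spread: float) -> np.ndarray:
    """Gaussian spatial bleed between V1 subpopulations over chord distance."""
    n = layout.n_locations
    B = np.eye(n)
    if spread <= 0:
        return B
    for i in range(n):
        for j in range(n):
            d = geometry.chord_distance(layout, i, j)
            B[i, j] = math.exp(-d * d / (2.0 * spread * spread))
    return B


def hippocampus_patterns(truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    """One random multivoxel pattern per stimulus location (8 x voxels).

    The pattern amplitude sets the hippocampal signal-to-noise ratio; the
    default keeps localizer decoding above chance but far from ceiling, so
    classifier evidence stays graded rather than saturated.
    """
    return truth.pattern_amplitude * rng.standard_normal(
        (8, truth.hippocampus_voxels))


def _main_task_events(run_trials, spec: SequenceSpec, truth: GroundTruth):
    """Per-location impulse events (onset, amplitude) for one main-task run.

    Neural events are impulses at trial onset; the 117 ms within-sequence dot
    offsets are far below the 1.5 s sampling resolution and are absorbed into
    the trial impulse, keeping the simulation in exact register with the
    trial-onset GLM regressors.
    """
    events: list[list[tuple[float, float]]] = [[] for _ in range(8)]
    amp = truth.stimulus_amplitude
    for trial in run_trials:
        if trial.trial_type == "full":
            for pos in range(4):
                events[spec.sequence_indices[pos]].append((trial.onset, amp))
        else:
            s = geometry.PARTIAL_TYPES.index(trial.trial_type)
            w = generative_row(truth, s)
            for pos in range(4):
                if w[pos] == 0.0:
                    continue
                events[spec.sequence_indices[pos]].append(
                    (trial.onset, amp * w[pos]))
    return events


def _location_signals(events, total_time: float, n_volumes: int, tr: float,
                      kind: str) -> np.ndarray:
    """Convolved, volume-sampled signal per location (8 x volumes)."""
    out = np.zeros((8, n_volumes))
    for loc in range(8):
        if not events[loc]:
            continue
        onsets = [e[0] for e in events[loc]]
        amps = [e[1] for e in events[loc]]
        fine = hemo.event_signal(onsets, amps, [0.0] * len(onsets),
                                 total_time, kind=kind)
        out[loc] = hemo.sample_at_volumes(fine, n_volumes, tr)
    return out


def simulate_subject(design: SessionDesign, spec: SequenceSpec,
                     truth: GroundTruth, rng: np.random.Generator,
                     patterns: np.ndarray | None = None,
                     layout: StimulusLayout | None = None,
                     rois: tuple[str, ...] = ("V1", "hippocampus"),
                     ) -> dict[str, VoxelTimeSeries]:
    """Main-task voxel time series for the requested ROIs.

    V1 subpopulation responses carry Gaussian spatial bleed; hippocampal
    voxels mix per-location random patterns.  Omitted-location drive on
    partial trials follows the generative model row.
    """
    if layout is None:
        layout = geometry.build_layout()
    if patterns is None and "hippocampus" in rois:
        patterns = hippocampus_patterns(truth, rng)
    B = bleed_matrix(layout, truth.spatial_spread)
    run_vols = [design.n_volumes(r) for r in range(len(design.runs))]
    v1_blocks, hip_blocks = [], []
    for r, trials in enumerate(design.runs):
        events = _main_task_events(trials, spec, truth)
        total = run_vols[r] * design.tr + hemo.KERNEL_LENGTH
        loc_sig = _location_signals(events, total, run_vols[r], design.tr,
                                    truth.hrf_kind)
        if "V1" in rois:
            sub_sig = B @ loc_sig     # subpopulation x volumes
            v1 = np.repeat(sub_sig, truth.voxels_per_location, axis=0)
            v1_blocks.append(v1)
        if "hippocampus" in rois:
            hip_blocks.append(patterns.T @ loc_sig)
    out = {}
    if "V1" in rois:
        values = np.concatenate(v1_blocks, axis=1)
        if truth.noise_sd > 0:
            values = values + truth.noise_sd * rng.standard_normal(values.shape)
        out["V1"] = VoxelTimeSeries(
            values=values, tr=design.tr, run_volumes=run_vols, roi="V1",
            preferred_location=np.repeat(np.arange(8), truth.voxels_per_location))
    if "hippocampus" in rois:
        values = np.concatenate(hip_blocks, axis=1)
        if truth.noise_sd > 0:
            values = values + truth.noise_sd * rng.standard_normal(values.shape)
        out["hippocampus"] = VoxelTimeSeries(
            values=values, tr=design.tr, run_volumes=run_vols, roi="hippocampus")
    return out


def localizer_coactivation(truth: GroundTruth, spec: SequenceSpec,
                           layout: StimulusLayout, s: int, j: int) -> float:
    """Ground-truth localizer drive of sequence position j when stimulating
    sequence position s, on the scale of the stimulated response.

    Tuned representations fade linearly away from the stimulated item — in
    sequence steps (temporal) or chord distance (spatial) — so the stimulated
    item itself (lag 0 / distance 0) sits on the same line at amplitude 1.
    With tuning "none" only the stimulated location responds.
    """
    if j == s:
        return 1.0
    if truth.hippocampus_tuning == "temporal":
        return max(0.0, 1.0 + truth.tuning_slope * abs(j - s))
    if truth.hippocampus_tuning == "spatial":
        d = geometry.chord_distance(layout, spec.sequence_indices[s],
                                    spec.sequence_indices[j])
        return max(0.0, 1.0 + truth.spatial_tuning_slope * d)
    return 0.0


def simulate_localizer(truth: GroundTruth, schedule, spec: SequenceSpec,
                       rng: np.random.Generator,
                       patterns: np.ndarray | None = None,
                       layout: StimulusLayout | None = None,
                       tr: float = geometry.TR,
                       rois: tuple[str, ...] = ("V1", "hippocampus"),
                       ) -> dict[str, VoxelTimeSeries]:
    """Localizer run: 13.5 s boxcar blocks, V1 bleed only, hippocampal
    coactivation of sequence-mates per the configured tuning."""
    if layout is None:
        layout = geometry.build_layout()
    if patterns is None and "hippocampus" in rois:
        patterns = hippocampus_patterns(truth, rng)
    last = schedule[-1]
    duration = last.onset + last.duration
    n_vols = math.ceil(duration / tr)
    total = n_vols * tr + hemo.KERNEL_LENGTH
    amp = truth.stimulus_amplitude
    events: list[list[tuple[float, float]]] = [[] for _ in range(8)]
    for block in schedule:
        if block.rest:
            continue
        events[block.location].append((block.onset, amp))
        pos = spec.position_of(block.location)
        if pos is not None:
            for j in range(4):
                if j == pos:
                    continue
                c = localizer_coactivation(truth, spec, layout, pos, j)
                if c > 0:
                    events[spec.sequence_indices[j]].append(
                        (block.onset, amp * c))
    loc_sig = np.zeros((8, n_vols))
    for loc in range(8):
        if not events[loc]:
            continue
        onsets = [e[0] for e in events[loc]]
        amps = [e[1] for e in events[loc]]
        fine = hemo.event_signal(onsets, amps,
                                 [geometry.LOCALIZER_BLOCK] * len(onsets),
                                 total, kind=truth.hrf_kind)
        loc_sig[loc] = hemo.sample_at_volumes(fine, n_vols, tr)
    out = {}
    if "V1" in rois:
        B = bleed_matrix(layout, truth.spatial_spread)
        # V1 responds with spatial bleed only: drop injected coactivation
        v1_events_sig = np.zeros((8, n_vols))
        for block in schedule:
            if block.rest:
                continue
            fine = hemo.event_signal([block.onset], [amp],
                                     [geometry.LOCALIZER_BLOCK], total,
                                     kind=truth.hrf_kind)
            v1_events_sig[block.location] += hemo.sample_at_volumes(
                fine, n_vols, tr)
        values = np.repeat(B @ v1_events_sig, truth.voxels_per_location, axis=0)
        if truth.noise_sd > 0:
            values = values + truth.noise_sd * rng.standard_normal(values.shape)
        out["V1"] = VoxelTimeSeries(
            values=values, tr=tr, run_volumes=[n_vols], roi="V1",
            preferred_location=np.repeat(np.arange(8), truth.voxels_per_location))
    if "hippocampus" in rois:
        values = patterns.T @ loc_sig
        if truth.noise_sd > 0:
            values = values + truth.noise_sd * rng.standard_normal(values.shape)
        out["hippocampus"] = VoxelTimeSeries(
            values=values, tr=tr, run_volumes=[n_vols], roi="hippocampus")
    return out


def simulate_subject_full(spec: SequenceSpec, truth: GroundTruth,
                          rng: np.random.Generator, n_runs: int = 3,
                          rois: tuple[str, ...] = ("V1", "hippocampus"),
                          layout: StimulusLayout | None = None) -> SubjectData:
    """Design + main task + localizer for one subject, sharing patterns."""
    if layout is None:
        layout = geometry.build_layout()
    design = geometry.build_session(spec, rng, n_runs=max(n_runs, 1), layout=layout)
    if n_runs == 0:  # localizer-only subject
        design.runs = []
    patterns = hippocampus_patterns(truth, rng) if "hippocampus" in rois else None
    main = {} if n_runs == 0 else simulate_subject(
        design, spec, truth, rng, patterns=patterns, layout=layout, rois=rois)
    localizer = simulate_localizer(truth, design.localizer, spec, rng,
                                   patterns=patterns, layout=layout,
                                   tr=design.tr, rois=rois)
    return SubjectData(spec=spec, design=design, truth=truth, main=main,
                       localizer=localizer, patterns=patterns)


def cohort_starts(n_subjects: int, rng: np.random.Generator) -> np.ndarray:
    """Counterbalanced starting locations: each sequence used floor(n/8) or
    ceil(n/8) times, assignment randomized."""
    reps = math.ceil(n_subjects / 8)
    starts = np.tile(np.arange(8), reps)[:n_subjects]
    rng.shuffle(starts)
    return starts


def make_cohort(n_subjects: int = 35, truth: GroundTruth | None = None,
                cohort_seed: int = 0, n_runs: int = 3,
                rois: tuple[str, ...] = ("V1", "hippocampus"),
                ) -> SyntheticCohort:
    """Seeded cohort with per-subject seeds spawned from the cohort seed."""
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    if truth is None:
        truth = GroundTruth()
    master = np.random.SeedSequence(cohort_seed)
    assign_ss, *subject_ss = master.spawn(n_subjects + 1)
    starts = cohort_starts(n_subjects, np.random.default_rng(assign_ss))
    layout = geometry.build_layout()
    specs = geometry.enumerate_sequences(layout)
    subjects = []
    for s in range(n_subjects):
        sub_truth = replace(truth, seed=int(subject_ss[s].generate_state(1)[0]
                                            % (2 ** 31)))
        rng = np.random.default_rng(subject_ss[s])
        subjects.append(simulate_subject_full(specs[int(starts[s])], sub_truth,
                                              rng, n_runs=n_runs, rois=rois,
                                              layout=layout))
    return SyntheticCohort(subjects=subjects, cohort_seed=cohort_seed)


def simulate_profiles(model_id: str, n_subjects: int,
                      rng: np.random.Generator, gamma: float = 0.3,
                      omega: float = 0.2, scale: float = 1.0,
                      noise_sd: float = 0.05) -> list[np.ndarray]:
    """Profile-level cohort: per-subject 4x4 activity profiles generated as the
    model prediction plus beta-level Gaussian noise (fast path for group-level
    model-comparison studies)."""
    unit = sr_models._unit_prediction(model_id, gamma=gamma, omega=omega)
    return [scale * unit + noise_sd * rng.standard_normal((4, 4))
            for _ in range(n_subjects)]
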