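"""Stimulus geometry, constrained sequences, and trial scheduling.

Eight dot locations sit evenly spaced on a circle around fixation.  A learned
sequence A-B-C-D visits four of them under three construction rules (B opposite
A, C 90 deg clockwise from B, D opposite C), which places one sequence dot in
every quadrant and decouples temporal order from spatial distance: the
temporally adjacent pair A-B is the spatially most distant one.

Angles are stored in degrees measured clockwise from the vertical meridian, so
"90 deg clockwise" is +90 in stored angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

TR = 1.5  # volume acquisition time, seconds

DOT_DURATION = 0.100       # single dot on-screen time, s
ISI = 0.017                # inter-stimulus interval within the sequence, s
DELAYED_ISI = 0.170        # ISI before the last dot on delayed trials, s
FULL_DURATION = 4 * DOT_DURATION + 3 * ISI            # 0.451 s
DELAYED_DURATION = 4 * DOT_DURATION + 2 * ISI + DELAYED_ISI  # 0.604 s
PARTIAL_DURATION = DOT_DURATION

TRIALS_PER_RUN = 192
FULL_PER_RUN = 128
PARTIAL_PER_RUN = 64
DELAYED_PER_RUN = 52

ITI_MIN = 2.0
ITI_MAX = 10.9
ITI_MEAN = 3.72

LOCALIZER_BLOCK = 13.5     # stimulation block length, s
LOCALIZER_REST = 15.0      # rest after each cycle of eight blocks, s
LOCALIZER_REPS = 8

PARTIAL_TYPES = ("partial_A", "partial_B", "partial_C", "partial_D")
SEQ_LABELS = "ABCD"


class LayoutError(ValueError):
    """Raised for invalid layout parameters or unsupported layouts."""


@dataclass(frozen=True)
class StimulusLayout:
    """Dot locations on a circle, angles clockwise from the vertical meridian."""

    radius: float = 7.0
    polar_angles: tuple[float, ...] = (
        22.5, 67.5, 112.5, 157.5, 202.5, 247.5, 292.5, 337.5)
    dot_diameter: float = 1.2

    @property
    def n_locations(self) -> int:
        return len(self.polar_angles)

    def coordinates(self) -> np.ndarray:
        """Cartesian (x, y) of each dot centre, in dva."""
        theta = np.deg2rad(np.asarray(self.polar_angles))
        # clockwise from vertical: x = r sin(theta), y = r cos(theta)
        return self.radius * np.column_stack([np.sin(theta), np.cos(theta)])


@dataclass(frozen=True)
class SequenceSpec:
    """One constrained sequence: indices of A,B,C,D plus the control dots."""

    sequence_indices: tuple[int, int, int, int]
    control_indices: tuple[int, int, int, int]

    def position_of(self, location_index: int) -> int | None:
        """Sequence position (0..3) of a location index, or None if control."""
        try:
            return self.sequence_indices.index(location_index)
        except ValueError:
            return None


@dataclass
class Trial:
    trial_type: str          # "full" or one of PARTIAL_TYPES
    delayed: bool
    onset: float             # s from run start
    duration: float          # s
    iti: float               # s, follows the trial


@dataclass
class LocalizerBlock:
    location: int | None     # stimulated location index, None for rest
    onset: float
    duration: float
    rest: bool


@dataclass
class SessionDesign:
    """Full session: main-task runs plus the stimulus localizer schedule."""

    runs: list[list[Trial]]
    tr: float = TR
    localizer: list[LocalizerBlock] = field(default_factory=list)

    def run_duration(self, run: int) -> float:
        last = self.runs[run][-1]
        return last.onset + last.duration + last.iti

    def n_volumes(self, run: int) -> int:
        return math.ceil(self.run_duration(run) / self.tr)

    def localizer_duration(self) -> float:
        last = self.localizer[-1]
        return last.onset + last.duration

    def localizer_volumes(self) -> int:
        return math.ceil(self.localizer_duration() / self.tr)


def build_layout(radius: float = 7.0, n_locations: int = 8) -> StimulusLayout:
    """Evenly spaced layout whose first angle is half the angular step."""
    if radius <= 0:
        raise LayoutError(f"radius must be positive, got {radius}")
    if n_locations < 2:
        raise LayoutError(f"need at least 2 locations, got {n_locations}")
    step = 360.0 / n_locations
    angles = tuple(step / 2 + k * step for k in range(n_locations))
    return StimulusLayout(radius=radius, polar_angles=angles)


def chord_distance(layout: StimulusLayout, i: int, j: int) -> float:
    """Euclidean distance between dot centres: 2 r sin(dtheta/2)."""
    n = layout.n_locations
    if not (0 <= i < n and 0 <= j < n):
        raise LayoutError(f"location index out of range: {i}, {j}")
    dtheta = abs(layout.polar_angles[i] - layout.polar_angles[j]) % 360.0
    if dtheta > 180.0:
        dtheta = 360.0 - dtheta
    return 2.0 * layout.radius * math.sin(math.radians(dtheta) / 2.0)


def _index_at_angle(layout: StimulusLayout, angle: float) -> int:
    angle %= 360.0
    for k, a in enumerate(layout.polar_angles):
        if abs(((a - angle) + 180.0) % 360.0 - 180.0) < 1e-9:
            return k
    raise LayoutError(f"no location at angle {angle}")


def enumerate_sequences(layout: StimulusLayout) -> list[SequenceSpec]:
    """All constrained sequences, one per starting location.

    B is 180 deg clockwise from A, C is 90 deg clockwise from B, and D is
    opposite C.
    """
    if layout.n_locations != 8:
        raise LayoutError("constrained sequences require an 8-location layout")
    specs = []
    for start in range(8):
        a = layout.polar_angles[start]
        seq = (
            start,
            _index_at_angle(layout, a + 180.0),
            _index_at_angle(layout, a + 270.0),
            _index_at_angle(layout, a + 90.0),
        )
        controls = tuple(k for k in range(8) if k not in seq)
        specs.append(SequenceSpec(sequence_indices=seq, control_indices=controls))
    return specs


def temporal_distance(spec: SequenceSpec, i, j) -> int:
    """Signed step count j - i in sequence order; accepts 'A'..'D' or 0..3."""

    def pos(x) -> int:
        if isinstance(x, str):
            if x not in SEQ_LABELS:
                raise ValueError(f"not a sequence position: {x!r}")
            return SEQ_LABELS.index(x)
        if 0 <= int(x) <= 3:
            return int(x)
        raise ValueError(f"not a sequence position: {x!r}")

    return pos(j) - pos(i)


def truncated_exponential_mean(scale: float, minimum: float, maximum: float) -> float:
    """Closed-form mean of a shifted exponential truncated at ``maximum``."""
    span = maximum - minimum
    r = span / scale
    if r > 700:  # exp overflow: effectively untruncated
        return minimum + scale
    return minimum + scale - span / math.expm1(r)


def calibrate_iti_scale(minimum: float = ITI_MIN, maximum: float = ITI_MAX,
                        target_mean: float = ITI_MEAN) -> float:
    """Scale of the truncated-exponential ITI law matching the design mean.

    The mean is increasing in the scale, from ``minimum`` (scale -> 0) to the
    midpoint (minimum + maximum)/2 (scale -> inf), so a root exists iff the
    target lies strictly between those bounds.
    """
    if not (minimum < target_mean < (minimum + maximum) / 2):
        raise ValueError(
            f"target mean {target_mean} not attainable in "
            f"({minimum}, {(minimum + maximum) / 2})")
    f = lambda b: truncated_exponential_mean(b, minimum, maximum) - target_mean
    lo, hi = 1e-9, 1.0
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, lo, hi, xtol=1e-9)


def sample_itis(rng: np.random.Generator, n: int,
                minimum: float = ITI_MIN, maximum: float = ITI_MAX,
                scale: float | None = None) -> np.ndarray:
    """Inverse-CDF draws from the truncated shifted-exponential ITI law."""
    if n < 1:
        raise ValueError("need n >= 1")
    if scale is None:
        scale = calibrate_iti_scale(minimum, maximum)
    u = rng.random(n)
    mass = -math.expm1(-(maximum - minimum) / scale)  # CDF mass below maximum
    return minimum - scale * np.log1p(-u * mass)


def _partial_positions(rng: np.random.Generator,
                       n_trials: int = TRIALS_PER_RUN,
                       n_partial: int = PARTIAL_PER_RUN) -> np.ndarray:
    """Uniform draw of partial-trial positions with a full trial on both sides.

    Valid position sets are the 64-subsets of {1..190} with pairwise gaps of at
    least 2.  The gap transform p_i = q_i + (i-1) maps them bijectively onto
    plain 64-subsets of {1..127}, so sampling the latter uniformly is an exact,
    rejection-free sampler of the constraint set.
    """
    n_slots = (n_trials - 2) - (n_partial - 1)  # 127 for the default counts
    q = np.sort(rng.choice(n_slots, size=n_partial, replace=False))
    return q + np.arange(n_partial) + 1


def build_session(spec: SequenceSpec, rng: np.random.Generator,
                  n_runs: int = 3, layout: StimulusLayout | None = None,
                  iti_scale: float | None = None) -> SessionDesign:
    """Main-task runs (192 trials: 128 full / 64 partial) plus the localizer."""
    if iti_scale is None:
        iti_scale = calibrate_iti_scale()
    if layout is None:
        layout = build_layout()
    runs = []
    for _ in range(n_runs):
        positions = set(_partial_positions(rng).tolist())
        partial_labels = list(np.repeat(PARTIAL_TYPES, PARTIAL_PER_RUN // 4))
        rng.shuffle(partial_labels)
        delayed_flags = np.zeros(FULL_PER_RUN, dtype=bool)
        delayed_flags[rng.choice(FULL_PER_RUN, DELAYED_PER_RUN, replace=False)] = True
        itis = sample_itis(rng, TRIALS_PER_RUN, scale=iti_scale)
        trials, t, i_partial, i_full = [], 0.0, 0, 0
        for k in range(TRIALS_PER_RUN):
            if k in positions:
                trial = Trial(partial_labels[i_partial], False, t,
                              PARTIAL_DURATION, float(itis[k]))
                i_partial += 1
            else:
                delayed = bool(delayed_flags[i_full])
                trial = Trial("full", delayed, t,
                              DELAYED_DURATION if delayed else FULL_DURATION,
                              float(itis[k]))
                i_full += 1
            trials.append(trial)
            t += trial.duration + trial.iti
        runs.append(trials)
    localizer = build_localizer_schedule(layout, rng)
    return SessionDesign(runs=runs, tr=TR, localizer=localizer)


def build_localizer_schedule(layout: StimulusLayout,
                             rng: np.random.Generator) -> list[LocalizerBlock]:
    """Eight cycles of eight 13.5 s blocks, each followed by a 15 s rest.

    Each location is stimulated once per cycle; the first block of every cycle
    (the post-rest slot, counting the run start as rest-like) carries a
    different location, so every location opens exactly one cycle.
    """
    if layout.n_locations != 8:
        raise LayoutError("localizer schedule requires an 8-location layout")
    openers = rng.permutation(8)
    blocks, t = [], 0.0
    for cycle in range(LOCALIZER_REPS):
        rest = [k for k in range(8) if k != openers[cycle]]
        rng.shuffle(rest)
        for loc in [int(openers[cycle])] + rest:
            blocks.append(LocalizerBlock(int(loc), t, LOCALIZER_BLOCK, False))
            t += LOCALIZER_BLOCK
        blocks.append(LocalizerBlock(None, t, LOCALIZER_REST, True))
        t += LOCALIZER_REST
    return blocks
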