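"""Hindlimb joint-angle kinematics and step-cycle gait metrics.

From a calibrated sagittal-plane track of six hindlimb landmarks this module
computes per-frame interior joint angles (hip, knee, ankle), segments the
recording into stance and swing phases from the toe's horizontal velocity
(on a treadmill the belt carries the stance foot rearward, so stance frames
have negative toe x-velocity when the animal faces +x), time-normalizes each
phase to a fixed number of samples (100 by default), averages all cycles of
a recording into a 200-sample representative step cycle (stance then swing),
and derives the study's gait metrics: the average joint angle over the
representative cycle and the RMS difference between a cycle and a reference
cycle (by default the same animal's pre-induction baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pose_io import CalibratedTrack

__all__ = [
    "JointAngleSeries",
    "PhaseParams",
    "PhaseSegmentation",
    "RepresentativeCycle",
    "GaitMetrics",
    "joint_angle_series",
    "detect_phases",
    "normalize_phase",
    "representative_cycle",
    "average_angle",
    "rms_difference",
    "rms_within_recording",
    "gait_metrics",
]

JOINTS = ("hip", "knee", "ankle")

#: Landmark triplets (A, B, C) whose interior angle at B defines each joint.
_JOINT_TRIPLETS = {
    "hip": ("iliac_crest", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "ankle", "mtp"),
}

N_PHASE_DEFAULT = 100


@dataclass
class JointAngleSeries:
    """Per-frame joint angles (degrees) and landmark heights (cm)."""

    fps: float
    hip_deg: np.ndarray
    knee_deg: np.ndarray
    ankle_deg: np.ndarray
    toe_y_cm: np.ndarray
    ankle_y_cm: np.ndarray

    def angle(self, joint: str) -> np.ndarray:
        if joint not in JOINTS:
            raise ValueError(f"unknown joint {joint!r}; expected one of {JOINTS}")
        return getattr(self, f"{joint}_deg")

    @property
    def frames(self) -> int:
        return self.hip_deg.size


@dataclass
class PhaseParams:
    """Tunables of the toe-velocity phase detector.

    smooth_window
        Moving-average window (frames, odd) applied to toe x before
        differentiation; 9 frames = 36 ms at 250 fps.
    v_min
        Hysteresis dead band (cm/s): |v| below this inherits the previous
        phase label rather than switching.
    min_phase
        Minimum run length (frames); shorter runs are merged into their
        neighbours to suppress flicker at phase transitions.
    """

    smooth_window: int = 9
    v_min: float = 0.5
    min_phase: int = 10

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.v_min <= 0:
            raise ValueError("v_min must be positive")
        if self.min_phase < 1:
            raise ValueError("min_phase must be >= 1")


@dataclass
class PhaseSegmentation:
    """Complete step cycles as half-open frame intervals.

    Each cycle is (stance_start, stance_end, swing_start, swing_end) with
    stance_end == swing_start; partial cycles at the recording edges are
    discarded.
    """

    cycles: list[tuple[int, int, int, int]] = field(default_factory=list)
    mirrored: bool = False  # x was mirrored (animal faced -x)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def duty_factor(self) -> float:
        """Mean stance fraction of the cycle period."""
        if not self.cycles:
            raise ValueError("no complete step cycles")
        fracs = [
            (se - ss) / (we - ss) for ss, se, ws, we in self.cycles
        ]
        return float(np.mean(fracs))


@dataclass
class RepresentativeCycle:
    """Per-recording average step cycle: n_phase stance + n_phase swing samples."""

    n_phase: int
    hip_deg: np.ndarray
    knee_deg: np.ndarray
    ankle_deg: np.ndarray
    n_cycles_averaged: int

    def angle(self, joint: str) -> np.ndarray:
        if joint not in JOINTS:
            raise ValueError(f"unknown joint {joint!r}; expected one of {JOINTS}")
        return getattr(self, f"{joint}_deg")

    def __post_init__(self) -> None:
        for j in JOINTS:
            a = np.asarray(self.angle(j), dtype=float)
            if a.size != 2 * self.n_phase:
                raise ValueError(
                    f"{j} curve has {a.size} samples, expected {2 * self.n_phase}"
                )
            setattr(self, f"{j}_deg", a)


@dataclass
class GaitMetrics:
    """Headline per-recording gait metrics."""

    avg_hip_deg: float
    avg_knee_deg: float
    avg_ankle_deg: float
    knee_rms_deg: float | None
    ankle_rms_deg: float | None
    n_cycles: int


def _interior_angle_deg(
    ax, ay, bx, by, cx, cy
) -> tuple[np.ndarray, np.ndarray]:
    """Interior angle at B between BA and BC, degrees; NaN where degenerate."""
    v1x, v1y = ax - bx, ay - by
    v2x, v2y = cx - bx, cy - by
    n1 = np.hypot(v1x, v1y)
    n2 = np.hypot(v2x, v2y)
    bad = (n1 == 0) | (n2 == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (v1x * v2x + v1y * v2y) / (n1 * n2)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[bad] = np.nan
    return ang, bad


def joint_angle_series(track: CalibratedTrack) -> JointAngleSeries:
    """Per-frame hip, knee and ankle interior angles from a calibrated track.

    The angle at joint B is the arc-cosine of the normalized dot product of
    (A - B) and (C - B) for the proximal/distal neighbours A, C.  Frames
    with coincident adjacent landmarks give an undefined angle; these are
    linearly interpolated, and more than 10% of them is a fatal error.
    """
    angles = {}
    for joint, (a, b, c) in _JOINT_TRIPLETS.items():
        ang, bad = _interior_angle_deg(
            track.x_cm[a], track.y_cm[a],
            track.x_cm[b], track.y_cm[b],
            track.x_cm[c], track.y_cm[c],
        )
        if bad.mean() > 0.10:
            raise ValueError(
                f"{joint}: {bad.sum()}/{bad.size} frames with coincident landmarks"
            )
        if bad.any():
            idx = np.arange(ang.size, dtype=float)
            ang = np.interp(idx, idx[~bad], ang[~bad])
        angles[joint] = ang
    return JointAngleSeries(
        fps=track.fps,
        hip_deg=angles["hip"],
        knee_deg=angles["knee"],
        ankle_deg=angles["ankle"],
        toe_y_cm=track.y_cm["toe"].copy(),
        ankle_y_cm=track.y_cm["ankle"].copy(),
    )


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(label, start, end) runs, half-open, in order."""
    changes = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], changes])
    ends = np.concatenate([changes, [labels.size]])
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def detect_phases(
    track: CalibratedTrack,
    params: PhaseParams | None = None,
    *,
    auto_orient: bool = True,
) -> PhaseSegmentation:
    """Segment a recording into stance/swing step cycles from toe velocity.

    Toe x is moving-average smoothed and differentiated by central
    differences.  Frames with velocity below -v_min are stance (the belt
    carries the planted foot rearward), above +v_min swing; dead-band
    frames inherit the previous label.  Runs shorter than ``min_phase``
    are merged into their neighbours, and only stance->swing pairs flanked
    by valid phases on both sides are emitted as complete cycles.

    With ``auto_orient`` the animal's facing direction is inferred from the
    sign structure of the toe velocity (stance occupies the larger share of
    the cycle, so the majority-time velocity sign is the stance sign); x is
    mirrored if the animal faces -x.
    """
    params = params or PhaseParams()
    n = track.frames
    if n <= 2 * params.min_phase:
        raise ValueError(
            f"track of {n} frames too short for min_phase={params.min_phase}"
        )
    x = track.x_cm["toe"].astype(float)
    xs = _smooth(x, params.smooth_window)
    v = np.gradient(xs) * track.fps  # cm/s

    mirrored = False
    if auto_orient:
        t_neg = float(np.sum(v < -params.v_min))
        t_pos = float(np.sum(v > params.v_min))
        if t_pos > t_neg:  # stance should dominate; animal faces -x
            mirrored = True
            v = -v
            xs = -xs

    # -1 stance, +1 swing, 0 undecided (inherits previous label)
    lab = np.zeros(n, dtype=int)
    lab[v < -params.v_min] = -1
    lab[v > params.v_min] = 1
    defined = np.flatnonzero(lab != 0)
    if defined.size == 0:
        warnings.warn("toe velocity never leaves the dead band; no cycles", stacklevel=2)
        return PhaseSegmentation(cycles=[], mirrored=mirrored)
    # forward fill, then leading undecided frames take the first defined label
    for i in range(defined[0] + 1, n):
        if lab[i] == 0:
            lab[i] = lab[i - 1]
    lab[: defined[0]] = lab[defined[0]]

    runs = _runs(lab)
    # merge short runs into the previous (or next, for the first) run
    merged = True
    while merged and len(runs) > 1:
        merged = False
        for i, (lbl, s, e) in enumerate(runs):
            if e - s < params.min_phase:
                j = i - 1 if i > 0 else i + 1
                lbl2, s2, e2 = runs[j]
                if j < i:
                    runs[j] = (lbl2, s2, e)
                else:
                    runs[j] = (lbl2, s, e2)
                del runs[i]
                merged = True
                break
    # re-merge adjacent runs that now share a label
    cleaned: list[tuple[int, int, int]] = []
    for lbl, s, e in runs:
        if cleaned and cleaned[-1][0] == lbl:
            cleaned[-1] = (lbl, cleaned[-1][1], e)
        else:
            cleaned.append((lbl, s, e))

    # refine run boundaries to the toe-x extremum: the hysteresis detector
    # fires only once |v| exceeds v_min, a systematic lag of a few frames,
    # while touch-down is the foremost and lift-off the rearmost toe
    # position (v = 0 exactly there)
    half = max(params.min_phase // 2, 2)
    refined = [cleaned[0]]
    for i in range(1, len(cleaned)):
        lbl_prev = refined[-1][0]
        lbl, s, e = cleaned[i]
        lo, hi = max(s - half, refined[-1][1] + 1), min(s + half + 1, e)
        window = xs[lo:hi]
        if window.size:
            if lbl == -1:  # swing -> stance: toe at its foremost point
                s_new = lo + int(np.argmax(window))
            else:  # stance -> swing: toe at its rearmost point
                s_new = lo + int(np.argmin(window))
        else:
            s_new = s
        prev_lbl, prev_s, _ = refined[-1]
        refined[-1] = (prev_lbl, prev_s, s_new)
        refined.append((lbl, s_new, e))
    cleaned = refined

    cycles = []
    # stance at i (preceded by a phase), swing at i+1 (followed by a phase)
    for i in range(1, len(cleaned) - 2):
        lbl, s, e = cleaned[i]
        lbl2, s2, e2 = cleaned[i + 1]
        if lbl == -1 and lbl2 == 1:
            if e - s >= params.min_phase and e2 - s2 >= params.min_phase:
                cycles.append((s, e, s2, e2))
    if not cycles:
        warnings.warn("no complete step cycles detected", stacklevel=2)
    return PhaseSegmentation(cycles=cycles, mirrored=mirrored)


def normalize_phase(values: np.ndarray, n: int = N_PHASE_DEFAULT) -> np.ndarray:
    """Resample one phase's samples onto n uniform points, endpoints preserved.

    Linear interpolation from the first to the last input sample inclusive;
    an input of exactly n samples is returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("phase must contain at least 2 samples")
    if n < 2:
        raise ValueError("n must be >= 2")
    if values.size == n:
        return values.copy()
    src = np.linspace(0.0, 1.0, values.size)
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, values)


def representative_cycle(
    angles: JointAngleSeries,
    seg: PhaseSegmentation,
    n_phase: int = N_PHASE_DEFAULT,
) -> RepresentativeCycle:
    """Average all time-normalized cycles into one representative step cycle.

    Every stance segment is resampled to ``n_phase`` samples and the
    resampled stances averaged pointwise; likewise for swing.  The output
    concatenates mean stance then mean swing (2 x n_phase samples: 200 at
    the defaults).
    """
    if seg.n_cycles == 0:
        raise ValueError("no complete step cycles")
    out = {}
    for joint in JOINTS:
        series = angles.angle(joint)
        stances = [
            normalize_phase(series[ss:se], n_phase) for ss, se, _, _ in seg.cycles
        ]
        swings = [
            normalize_phase(series[ws:we], n_phase) for _, _, ws, we in seg.cycles
        ]
        out[joint] = np.concatenate(
            [np.mean(stances, axis=0), np.mean(swings, axis=0)]
        )
    return RepresentativeCycle(
        n_phase=n_phase,
        hip_deg=out["hip"],
        knee_deg=out["knee"],
        ankle_deg=out["ankle"],
        n_cycles_averaged=seg.n_cycles,
    )


def average_angle(cycle: RepresentativeCycle, joint: str) -> float:
    """Arithmetic mean of the representative cycle's samples for one joint."""
    return float(np.mean(cycle.angle(joint)))


def rms_difference(
    cycle: RepresentativeCycle, reference: RepresentativeCycle, joint: str
) -> float:
    """RMS difference (degrees) between two representative cycles of a joint.

    sqrt(mean((theta_t - theta_ref,t)^2)) over the 2 x n_phase samples: a
    scaled Euclidean metric on cycle curves (symmetric, triangle
    inequality).  Both cycles must share n_phase.
    """
    if cycle.n_phase != reference.n_phase:
        raise ValueError(
            f"cycle lengths differ: {cycle.n_phase} vs {reference.n_phase}"
        )
    d = cycle.angle(joint) - reference.angle(joint)
    return float(np.sqrt(np.mean(d**2)))


def rms_within_recording(
    angles: JointAngleSeries,
    seg: PhaseSegmentation,
    joint: str,
    n_phase: int = N_PHASE_DEFAULT,
) -> float:
    """Within-recording variability: mean RMS of each cycle vs the mean cycle.

    Alternative RMS mode for recordings without a baseline reference: each
    cycle is normalized, the recording's mean cycle computed, and the RMS
    deviations of the individual cycles from that mean averaged.
    """
    if seg.n_cycles == 0:
        raise ValueError("no complete step cycles")
    series = angles.angle(joint)
    curves = [
        np.concatenate(
            [
                normalize_phase(series[ss:se], n_phase),
                normalize_phase(series[ws:we], n_phase),
            ]
        )
        for ss, se, ws, we in seg.cycles
    ]
    curves = np.asarray(curves)
    mean_curve = curves.mean(axis=0)
    return float(np.mean(np.sqrt(np.mean((curves - mean_curve) ** 2, axis=1))))


def gait_metrics(
    cycle: RepresentativeCycle,
    reference: RepresentativeCycle | None = None,
) -> GaitMetrics:
    """Headline metrics: average hip/knee/ankle angle and knee/ankle RMS.

    RMS values are computed against ``reference`` (typically the animal's
    baseline representative cycle) and are None when no reference exists.
    """
    knee_rms = ankle_rms = None
    if reference is not None:
        knee_rms = rms_difference(cycle, reference, "knee")
        ankle_rms = rms_difference(cycle, reference, "ankle")
    return GaitMetrics(
        avg_hip_deg=average_angle(cycle, "hip"),
        avg_knee_deg=average_angle(cycle, "knee"),
        avg_ankle_deg=average_angle(cycle, "ankle"),
        knee_rms_deg=knee_rms,
        ankle_rms_deg=ankle_rms,
        n_cycles=cycle.n_cycles_averaged,
    )
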