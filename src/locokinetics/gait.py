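"""Hindlimb gait cycles from side-view corridor tracks.

Joint angles (hip, knee, ankle, MTP) are the interior angles of the labeled
chain iliac crest - hip - knee - ankle - MTP - toe tip, frame by frame.
Stance and swing are segmented from the moving-averaged MTP speed: a
lift-off is the first frame of a run of at least 14 consecutive frames above
15 cm/s, and the following touchdown is the first frame back at or below
threshold.  Angular excursions are normalized to the step cycle (touchdown
to touchdown) on a fixed 101-point grid, the standard resolution in gait
analysis, and compared between spontaneous and evoked locomotion by
per-animal amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .track_io import PoseTrack, _bool_runs, bridged_xy
from .openfield import moving_average, paired_comparison_gate

__all__ = [
    "DEFAULT_CHAIN", "JointAngleTrace", "StepEvents", "StepCycleSet",
    "GaitParams", "ExcursionSummary", "joint_angles", "detect_step_events",
    "normalize_cycles", "excursion_comparison",
]

#: anatomical chain, proximal to distal
DEFAULT_CHAIN = ("iliac_crest", "hip", "knee", "ankle", "mtp", "toe_tip")

#: joints with both a proximal and a distal neighbor in the default chain
DEFAULT_JOINTS = ("hip", "knee", "ankle", "mtp")

CYCLE_POINTS = 101


@dataclass
class GaitParams:
    """Stance/swing segmentation parameters.

    ``stance_speed_threshold`` (15 cm/s) separates a paw at rest from a paw
    in swing; a lift-off requires ``liftoff_min_frames`` (14) consecutive
    supra-threshold frames so brief tracking twitches do not fragment the
    stance.  MTP speed is smoothed over ``mtp_smooth_frames`` first.
    """
    stance_speed_threshold: float = 15.0
    liftoff_min_frames: int = 14
    mtp_smooth_frames: int = 5
    fps: float = 300.0

    def __post_init__(self):
        for name in ("stance_speed_threshold", "liftoff_min_frames",
                     "mtp_smooth_frames", "fps"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class JointAngleTrace:
    """Per-frame interior joint angles (deg) for the hindlimb chain."""
    angles: dict                 # joint -> (n_frames,) array, NaN where invalid
    chain: tuple
    fps: float

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.angles.values())))


@dataclass
class StepEvents:
    liftoffs: np.ndarray         # frame indices
    touchdowns: np.ndarray
    params: GaitParams
    mtp_speed: np.ndarray        # smoothed trace the events were read from


@dataclass
class StepCycleSet:
    """Step cycles (touchdown to touchdown) resampled to a fixed grid."""
    touchdowns: np.ndarray
    pct_grid: np.ndarray                       # 0..100, CYCLE_POINTS samples
    profiles: dict                             # joint -> (n_cycles, 101)
    cycle_durations_s: np.ndarray
    n_dropped: int
    mean: dict = field(default_factory=dict)   # joint -> (101,)
    sd: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_durations_s)


@dataclass
class ExcursionSummary:
    """Per-joint angular amplitudes (max - min of the cycle-mean profile)
    compared between conditions across animals."""
    joints: tuple
    amplitudes_spont: dict       # joint -> per-animal array
    amplitudes_evoked: dict
    percent_change: dict         # joint -> 100 * (evoked - spont) / spont
    tests: dict                  # joint -> GateResult


# ---------------------------------------------------------------------------

def joint_angles(track: PoseTrack, chain: tuple = DEFAULT_CHAIN) -> JointAngleTrace:
    """Interior angle at each joint with two neighbors in the chain.

    The angle at joint J is formed by the segments to its proximal and
    distal neighbors (hip: iliac crest-hip-knee; MTP: ankle-MTP-toe tip),
    in degrees in (0, 180].  Invariant under rigid motion and uniform
    scaling.  Frames with coincident neighbors are flagged NaN.
    """
    pts = {name: bridged_xy(track, name) for name in chain}
    angles = {}
    for prox, joint, dist in zip(chain[:-2], chain[1:-1], chain[2:]):
        u = pts[prox] - pts[joint]
        v = pts[dist] - pts[joint]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (u * v).sum(axis=1) / (nu * nv)
        bad = (nu == 0) | (nv == 0)
        cosang[bad] = np.nan
        angles[joint] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return JointAngleTrace(angles=angles, chain=chain, fps=track.fps)


def detect_step_events(track: PoseTrack, params: GaitParams | None = None,
                       landmark: str = "mtp") -> StepEvents:
    """Touchdown and lift-off times from the moving-averaged MTP speed.

    Lift-off: first frame of a run of at least ``liftoff_min_frames``
    consecutive frames with speed above ``stance_speed_threshold``.
    Touchdown: the first frame after a lift-off where speed is back at or
    below threshold (no minimum run; the run rule applies to lift-off only).
    Events alternate; no qualifying run means empty lists.
    """
    if params is None:
        params = GaitParams(fps=track.fps)
    if track.units != "cm":
        raise ValueError("detect_step_events needs cm units; calibrate first")
    p = bridged_xy(track, landmark)
    raw = np.concatenate([np.linalg.norm(np.diff(p, axis=0), axis=1)
                          * params.fps, [np.nan]])
    speed = moving_average(raw, params.mtp_smooth_frames)
    above = np.nan_to_num(speed, nan=-1.0) > params.stance_speed_threshold

    liftoffs, touchdowns = [], []
    for s, e in _bool_runs(above):
        if e - s + 1 < params.liftoff_min_frames:
            continue
        liftoffs.append(s)
        if e + 1 < len(above):
            touchdowns.append(e + 1)
    return StepEvents(liftoffs=np.array(liftoffs, dtype=int),
                      touchdowns=np.array(touchdowns, dtype=int),
                      params=params, mtp_speed=speed)


def normalize_cycles(angles: JointAngleTrace, touchdowns: np.ndarray,
                     fps: float | None = None) -> StepCycleSet:
    """Resample joint-angle excursions onto the normalized step cycle.

    A cycle spans consecutive MTP touchdowns; each is linearly interpolated
    onto ``CYCLE_POINTS`` samples from 0 % (touchdown) to 100 % (next
    touchdown).  Cycles containing an unmasked gap in any joint trace are
    dropped and counted.  Returns per-cycle profiles plus the across-cycle
    mean and SD per joint.
    """
    touchdowns = np.asarray(touchdowns, dtype=int)
    if len(touchdowns) < 2:
        raise ValueError("need at least 2 touchdowns to form a cycle")
    if np.any(np.diff(touchdowns) <= 0):
        raise ValueError("touchdowns must be strictly increasing")
    fps = fps or angles.fps
    pct = np.linspace(0.0, 100.0, CYCLE_POINTS)
    profiles = {j: [] for j in angles.angles}
    durations, dropped = [], 0
    for t0, t1 in zip(touchdowns[:-1], touchdowns[1:]):
        segs = {j: a[t0:t1 + 1] for j, a in angles.angles.items()}
        if any(np.isnan(seg).any() for seg in segs.values()):
            dropped += 1
            continue
        src = np.linspace(0.0, 100.0, t1 - t0 + 1)
        for j, seg in segs.items():
            profiles[j].append(np.interp(pct, src, seg))
        durations.append((t1 - t0) / fps)
    if not durations:
        raise ValueError("no complete step cycles (all dropped or masked)")
    profiles = {j: np.vstack(v) for j, v in profiles.items()}
    mean = {j: v.mean(axis=0) for j, v in profiles.items()}
    sd = {j: v.std(axis=0, ddof=0) for j, v in profiles.items()}
    return StepCycleSet(touchdowns=touchdowns, pct_grid=pct,
                        profiles=profiles,
                        cycle_durations_s=np.array(durations),
                        n_dropped=dropped, mean=mean, sd=sd)


def excursion_comparison(profiles_spont: dict, profiles_evoked: dict) -> ExcursionSummary:
    """Compare per-joint angular amplitudes between conditions.

    Inputs map animal id -> {joint -> cycle-mean profile}.  The amplitude is
    max - min of the animal's mean profile; conditions are compared per
    joint with the parametric/non-parametric gate on paired per-animal
    values, and the percent change is 100 * (evoked - spont) / spont of the
    across-animal mean amplitudes.
    """
    animals = sorted(profiles_spont)
    if set(profiles_evoked) != set(animals):
        raise ValueError("animal sets differ between conditions")
    if len(animals) < 2:
        raise ValueError("need at least 2 animals for a comparison")
    joints = tuple(sorted(next(iter(profiles_spont.values()))))
    amp_s = {j: np.array([np.ptp(profiles_spont[a][j]) for a in animals])
             for j in joints}
    amp_e = {j: np.array([np.ptp(profiles_evoked[a][j]) for a in animals])
             for j in joints}
    pct = {j: 100.0 * (amp_e[j].mean() - amp_s[j].mean()) / amp_s[j].mean()
           for j in joints}
    tests = {}
    for j in joints:
        if len(animals) >= 3:
            tests[j] = paired_comparison_gate(amp_e[j], amp_s[j], paired=True)
        else:
            tests[j] = None
    return ExcursionSummary(joints=joints, amplitudes_spont=amp_s,
                            amplitudes_evoked=amp_e, percent_change=pct,
                            tests=tests)
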