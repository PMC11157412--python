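"""Limb-pair phase, motor-arrest detection, and step-cycle continuity.

From ventral-view paw tracks, each limb pair (forelimbs, hindlimbs) gets a
phase value from the signed distance between its left and right paws along
the corridor length axis: +180 deg at maximum positive alternation, 0 deg
when the paws are level, -180 deg at maximum negative alternation.  The
phase is smoothed with a 10-frame moving average and its frame-to-frame
variation drives the arrest/resume rule: an arrest is the first frame after
light onset beginning a run of twenty contiguous frames with variation below
0.1 deg/frame, and a resume is the first frame after light offset beginning
a run of twenty contiguous frames with variation above that threshold.
The phase difference (resume minus arrest) reports whether limbs restart
from the configuration in which they froze, and step-cycle continuity asks
whether the phase slope after resume continues the slope at arrest
(ascending resumes ascending; a phase frozen at a peak or trough resumes
with the opposite slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .track_io import PoseTrack, StimEpoch, bridged_xy
from .openfield import moving_average

__all__ = [
    "PAIR_PAWS", "LimbPairPhase", "ArrestParams", "ArrestEvent",
    "PawSpeedMap", "limb_pair_phase", "detect_arrest_resume",
    "phase_difference", "classify_continuity", "paw_speeds",
    "corridor_axis_from_markers",
]

PAIR_PAWS = {"forelimbs": ("paw_fl", "paw_fr"),
             "hindlimbs": ("paw_hl", "paw_hr")}


@dataclass
class ArrestParams:
    """Arrest/resume detection parameters.

    ``variation_threshold`` (0.1 deg/frame) separates a moving from a frozen
    phase trace; a state change needs ``run_frames`` (20) contiguous
    qualifying frames; the phase is smoothed over ``smooth_frames`` (10)
    first; continuity extrema need ``prominence`` (60 deg).
    ``run_anchor`` selects whether the reported event frame is the first
    ("start") or the last ("end") frame of the qualifying run.
    """
    variation_threshold: float = 0.1
    run_frames: int = 20
    smooth_frames: int = 10
    prominence: float = 60.0
    run_anchor: str = "start"
    extremum_tolerance: float = 0.05  # fraction of phase amplitude

    def __post_init__(self):
        for name in ("variation_threshold", "run_frames", "smooth_frames",
                     "prominence"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.run_anchor not in ("start", "end"):
            raise ValueError("run_anchor must be 'start' or 'end'")


@dataclass
class LimbPairPhase:
    """Alternation phase of one limb pair.

    ``d`` is the left-minus-right paw distance along the corridor axis (cm);
    ``phase`` maps it linearly onto [-180, +180] using the normalization
    constant ``d_max`` (95th percentile of |d| over the reference window,
    recorded here because the mapping has no canonical constant);
    ``smoothed`` is the moving-averaged phase and ``variation`` its
    frame-to-frame absolute change (deg/frame).
    """
    pair: str
    d: np.ndarray
    d_max: float
    phase: np.ndarray
    smoothed: np.ndarray
    variation: np.ndarray     # variation[i] = |smoothed[i] - smoothed[i-1]|
    fps: float
    params: ArrestParams


@dataclass
class ArrestEvent:
    """Per-trial arrest/resume summary around one stimulation train."""
    pair: str
    trial: int | None = None
    arrest_frame: int | None = None
    resume_frame: int | None = None
    latency_to_arrest_s: float | None = None
    latency_to_resume_s: float | None = None
    phase_at_arrest: float | None = None
    phase_at_resume: float | None = None
    phase_difference: float | None = None
    continuity: str = "not_detected"       # "true" | "false" | "not_detected"


@dataclass
class PawSpeedMap:
    """Per-paw smoothed speed traces, plus onset-aligned windows."""
    speeds: dict                  # paw -> (n_frames,) cm/s
    fps: float
    windows: list = field(default_factory=list)  # (epoch, paw -> window)


# ---------------------------------------------------------------------------

def corridor_axis_from_markers(track: PoseTrack, marker_prefix: str = "cal_marker") -> np.ndarray:
    """Unit vector of the corridor length axis: the principal axis of the
    calibration-marker line."""
    pts = np.array([np.nanmedian(track.xy[:, j, :], axis=0)
                    for j, bp in enumerate(track.landmarks)
                    if bp.startswith(marker_prefix)])
    if len(pts) < 2:
        raise ValueError("need at least 2 calibration markers for the axis")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[0] < 0:  # orient along +x for a reproducible sign
        axis = -axis
    return axis


def limb_pair_phase(track: PoseTrack, pair: str,
                    corridor_axis: np.ndarray | None = None,
                    params: ArrestParams | None = None,
                    reference_frames: slice | None = None) -> LimbPairPhase:
    """Phase trace of a limb pair from along-corridor paw alternation.

    ``d_t`` is the left-paw minus right-paw position projected on the
    corridor axis; ``d_max`` is the 95th percentile of |d| over
    ``reference_frames`` (intended: pre-stimulus locomotion; default the
    whole trial); ``phase = 180 * clip(d / d_max, -1, 1)``.  The phase is
    odd in d: swapping the paws flips its sign everywhere.
    """
    if params is None:
        params = ArrestParams()
    lpaw, rpaw = PAIR_PAWS[pair]
    if corridor_axis is None:
        corridor_axis = corridor_axis_from_markers(track)
    axis = np.asarray(corridor_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    d = (bridged_xy(track, lpaw) - bridged_xy(track, rpaw)) @ axis
    ref = d[reference_frames] if reference_frames is not None else d
    d_max = float(np.nanpercentile(np.abs(ref), 95))
    if not d_max > 0:
        raise ValueError("no alternation signal: paws never separate along "
                         "the corridor axis")
    phase = 180.0 * np.clip(d / d_max, -1.0, 1.0)
    smoothed = moving_average(phase, params.smooth_frames)
    variation = np.concatenate([[np.nan], np.abs(np.diff(smoothed))])
    return LimbPairPhase(pair=pair, d=d, d_max=d_max, phase=phase,
                         smoothed=smoothed, variation=variation,
                         fps=track.fps, params=params)


def _first_qualifying_run(cond: np.ndarray, start: int, run_frames: int,
                          anchor: str) -> int | None:
    """Index anchoring the first run of >= run_frames True values at or
    after ``start``; None when absent."""
    n = len(cond)
    i = start
    while i < n:
        if not cond[i]:
            i += 1
            continue
        j = i
        while j < n and cond[j]:
            j += 1
        if j - i >= run_frames:
            return i if anchor == "start" else i + run_frames - 1
        i = j
    return None


def detect_arrest_resume(phase: LimbPairPhase, epoch: StimEpoch,
                         params: ArrestParams | None = None,
                         trial: int | None = None) -> ArrestEvent:
    """Latency to arrest and to resume around one stimulation train.

    Arrest: first frame after light onset beginning a run of
    ``run_frames`` contiguous frames with phase variation strictly below
    ``variation_threshold`` (latency from onset).  Resume: first frame after
    light offset beginning a run with variation strictly above threshold
    (latency from offset).  Missing qualifying runs leave the event
    not-detected.  Depends only on the variation trace, so it is invariant
    to adding a constant to the phase.
    """
    params = params or phase.params
    n = len(phase.variation)
    onset_f = int(round(epoch.onset_s * phase.fps))
    offset_f = int(round(epoch.offset_s * phase.fps))
    if onset_f < 0 or offset_f > n:
        raise ValueError("stimulation epoch falls outside the recording")
    var = np.nan_to_num(phase.variation, nan=np.inf)
    ev = ArrestEvent(pair=phase.pair, trial=trial)
    below = var < params.variation_threshold
    a = _first_qualifying_run(below, onset_f, params.run_frames,
                              params.run_anchor)
    if a is not None:
        ev.arrest_frame = a
        ev.latency_to_arrest_s = (a - onset_f) / phase.fps
    above = var > params.variation_threshold
    r = _first_qualifying_run(above, offset_f, params.run_frames,
                              params.run_anchor)
    if r is not None:
        ev.resume_frame = r
        ev.latency_to_resume_s = (r - offset_f) / phase.fps
    return ev


def phase_difference(event: ArrestEvent, phase: LimbPairPhase) -> ArrestEvent:
    """Fill in the phase at arrest/resume and their difference.

    The difference (resume minus arrest, no wrapping: the phase is bounded
    in [-180, 180]) is near zero when the limbs restart from the
    configuration in which they froze.  Undetected events leave the fields
    empty.
    """
    if event.arrest_frame is not None:
        event.phase_at_arrest = float(phase.smoothed[event.arrest_frame])
    if event.resume_frame is not None:
        event.phase_at_resume = float(phase.smoothed[event.resume_frame])
    if event.phase_at_arrest is not None and event.phase_at_resume is not None:
        event.phase_difference = event.phase_at_resume - event.phase_at_arrest
    return event


def _phase_extrema(smoothed: np.ndarray, prominence: float) -> np.ndarray:
    x = np.nan_to_num(smoothed, nan=0.0)
    peaks, _ = find_peaks(x, prominence=prominence)
    troughs, _ = find_peaks(-x, prominence=prominence)
    return np.sort(np.concatenate([peaks, troughs]))


def classify_continuity(phase: LimbPairPhase, event: ArrestEvent,
                        params: ArrestParams | None = None) -> str:
    """Step-cycle continuity across a motor arrest.

    Phase peaks and troughs with prominence >= 60 deg anchor the slope
    signs: the pre-arrest slope runs from the last extremum before the
    arrest frame to the arrest frame, and the post-resume slope from the
    resume frame to the first extremum after it.  Continuity is "true" when
    an ascending (descending) arrest resumes ascending (descending); when
    the phase froze at an extremum (arrest value within
    ``extremum_tolerance`` of the phase amplitude from an extremum level of
    the surrounding cycles) the slope must switch sign instead.
    "not_detected" when the resume is undetected or no qualifying extremum
    exists on either side.
    """
    params = params or phase.params
    if event.arrest_frame is None or event.resume_frame is None:
        event.continuity = "not_detected"
        return event.continuity
    ext = _phase_extrema(phase.smoothed, params.prominence)
    pre = ext[ext < event.arrest_frame]
    post = ext[ext > event.resume_frame]
    if pre.size == 0 or post.size == 0:
        event.continuity = "not_detected"
        return event.continuity
    last_pre, first_post = pre[-1], post[0]
    x = phase.smoothed
    slope_pre = np.sign(x[event.arrest_frame] - x[last_pre])
    slope_post = np.sign(x[first_post] - x[event.resume_frame])

    amp = np.nanmax(x) - np.nanmin(x)
    # compare the frozen value against cycle-extremum levels outside the
    # arrest window (the frozen plateau itself can register as an extremum)
    cycle_ext = np.concatenate([pre, post])
    at_extremum = np.min(np.abs(x[event.arrest_frame] - x[cycle_ext])) \
        <= params.extremum_tolerance * amp
    if at_extremum:
        ok = slope_post == -slope_pre and slope_post != 0
    else:
        ok = slope_post == slope_pre and slope_post != 0
    event.continuity = "true" if ok else "false"
    return event.continuity


def paw_speeds(track: PoseTrack, epochs: list | None = None,
               smooth_frames: int = 5) -> PawSpeedMap:
    """Per-paw displacement speeds, 5-frame moving average, optionally cut
    into onset-aligned windows around each stimulation train."""
    speeds = {}
    for paw in [bp for bp in track.landmarks if bp.startswith("paw_")]:
        p = bridged_xy(track, paw)
        raw = np.concatenate([np.linalg.norm(np.diff(p, axis=0), axis=1)
                              * track.fps, [np.nan]])
        speeds[paw] = moving_average(raw, smooth_frames)
    windows = []
    for ep in (epochs or []):
        a = int(round(ep.onset_s * track.fps))
        b = int(round(ep.offset_s * track.fps))
        windows.append((ep, {paw: s[a:b] for paw, s in speeds.items()}))
    return PawSpeedMap(speeds=speeds, fps=track.fps, windows=windows)
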