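"""Open-field kinematics: speed, locomotor bouts, turning.

Works on above-view tracks of the body center, tail base and ears.  Speed is
the frame-to-frame body-center displacement over elapsed time, smoothed by a
centered moving average.  Locomotion/immobility is segmented with a
hysteresis rule.  Turning is quantified three ways: the signed angle between
consecutive body-orientation vectors (angular velocity, clockwise-from-above
positive, i.e. toward the animal's right), the arena-frame body orientation
angle alpha of the tail-base -> ear-midpoint vector, and the head rotation
angle beta between the body axis and the perpendicular to the inter-ear
line; alpha and beta are baseline-normalized to the 500 ms preceding
stimulation onset so trials can be pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .track_io import PoseTrack, StimEpoch, bridged_xy

__all__ = [
    "SpeedTrace", "LocomotionBouts", "OrientationTrace", "PeristimSummary",
    "GateResult", "compute_speed", "segment_locomotion", "angular_velocity",
    "body_orientation_angle", "head_rotation_angle", "peristimulus_average",
    "trajectory_vectors", "paired_comparison_gate", "moving_average",
]


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average that ignores NaNs inside the window.

    A frame whose whole window is NaN stays NaN.  ``window <= 1`` is the
    identity.
    """
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    half_l = (window - 1) // 2
    half_r = window // 2
    out = np.full_like(x, np.nan)
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(int))])
    n = len(x)
    for i in range(n):
        a, b = max(0, i - half_l), min(n, i + half_r + 1)
        cnt = ccnt[b] - ccnt[a]
        if cnt:
            out[i] = (csum[b] - csum[a]) / cnt
    return out


@dataclass
class SpeedTrace:
    """Body-center speed (cm/s).  ``speed[i]`` is the displacement from
    frame i to i+1 over the elapsed time, after smoothing; ``raw`` is the
    unsmoothed trace.  NaN marks gaps."""
    speed: np.ndarray
    raw: np.ndarray
    fps: float
    smooth_frames: int
    times: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.speed)


@dataclass
class LocomotionBouts:
    """Hysteresis segmentation of a speed trace into locomotion/immobility."""
    bouts: list                      # (start_s, end_s, state)
    n_initiations: int
    time_locomoting_s: float
    time_immobile_s: float
    speed_on: float
    speed_off: float
    min_duration_s: float


@dataclass
class OrientationTrace:
    """Angular kinematics of the body axis.

    ``theta`` is the per-step signed angle between consecutive orientation
    vectors (deg, clockwise-from-above positive); ``omega`` = theta * fps
    (deg/s).  ``alpha``/``beta`` are the baseline-normalized body-orientation
    and head-rotation angles when computed.
    """
    times: np.ndarray
    fps: float
    theta: np.ndarray | None = None
    omega: np.ndarray | None = None
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    baseline_s: float | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class PeristimSummary:
    """Onset-aligned across-trial mean +/- SEM of a per-frame trace."""
    grid_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray | None
    n_trials: int
    n_dropped: int = 0


@dataclass
class GateResult:
    test: str
    statistic: float
    p_value: float
    normal: bool
    equal_variance: bool | None = None


# ---------------------------------------------------------------------------

def compute_speed(track: PoseTrack, smooth_frames: int = 5,
                  landmark: str = "body_center",
                  timestamps: np.ndarray | None = None) -> SpeedTrace:
    """Locomotor speed from landmark positions and frame times.

    ``speed_i = |p_{i+1} - p_i| / dt_i`` followed by a centered moving
    average over ``smooth_frames``.  Masked frames propagate as gaps (short
    gaps are bridged, see :func:`locokinetics.track_io.bridged_xy`).
    """
    if track.units != "cm":
        raise ValueError("compute_speed needs cm units; calibrate first")
    p = bridged_xy(track, landmark)
    if np.isfinite(p).all(axis=1).sum() < 2:
        raise ValueError("need at least 2 valid frames to compute speed")
    t = np.asarray(timestamps, dtype=float) if timestamps is not None \
        else track.times
    step = np.linalg.norm(np.diff(p, axis=0), axis=1)
    dt = np.diff(t)
    raw = np.concatenate([step / dt, [np.nan]])
    return SpeedTrace(speed=moving_average(raw, smooth_frames), raw=raw,
                      fps=track.fps, smooth_frames=smooth_frames, times=t)


def _runs_at_least(cond: np.ndarray, min_len: int) -> np.ndarray:
    """Start indices of maximal True runs of length >= min_len."""
    from .track_io import _bool_runs
    return np.array([s for s, e in _bool_runs(cond) if e - s + 1 >= min_len],
                    dtype=int)


def segment_locomotion(speed: SpeedTrace, speed_on: float = 3.0,
                       speed_off: float = 1.0,
                       min_duration_s: float = 0.5) -> LocomotionBouts:
    """Segment locomotion bouts with a hysteresis rule.

    Locomotion starts where speed stays >= ``speed_on`` for at least
    ``min_duration_s`` and ends where it stays < ``speed_off`` for at least
    ``min_duration_s``.  These thresholds are conventions of this package
    (exposed in the result), not measured constants.
    """
    if speed_off > speed_on:
        raise ValueError("speed_off must not exceed speed_on")
    v = speed.speed
    n = len(v)
    min_frames = max(1, int(round(min_duration_s * speed.fps)))
    hi_starts = _runs_at_least(np.nan_to_num(v, nan=-1.0) >= speed_on, min_frames)
    lo_starts = _runs_at_least(np.nan_to_num(v, nan=-1.0) < speed_off, min_frames)

    bouts = []
    state = "immobile"
    seg_start = 0
    i = 0
    hi = list(hi_starts)
    lo = list(lo_starts)
    while True:
        if state == "immobile":
            nxt = next((s for s in hi if s >= i), None)
        else:
            nxt = next((s for s in lo if s >= i), None)
        if nxt is None:
            break
        bouts.append((seg_start / speed.fps, nxt / speed.fps, state))
        state = "locomotion" if state == "immobile" else "immobile"
        seg_start = nxt
        i = nxt + 1
    bouts.append((seg_start / speed.fps, n / speed.fps, state))
    bouts = [b for b in bouts if b[1] > b[0]]

    t_loco = sum(e - s for s, e, st in bouts if st == "locomotion")
    t_immo = sum(e - s for s, e, st in bouts if st == "immobile")
    n_init = sum(1 for _, _, st in bouts if st == "locomotion")
    if bouts and bouts[0][2] == "locomotion":
        # a recording that begins mid-locomotion is not an initiation
        n_init -= 1
    return LocomotionBouts(bouts=bouts, n_initiations=n_init,
                           time_locomoting_s=t_loco, time_immobile_s=t_immo,
                           speed_on=speed_on, speed_off=speed_off,
                           min_duration_s=min_duration_s)


# ---------------------------------------------------------------------------
# Angular kinematics
# ---------------------------------------------------------------------------

def _signed_angle_deg(v1: np.ndarray, v2: np.ndarray, y_down: bool) -> np.ndarray:
    """Signed angle from v1 to v2 (deg), positive for clockwise-from-above.

    In image coordinates (y down) a clockwise rotation of the scene has a
    positive planar cross product; with y up the sign flips.
    """
    cross = v1[..., 0] * v2[..., 1] - v1[..., 1] * v2[..., 0]
    dot = (v1 * v2).sum(axis=-1)
    ang = np.degrees(np.arctan2(cross, dot))
    return ang if y_down else -ang


def angular_velocity(track: PoseTrack, fps: float | None = None,
                     tail: str = "tail_base",
                     center: str = "body_center") -> OrientationTrace:
    """Angular velocity from successive body-orientation vectors.

    The orientation vector runs from the tail base to the body center.  The
    circle tangent to two consecutive orientation vectors at the body-center
    positions subtends, at its center, exactly the angle between the two
    vectors, so the per-step signed vector angle times fps is the angular
    velocity.  Positive = turning toward the animal's right (clockwise seen
    from above).  Frames with a zero-length orientation vector are skipped.
    """
    fps = fps or track.fps
    v = bridged_xy(track, center) - bridged_xy(track, tail)
    norm = np.linalg.norm(v, axis=1)
    v = v.copy()
    v[norm == 0] = np.nan
    theta = _signed_angle_deg(v[:-1], v[1:], track.y_down)
    theta = np.concatenate([theta, [np.nan]])
    omega = theta * fps
    return OrientationTrace(times=track.times, fps=fps, theta=theta,
                            omega=omega)


def _body_axis_angle(track: PoseTrack) -> np.ndarray:
    """Arena-frame angle of the tail-base -> ear-midpoint vector,
    clockwise-from-above positive, unwrapped over time (deg)."""
    em = (bridged_xy(track, "ear_left") + bridged_xy(track, "ear_right")) / 2.0
    v = em - bridged_xy(track, "tail_base")
    raw = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    if not track.y_down:
        raw = -raw
    return _nan_unwrap(raw)


def _nan_unwrap(deg: np.ndarray) -> np.ndarray:
    out = deg.copy()
    ok = np.isfinite(deg)
    if ok.sum() >= 2:
        out[ok] = np.degrees(np.unwrap(np.radians(deg[ok])))
    return out


def _baseline_normalize(angle: np.ndarray, track: PoseTrack,
                        epoch: StimEpoch, baseline_s: float) -> np.ndarray:
    onset_f = int(round(epoch.onset_s * track.fps))
    base_f = int(round(baseline_s * track.fps))
    if onset_f - base_f < 0:
        raise ValueError(
            f"epoch onset at {epoch.onset_s} s leaves less than "
            f"{baseline_s} s of pre-stimulus baseline")
    base = angle[onset_f - base_f:onset_f]
    if not np.isfinite(base).any():
        raise ValueError("no valid frames in the baseline window")
    return angle - np.nanmean(base)


def body_orientation_angle(track: PoseTrack, epoch: StimEpoch,
                           baseline_s: float = 0.5) -> OrientationTrace:
    """Body orientation angle alpha, baseline-normalized.

    Alpha is the arena-frame angle of the vector from the tail base (T) to
    the midpoint (EM) of the inter-ear line, unwrapped so multi-revolution
    turns accumulate past +/-180 deg, minus its mean over the ``baseline_s``
    window preceding stimulation onset.  Clockwise (toward the stimulated
    side) positive.
    """
    alpha = _baseline_normalize(_body_axis_angle(track), track, epoch,
                                baseline_s)
    return OrientationTrace(times=track.times, fps=track.fps, alpha=alpha,
                            baseline_s=baseline_s)


def head_rotation_angle(track: PoseTrack, epoch: StimEpoch,
                        baseline_s: float = 0.5) -> OrientationTrace:
    """Head rotation angle beta, baseline-normalized.

    Beta is the signed angle between the body axis vector (T -> EM) and the
    perpendicular to the inter-ear vector, the perpendicular chosen to point
    rostrally (within 90 deg of the body axis).  Clockwise positive; frames
    where the ears coincide are flagged NaN.
    """
    el = bridged_xy(track, "ear_left")
    er = bridged_xy(track, "ear_right")
    em = (el + er) / 2.0
    body = em - bridged_xy(track, "tail_base")
    ear = er - el
    ear[np.linalg.norm(ear, axis=1) == 0] = np.nan
    # two perpendiculars of the ear vector; keep the rostral one
    perp = np.stack([-ear[:, 1], ear[:, 0]], axis=-1)
    flip = (perp * body).sum(axis=1) < 0
    perp[flip] *= -1.0
    beta = _signed_angle_deg(body, perp, track.y_down)
    beta = _baseline_normalize(beta, track, epoch, baseline_s)
    return OrientationTrace(times=track.times, fps=track.fps, beta=beta,
                            baseline_s=baseline_s)


# ---------------------------------------------------------------------------

def peristimulus_average(values: np.ndarray, fps: float, epochs: list,
                         pre_s: float, post_s: float,
                         max_nan_fraction: float = 0.5) -> PeristimSummary:
    """Average a per-frame trace across trials, aligned at stimulation onset.

    Each epoch contributes the window [onset - pre_s, onset + post_s) on the
    common grid; trials with more than ``max_nan_fraction`` missing frames
    in-window are dropped and counted.  SEM = SD / sqrt(n) on >= 2 trials.
    """
    values = np.asarray(values, dtype=float)
    if not epochs:
        raise ValueError("need at least one stimulation epoch")
    pre_f, post_f = int(round(pre_s * fps)), int(round(post_s * fps))
    grid = (np.arange(-pre_f, post_f)) / fps
    rows, dropped = [], 0
    for ep in epochs:
        onset_f = int(round(ep.onset_s * fps))
        a, b = onset_f - pre_f, onset_f + post_f
        if a < 0 or b > len(values):
            raise ValueError(f"peristimulus window for epoch at {ep.onset_s} s "
                             "falls outside the recording")
        w = values[a:b]
        if np.mean(~np.isfinite(w)) > max_nan_fraction:
            dropped += 1
            continue
        rows.append(w)
    if not rows:
        raise ValueError("no usable trials after dropping masked windows")
    arr = np.vstack(rows)
    mean = np.nanmean(arr, axis=0)
    if len(rows) >= 2:
        sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(
            np.sum(np.isfinite(arr), axis=0))
    else:
        sem = None
    return PeristimSummary(grid_s=grid, mean=mean, sem=sem,
                           n_trials=len(rows), n_dropped=dropped)


def trajectory_vectors(track: PoseTrack,
                       landmark: str = "body_center") -> np.ndarray:
    """Frame-to-frame body-center displacement vectors, re-centered on a
    common origin.  ``|vector| * fps`` equals the unsmoothed speed at that
    frame.  Shape (n_frames - 1, 2); NaN rows at gaps."""
    p = bridged_xy(track, landmark)
    return np.diff(p, axis=0)


# ---------------------------------------------------------------------------
# Statistical gate
# ---------------------------------------------------------------------------

def paired_comparison_gate(sample_a, sample_b, paired: bool = True,
                           alpha: float = 0.05) -> GateResult:
    """Choose and run the two-group comparison the data support.

    Normality is assessed with the Shapiro-Wilk test and (for independent
    groups) equal variance with the Levene test.  Dependent groups: paired
    t test when the differences pass normality, else the Wilcoxon
    signed-rank test.  Independent groups: t test (pooled or Welch per
    Levene) when both samples pass normality, else Mann-Whitney.  Two-sided
    throughout; significance threshold ``alpha``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal n")
        d = a - b
        if np.allclose(d, 0):
            # degenerate: identical samples; t statistic is 0 by convention
            return GateResult(test="paired t", statistic=0.0, p_value=1.0,
                              normal=True)
        normal = stats.shapiro(d).pvalue >= alpha
        if normal:
            res = stats.ttest_rel(a, b)
            return GateResult("paired t", float(res.statistic),
                              float(res.pvalue), normal=True)
        res = stats.wilcoxon(a, b)
        return GateResult("wilcoxon", float(res.statistic), float(res.pvalue),
                          normal=False)
    normal = (stats.shapiro(a).pvalue >= alpha
              and stats.shapiro(b).pvalue >= alpha)
    eqvar = stats.levene(a, b).pvalue >= alpha
    if normal:
        res = stats.ttest_ind(a, b, equal_var=eqvar)
        return GateResult("t" if eqvar else "welch t", float(res.statistic),
                          float(res.pvalue), normal=True, equal_variance=eqvar)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GateResult("mann-whitney", float(res.statistic), float(res.pvalue),
                      normal=False, equal_variance=eqvar)
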