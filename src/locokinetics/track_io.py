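"""Pose-table I/O, calibration, stimulation-epoch detection and quality control.

Pose tables arrive in the single-animal DeepLabCut CSV dialect: three header
rows (scorer / bodyparts / coords) followed by one row per video frame with
x, y, likelihood triplets per tracked landmark.  This module parses that
dialect into a :class:`PoseTrack`, converts pixels to centimeters using
calibration markers of known spacing, locates optogenetic stimulation trains
from the tracked synchronization LED, and applies the exclusion rules used
for video kinematics (likelihood, arena containment, implausible speeds,
implausible inter-joint distances).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PoseTrack",
    "TimestampSeries",
    "CalibrationSet",
    "StimEpoch",
    "QCRules",
    "QCReport",
    "read_pose_table",
    "read_timestamps",
    "calibrate",
    "detect_stim_epochs",
    "apply_qc",
    "write_tidy_table",
    "read_tidy_table",
    "bridged_xy",
]

#: landmark-name substrings that are static scene references, not body parts;
#: QC exclusion rules never apply to them.
STATIC_LANDMARK_HINTS = ("corner", "marker", "led")

#: maximum run of masked frames bridged by linear interpolation when
#: computing derivatives downstream; longer gaps split the trace.
MAX_BRIDGE_GAP = 2


@dataclass
class PoseTrack:
    """Per-frame landmark coordinates with likelihoods and a validity mask.

    Attributes
    ----------
    landmarks : list of str
        Landmark names, in header order.
    xy : ndarray, shape (n_frames, n_landmarks, 2)
        Coordinates, in pixels or centimeters depending on ``units``.
    likelihood : ndarray, shape (n_frames, n_landmarks)
        Detection likelihood in [0, 1].
    fps : float
        Frame rate (frames/s).
    units : {"px", "cm"}
    arena : str or None
        One of ``open_field_40cm``, ``corridor_side``, ``corridor_ventral``.
    mask : ndarray of bool, shape (n_frames, n_landmarks)
        True where the landmark-frame is valid.  All-true on construction;
        QC clears entries.
    y_down : bool
        True when the y axis points down (image convention).  Angular signs
        are normalized so that clockwise-as-seen-from-above is positive.
    """

    landmarks: list
    xy: np.ndarray
    likelihood: np.ndarray
    fps: float
    units: str = "px"
    arena: str | None = None
    mask: np.ndarray | None = None
    y_down: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[2] != 2:
            raise ValueError("xy must have shape (n_frames, n_landmarks, 2)")
        if self.likelihood.shape != self.xy.shape[:2]:
            raise ValueError("likelihood shape does not match xy")
        if np.nanmin(self.likelihood) < 0 or np.nanmax(self.likelihood) > 1:
            raise ValueError("likelihoods must lie in [0, 1]")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.mask is None:
            self.mask = np.ones(self.xy.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.xy.shape[:2]:
            raise ValueError("mask shape does not match xy")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def times(self) -> np.ndarray:
        ts = self.meta.get("timestamps")
        if ts is not None:
            return np.asarray(ts, dtype=float)
        return np.arange(self.n_frames) / self.fps

    def index(self, landmark: str) -> int:
        try:
            return self.landmarks.index(landmark)
        except ValueError:
            raise KeyError(f"landmark {landmark!r} not in track "
                           f"(have: {', '.join(self.landmarks)})") from None

    def point(self, landmark: str, masked: bool = True) -> np.ndarray:
        """(n_frames, 2) coordinates; invalid frames NaN when ``masked``."""
        j = self.index(landmark)
        p = self.xy[:, j, :].copy()
        if masked:
            p[~self.mask[:, j]] = np.nan
        return p

    def copy(self) -> "PoseTrack":
        return replace(self, xy=self.xy.copy(), likelihood=self.likelihood.copy(),
                       mask=self.mask.copy(), meta=dict(self.meta))


@dataclass
class TimestampSeries:
    """Per-frame acquisition times in seconds, strictly increasing."""

    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("timestamps must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class CalibrationSet:
    """Calibration markers of known physical spacing.

    ``markers`` are landmark names in spatial order; each consecutive pair is
    ``spacing_cm`` apart (corridor dots 5 cm apart, or open-field corners one
    arena side apart).
    """

    markers: list
    spacing_cm: float
    scale_cm_per_px: float | None = None

    def __post_init__(self):
        if len(self.markers) < 2:
            raise ValueError("need at least 2 calibration markers")
        if not self.spacing_cm > 0:
            raise ValueError("spacing_cm must be positive")


@dataclass
class StimEpoch:
    """A single optogenetic stimulation train (2 or 10 s, 10 ms pulses, 20 Hz)."""

    onset_s: float
    offset_s: float
    pulse_width_ms: float = 10.0
    pulse_rate_hz: float = 20.0
    power_pct: float = 100.0
    wavelength_nm: int = 470

    def __post_init__(self):
        if not self.offset_s > self.onset_s:
            raise ValueError("epoch offset must follow onset")
        if not (0 < self.power_pct <= 100):
            raise ValueError("power_pct must lie in (0, 100]")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class QCRules:
    """Exclusion thresholds for video-kinematics quality control.

    Defaults follow the rules used for DeepLabCut-tracked mouse video:
    likelihood < 0.8 excluded; body-center speed capped at the fastest
    locomotor speed recorded in mice (334 cm/s); individual joints/paws capped
    at 400 cm/s (20 % margin for limb segments moving faster than the body);
    adjacent-joint distance capped at 2.3 cm (tibia length in wild-type mice).
    """

    likelihood_min: float = 0.8
    body_speed_max: float = 334.0
    part_speed_max: float = 400.0
    joint_gap_max: float = 2.3
    in_arena_required: bool = True

    def __post_init__(self):
        if not (0 < self.likelihood_min < 1):
            raise ValueError("likelihood_min must lie in (0, 1)")
        for name in ("body_speed_max", "part_speed_max", "joint_gap_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QCReport:
    """Tally of landmark-frames excluded per rule and per landmark."""

    per_rule: dict
    per_landmark: dict
    total_landmark_frames: int
    n_excluded: int

    @property
    def fraction_retained(self) -> float:
        if self.total_landmark_frames == 0:
            return 1.0
        return 1.0 - self.n_excluded / self.total_landmark_frames

    def __str__(self) -> str:
        lines = ["qc_report:"]
        lines.append(f"  total_landmark_frames: {self.total_landmark_frames}")
        lines.append(f"  n_excluded: {self.n_excluded}")
        lines.append(f"  fraction_retained: {self.fraction_retained:.4f}")
        lines.append("  per_rule:")
        for k, v in sorted(self.per_rule.items()):
            lines.append(f"    {k}: {v}")
        lines.append("  per_landmark:")
        for k, v in sorted(self.per_landmark.items()):
            lines.append(f"    {k}: {v}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def read_pose_table(path, fps: float = 30.0, arena: str | None = None) -> PoseTrack:
    """Parse a single-animal DeepLabCut-style CSV into a :class:`PoseTrack`.

    The dialect has three header rows (scorer, bodyparts, coords) and an index
    column of frame numbers; each bodypart contributes an x, y, likelihood
    column triplet.  Frame order is preserved; coordinates stay in pixels.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed pose table header in {path}: {exc}") from exc
    if df.columns.nlevels != 3:
        raise ValueError(f"malformed pose table header in {path}: expected "
                         "three header rows (scorer/bodyparts/coords)")

    landmarks: list[str] = []
    for _, bp, _ in df.columns:
        if bp not in landmarks:
            landmarks.append(bp)

    n = len(df)
    xy = np.empty((n, len(landmarks), 2))
    lik = np.empty((n, len(landmarks)))
    for j, bp in enumerate(landmarks):
        block = df.xs(bp, axis=1, level=1)
        coords = list(block.columns.get_level_values(-1))
        for needed in ("x", "y", "likelihood"):
            if needed not in coords:
                raise ValueError(
                    f"malformed pose table: landmark {bp!r} is missing the "
                    f"{needed!r} column")
        for k, coord in enumerate(("x", "y")):
            col = block.xs(coord, axis=1, level=-1).iloc[:, 0]
            vals = pd.to_numeric(col, errors="coerce").to_numpy()
            bad = np.nonzero(np.isnan(vals) & ~col.isna().to_numpy())[0]
            if bad.size:
                raise ValueError(f"non-numeric {coord} value for {bp!r} at "
                                 f"frame index {bad[0]}")
            xy[:, j, k] = vals
        col = block.xs("likelihood", axis=1, level=-1).iloc[:, 0]
        lik[:, j] = pd.to_numeric(col, errors="raise").to_numpy()

    return PoseTrack(landmarks=landmarks, xy=xy, likelihood=lik,
                     fps=fps, units="px", arena=arena)


def read_timestamps(path) -> TimestampSeries:
    """Read a one-float-per-line timestamp file (seconds)."""
    vals = np.loadtxt(path, dtype=float, ndmin=1)
    return TimestampSeries(vals)


def write_pose_table(track: PoseTrack, path, scorer: str = "locokinetics") -> None:
    """Emit a track in the three-header-row pose CSV dialect (lossless at
    10 significant digits)."""
    buf = io.StringIO()
    cols = ["scorer"] + [scorer] * (3 * len(track.landmarks))
    buf.write(",".join(cols) + "\n")
    buf.write("bodyparts," + ",".join(
        f"{bp},{bp},{bp}" for bp in track.landmarks) + "\n")
    buf.write("coords," + ",".join(
        "x,y,likelihood" for _ in track.landmarks) + "\n")
    for i in range(track.n_frames):
        cells = [str(i)]
        for j in range(len(track.landmarks)):
            cells.append(f"{track.xy[i, j, 0]:.10g}")
            cells.append(f"{track.xy[i, j, 1]:.10g}")
            cells.append(f"{track.likelihood[i, j]:.10g}")
        buf.write(",".join(cells) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_tidy_table(records, path) -> None:
    """Write analysis records as a long-format CSV.

    Records must share a schema (identical key sets).  Rows are ordered
    deterministically by (animal, trial, time) where those columns exist.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if records:
            keys = set(records[0])
            for r in records:
                if set(r) != keys:
                    raise ValueError("records have mixed schemas: "
                                     f"{sorted(keys)} vs {sorted(r)}")
        df = pd.DataFrame.from_records(records)
    sort_cols = [c for c in ("animal", "trial", "epoch", "time") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, index=False)


def read_tidy_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(track: PoseTrack, cal: CalibrationSet,
              likelihood_min: float = 0.8) -> PoseTrack:
    """Rescale a pixel track to centimeters using calibration markers.

    The scale is ``spacing_cm`` divided by the median pixel distance between
    consecutive markers, the median taken over frames where both markers of a
    pair have likelihood >= ``likelihood_min``.
    """
    if track.units == "cm":
        return track.copy()
    dists = []
    for a, b in zip(cal.markers[:-1], cal.markers[1:]):
        ja, jb = track.index(a), track.index(b)
        ok = ((track.likelihood[:, ja] >= likelihood_min)
              & (track.likelihood[:, jb] >= likelihood_min))
        if not ok.any():
            raise ValueError(f"markers {a!r}/{b!r} never tracked with "
                             f"likelihood >= {likelihood_min}")
        d = np.linalg.norm(track.xy[ok, ja] - track.xy[ok, jb], axis=1)
        dists.append(np.median(d))
    med = float(np.median(dists))
    if med <= 0:
        raise ValueError("degenerate calibration: coincident markers "
                         "(zero pixel spacing)")
    scale = cal.spacing_cm / med
    out = track.copy()
    out.xy = out.xy * scale
    out.units = "cm"
    out.meta["scale_cm_per_px"] = scale
    cal.scale_cm_per_px = scale
    return out


# ---------------------------------------------------------------------------
# Stimulation epochs
# ---------------------------------------------------------------------------

def detect_stim_epochs(track: PoseTrack, led_landmark: str = "led",
                       min_on_s: float = 0.5, merge_gap_s: float = 0.2,
                       likelihood_min: float = 0.8, **epoch_kwargs) -> list:
    """Detect stimulation trains from the synchronization LED landmark.

    The LED is only detectable by the pose estimator while lit, so its
    likelihood trace encodes the train.  Because a 20 Hz pulse train flickers
    (50 ms inter-pulse interval), supra-threshold runs separated by less than
    ``merge_gap_s`` are merged; merged runs shorter than ``min_on_s`` are
    discarded.  Depends only on the likelihood series, never on LED position.
    """
    j = track.index(led_landmark)
    on = track.likelihood[:, j] >= likelihood_min
    runs = _bool_runs(on)
    if not runs:
        return []
    merged = [list(runs[0])]
    max_gap = merge_gap_s * track.fps
    for s, e in runs[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    epochs = []
    for s, e in merged:
        onset, offset = s / track.fps, (e + 1) / track.fps
        if offset - onset >= min_on_s:
            epochs.append(StimEpoch(onset_s=onset, offset_s=offset, **epoch_kwargs))
    return epochs


def _bool_runs(b: np.ndarray) -> list:
    """Maximal runs of True as (start, end_inclusive) index pairs."""
    b = np.asarray(b, dtype=bool)
    if not b.any():
        return []
    d = np.diff(b.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if b[0]:
        starts.insert(0, 0)
    if b[-1]:
        ends.append(len(b) - 1)
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def _is_static(name: str) -> bool:
    low = name.lower()
    return any(h in low for h in STATIC_LANDMARK_HINTS)


def _raw_speed(track: PoseTrack, j: int) -> np.ndarray:
    """Unsmoothed displacement speed; speed[i] is the step into frame i
    (NaN at frame 0).  Computed from raw coordinates so QC is idempotent."""
    d = np.linalg.norm(np.diff(track.xy[:, j, :], axis=0), axis=1) * track.fps
    return np.concatenate([[np.nan], d])


def apply_qc(track: PoseTrack, rules: QCRules | None = None,
             joint_adjacency: list | None = None,
             corner_landmarks: list | None = None,
             body_landmark: str = "body_center",
             companion_landmarks: tuple = ("tail_base",)):
    """Apply exclusion rules; return ``(masked_track, QCReport)``.

    Rules (evaluated on raw, unsmoothed coordinates, so a second application
    with the same rules is a no-op):

    - ``likelihood``: landmark-frames with likelihood below threshold.
    - ``out_of_arena``: body landmarks outside the convex hull of the corner
      markers (open field only; requires ``corner_landmarks``).
    - ``body_speed``: frames where the body-center step speed exceeds the
      cap; the body center and its companions (tail base) are excluded there.
    - ``part_speed``: frames where a joint/paw step speed exceeds the cap.
    - ``joint_gap``: frames where two adjacent joints are further apart than
      the cap (pairs from ``joint_adjacency``); the distal joint is excluded.

    Static scene landmarks (corners, calibration markers, LED) are exempt.
    """
    if rules is None:
        rules = QCRules()
    if track.units != "cm":
        raise ValueError("QC speed/distance rules need physical units; "
                         "run calibrate() first")
    out = track.copy()
    body_names = [bp for bp in track.landmarks if not _is_static(bp)]
    per_rule = {"likelihood": 0, "out_of_arena": 0, "body_speed": 0,
                "part_speed": 0, "joint_gap": 0}
    per_landmark = {bp: 0 for bp in body_names}
    newly = np.zeros_like(out.mask)

    def exclude(rule, j, frames):
        frames = np.asarray(frames, dtype=int)
        if frames.size == 0:
            return
        per_rule[rule] += int(frames.size)
        per_landmark[track.landmarks[j]] += int(frames.size)
        newly[frames, j] = True

    # likelihood
    for bp in body_names:
        j = out.index(bp)
        exclude("likelihood", j,
                np.nonzero(out.likelihood[:, j] < rules.likelihood_min)[0])

    # arena containment (open field)
    if (rules.in_arena_required and track.arena == "open_field_40cm"
            and corner_landmarks):
        hull = _corner_hull(out, corner_landmarks)
        for bp in body_names:
            j = out.index(bp)
            inside = _in_hull(out.xy[:, j, :], hull)
            exclude("out_of_arena", j, np.nonzero(~inside)[0])

    # body-center speed cap (open field); excludes center and companions
    if body_landmark in out.landmarks:
        jb = out.index(body_landmark)
        fast = np.nonzero(_raw_speed(out, jb) > rules.body_speed_max)[0]
        exclude("body_speed", jb, fast)
        for bp in companion_landmarks:
            if bp in out.landmarks:
                exclude("body_speed", out.index(bp), fast)

    # per-part speed cap (joints and paws)
    part_names = [bp for bp in body_names
                  if bp not in (body_landmark, *companion_landmarks)]
    for bp in part_names:
        j = out.index(bp)
        exclude("part_speed", j,
                np.nonzero(_raw_speed(out, j) > rules.part_speed_max)[0])

    # adjacent-joint distance cap; distal joint excluded
    for prox, dist in (joint_adjacency or []):
        jp, jd = out.index(prox), out.index(dist)
        gap = np.linalg.norm(out.xy[:, jp, :] - out.xy[:, jd, :], axis=1)
        exclude("joint_gap", jd, np.nonzero(gap > rules.joint_gap_max)[0])

    out.mask = out.mask & ~newly
    total = len(body_names) * out.n_frames
    n_excl = int((~out.mask[:, [out.index(bp) for bp in body_names]]).sum())
    report = QCReport(per_rule=per_rule, per_landmark=per_landmark,
                      total_landmark_frames=total, n_excluded=n_excl)
    return out, report


def _corner_hull(track: PoseTrack, corner_landmarks: list) -> np.ndarray:
    """Convex hull vertices (CCW) of the median corner-marker positions."""
    from scipy.spatial import ConvexHull
    pts = np.array([np.nanmedian(track.xy[:, track.index(c), :], axis=0)
                    for c in corner_landmarks])
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def _in_hull(points: np.ndarray, hull_ccw: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    inside = np.ones(len(points), dtype=bool)
    m = len(hull_ccw)
    for i in range(m):
        a, b = hull_ccw[i], hull_ccw[(i + 1) % m]
        edge = b - a
        rel = points - a
        cross = edge[0] * rel[:, 1] - edge[1] * rel[:, 0]
        inside &= cross >= -tol
    return inside


# ---------------------------------------------------------------------------
# Gap bridging shared by downstream derivative computations
# ---------------------------------------------------------------------------

def bridged_xy(track: PoseTrack, landmark: str,
               max_gap: int = MAX_BRIDGE_GAP) -> np.ndarray:
    """Landmark coordinates with short masked gaps linearly interpolated.

    Gaps of up to ``max_gap`` frames are bridged so one bad detection does
    not shatter a derivative trace; longer gaps stay NaN, splitting the trace.
    """
    p = track.point(landmark, masked=True)
    out = p.copy()
    bad = np.isnan(p).any(axis=1)
    for s, e in _bool_runs(bad):
        if s == 0 or e == len(p) - 1 or (e - s + 1) > max_gap:
            continue
        left, right = p[s - 1], p[e + 1]
        for k, i in enumerate(range(s, e + 1), start=1):
            w = k / (e - s + 2)
            out[i] = left + w * (right - left)
    return out
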