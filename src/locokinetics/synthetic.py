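"""Ground-truth pose-table simulator for the three camera setups.

Emulates the video-derived data the pipeline consumes, with known ground
truth so every estimator can be tested end to end:

- open field, filmed from above at 30 fps in a 40 x 40 cm arena: a point
  mouse follows a schedule of locomotor bouts and turns, with tail base,
  ear and LED landmarks, arena corners, and 10-s stimulation trains
  delivered on a configurable schedule;
- linear corridor, side view at 300 fps: hindlimb joint chain (iliac crest,
  hip, knee, ankle, MTP, toe tip) driven by configurable joint-angle
  waveforms, plus calibration dots 5 cm apart and the LED;
- linear corridor, ventral view at 300 fps: the four paw MTPs oscillating
  in left-right antiphase, with programmable motor arrests.

The noise model is isotropic Gaussian pixel jitter plus Bernoulli dropout
frames carrying a low likelihood, matching how markerless pose estimators
fail in practice.  Same seed and config give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .track_io import PoseTrack, StimEpoch, write_pose_table

__all__ = [
    "BoutSpec", "TurnSpec", "HeadYawSpec", "StimSpec", "ArrestSpec",
    "GaitSpec", "NoiseSpec", "SimConfig", "GroundTruth",
    "default_openfield_config", "default_corridor_config",
    "simulate_openfield", "simulate_corridor", "emit_pose_csv",
]


@dataclass
class BoutSpec:
    """A locomotor bout: constant speed (cm/s) over [start, start+duration)."""
    start_s: float
    duration_s: float
    speed_cm_s: float


@dataclass
class TurnSpec:
    """A turn: constant angular velocity (deg/s, clockwise-from-above > 0)."""
    start_s: float
    duration_s: float
    omega_deg_s: float


@dataclass
class HeadYawSpec:
    """Head-only yaw (deg, clockwise > 0) held over [start, start+duration)."""
    start_s: float
    duration_s: float
    yaw_deg: float


@dataclass
class StimSpec:
    """One stimulation train; power as % of the animal's maximum."""
    onset_s: float
    duration_s: float = 10.0
    power_pct: float = 100.0


@dataclass
class ArrestSpec:
    """Motor arrest: all body landmarks freeze ``latency_s`` after light
    onset and resume ``resume_latency_s`` after light offset.  With
    ``at_next_stance`` the freeze is deferred to the next hindlimb-left
    touchdown, emulating arrests captured in stance."""
    latency_s: float = 0.33
    resume_latency_s: float = 1.1
    at_next_stance: bool = False


@dataclass
class GaitSpec:
    """Corridor gait: stride frequency, swing fraction, stride length, and
    per-joint angle waveforms (mean, amplitude, phase offset in degrees)."""
    stride_hz: float = 4.0
    swing_fraction: float = 0.35
    stride_length_cm: float = 7.0
    joint_waveforms: dict = field(default_factory=lambda: {
        "hip": (120.0, 15.0, 0.0),
        "knee": (120.0, 30.0, 90.0),
        "ankle": (110.0, 25.0, 180.0),
        "mtp": (140.0, 20.0, 270.0),
    })

    def __post_init__(self):
        if not (0 < self.swing_fraction < 1):
            raise ValueError("swing_fraction must lie in (0, 1)")

    @property
    def body_speed_cm_s(self) -> float:
        return self.stride_hz * self.stride_length_cm


@dataclass
class NoiseSpec:
    """Landmark jitter (Gaussian, px) and dropout (Bernoulli per
    landmark-frame, emitted with a low likelihood)."""
    jitter_px: float = 0.0
    dropout_p: float = 0.0
    dropout_likelihood: float = 0.05

    def __post_init__(self):
        if self.jitter_px < 0 or not (0 <= self.dropout_p < 1):
            raise ValueError("invalid noise specification")


@dataclass
class SimConfig:
    seed: int = 0
    fps: float = 30.0
    duration_s: float = 60.0
    arena_cm: float = 40.0
    corridor_cm: float = 100.0
    scale_cm_per_px: float = 0.05
    bouts: list = field(default_factory=list)
    turns: list = field(default_factory=list)
    head_yaws: list = field(default_factory=list)
    stims: list = field(default_factory=list)
    gait: GaitSpec = field(default_factory=GaitSpec)
    arrest: ArrestSpec | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    tail_offset_cm: float = 3.0
    ear_halfspan_cm: float = 1.0
    snout_offset_cm: float = 1.5

    def __post_init__(self):
        for sched in (self.bouts, self.turns, self.head_yaws, self.stims):
            for item in sched:
                end = item.start_s + item.duration_s if hasattr(item, "start_s") \
                    else item.onset_s + item.duration_s
                if end > self.duration_s + 1e-9:
                    raise ValueError(
                        f"schedule item {item} exceeds duration {self.duration_s}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


def default_openfield_config(seed: int = 0) -> SimConfig:
    """Study-condition open-field session: 15-min trial at 30 fps in a
    40 x 40 cm arena with 10-s stimulation trains every 80 s."""
    stims = [StimSpec(onset_s=t, duration_s=10.0)
             for t in np.arange(40.0, 900.0 - 10.0, 80.0)]
    return SimConfig(seed=seed, fps=30.0, duration_s=900.0, arena_cm=40.0,
                     stims=stims)


def default_corridor_config(seed: int = 0) -> SimConfig:
    """Study-condition corridor pass: 6 s at 300 fps, gait at 4 strides/s,
    one 2-s train at 2 s with an arrest (latency 0.33 s, resume 1.1 s),
    matching the evoked motor-arrest regime."""
    return SimConfig(seed=seed, fps=300.0, duration_s=6.0,
                     stims=[StimSpec(onset_s=2.0, duration_s=2.0)],
                     arrest=ArrestSpec(latency_s=0.33, resume_latency_s=1.1))


@dataclass
class GroundTruth:
    """Per-frame truths consistent with the emitted track by construction."""
    times: np.ndarray | None = None
    position_cm: np.ndarray | None = None     # body center, arena coords (y up)
    speed_cm_s: np.ndarray | None = None      # scheduled body speed
    omega_deg_s: np.ndarray | None = None     # clockwise-positive
    heading_deg: np.ndarray | None = None     # math convention, y-up arena
    head_yaw_deg: np.ndarray | None = None    # clockwise-positive
    bouts: list | None = None
    n_initiations: int | None = None
    stim_epochs: list | None = None
    liftoff_frames: dict | None = None        # per paw
    touchdown_frames: dict | None = None
    limb_phase_deg: dict | None = None        # per pair, ideal +/-180 phase
    arrest_frame: int | None = None
    resume_frame: int | None = None
    joint_angles_deg: dict | None = None      # side-view waveform truth
    gait_time_s: np.ndarray | None = None     # warped time (halts during arrest)


def _schedule_value(t: np.ndarray, sched, attr: str) -> np.ndarray:
    out = np.zeros_like(t)
    for item in sched:
        sel = (t >= item.start_s) & (t < item.start_s + item.duration_s)
        out[sel] = getattr(item, attr)
    return out


def _rot(v: np.ndarray, deg: float | np.ndarray) -> np.ndarray:
    rad = np.deg2rad(deg)
    c, s = np.cos(rad), np.sin(rad)
    return np.stack([c * v[..., 0] - s * v[..., 1],
                     s * v[..., 0] + c * v[..., 1]], axis=-1)


def _unit(deg: np.ndarray) -> np.ndarray:
    rad = np.deg2rad(deg)
    return np.stack([np.cos(rad), np.sin(rad)], axis=-1)


# ---------------------------------------------------------------------------
# Open field
# ---------------------------------------------------------------------------

def simulate_openfield(config: SimConfig):
    """Simulate an above-view open-field session.

    The body center integrates the bout/turn schedule with reflective walls;
    the tail base trails the heading; ears sit perpendicular to the head
    axis; the LED landmark is detectable (likelihood 0.99) only during
    stimulation trains.  Returns ``(PoseTrack, GroundTruth)``.
    """
    n = config.n_frames
    dt = 1.0 / config.fps
    t = np.arange(n) * dt
    rng = np.random.default_rng(config.seed)

    speed = _schedule_value(t, config.bouts, "speed_cm_s")
    omega_cw = _schedule_value(t, config.turns, "omega_deg_s")
    head_yaw = _schedule_value(t, config.head_yaws, "yaw_deg")

    # heading in math convention (y-up arena): clockwise-from-above = negative
    heading = np.empty(n)
    pos = np.empty((n, 2))
    heading[0] = 0.0
    pos[0] = (config.arena_cm / 2.0, config.arena_cm / 2.0)
    margin = 3.5  # keeps tail base and ears inside the walls
    lo, hi = margin, config.arena_cm - margin
    for i in range(1, n):
        heading[i] = heading[i - 1] - omega_cw[i - 1] * dt
        step = speed[i - 1] * dt
        d = np.array([math.cos(math.radians(heading[i])),
                      math.sin(math.radians(heading[i]))])
        nxt = pos[i - 1] + step * d
        # reflective walls
        for k in range(2):
            if nxt[k] < lo:
                nxt[k] = 2 * lo - nxt[k]
                heading[i] = -heading[i] if k == 1 else 180.0 - heading[i]
            elif nxt[k] > hi:
                nxt[k] = 2 * hi - nxt[k]
                heading[i] = -heading[i] if k == 1 else 180.0 - heading[i]
        pos[i] = nxt

    u = _unit(heading)
    # head axis: clockwise yaw = negative math rotation in y-up coords
    u_head = _unit(heading - head_yaw)
    left = _rot(u_head, 90.0)

    body_center = pos
    tail_base = pos - config.tail_offset_cm * u
    ear_mid = pos + config.snout_offset_cm * u
    ear_left = ear_mid + config.ear_halfspan_cm * left
    ear_right = ear_mid - config.ear_halfspan_cm * left

    a = config.arena_cm
    corners = {"corner_1": (0.0, 0.0), "corner_2": (a, 0.0),
               "corner_3": (a, a), "corner_4": (0.0, a)}

    stim_on = np.zeros(n, dtype=bool)
    for s in config.stims:
        stim_on[(t >= s.onset_s) & (t < s.onset_s + s.duration_s)] = True

    landmarks = ["body_center", "tail_base", "ear_left", "ear_right",
                 *corners, "led"]
    coords_cm = {
        "body_center": body_center, "tail_base": tail_base,
        "ear_left": ear_left, "ear_right": ear_right,
        **{k: np.broadcast_to(np.array(v), (n, 2)) for k, v in corners.items()},
        "led": np.broadcast_to(np.array([-2.0, -2.0]), (n, 2)),
    }
    lik = {bp: np.full(n, 0.99) for bp in landmarks}
    lik["led"] = np.where(stim_on, 0.99, 0.01)

    track = _emit_track(config, landmarks, coords_cm, lik, rng,
                        arena="open_field_40cm",
                        noisy=("body_center", "tail_base", "ear_left",
                               "ear_right"))

    epochs = [StimEpoch(onset_s=s.onset_s, offset_s=s.onset_s + s.duration_s,
                        power_pct=s.power_pct) for s in config.stims]
    bouts = [(b.start_s, b.start_s + b.duration_s) for b in config.bouts]
    truth = GroundTruth(times=t, position_cm=pos, speed_cm_s=speed,
                        omega_deg_s=omega_cw, heading_deg=heading,
                        head_yaw_deg=head_yaw, bouts=bouts,
                        n_initiations=len(config.bouts), stim_epochs=epochs)
    return track, truth


# ---------------------------------------------------------------------------
# Corridor
# ---------------------------------------------------------------------------

def _swing_profile(frac: np.ndarray, swing_fraction: float) -> np.ndarray:
    """Cyclic paw position relative to the body, in stride-length units,
    over cycle fraction in [0, 1).  Stance first: the paw is fixed in the
    world, so relative to the advancing body it slips backward at exactly
    the body speed (excursion = stance fraction of a stride).  A smooth
    cosine swing then carries it forward again."""
    stance = 1.0 - swing_fraction
    rel = np.empty_like(frac)
    in_stance = frac < stance
    # stance: +stance/2 -> -stance/2 at slope -1 (cancels the body advance)
    rel[in_stance] = stance / 2.0 - frac[in_stance]
    sw = ~in_stance
    s = (frac[sw] - stance) / swing_fraction  # 0..1 through swing
    rel[sw] = -stance / 2.0 + stance * (1.0 - np.cos(np.pi * s)) / 2.0
    return rel


def _gait_paw_x(tau: np.ndarray, gait: GaitSpec, phase_offset: float) -> np.ndarray:
    """World x of a paw given warped gait time tau; body reference advances
    at stride_hz * stride_length."""
    frac = (gait.stride_hz * tau + phase_offset) % 1.0
    body_x = gait.body_speed_cm_s * tau
    return body_x + gait.stride_length_cm * _swing_profile(frac, gait.swing_fraction)


#: cycle-fraction offsets per paw (trot-like; left/right antiphase per pair)
PAW_OFFSETS = {"paw_hl": 0.0, "paw_hr": 0.5, "paw_fl": 0.5, "paw_fr": 0.0}


def simulate_corridor(config: SimConfig):
    """Simulate one corridor pass: side-view hindlimb kinematics and
    ventral-view paw tracking at the same frame times.

    Paws oscillate along the corridor axis in left-right antiphase; the
    side-view MTP follows the hindlimb-left paw so its speed crosses the
    stance/swing threshold on the swing schedule; proximal joints are placed
    by a 2-D forward-kinematic chain driven by the configured joint-angle
    waveforms.  An arrest freezes all body landmarks between the scheduled
    arrest and resume frames via a warped gait clock, so motion resumes in
    the phase where it stopped.  Returns ``(side_track, ventral_track,
    GroundTruth)``.
    """
    n = config.n_frames
    dt = 1.0 / config.fps
    t = np.arange(n) * dt
    rng = np.random.default_rng(config.seed)
    gait = config.gait

    stim_on = np.zeros(n, dtype=bool)
    for s in config.stims:
        stim_on[(t >= s.onset_s) & (t < s.onset_s + s.duration_s)] = True

    arrest_f = resume_f = None
    moving = np.ones(n, dtype=bool)
    if config.arrest is not None and config.stims:
        s0 = config.stims[0]
        arrest_f = int(round((s0.onset_s + config.arrest.latency_s) * config.fps))
        resume_f = int(round((s0.onset_s + s0.duration_s
                              + config.arrest.resume_latency_s) * config.fps))
        if config.arrest.at_next_stance:
            arrest_f = _next_touchdown_frame(arrest_f, config)
        moving[arrest_f:resume_f] = False
    # warped gait clock: advances only while moving
    tau = np.concatenate([[0.0], np.cumsum(moving[:-1]) * dt])

    paw_x = {paw: _gait_paw_x(tau, gait, off) + 10.0
             for paw, off in PAW_OFFSETS.items()}
    fore_shift = 3.5
    for paw in ("paw_fl", "paw_fr"):
        paw_x[paw] = paw_x[paw] + fore_shift

    # ventral view: corridor axis = x; lateral offsets in y (arena coords)
    lateral = {"paw_fl": 5.2, "paw_fr": 2.8, "paw_hl": 5.5, "paw_hr": 2.5}
    ventral_coords = {paw: np.stack([paw_x[paw],
                                     np.full(n, lateral[paw])], axis=-1)
                      for paw in PAW_OFFSETS}

    # side view: MTP follows the hind-left paw; small vertical lift in swing
    frac_hl = (gait.stride_hz * tau + PAW_OFFSETS["paw_hl"]) % 1.0
    stance = 1.0 - gait.swing_fraction
    in_swing = frac_hl >= stance
    sfrac = np.where(in_swing, (frac_hl - stance) / gait.swing_fraction, 0.0)
    mtp_y = 0.3 + np.where(in_swing, 0.7 * np.sin(np.pi * sfrac), 0.0)
    mtp = np.stack([paw_x["paw_hl"], mtp_y], axis=-1)

    side_coords, joint_truth = _side_chain(mtp, tau, gait)

    markers = {f"cal_marker_{k+1}": (5.0 + 5.0 * k, 0.5) for k in range(4)}
    led_lik = np.where(stim_on, 0.99, 0.01)

    side_landmarks = ["iliac_crest", "hip", "knee", "ankle", "mtp", "toe_tip",
                      *markers, "led"]
    side_all = {**side_coords,
                **{k: np.broadcast_to(np.array(v), (n, 2)) for k, v in markers.items()},
                "led": np.broadcast_to(np.array([95.0, 9.0]), (n, 2))}
    side_lik = {bp: np.full(n, 0.99) for bp in side_landmarks}
    side_lik["led"] = led_lik
    side = _emit_track(config, side_landmarks, side_all, side_lik, rng,
                       arena="corridor_side",
                       noisy=("iliac_crest", "hip", "knee", "ankle", "mtp",
                              "toe_tip"),
                       frame_height_cm=12.0)

    ventral_landmarks = [*PAW_OFFSETS, *markers, "led"]
    ventral_all = {**ventral_coords,
                   **{k: np.broadcast_to(np.array(v), (n, 2)) for k, v in markers.items()},
                   "led": np.broadcast_to(np.array([95.0, 7.0]), (n, 2))}
    ventral_lik = {bp: np.full(n, 0.99) for bp in ventral_landmarks}
    ventral_lik["led"] = led_lik
    ventral = _emit_track(config, ventral_landmarks, ventral_all, ventral_lik,
                          rng, arena="corridor_ventral",
                          noisy=tuple(PAW_OFFSETS), frame_height_cm=8.0)

    liftoffs, touchdowns = {}, {}
    for paw, off in PAW_OFFSETS.items():
        lo, td = _true_step_events(tau, gait, off)
        liftoffs[paw], touchdowns[paw] = lo, td

    phase = {}
    for pair, (lpaw, rpaw) in (("hindlimbs", ("paw_hl", "paw_hr")),
                               ("forelimbs", ("paw_fl", "paw_fr"))):
        d = paw_x[lpaw] - paw_x[rpaw]
        dmax = np.max(np.abs(d))
        phase[pair] = 180.0 * d / dmax if dmax > 0 else np.zeros(n)

    epochs = [StimEpoch(onset_s=s.onset_s, offset_s=s.onset_s + s.duration_s,
                        power_pct=s.power_pct) for s in config.stims]
    truth = GroundTruth(times=t, gait_time_s=tau, stim_epochs=epochs,
                        liftoff_frames=liftoffs, touchdown_frames=touchdowns,
                        limb_phase_deg=phase, arrest_frame=arrest_f,
                        resume_frame=resume_f, joint_angles_deg=joint_truth,
                        speed_cm_s=np.where(moving, gait.body_speed_cm_s, 0.0))
    return side, ventral, truth


def _next_touchdown_frame(frame: int, config: SimConfig) -> int:
    """First hindlimb-left touchdown at or after ``frame`` (pre-arrest clock)."""
    gait = config.gait
    t0 = frame / config.fps
    cycles = gait.stride_hz * t0 + PAW_OFFSETS["paw_hl"]
    next_td = math.ceil(cycles - 1e-9) - PAW_OFFSETS["paw_hl"]
    return int(round(next_td / gait.stride_hz * config.fps))


def _true_step_events(tau: np.ndarray, gait: GaitSpec, offset: float):
    """Ground-truth lift-off and touchdown frame indices from the warped
    gait clock (lift-off = stance->swing boundary; touchdown = cycle wrap)."""
    frac = (gait.stride_hz * tau + offset) % 1.0
    stance = 1.0 - gait.swing_fraction
    swinging = frac >= stance
    d = np.diff(swinging.astype(int))
    liftoffs = np.nonzero(d == 1)[0] + 1
    touchdowns = np.nonzero(d == -1)[0] + 1
    # drop spurious boundaries created by the frozen clock (no motion)
    still = np.diff(tau) == 0
    liftoffs = np.array([i for i in liftoffs if not still[i - 1]], dtype=int)
    touchdowns = np.array([i for i in touchdowns if not still[i - 1]], dtype=int)
    return liftoffs, touchdowns


#: side-view chain segment lengths (cm); all below the 2.3 cm QC gap cap
SEGMENT_CM = {"toe_mtp": 0.6, "mtp_ankle": 1.2, "ankle_knee": 1.8,
              "knee_hip": 1.6, "hip_crest": 1.0}

#: turn-direction signs used when unfolding the chain from the toe upward
_CHAIN_SIGNS = {"mtp": 1.0, "ankle": 1.0, "knee": -1.0, "hip": 1.0}


def _side_chain(mtp: np.ndarray, tau: np.ndarray, gait: GaitSpec):
    """Place toe tip and proximal joints from the MTP via forward kinematics
    so that the interior angle at each joint equals its configured waveform."""
    n = len(tau)
    angles = {}
    for joint, (mean, amp, ph) in gait.joint_waveforms.items():
        angles[joint] = mean + amp * np.sin(
            2 * np.pi * gait.stride_hz * tau + np.deg2rad(ph))

    toe = mtp + np.array([SEGMENT_CM["toe_mtp"], 0.0])  # toe forward of MTP
    coords = {"mtp": mtp, "toe_tip": toe}
    # direction of joint->previous segment, walked from the MTP upward
    d_prev = np.zeros(n)  # mtp->toe direction (deg, math, y up)
    chain = [("ankle", "mtp", "mtp_ankle"),
             ("knee", "ankle", "ankle_knee"),
             ("hip", "knee", "knee_hip"),
             ("iliac_crest", "hip", "hip_crest")]
    for upper, lower, seg in chain:
        joint_name = lower if lower in angles else upper
        d_next = d_prev + _CHAIN_SIGNS[joint_name] * angles[joint_name]
        coords[upper] = coords[lower] + SEGMENT_CM[seg] * _unit(d_next)
        d_prev = d_next - 180.0  # direction upper->lower
    return coords, angles


# ---------------------------------------------------------------------------
# Track assembly and emission
# ---------------------------------------------------------------------------

def _emit_track(config: SimConfig, landmarks, coords_cm: dict, lik: dict,
                rng: np.random.Generator, arena: str, noisy: tuple,
                frame_height_cm: float | None = None) -> PoseTrack:
    """Convert arena-frame cm coordinates (y up) to image pixels (y down),
    apply the noise model, and assemble a :class:`PoseTrack`."""
    n = config.n_frames
    scale = config.scale_cm_per_px
    height = frame_height_cm if frame_height_cm is not None else config.arena_cm
    xy = np.empty((n, len(landmarks), 2))
    like = np.empty((n, len(landmarks)))
    for j, bp in enumerate(landmarks):
        c = np.asarray(coords_cm[bp], dtype=float)
        xy[:, j, 0] = c[:, 0] / scale
        xy[:, j, 1] = (height - c[:, 1]) / scale
        like[:, j] = lik[bp]
    if config.noise.jitter_px > 0:
        for bp in noisy:
            j = landmarks.index(bp)
            xy[:, j, :] += rng.normal(0.0, config.noise.jitter_px, size=(n, 2))
    if config.noise.dropout_p > 0:
        for bp in noisy:
            j = landmarks.index(bp)
            drop = rng.random(n) < config.noise.dropout_p
            like[drop, j] = config.noise.dropout_likelihood
    return PoseTrack(landmarks=list(landmarks), xy=xy, likelihood=like,
                     fps=config.fps, units="px", arena=arena, y_down=True,
                     meta={"scale_cm_per_px_true": scale,
                           "sim_seed": config.seed})


def emit_pose_csv(track: PoseTrack, path, scorer: str = "locokinetics-sim") -> None:
    """Write a simulated track in the pose-table CSV dialect.  Round-trips
    losslessly through :func:`locokinetics.track_io.read_pose_table`."""
    if track.n_frames == 0:
        raise ValueError("refusing to emit an empty track")
    write_pose_table(track, path, scorer=scorer)


def config_to_dict(config: SimConfig) -> dict:
    """Resolved configuration as plain data (for provenance output)."""
    return asdict(config)
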