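"""Synthetic single-cell video generator.

Produces videos of one deforming cell with intracellular "cargo" particles
advected by a smooth streaming field, together with ground-truth contours and
displacement fields.  Class identity is controlled by the amplitude of contour
deformation and the mean streaming speed, emulating graded activation states
of lymphocytes (normal -> slight -> moderate -> drastic activation).

All randomness flows through an explicit integer seed; identical parameters
and seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy.ndimage import gaussian_filter, map_coordinates


@dataclasses.dataclass(frozen=True)
class CellVideoParams:
    """Parameters of one synthetic cell video.

    deform_amplitude is the total relative radial perturbation of the contour
    (sum of Fourier-mode amplitudes); it must stay below 1 so the contour
    remains a simple closed curve.  stream_speed is the mean magnitude, in
    pixels per frame, of the intracellular velocity field.
    appearance_event_rate is the per-particle, per-frame probability of a
    split / merge / disappear event of a cargo particle.
    """

    frame_count: int = 24
    frame_size: int = 64
    contour_base_radius: float = 20.0
    deform_amplitude: float = 0.1
    deform_n_modes: int = 4
    stream_speed: float = 1.0
    appearance_event_rate: float = 0.05
    particle_count: int = 150
    noise_sigma: float = 2.0
    class_label: str = "unlabeled"
    # deformation timescale: full-amplitude oscillation period in frames
    deform_period: float = 12.0
    # optional constant drift added to the streaming field (pixels/frame)
    uniform_velocity: tuple[float, float] | None = None
    # standard deviation (pixels) of the Gaussian cargo granules
    particle_sigma: float = 1.2
    # smoothing scale (pixels) of the random streaming field
    flow_smooth_sigma: float = 8.0
    n_distractors: int = 3
    # intermittent activity bouts: activated cells alternate quiescent and
    # active episodes; deform_amplitude / stream_speed are the *active* levels
    # and rest_* the quiescent floor.  bout_duty is the active fraction of a
    # bout period (None: constantly active).
    bout_duty: float | None = None
    bout_period: float = 16.0
    bout_sharpness: float = 8.0
    rest_amplitude: float = 0.02
    rest_speed: float = 0.3
    # optional observed-contour imperfection, emulating automatic
    # segmentation: smooth per-frame boundary wobble (pixels) and an
    # occasional gross glitch (spurious bulge/bite over a short sector).
    # Defaults are 0: the videos ship with ground-truth contours.
    contour_noise_sigma: float = 0.0
    contour_glitch_rate: float = 0.0
    contour_glitch_magnitude: float = 0.25

    def __post_init__(self) -> None:
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if not 0.0 <= self.deform_amplitude < 1.0:
            raise ValueError(
                "deform_amplitude must lie in [0, 1) to keep the contour simple"
            )
        if self.stream_speed < 0:
            raise ValueError("stream_speed must be >= 0")


@dataclasses.dataclass
class SyntheticVideo:
    frames: list[np.ndarray]          # uint8 grayscale, frame_size x frame_size
    contours: list[np.ndarray]        # observed (n_vertices, 2) (x, y), closed
    true_flows: list[np.ndarray]      # (H, W, 2) float (u, v), frame_count-1 of them
    params: CellVideoParams
    seed: int
    # noiseless contours the frames were rendered from (ground truth)
    true_contours: list[np.ndarray] | None = None


# ---------------------------------------------------------------- contours

_N_VERTICES = 120


def _activity_envelope(t, params: CellVideoParams, phase: float) -> float:
    """Smooth periodic bout envelope in [0, 1], active ~bout_duty of the time.

    A logistic squashing of a sine: the threshold cos(pi * duty) makes the
    high phase occupy exactly the duty fraction of each period.
    """
    if params.bout_duty is None:
        return 1.0
    s = np.sin(2 * np.pi * t / params.bout_period + phase)
    b = np.cos(np.pi * np.clip(params.bout_duty, 0.0, 1.0))
    return float(1.0 / (1.0 + np.exp(-params.bout_sharpness * (s - b))))


def make_contour_sequence(params: CellVideoParams, seed: int) -> list[np.ndarray]:
    """Star-shaped contour with membrane waves traveling around the cell.

    r(theta, t) = R0 (1 + sum_m a_m(t) cos(m theta + phi_m + s_m omega_m t)):
    each angular Fourier mode is a bump pattern of constant amplitude whose
    phase drifts at a constant rate (direction s_m = +/-1), so the cell
    elongates from a slowly rotating angle, and the frame-to-frame
    deformation during an active episode is a stable function of the
    amplitude.  Amplitudes sum to at most ``deform_amplitude`` (or the bout
    envelope level), keeping the radius positive and the polygon simple;
    contours are centered in the frame.  Returns one (n_vertices, 2) array of
    (x, y) per frame.
    """
    rng = np.random.default_rng(seed)
    m_modes = np.arange(2, 2 + params.deform_n_modes)
    # random split of the amplitude budget over modes (Dirichlet-like)
    if params.deform_n_modes > 0:
        share = rng.dirichlet(np.ones(params.deform_n_modes))
    else:
        share = np.zeros(0)
    amp = params.deform_amplitude * share
    spatial_phase = rng.uniform(0, 2 * np.pi, size=m_modes.shape)
    direction = rng.choice([-1.0, 1.0], size=m_modes.shape)
    # per-mode wave speed, narrowly spread around the base period so the
    # deformation rate is a stable function of the amplitude
    omega = (2 * np.pi / params.deform_period) * rng.uniform(
        0.85, 1.15, size=m_modes.shape
    )

    bout_phase = rng.uniform(0, 2 * np.pi)
    theta = np.linspace(0, 2 * np.pi, _N_VERTICES, endpoint=False)
    center = params.frame_size / 2.0
    contours = []
    for t in range(params.frame_count):
        env = _activity_envelope(t, params, bout_phase)
        level = (params.rest_amplitude
                 + (params.deform_amplitude - params.rest_amplitude) * env
                 if params.bout_duty is not None else params.deform_amplitude)
        scale = level / params.deform_amplitude if params.deform_amplitude > 0 else 0.0
        a_t = amp * scale
        phase_t = spatial_phase + direction * omega * t
        r = params.contour_base_radius * (
            1.0 + (a_t[:, None] * np.cos(np.outer(m_modes, theta)
                                         + phase_t[:, None])).sum(axis=0)
        )
        xy = np.stack([center + r * np.cos(theta), center + r * np.sin(theta)], axis=1)
        contours.append(xy)
    return contours


# ---------------------------------------------------------------- streaming

def _smooth_flow_field(shape: tuple[int, int], speed: float, smooth_sigma: float,
                       rng: np.random.Generator,
                       uniform: tuple[float, float] | None) -> np.ndarray:
    """Gaussian-filtered white noise scaled to a mean magnitude of ``speed``."""
    h, w = shape
    field = np.zeros((h, w, 2))
    if speed > 0:
        raw = rng.standard_normal((h, w, 2))
        for c in range(2):
            field[..., c] = gaussian_filter(raw[..., c], smooth_sigma, mode="reflect")
        mag = np.hypot(field[..., 0], field[..., 1])
        mean_mag = mag.mean()
        if mean_mag > 0:
            field *= speed / mean_mag
    if uniform is not None:
        field[..., 0] += uniform[0]
        field[..., 1] += uniform[1]
    return field


def _render_particles(shape: tuple[int, int], pos: np.ndarray, amps: np.ndarray,
                      sigma: float) -> np.ndarray:
    """Sum of Gaussian blobs at ``pos`` (x, y) with amplitudes ``amps``."""
    h, w = shape
    img = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    half = int(np.ceil(4 * sigma))
    for (x, y), a in zip(pos, amps):
        if a == 0.0:
            continue
        x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        sub_y, sub_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += a * np.exp(
            -((sub_x - x) ** 2 + (sub_y - y) ** 2) / (2 * sigma**2)
        )
    return img


def _points_inside(contour: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return MplPath(contour).contains_points(pts)


def _sample_inside(contour: np.ndarray, n: int, rng: np.random.Generator,
                   margin: float = 2.0) -> np.ndarray:
    """Rejection-sample n points strictly inside the contour polygon."""
    c = contour.mean(axis=0)
    rad = np.linalg.norm(contour - c, axis=1).mean()
    shrunk = c + (contour - c) * max(1.0 - margin / rad, 0.1)
    lo, hi = shrunk.min(axis=0), shrunk.max(axis=0)
    out = np.empty((0, 2))
    while len(out) < n:
        cand = rng.uniform(lo, hi, size=(4 * n, 2))
        keep = cand[_points_inside(shrunk, cand)]
        out = np.vstack([out, keep])
    return out[:n]


_CELL_LEVEL = 90.0     # interior brightness above background
_BACKGROUND = 40.0
# granule contrast range; signs are mixed (bright and dark granules) so the
# cytoplasm is a speckled texture a dense-descriptor matcher can latch onto
_AMP_LO, _AMP_HI = 40.0, 120.0


def _draw_amplitudes(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(_AMP_LO, _AMP_HI, n) * rng.choice([-1.0, 1.0], n)


def _render_cell_frame(contour: np.ndarray, pos: np.ndarray, amps: np.ndarray,
                       params: CellVideoParams,
                       distractors: np.ndarray | None,
                       rng: np.random.Generator | None) -> np.ndarray:
    """Background + bright cell body + cargo particles (+ optional noise)."""
    h = w = params.frame_size
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.stack([xx.ravel(), yy.ravel()], axis=1)
    inside = _points_inside(contour, grid).reshape(h, w)
    img = np.full((h, w), _BACKGROUND)
    # soft-edged cell body
    body = gaussian_filter(inside.astype(float), 1.0)
    img += _CELL_LEVEL * body
    img += _render_particles((h, w), pos, amps, params.particle_sigma)
    if distractors is not None and len(distractors):
        img += _render_particles((h, w), distractors[:, :2], distractors[:, 2],
                                 params.particle_sigma * 1.8)
    if rng is not None and params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def observe_contour(contour: np.ndarray, params: CellVideoParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Segmentation-like observation of a contour: wobble + occasional glitch.

    The wobble is smooth radial noise of ``contour_noise_sigma`` pixels; with
    probability ``contour_glitch_rate`` a spurious bulge or bite of relative
    magnitude ``contour_glitch_magnitude`` over a random 20-60 degree sector
    is added, emulating a gross automatic-segmentation error.
    """
    c = contour.mean(axis=0)
    rel = contour - c
    r = np.linalg.norm(rel, axis=1)
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    n = len(contour)
    noise = rng.standard_normal(n)
    # periodic smoothing over the vertex index keeps the wobble closed
    k = np.exp(-0.5 * (np.arange(n) - n // 2) ** 2 / 6.0**2)
    k /= k.sum()
    noise = np.real(np.fft.ifft(np.fft.fft(noise) * np.fft.fft(np.roll(k, -(n // 2)))))
    if noise.std() > 0:
        noise = noise / noise.std() * params.contour_noise_sigma
    r_obs = r + noise
    if rng.uniform() < params.contour_glitch_rate:
        center = rng.uniform(0, 2 * np.pi)
        width = rng.uniform(np.pi / 9, np.pi / 3)
        sign = rng.choice([-1.0, 1.0])
        delta = np.mod(ang - center + np.pi, 2 * np.pi) - np.pi
        bump = np.exp(-0.5 * (delta / (width / 2)) ** 2)
        r_obs = r_obs + sign * params.contour_glitch_magnitude * r * bump
    r_obs = np.maximum(r_obs, 0.2 * r.mean())
    return c + np.stack([r_obs * np.cos(ang), r_obs * np.sin(ang)], axis=1)


def make_streaming_pair(params: CellVideoParams, seed: int):
    """One pair of frames linked by an intracellular streaming field.

    Returns ``(frame1, frame2, true_field)`` where ``true_field`` is the
    (H, W, 2) per-pixel displacement actually applied to the cargo particles.
    With probability ``appearance_event_rate`` a particle undergoes an
    appearance event between the frames: a split into two half-amplitude
    blobs, a merge (amplitude doubled), or a disappearance.
    """
    if params.particle_count < 1:
        raise ValueError("particle_count must be >= 1")
    rng = np.random.default_rng(seed)
    contour = make_contour_sequence(
        dataclasses.replace(params, frame_count=2), seed
    )[0]
    pos = _sample_inside(contour, params.particle_count, rng)
    amps = _draw_amplitudes(params.particle_count, rng)

    field = _smooth_flow_field((params.frame_size, params.frame_size),
                               params.stream_speed, params.flow_smooth_sigma,
                               rng, params.uniform_velocity)
    disp = np.stack([
        map_coordinates(field[..., 0], [pos[:, 1], pos[:, 0]], order=1),
        map_coordinates(field[..., 1], [pos[:, 1], pos[:, 0]], order=1),
    ], axis=1)
    pos2 = pos + disp
    amps2 = amps.copy()
    extra_pos, extra_amps = [], []
    events = rng.uniform(size=params.particle_count) < params.appearance_event_rate
    kinds = rng.integers(0, 3, size=params.particle_count)
    for i in np.flatnonzero(events):
        if kinds[i] == 0:       # split
            amps2[i] *= 0.5
            offset = rng.normal(0.0, 2.0, size=2)
            extra_pos.append(pos2[i] + offset)
            extra_amps.append(amps2[i])
        elif kinds[i] == 1:     # merge (contrast doubles)
            amps2[i] = np.clip(amps2[i] * 2.0, -2 * _AMP_HI, 2 * _AMP_HI)
        else:                   # disappear
            amps2[i] = 0.0
    if extra_pos:
        pos2 = np.vstack([pos2, np.asarray(extra_pos)])
        amps2 = np.concatenate([amps2, np.asarray(extra_amps)])

    noisy = params.noise_sigma > 0
    frame1 = _render_cell_frame(contour, pos, amps, params, None,
                                np.random.default_rng(seed + 1) if noisy else None)
    frame2 = _render_cell_frame(contour, pos2, amps2, params, None,
                                np.random.default_rng(seed + 2) if noisy else None)
    return frame1, frame2, field


def make_video(params: CellVideoParams, seed: int) -> SyntheticVideo:
    """Full video: deforming contour + particles advected frame to frame."""
    rng = np.random.default_rng(seed)
    contours = make_contour_sequence(params, seed)
    pos = _sample_inside(contours[0], params.particle_count, rng)
    amps = _draw_amplitudes(params.particle_count, rng)

    # distractor blobs strictly outside every contour (red-blood-cell stand-ins)
    distractors = None
    if params.n_distractors > 0:
        h = params.frame_size
        cand = rng.uniform(0, h, size=(20 * params.n_distractors, 2))
        keep = np.ones(len(cand), bool)
        for c in contours:
            keep &= ~_points_inside(
                c.mean(axis=0) + (c - c.mean(axis=0)) * 1.2, cand)
        cand = cand[keep][: params.n_distractors]
        distractors = np.column_stack(
            [cand, np.full(len(cand), 0.5 * _AMP_HI)])

    stream_phase = rng.uniform(0, 2 * np.pi)
    frames, flows = [], []
    for t in range(params.frame_count):
        noise = np.random.default_rng(seed + 1000 + t) if params.noise_sigma > 0 else None
        frames.append(_render_cell_frame(contours[t], pos, amps, params,
                                         distractors, noise))
        if t == params.frame_count - 1:
            break
        if params.bout_duty is not None:
            env = _activity_envelope(t, params, stream_phase)
            speed = (params.rest_speed
                     + (params.stream_speed - params.rest_speed) * env)
        else:
            speed = params.stream_speed
        field = _smooth_flow_field((params.frame_size, params.frame_size),
                                   speed, params.flow_smooth_sigma,
                                   rng, params.uniform_velocity)
        disp = np.stack([
            map_coordinates(field[..., 0], [pos[:, 1], pos[:, 0]], order=1),
            map_coordinates(field[..., 1], [pos[:, 1], pos[:, 0]], order=1),
        ], axis=1)
        pos = pos + disp
        # keep particles inside the next contour: reflect strays to centroid side
        nxt = contours[t + 1]
        outside = ~_points_inside(nxt, pos)
        if outside.any():
            c = nxt.mean(axis=0)
            pos[outside] = c + 0.7 * (pos[outside] - c)
        # appearance events
        ev = rng.uniform(size=len(amps)) < params.appearance_event_rate
        kinds = rng.integers(0, 3, size=len(amps))
        for i in np.flatnonzero(ev):
            if kinds[i] == 0:
                amps[i] *= 0.5
            elif kinds[i] == 1:
                amps[i] = np.clip(amps[i] * 2.0, -2 * _AMP_HI, 2 * _AMP_HI)
            else:
                amps[i] = 0.0
        flows.append(field)
    if params.contour_noise_sigma > 0 or params.contour_glitch_rate > 0:
        obs_rng = np.random.default_rng(seed + 5000)
        observed = [observe_contour(c, params, obs_rng) for c in contours]
    else:
        observed = contours
    return SyntheticVideo(frames=frames, contours=observed, true_flows=flows,
                          params=params, seed=seed, true_contours=contours)


# ---------------------------------------------------------------- datasets

#: canonical graded activation classes: deformation amplitude and streaming
#: speed both increase with activation level
FOUR_CLASS_PARAMS = {
    "normal": dict(deform_amplitude=0.02, stream_speed=0.5),
    "slight": dict(deform_amplitude=0.10, stream_speed=1.0),
    "moderate": dict(deform_amplitude=0.20, stream_speed=2.0),
    "drastic": dict(deform_amplitude=0.35, stream_speed=3.0),
}

TWO_CLASS_PARAMS = {
    "normal": dict(deform_amplitude=0.05, stream_speed=0.5),
    "abnormal": dict(deform_amplitude=0.30, stream_speed=3.0),
}

#: multiplicative per-video jitter of amplitude and speed; kept small — the
#: dominant within-class heterogeneity is how *often* a cell is active (duty
#: cycle), while the intensity of its active episodes is the class signature
_VIDEO_JITTER = 0.05

#: per-video bout duty-cycle range: how much of the time a cell is in an
#: active episode varies between cells of the same class, so the *time-mean*
#: activity confounds duty with intensity while the episode intensities
#: themselves stay class-specific
_DUTY_RANGE = (0.25, 0.75)


def make_dataset(class_param_list: dict[str, dict] | list[CellVideoParams],
                 videos_per_class: int, seed: int,
                 base_params: CellVideoParams | None = None,
                 out_dir: str | Path | None = None,
                 jitter: float = _VIDEO_JITTER):
    """Balanced labeled collection of synthetic videos.

    ``class_param_list`` maps label -> overrides of ``base_params`` (or is a
    list of fully-formed per-class ``CellVideoParams``).  Per video, the class
    deform_amplitude and stream_speed are jittered by a uniform factor in
    ``[1-jitter, 1+jitter]`` and, when bouts are enabled, the bout duty cycle
    is drawn from ``_DUTY_RANGE``.  If ``out_dir`` is given, frames are
    written as zero-padded PNGs, contours as contours.csv and labels as
    manifest.csv.

    Returns ``(videos, manifest)`` with ``videos`` a list of SyntheticVideo
    and ``manifest`` a DataFrame with columns video_id, path, label.
    """
    if isinstance(class_param_list, dict):
        classes = []
        for label, overrides in class_param_list.items():
            bp = base_params or CellVideoParams()
            classes.append(dataclasses.replace(bp, class_label=label, **overrides))
    else:
        classes = list(class_param_list)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    keys = {(c.deform_amplitude, c.stream_speed) for c in classes}
    if len(keys) < len(classes):
        raise ValueError(
            "two classes share identical (deform_amplitude, stream_speed); "
            "they would be indistinguishable by construction"
        )

    rng = np.random.default_rng(seed)
    videos, rows = [], []
    for ci, cp in enumerate(classes):
        for vi in range(videos_per_class):
            vid_seed = int(rng.integers(0, 2**31 - 1))
            vrng = np.random.default_rng(vid_seed)
            f = 1.0 + jitter * (2 * vrng.uniform() - 1)
            duty = (vrng.uniform(*_DUTY_RANGE)
                    if cp.bout_duty is not None else None)
            vp = dataclasses.replace(
                cp,
                deform_amplitude=min(cp.deform_amplitude * f, 0.95),
                stream_speed=cp.stream_speed * f,
                bout_duty=duty,
            )
            video = make_video(vp, vid_seed)
            video_id = f"{cp.class_label}_{vi:03d}"
            videos.append(video)
            rows.append(dict(video_id=video_id,
                             path=f"{video_id}",
                             label=cp.class_label))
    manifest = pd.DataFrame(rows, columns=["video_id", "path", "label"])
    if out_dir is not None:
        write_dataset(videos, manifest, out_dir)
    return videos, manifest


def two_class_dataset(videos_per_class: int = 20, seed: int = 11,
                      frame_count: int = 24, frame_size: int = 64,
                      out_dir: str | Path | None = None):
    """Canonical binary normal/abnormal study: sustained dynamics, 24 frames.

    Abnormal cells show continuously irregular contour dynamics and fast
    streaming; no bout structure.
    """
    base = CellVideoParams(frame_count=frame_count, frame_size=frame_size)
    return make_dataset(TWO_CLASS_PARAMS, videos_per_class, seed,
                        base_params=base, out_dir=out_dir)


def four_class_dataset(videos_per_class: int = 20, seed: int = 23,
                       frame_count: int = 36, frame_size: int = 64,
                       out_dir: str | Path | None = None):
    """Canonical graded-activation study: 4 classes, intermittent bouts.

    Activation grade sets the *intensity* of active episodes (deformation
    amplitude and streaming speed); how much of the time a cell is active
    (bout duty cycle) varies per video, so the time-averaged activity is an
    ambiguous readout while episode intensity separates the classes.
    """
    base = CellVideoParams(frame_count=frame_count, frame_size=frame_size,
                           bout_duty=0.5)
    return make_dataset(FOUR_CLASS_PARAMS, videos_per_class, seed,
                        base_params=base, out_dir=out_dir)


def write_dataset(videos: list[SyntheticVideo], manifest: pd.DataFrame,
                  out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for video, (_, row) in zip(videos, manifest.iterrows()):
        vdir = out / row["path"]
        vdir.mkdir(parents=True, exist_ok=True)
        for t, frame in enumerate(video.frames):
            imageio.imwrite(vdir / f"frame_{t:04d}.png", frame)
        recs = []
        for t, c in enumerate(video.contours):
            for i, (x, y) in enumerate(c):
                recs.append((t, i, x, y))
        pd.DataFrame(recs, columns=["frame", "point_index", "x", "y"]).to_csv(
            vdir / "contours.csv", index=False)
        np.savez_compressed(vdir / "true_flows.npz",
                            flows=np.stack(video.true_flows))
    manifest.to_csv(out / "manifest.csv", index=False)


def load_video_dir(vdir: str | Path):
    """Read back a per-video directory written by :func:`write_dataset`."""
    vdir = Path(vdir)
    frame_paths = sorted(vdir.glob("frame_*.png"))
    frames = [np.asarray(imageio.imread(p)) for p in frame_paths]
    df = pd.read_csv(vdir / "contours.csv")
    contours = [g.sort_values("point_index")[["x", "y"]].to_numpy()
                for _, g in df.groupby("frame")]
    return frames, contours
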