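"""Synthetic rectified binocular stimulus generation.

Renders the classic looming-laboratory stimuli as paired left/right image
streams from a rectified stereo rig: a solid mid-grey background with an
axis-aligned rectangular object moving in depth (approaching / receding),
translating, elongating or shortening at constant depth, drifting grating
stripes, and three approach patterns (constant speed; decelerating with a
linear growth of imaging size; decelerating with shrinking size
increments).  Ground-truth depth and disparity sidecars accompany every
sequence, and seeded white Gaussian noise can be added per eye.

Geometry is plain pinhole projection.  The cameras share all intrinsics,
their optical axes are parallel, and the baseline is horizontal, so the
two images of a world point differ only by the disparity
``d = b·f / (D · pixelsize)`` pixels along the columns, with the left-eye
column the larger.  Projected coordinates round half up, and the left-eye
rectangle is the right-eye rectangle shifted by the rounded disparity, so
the two eyes see congruent shapes and contour matching can be exact.

The simulator works on the 0-1 intensity scale and quantises to 8 bits on
output; the network consumes the resulting 0-255 luminance.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "MODES",
    "CameraRig",
    "Trajectory",
    "SceneSpec",
    "StereoFrameSequence",
    "Rect",
    "project_rectangle",
    "make_trajectory",
    "render_sequence",
    "add_noise",
]

MODES = (
    "approaching",
    "receding",
    "translating_left",
    "translating_right",
    "elongating",
    "shortening",
    "grating",
    "approach_pattern_1",
    "approach_pattern_2",
    "approach_pattern_3",
)

#: Rec. 601 luma weights for RGB ingestion.
_REC601 = np.array([0.299, 0.587, 0.114])


def round_half_up(x):
    """Round half away from zero toward +inf (0.5 -> 1, 1.5 -> 2)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class CameraRig:
    """Rectified stereo rig: shared intrinsics, parallel optical axes,
    horizontal baseline.

    Attributes
    ----------
    baseline_m:
        Camera separation ``b`` (m).
    focal_m:
        Focal length ``f`` (m).
    pixel_size_m:
        Physical pixel pitch (m/px).
    rows, cols:
        Image dimensions ``R`` x ``C``.
    fps:
        Frame rate (Hz).
    """

    baseline_m: float
    focal_m: float
    pixel_size_m: float
    rows: int
    cols: int
    fps: float = 30.0

    def __post_init__(self) -> None:
        if min(self.baseline_m, self.focal_m, self.pixel_size_m, self.fps) <= 0:
            raise ValueError("baseline, focal length, pixel size and fps must be > 0")
        if self.rows < 3 or self.cols < 3:
            raise ValueError("image must be at least 3x3 pixels")

    @property
    def focal_px(self) -> float:
        """Focal length in pixels, ``f / pixelsize``."""
        return self.focal_m / self.pixel_size_m

    def disparity_px(self, depth_m: float) -> float:
        """Exact (unrounded) disparity of a point at the given depth."""
        if depth_m <= 0:
            raise ValueError(f"depth must be > 0, got {depth_m}")
        return self.baseline_m * self.focal_px / depth_m

    def depth_m(self, dp_px: float) -> float:
        """Depth of a point with the given disparity (+inf at 0 px)."""
        if dp_px == 0:
            return math.inf
        return self.baseline_m * self.focal_px / dp_px


@dataclass(frozen=True)
class Trajectory:
    """Per-frame world-space motion of the rectangular object.

    ``depth_m`` and ``lateral_m`` give the object centre per frame; the
    half-extents are fixed physical sizes.  Depths of +inf are allowed
    (used by the grating plane, rendered at zero disparity).
    """

    depth_m: np.ndarray
    lateral_m: np.ndarray
    object_halfwidth_m: float
    object_halfheight_m: float

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth_m, dtype=float)
        lateral = np.asarray(self.lateral_m, dtype=float)
        if depth.ndim != 1 or depth.shape != lateral.shape:
            raise ValueError("depth and lateral sequences must be equal-length 1-D")
        if np.any(depth <= 0):
            raise ValueError("all depths must be > 0")
        object.__setattr__(self, "depth_m", depth)
        object.__setattr__(self, "lateral_m", lateral)

    @property
    def n_frames(self) -> int:
        return len(self.depth_m)


@dataclass(frozen=True)
class SceneSpec:
    """Photometry and noise of a rendered scene.

    Grey levels are on the 0-1 scale; ``noise_variance`` is the white
    Gaussian noise variance (GNV) on that scale, applied independently per
    pixel, frame and eye with the stated seed.
    """

    mode: str
    object_gray: float = 0.0
    background_gray: float = 0.5
    noise_variance: float = 0.0
    noise_seed: int = 0
    grating_period_px: int = 24
    grating_speed_px_per_frame: int = 2

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.mode != "grating" and self.object_gray == self.background_gray:
            raise ValueError("object and background grey levels must differ")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")
        if self.mode == "grating" and self.grating_period_px < 1:
            raise ValueError("grating period must be >= 1 px")


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle ``[row0, row1) x [col0, col1)``."""

    row0: int
    row1: int
    col0: int
    col1: int

    def shift_cols(self, d: int) -> "Rect":
        return Rect(self.row0, self.row1, self.col0 + d, self.col1 + d)

    def clip(self, rows: int, cols: int) -> "Rect":
        return Rect(
            max(0, min(self.row0, rows)),
            max(0, min(self.row1, rows)),
            max(0, min(self.col0, cols)),
            max(0, min(self.col1, cols)),
        )

    @property
    def empty(self) -> bool:
        return self.row1 <= self.row0 or self.col1 <= self.col0

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


def project_rectangle(
    rig: CameraRig,
    center_depth_m: float,
    center_lateral_m: float,
    halfwidth_m: float,
    halfheight_m: float,
) -> tuple[Rect, Rect]:
    """Project a fronto-parallel rectangle into both eyes.

    The world origin sits midway between the cameras; lateral offsets are
    positive to the right.  Returns ``(left_rect, right_rect)`` clipped to
    the image.  The left-eye rectangle equals the right-eye rectangle
    shifted along the columns by the rounded disparity, so for a fully
    visible object the two eyes see congruent shapes.
    """
    if center_depth_m <= 0:
        raise ValueError(f"depth must be > 0, got {center_depth_m}")
    fpx = rig.focal_px
    hw_px = halfwidth_m * fpx / center_depth_m
    hh_px = halfheight_m * fpx / center_depth_m
    dp = int(round_half_up(rig.disparity_px(center_depth_m)))

    c_row = (rig.rows - 1) / 2.0
    c_col = (rig.cols - 1) / 2.0
    # right-eye centre column: camera sits +b/2 right of the world origin
    col_right = (
        c_col + (center_lateral_m - rig.baseline_m / 2.0) * fpx / center_depth_m
    )
    right = Rect(
        row0=int(round_half_up(c_row - hh_px)),
        row1=int(round_half_up(c_row + hh_px)) + 1,
        col0=int(round_half_up(col_right - hw_px)),
        col1=int(round_half_up(col_right + hw_px)) + 1,
    )
    left = right.shift_cols(dp)
    return left.clip(rig.rows, rig.cols), right.clip(rig.rows, rig.cols)


def _field_halfwidth_m(rig: CameraRig, depth_m: float) -> float:
    """Physical half-width of the field of view at the given depth."""
    return (rig.cols / 2.0) * depth_m / rig.focal_px


def _pad_stationary(depth, lateral, stationary_frames):
    pre = [depth[0]] * stationary_frames
    post = [depth[-1]] * stationary_frames
    lat_pre = [lateral[0]] * stationary_frames
    lat_post = [lateral[-1]] * stationary_frames
    return np.concatenate([pre, depth, post]), np.concatenate(
        [lat_pre, lateral, lat_post]
    )


def make_trajectory(
    mode: str,
    rig: CameraRig,
    *,
    n_frames: int = 60,
    start_depth_m: float | None = None,
    end_depth_m: float | None = None,
    speed_m_per_frame: float | None = None,
    depth_m: float | None = None,
    lateral_start_m: float = 0.0,
    lateral_speed_m_per_frame: float = 0.0,
    halfwidth_m: float = 0.05,
    halfheight_m: float = 0.05,
    stationary_frames: int = 15,
    initial_speed_m_per_frame: float | None = None,
    deceleration_ratio: float = 0.9,
) -> Trajectory:
    """Build the per-frame world trajectory for a motion mode.

    * ``approaching`` / ``receding``: constant-speed depth ramp at fixed
      lateral position (needs ``start_depth_m`` and ``speed_m_per_frame``).
    * ``translating_left`` / ``translating_right``: constant depth
      (``depth_m``), constant lateral speed.
    * ``elongating`` / ``shortening``: constant depth; the object is wide
      enough that one vertical edge stays outside the field of view while
      the opposite edge translates, growing (shrinking) the visible extent.
    * ``grating``: placeholder plane at infinite depth (zero disparity).
    * ``approach_pattern_1``: constant depth speed, padded with
      ``stationary_frames`` static frames before and after the motion.
    * ``approach_pattern_2``: decelerating approach with inverse depth —
      hence projected size — growing linearly in time (needs
      ``start_depth_m`` and ``end_depth_m``); same stationary padding.
    * ``approach_pattern_3``: decelerating approach whose depth decrements
      shrink geometrically by ``deceleration_ratio`` per frame (needs
      ``start_depth_m`` and ``initial_speed_m_per_frame``), so the imaging
      size increments decrease each frame; same stationary padding.

    ``n_frames`` counts the motion frames (stationary padding excluded).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    t = np.arange(n_frames, dtype=float)
    lateral = lateral_start_m + lateral_speed_m_per_frame * t

    if mode in ("approaching", "receding", "approach_pattern_1"):
        if start_depth_m is None or speed_m_per_frame is None:
            raise ValueError(f"{mode} needs start_depth_m and speed_m_per_frame")
        sign = 1.0 if mode == "receding" else -1.0
        depth = start_depth_m + sign * speed_m_per_frame * t
        if np.any(depth <= 0):
            raise ValueError("approach overshoots zero depth; shorten the run")
        if mode == "approach_pattern_1":
            depth, lateral = _pad_stationary(depth, lateral, stationary_frames)
        lateral = np.full_like(depth, lateral_start_m)
    elif mode in ("translating_left", "translating_right"):
        d = depth_m if depth_m is not None else start_depth_m
        if d is None or d <= 0:
            raise ValueError("translation needs a positive constant depth_m")
        speed = abs(lateral_speed_m_per_frame)
        sign = -1.0 if mode == "translating_left" else 1.0
        depth = np.full(n_frames, float(d))
        lateral = lateral_start_m + sign * speed * t
    elif mode in ("elongating", "shortening"):
        d = depth_m if depth_m is not None else start_depth_m
        if d is None or d <= 0:
            raise ValueError("elongation needs a positive constant depth_m")
        fov_hw = _field_halfwidth_m(rig, d)
        halfwidth_m = 2.0 * fov_hw  # left edge parked far outside the view
        speed = abs(lateral_speed_m_per_frame)
        sign = 1.0 if mode == "elongating" else -1.0
        # visible right edge sweeps across the view; centre = edge - halfwidth
        depth = np.full(n_frames, float(d))
        lateral = (lateral_start_m + sign * speed * t) - halfwidth_m
    elif mode == "grating":
        depth = np.full(n_frames, math.inf)
        lateral = np.zeros(n_frames)
    elif mode == "approach_pattern_2":
        if start_depth_m is None or end_depth_m is None:
            raise ValueError("approach_pattern_2 needs start_depth_m and end_depth_m")
        if end_depth_m <= 0:
            raise ValueError("end depth must be > 0")
        inv = np.linspace(1.0 / start_depth_m, 1.0 / end_depth_m, n_frames)
        depth = 1.0 / inv
        depth, lateral = _pad_stationary(depth, lateral, stationary_frames)
        lateral = np.full_like(depth, lateral_start_m)
    elif mode == "approach_pattern_3":
        if start_depth_m is None or initial_speed_m_per_frame is None:
            raise ValueError(
                "approach_pattern_3 needs start_depth_m and initial_speed_m_per_frame"
            )
        steps = initial_speed_m_per_frame * deceleration_ratio ** t[:-1]
        depth = start_depth_m - np.concatenate([[0.0], np.cumsum(steps)])
        if np.any(depth <= 0):
            raise ValueError("approach overshoots zero depth; shorten the run")
        depth, lateral = _pad_stationary(depth, lateral, stationary_frames)
        lateral = np.full_like(depth, lateral_start_m)

    return Trajectory(np.asarray(depth), np.asarray(lateral), halfwidth_m, halfheight_m)


@dataclass
class StereoFrameSequence:
    """Paired 8-bit left/right frame streams with ground-truth sidecars.

    ``truth_disparity_px[t]`` is the rounded pinhole disparity of the
    object plane (0 for the grating, which is rendered at zero disparity).
    """

    left: np.ndarray
    right: np.ndarray
    truth_depth_m: np.ndarray | None = None
    truth_disparity_px: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("left and right streams must have identical shape")
        if self.left.ndim != 3:
            raise ValueError("expected (n_frames, rows, cols) streams")

    def __len__(self) -> int:
        return self.left.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.left.shape[1:]

    def save(self, out_dir) -> None:
        """Write ``left/%06d.png``, ``right/%06d.png`` and ``truth.csv``."""
        out = Path(out_dir)
        for eye, frames in (("left", self.left), ("right", self.right)):
            eye_dir = out / eye
            eye_dir.mkdir(parents=True, exist_ok=True)
            for i, frame in enumerate(frames):
                iio.imwrite(eye_dir / f"{i:06d}.png", frame)
        if self.truth_depth_m is not None:
            pd.DataFrame(
                {
                    "frame": np.arange(len(self)),
                    "depth_m": self.truth_depth_m,
                    "disparity_px": self.truth_disparity_px,
                }
            ).to_csv(out / "truth.csv", index=False)

    @classmethod
    def load(cls, left_dir, right_dir, truth_csv=None) -> "StereoFrameSequence":
        """Load image-sequence directories (zero-padded numeric names).

        RGB frames are converted to luminance with Rec. 601 weights.
        """
        left = _load_eye(left_dir)
        right = _load_eye(right_dir)
        if left.shape[0] != right.shape[0]:
            raise ValueError(
                f"unequal stream lengths: {left.shape[0]} left vs "
                f"{right.shape[0]} right frames"
            )
        truth_depth = truth_disp = None
        if truth_csv is not None:
            truth = pd.read_csv(truth_csv)
            truth_depth = truth["depth_m"].to_numpy(dtype=float)
            truth_disp = truth["disparity_px"].to_numpy(dtype=int)
        return cls(left, right, truth_depth, truth_disp)


def _numeric_key(path: Path):
    m = re.search(r"(\d+)", path.stem)
    return (int(m.group(1)) if m else -1, path.name)


def _load_eye(directory) -> np.ndarray:
    directory = Path(directory)
    paths = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in (".png", ".pgm", ".tif", ".tiff")),
        key=_numeric_key,
    )
    if not paths:
        raise FileNotFoundError(f"no image frames found in {directory}")
    frames = []
    for p in paths:
        try:
            img = np.asarray(iio.imread(p))
        except Exception as exc:  # pragma: no cover - I/O edge
            raise OSError(f"unreadable frame {p}") from exc
        if img.ndim == 3:
            img = round_half_up(img[..., :3].astype(float) @ _REC601)
        frames.append(np.clip(img, 0, 255).astype(np.uint8))
    return np.stack(frames)


def _quantize(img01: np.ndarray) -> np.ndarray:
    """0-1 intensities to 8-bit, rounding half up."""
    return np.clip(np.floor(img01 * 255.0 + 0.5), 0, 255).astype(np.uint8)


def _render_grating(rig: CameraRig, n_frames: int, spec: SceneSpec) -> np.ndarray:
    period = spec.grating_period_px
    cols = np.arange(rig.cols)
    frames = np.empty((n_frames, rig.rows, rig.cols), dtype=np.uint8)
    for t in range(n_frames):
        offset = t * spec.grating_speed_px_per_frame
        stripe = ((cols - offset) // period) % 2
        row = np.where(stripe == 0, spec.object_gray, spec.background_gray)
        frames[t] = _quantize(np.tile(row, (rig.rows, 1)))
    return frames


def render_sequence(
    rig: CameraRig, trajectory: Trajectory, spec: SceneSpec
) -> StereoFrameSequence:
    """Render a trajectory into a paired 8-bit stereo stream.

    Each frame is the background grey everywhere except the projected
    object rectangle; the grating mode instead renders vertical stripes at
    zero disparity (no change in depth distance) advancing a fixed number
    of pixels per frame.  Ground-truth depth/disparity sidecars are always
    populated.  Noise, if requested in the spec, is added afterwards.
    """
    n = trajectory.n_frames
    if n == 0:
        raise ValueError("empty trajectory")

    if spec.mode == "grating":
        frames = _render_grating(rig, n, spec)
        seq = StereoFrameSequence(
            left=frames.copy(),
            right=frames,
            truth_depth_m=np.full(n, math.inf),
            truth_disparity_px=np.zeros(n, dtype=int),
        )
    else:
        left = np.empty((n, rig.rows, rig.cols), dtype=np.uint8)
        right = np.empty_like(left)
        truth_depth = np.asarray(trajectory.depth_m, dtype=float)
        truth_disp = np.array(
            [int(round_half_up(rig.disparity_px(d))) for d in truth_depth]
        )
        bg = _quantize(np.full((rig.rows, rig.cols), spec.background_gray))
        obj8 = _quantize(np.array(spec.object_gray))
        for t in range(n):
            rect_l, rect_r = project_rectangle(
                rig,
                trajectory.depth_m[t],
                trajectory.lateral_m[t],
                trajectory.object_halfwidth_m,
                trajectory.object_halfheight_m,
            )
            for canvas, rect in ((left, rect_l), (right, rect_r)):
                canvas[t] = bg
                if not rect.empty:
                    canvas[t][rect.slices] = obj8
        seq = StereoFrameSequence(left, right, truth_depth, truth_disp)

    if spec.noise_variance > 0:
        seq = add_noise(seq, spec.noise_variance, spec.noise_seed)
    return seq


def add_noise(
    seq: StereoFrameSequence, variance: float, seed: int
) -> StereoFrameSequence:
    """Add seeded white Gaussian noise independently per pixel, frame, eye.

    The noise has zero mean and the given variance on the 0-1 intensity
    scale; the result is clamped to [0, 1] before 8-bit re-quantisation.
    Variance 0 returns the sequence unchanged.
    """
    if variance < 0:
        raise ValueError("noise variance must be >= 0")
    if variance == 0:
        return seq
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(variance)

    def corrupt(frames: np.ndarray) -> np.ndarray:
        img01 = frames.astype(float) / 255.0
        noisy = img01 + rng.normal(0.0, sigma, size=frames.shape)
        return _quantize(np.clip(noisy, 0.0, 1.0))

    return replace(seq, left=corrupt(seq.left), right=corrupt(seq.right))
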