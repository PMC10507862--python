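"""Disparity (DP) layer and depth recovery for the binocular network.

The two eyes' thresholded grouped-excitation maps are cross-matched along
the column (epipolar) axis: the integer disparity at time ``t`` is the
shift ``d`` maximising

    score(d) = Σ_x Σ_y  Ĝ_l(x, y + d) · Ĝ_r(x, y)

with the left-eye column the larger (rectified rig, horizontal baseline).
Ties break toward the smallest ``d`` (the farther interpretation).  Metric
depth follows from the pinhole relation ``D = b·f / (d · pixelsize)``; a
zero disparity maps to infinite depth (no collision threat).

Frames where either map is identically zero carry the previous disparity
forward and are flagged invalid; the decision layer treats them as
non-approaching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import CameraRig

__all__ = [
    "DisparitySearch",
    "DisparityTrace",
    "match_score",
    "compute_disparity",
    "disparity_to_depth",
    "track_disparity",
]


@dataclass(frozen=True)
class DisparitySearch:
    """Search strategy for the disparity argmax.

    ``d_max`` bounds the searched shift; with a warm start the search is
    restricted to ``prev_dp ± warm_window`` unless ``exhaustive`` forces the
    full range every frame.
    """

    d_max: int
    warm_window: int = 3
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.d_max < 0:
            raise ValueError("d_max must be >= 0")
        if self.warm_window < 1:
            raise ValueError("warm_window must be >= 1")


def match_score(g_left: np.ndarray, g_right: np.ndarray, d: int) -> float:
    """The cross-matching objective at shift ``d`` (left columns lead)."""
    if d == 0:
        return float(np.multiply(g_left, g_right).sum())
    return float(np.multiply(g_left[:, d:], g_right[:, :-d]).sum())


def compute_disparity(
    g_left: np.ndarray,
    g_right: np.ndarray,
    search: DisparitySearch,
    prev_dp: int | None = None,
) -> tuple[int, float, bool]:
    """Per-frame integer disparity of the moving contour.

    Returns ``(dp_px, score, valid)``.  When either map is identically zero
    the objective is undefined; the previous disparity (or 0) is reported
    with ``valid=False``.  With a warm start the candidate range is
    ``[prev_dp - warm_window, prev_dp + warm_window] ∩ [0, d_max]``.
    """
    gl = np.asarray(g_left, dtype=float)
    gr = np.asarray(g_right, dtype=float)
    if gl.shape != gr.shape:
        raise ValueError(f"shape mismatch: {gl.shape} vs {gr.shape}")
    if gl.ndim != 2:
        raise ValueError("expected 2-D excitation maps")
    d_max = min(search.d_max, gl.shape[1] - 1)

    if not gl.any() or not gr.any():
        return (int(prev_dp) if prev_dp is not None else 0, 0.0, False)

    if search.exhaustive or prev_dp is None:
        lo, hi = 0, d_max
    else:
        lo = max(0, int(prev_dp) - search.warm_window)
        hi = min(d_max, int(prev_dp) + search.warm_window)

    # Rows where either map is all-zero contribute nothing at any shift;
    # restricting to the jointly active row band is an exact speed-up.
    rows = gl.any(axis=1) & gr.any(axis=1)
    if rows.any():
        gl_c, gr_c = gl[rows], gr[rows]
    else:  # disjoint row support: every score is zero, smallest d wins
        return lo, 0.0, True

    best_d, best_score = lo, -math.inf
    for d in range(lo, hi + 1):
        s = match_score(gl_c, gr_c, d)
        if s > best_score:  # strict: ties keep the smallest d
            best_d, best_score = d, s
    return best_d, best_score, True


def disparity_to_depth(dp_px: int, rig: CameraRig) -> float:
    """Depth distance ``D = b·f / (dp · pixelsize)``; 0 px maps to +inf."""
    if dp_px < 0:
        raise ValueError(f"disparity must be >= 0, got {dp_px}")
    if dp_px == 0:
        return math.inf
    return rig.baseline_m * rig.focal_m / (dp_px * rig.pixel_size_m)


@dataclass
class DisparityTrace:
    """Per-frame disparity, matching score, validity and recovered depth."""

    dp_px: np.ndarray
    score: np.ndarray
    valid: np.ndarray
    depth_m: np.ndarray

    def __len__(self) -> int:
        return len(self.dp_px)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "dp_px": self.dp_px,
                "score": self.score,
                "valid": self.valid,
                "depth_m": self.depth_m,
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def track_disparity(
    g_left_maps,
    g_right_maps,
    rig: CameraRig,
    search: DisparitySearch,
) -> DisparityTrace:
    """Run the disparity layer over paired ``Ĝ`` map sequences.

    The previous *valid* disparity warm-starts each frame's search and is
    carried forward on invalid frames.
    """
    dps, scores, valids, depths = [], [], [], []
    prev_dp: int | None = None
    for gl, gr in zip(g_left_maps, g_right_maps, strict=True):
        dp, score, valid = compute_disparity(gl, gr, search, prev_dp)
        if valid:
            prev_dp = dp
        dps.append(dp)
        scores.append(score)
        valids.append(valid)
        depths.append(disparity_to_depth(dp, rig) if valid else math.inf)
    return DisparityTrace(
        dp_px=np.array(dps, dtype=int),
        score=np.array(scores, dtype=float),
        valid=np.array(valids, dtype=bool),
        depth_m=np.array(depths, dtype=float),
    )
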