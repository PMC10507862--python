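"""LGMD layer: adaptive warning depth-distance and binary activation.

The warning depth-distance is proportional to the per-frame closing speed,

    D_W(t) = C_T · (D(t-1) - D(t)),

so ``C_T`` (in frames; 15 frames ≈ 0.5 s at 30 Hz) is the time the
machine needs to complete an avoidance manoeuvre: if the object keeps its
current speed, the alarm sounds ``C_T`` frames before contact.  The neuron
is active only while the object is both approaching and inside the warning
distance:

    LGMD(t) = 1  iff  D(t) < D_W(t)  and  D(t) < D(t-1).

Receding or translating objects give a non-positive ``D_W`` and can never
activate.  Frames with invalid disparity (no moving contour) output 0 and
do not update the previous depth, so an object appearing from invalid or
infinite depth is non-approaching for that frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DecisionParams",
    "DecisionTrace",
    "warning_distance",
    "lgmd_activation",
    "evaluate_depth_trace",
]


@dataclass(frozen=True)
class DecisionParams:
    """``warning_horizon_frames`` is C_T: frames needed to avoid collision
    (default 15; the recommended range is 10-20 at 30 Hz)."""

    warning_horizon_frames: float = 15.0

    def __post_init__(self) -> None:
        if self.warning_horizon_frames <= 0:
            raise ValueError("warning horizon C_T must be > 0")


def warning_distance(
    d_prev: float, d_curr: float, params: DecisionParams
) -> float:
    """Adaptive warning depth-distance ``D_W = C_T · (D(t-1) - D(t))``.

    May be <= 0 for receding or static objects, in which case no finite
    depth can fall below it.  If either depth is infinite the object is
    treated as non-approaching for this frame and ``D_W = 0``.
    """
    if math.isinf(d_prev) or math.isinf(d_curr):
        return 0.0
    return params.warning_horizon_frames * (d_prev - d_curr)


def lgmd_activation(d_prev: float, d_curr: float, d_w: float) -> int:
    """Binary LGMD output: 1 iff approaching and inside the warning distance."""
    return int(d_curr < d_w and d_curr < d_prev)


@dataclass
class DecisionTrace:
    """Per-frame warning distance, approaching flag and binary output."""

    warning_m: np.ndarray
    approaching: np.ndarray
    lgmd: np.ndarray

    def __len__(self) -> int:
        return len(self.lgmd)

    def to_dataframe(self, depth_m: np.ndarray | None = None) -> pd.DataFrame:
        cols = {"frame": np.arange(len(self))}
        if depth_m is not None:
            cols["depth_m"] = np.asarray(depth_m, dtype=float)
        cols.update(
            D_W_m=self.warning_m,
            approaching=self.approaching,
            lgmd=self.lgmd,
        )
        return pd.DataFrame(cols)


def evaluate_depth_trace(
    depth_m,
    params: DecisionParams,
    valid=None,
) -> DecisionTrace:
    """Run the LGMD layer over a depth trace.

    ``valid`` marks frames with a usable disparity estimate; invalid frames
    output 0, report ``D_W = 0`` and leave the previous depth untouched.
    The previous depth starts at +infinity, so the first frame can never
    activate.
    """
    depth = np.asarray(depth_m, dtype=float)
    if valid is None:
        valid = np.isfinite(depth)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != depth.shape:
        raise ValueError("depth and validity traces must have equal length")

    n = len(depth)
    warning = np.zeros(n)
    approaching = np.zeros(n, dtype=bool)
    lgmd = np.zeros(n, dtype=int)
    d_prev = math.inf
    for t in range(n):
        if not valid[t]:
            continue
        d_curr = depth[t]
        d_w = warning_distance(d_prev, d_curr, params)
        warning[t] = d_w
        approaching[t] = d_curr < d_prev
        lgmd[t] = lgmd_activation(d_prev, d_curr, d_w)
        d_prev = d_curr
    return DecisionTrace(warning_m=warning, approaching=approaching, lgmd=lgmd)
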