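"""Conventional monocular LGMD read-out used for comparison.

Classic LGMD models activate a sigmoid membrane potential (SMP) over the
summed grouped-layer output,

    SMP(t) = (1 + exp(-ΣΣ Ĝ(x, y, t) / (α · R · C)))^-1,

and fire when the SMP exceeds a fixed threshold ``T_fir``.  Since the sum
is non-negative the SMP lives in [0.5, 1); the scale ``α`` must be matched
to the scene and to the image size ``R·C`` for the curve to span the
useful range — the sensitivity the binocular decision rule avoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BaselineParams", "sigmoid_membrane_potential", "fire", "run_baseline"]


@dataclass(frozen=True)
class BaselineParams:
    """``alpha`` scales the summed Ĝ; ``firing_threshold`` is T_fir."""

    alpha: float
    firing_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.5 < self.firing_threshold < 1.0:
            raise ValueError("firing threshold must lie in (0.5, 1)")


def sigmoid_membrane_potential(
    g_hat: np.ndarray, alpha: float, rows: int | None = None, cols: int | None = None
) -> float:
    """Logistic activation of the summed Ĝ map, in [0.5, 1)."""
    g = np.asarray(g_hat, dtype=float)
    r = rows if rows is not None else g.shape[0]
    c = cols if cols is not None else g.shape[1]
    return 1.0 / (1.0 + math.exp(-g.sum() / (alpha * r * c)))


def fire(smp: float, firing_threshold: float = 0.7) -> int:
    """1 iff the membrane potential reaches the firing threshold."""
    return int(smp >= firing_threshold)


def run_baseline(g_hat_maps, params: BaselineParams) -> pd.DataFrame:
    """SMP and firing trace over a sequence of Ĝ maps."""
    smps = [sigmoid_membrane_potential(g, params.alpha) for g in g_hat_maps]
    return pd.DataFrame(
        {
            "frame": np.arange(len(smps)),
            "smp": smps,
            "fired": [fire(s, params.firing_threshold) for s in smps],
        }
    )
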