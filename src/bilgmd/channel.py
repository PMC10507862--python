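"""Monocular five-layer motion-contour cascade: P, E, I, S and G layers.

This is the classic LGMD front end shared by one eye of the binocular
network.  A stream of 8-bit luminance frames is converted, frame by frame,
into a thresholded grouped-excitation map ``Ĝ`` that highlights the contour
of a moving object while suppressing isolated excitations:

* **P (photoreceptor)** — temporal luminance difference with a short
  persistence memory: ``P_t = L_t - L_{t-1} + Σ_i a_i P_{t-i}``, where the
  decay coefficients are ``a_i = 1 / (1 + e^i)``.
* **E (excitation)** — the identity pass of P (not materialised separately).
* **I (inhibition)** — lateral inhibition: the previous P map convolved with
  a 3x3 kernel whose centre is zero (edge neighbours 0.25, corners 0.125),
  i.e. inhibition arrives from the surround with a one-frame delay.
* **S (summation)** — rectified competition between excitation and
  inhibition: ``S = max(0, |P| - W_I * |I|)``.
* **G (grouping)** — a passing coefficient ``Ce`` (3x3 uniform mean of S)
  scales each S cell; clustered excitation is amplified roughly by the
  gain ``C_w`` while isolated excitation falls below the decay threshold
  ``T_de`` and is zeroed.

All arithmetic is floating point; luminance is on the 0-255 scale (the
decay threshold ``T_de`` defaults to 30 on that scale).  Both convolutions
use zero padding: outside the image there is no excitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LATERAL_INHIBITION_KERNEL",
    "GROUPING_KERNEL",
    "persistence_coefficients",
    "ChannelParams",
    "ChannelState",
    "Channel",
    "photoreceptor",
    "lateral_inhibition",
    "summation",
    "grouping",
]

#: Lateral-inhibition kernel w_I: zero centre, 0.25 edge neighbours,
#: 0.125 corner neighbours (sums to 1.5).
LATERAL_INHIBITION_KERNEL = np.array(
    [
        [0.125, 0.25, 0.125],
        [0.25, 0.0, 0.25],
        [0.125, 0.25, 0.125],
    ]
)

#: Grouping kernel w_e: uniform 3x3 mean (every entry 1/9).
GROUPING_KERNEL = np.full((3, 3), 1.0 / 9.0)


def persistence_coefficients(n_p: int) -> np.ndarray:
    """Decay coefficients ``a_i = (1 + e^i)^-1`` for ``i = 1..n_p``."""
    if n_p < 0:
        raise ValueError(f"persistence depth must be >= 0, got {n_p}")
    return 1.0 / (1.0 + np.exp(np.arange(1, n_p + 1, dtype=float)))


@dataclass(frozen=True)
class ChannelParams:
    """Parameters of the monocular cascade.

    Attributes
    ----------
    n_p:
        Persistence depth of the photoreceptor memory (frames, 0-2).
    inhibition_weight:
        Global inhibition weight ``W_I`` in the S layer.
    grouping_gain:
        Constant ``C_w``; clustered excitation is amplified by roughly this
        factor in the G layer.
    grouping_eps:
        Small constant ``Δ_c`` keeping the grouping scale strictly positive.
    decay_threshold:
        Decay threshold ``T_de`` in 8-bit luminance-change units; G values
        below it are zeroed.
    """

    n_p: int = 1
    inhibition_weight: float = 0.3
    grouping_gain: float = 4.0
    grouping_eps: float = 0.01
    decay_threshold: float = 30.0

    def __post_init__(self) -> None:
        if self.n_p not in (0, 1, 2):
            raise ValueError(f"n_p must be 0, 1 or 2, got {self.n_p}")
        if self.grouping_eps <= 0:
            raise ValueError("grouping_eps must be > 0")

    @property
    def decay(self) -> np.ndarray:
        """Persistence decay coefficients ``a_1..a_{n_p}``."""
        return persistence_coefficients(self.n_p)


@dataclass
class ChannelState:
    """Rolling per-eye state of the cascade.

    ``prev_luminance`` holds ``L(t-1)``; ``p_history`` the last ``n_p``
    photoreceptor maps (most recent last); ``prev_p`` the last P map used
    by the one-frame-delayed inhibition.  All buffers are zero until their
    inputs exist, so the first frame yields an all-zero P map.
    """

    shape: tuple[int, int]
    prev_luminance: np.ndarray | None = None
    p_history: list[np.ndarray] = field(default_factory=list)
    prev_p: np.ndarray | None = None


def photoreceptor(
    luminance: np.ndarray, state: ChannelState, params: ChannelParams
) -> np.ndarray:
    """P layer: temporal luminance difference with persistence memory.

    Returns the signed luminance-change map ``P_t`` and updates the state
    buffers (the oldest P map beyond ``n_p`` is dropped).  On the first
    frame the map is all zeros and the frame only primes ``prev_luminance``.
    """
    lum = np.asarray(luminance, dtype=float)
    if lum.shape != state.shape:
        raise ValueError(
            f"frame shape {lum.shape} does not match channel shape {state.shape}"
        )
    if state.prev_luminance is None:
        p = np.zeros(state.shape)
    else:
        p = lum - state.prev_luminance
        # a_i weights P(t-i); history is stored most recent last.
        for a_i, past in zip(params.decay, reversed(state.p_history)):
            p += a_i * past
    state.prev_luminance = lum
    state.prev_p = p
    if params.n_p > 0:
        state.p_history.append(p)
        del state.p_history[: -params.n_p]
    return p


def lateral_inhibition(prev_p: np.ndarray, params: ChannelParams) -> np.ndarray:
    """I layer: convolve the one-frame-delayed P map with ``w_I``.

    Zero padding at the borders; the kernel is symmetric so convolution and
    correlation coincide.
    """
    return ndimage.convolve(
        np.asarray(prev_p, dtype=float), LATERAL_INHIBITION_KERNEL, mode="constant"
    )


def summation(
    excitation: np.ndarray, inhibition: np.ndarray, params: ChannelParams
) -> np.ndarray:
    """S layer: ``max(0, |E| - W_I * |I|)`` element-wise."""
    e = np.asarray(excitation, dtype=float)
    i = np.asarray(inhibition, dtype=float)
    if e.shape != i.shape:
        raise ValueError(f"shape mismatch: {e.shape} vs {i.shape}")
    return np.maximum(0.0, np.abs(e) - params.inhibition_weight * np.abs(i))


def grouping(s: np.ndarray, params: ChannelParams) -> np.ndarray:
    """G layer: amplify clustered excitation, zero isolated excitation.

    ``Ce = S * w_e`` (uniform 3x3 mean, zero padded),
    ``w = max(Ce) / C_w + Δ_c``, ``G = S * Ce / w``; entries of ``G`` below
    the decay threshold ``T_de`` are zeroed.
    """
    s = np.asarray(s, dtype=float)
    ce = ndimage.convolve(s, GROUPING_KERNEL, mode="constant")
    w = ce.max() / params.grouping_gain + params.grouping_eps
    g = s * ce / w
    return np.where(g >= params.decay_threshold, g, 0.0)


class Channel:
    """One eye's cascade, stepped frame by frame.

    >>> ch = Channel(ChannelParams(), shape=(200, 200))
    >>> g_hat = ch.step(frame)          # doctest: +SKIP
    """

    def __init__(self, params: ChannelParams, shape: tuple[int, int]):
        self.params = params
        self.state = ChannelState(shape=tuple(shape))

    def step_layers(self, luminance: np.ndarray) -> dict[str, np.ndarray]:
        """Feed one frame; return all layer outputs (``P``, ``I``, ``S``, ``G``).

        ``G`` is the thresholded grouped map ``Ĝ``.  Intended for
        debugging dumps; :meth:`step` returns only ``Ĝ``.
        """
        prev_p = (
            self.state.prev_p
            if self.state.prev_p is not None
            else np.zeros(self.state.shape)
        )
        i_map = lateral_inhibition(prev_p, self.params)
        p_map = photoreceptor(luminance, self.state, self.params)
        s_map = summation(p_map, i_map, self.params)
        return {
            "P": p_map,
            "I": i_map,
            "S": s_map,
            "G": grouping(s_map, self.params),
        }

    def step(self, luminance: np.ndarray) -> np.ndarray:
        """Feed one luminance frame; return the thresholded ``Ĝ`` map."""
        return self.step_layers(luminance)["G"]

    def run(self, frames) -> list[np.ndarray]:
        """Process an ordered iterable of frames; return the ``Ĝ`` maps."""
        return [self.step(f) for f in frames]
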