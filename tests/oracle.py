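"""Independent nested-loop reference implementation of the cascade.

Evaluates the layer equations literally, pixel by pixel, with explicit
zero padding — deliberately naive so it shares no code path with the
vectorised implementation it cross-checks.
"""

import math

import numpy as np

W_I = [[0.125, 0.25, 0.125], [0.25, 0.0, 0.25], [0.125, 0.25, 0.125]]


def conv3(image, kernel):
    rows, cols = image.shape
    out = np.zeros((rows, cols))
    for x in range(rows):
        for y in range(cols):
            acc = 0.0
            for i in (-1, 0, 1):
                for j in (-1, 0, 1):
                    xi, yj = x + i, y + j
                    if 0 <= xi < rows and 0 <= yj < cols:
                        acc += image[xi, yj] * kernel[i + 1][j + 1]
            out[x, y] = acc
    return out


def run_cascade(frames, n_p=1, w_i=0.3, c_w=4.0, delta_c=0.01, t_de=30.0):
    """Return the per-frame (P, I, S, Ĝ) maps for a luminance stream."""
    frames = [np.asarray(f, dtype=float) for f in frames]
    decay = [1.0 / (1.0 + math.exp(i)) for i in range(1, n_p + 1)]
    w_e = [[1.0 / 9.0] * 3 for _ in range(3)]
    p_maps, outputs = [], []
    for t, lum in enumerate(frames):
        if t == 0:
            p = np.zeros_like(lum)
        else:
            p = lum - frames[t - 1]
            for i, a_i in enumerate(decay, start=1):
                if t - i >= 0:
                    p = p + a_i * p_maps[t - i]
        inhib = conv3(p_maps[t - 1], W_I) if t >= 1 else np.zeros_like(lum)
        s = np.maximum(0.0, np.abs(p) - w_i * np.abs(inhib))
        ce = conv3(s, w_e)
        w = ce.max() / c_w + delta_c
        g = s * ce / w
        g_hat = np.where(g >= t_de, g, 0.0)
        p_maps.append(p)
        outputs.append((p, inhib, s, g_hat))
    return outputs


def brute_force_disparity(g_left, g_right, d_max):
    """Exhaustive argmax of the cross-matching objective (smallest-d ties)."""
    best_d, best = 0, -math.inf
    cols = g_left.shape[1]
    for d in range(0, min(d_max, cols - 1) + 1):
        score = 0.0
        for x in range(g_left.shape[0]):
            for y in range(cols - d):
                score += g_left[x, y + d] * g_right[x, y]
        if score > best:
            best_d, best = d, score
    return best_d, best
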