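"""End-to-end Bi-LGMD orchestration.

Two parallel channels with identical parameters process the left and
right streams; their Ĝ maps are cross-matched into a disparity and depth
trace, the LGMD layer turns the depth trace into the adaptive warning
distance and binary output, and the classic monocular sigmoid read-out
can be run alongside for comparison (it consumes the left-eye Ĝ maps).

The per-frame results are returned as a tidy ``pandas.DataFrame`` with
one row per input frame:

    frame, dp_px, score, valid, depth_m, D_W_m, approaching, lgmd
    [, smp, fired]

Everything is deterministic given the configuration (and the noise seed
for synthetic input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baseline import BaselineParams, fire, sigmoid_membrane_potential
from .channel import Channel, ChannelParams
from .decision import DecisionParams, evaluate_depth_trace
from .stereo import DisparitySearch, DisparityTrace, compute_disparity, disparity_to_depth
from .stimuli import (
    CameraRig,
    SceneSpec,
    StereoFrameSequence,
    make_trajectory,
    render_sequence,
)

__all__ = ["RunConfig", "run", "run_model", "process_stereo"]

logger = logging.getLogger("bilgmd")


@dataclass
class RunConfig:
    """Full configuration of one end-to-end run.

    Exactly one input source must be given: a synthetic scene (``scene``
    plus ``trajectory`` keyword arguments for :func:`make_trajectory`) or
    a pair of on-disk frame directories.
    """

    rig: CameraRig
    channel: ChannelParams = field(default_factory=ChannelParams)
    search: DisparitySearch | None = None
    decision: DecisionParams = field(default_factory=DecisionParams)
    baseline: BaselineParams | None = None
    scene: SceneSpec | None = None
    trajectory_params: dict = field(default_factory=dict)
    left_dir: str | None = None
    right_dir: str | None = None

    def __post_init__(self) -> None:
        synthetic = self.scene is not None
        on_disk = self.left_dir is not None or self.right_dir is not None
        if synthetic == on_disk:
            raise ValueError(
                "exactly one input source required: a scene spec or "
                "left/right frame directories"
            )
        if on_disk and (self.left_dir is None or self.right_dir is None):
            raise ValueError("both left and right frame directories are required")
        if self.search is None:
            self.search = DisparitySearch(d_max=self.rig.cols // 3)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Build a config from a flat key-value YAML file.

        Recognised sections: ``rig`` (b, f, pixelsize, rows, cols, fps),
        ``channel``, ``search``, ``decision``, ``baseline``, ``scene``
        and ``trajectory``; unknown keys raise.
        """
        raw = yaml.safe_load(Path(path).read_text())
        rig_raw = dict(raw.pop("rig"))
        rig = CameraRig(
            baseline_m=rig_raw.pop("b"),
            focal_m=rig_raw.pop("f"),
            pixel_size_m=rig_raw.pop("pixelsize"),
            rows=rig_raw.pop("rows"),
            cols=rig_raw.pop("cols"),
            fps=rig_raw.pop("fps", 30.0),
        )
        if rig_raw:
            raise ValueError(f"unknown rig keys: {sorted(rig_raw)}")
        kwargs: dict = {"rig": rig}
        if "channel" in raw:
            kwargs["channel"] = ChannelParams(**raw.pop("channel"))
        if "search" in raw:
            kwargs["search"] = DisparitySearch(**raw.pop("search"))
        if "decision" in raw:
            kwargs["decision"] = DecisionParams(**raw.pop("decision"))
        if "baseline" in raw:
            kwargs["baseline"] = BaselineParams(**raw.pop("baseline"))
        if "scene" in raw:
            kwargs["scene"] = SceneSpec(**raw.pop("scene"))
        kwargs["trajectory_params"] = raw.pop("trajectory", {})
        kwargs["left_dir"] = raw.pop("left", None)
        kwargs["right_dir"] = raw.pop("right", None)
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def build_input(self) -> StereoFrameSequence:
        if self.scene is not None:
            trajectory = make_trajectory(self.scene.mode, self.rig, **self.trajectory_params)
            return render_sequence(self.rig, trajectory, self.scene)
        return StereoFrameSequence.load(self.left_dir, self.right_dir)


def _dump_layer_maps(dump_dir, t, eye, layers) -> None:
    """Debug dump: clipped 8-bit PNGs per layer, raw CSV for small frames."""
    import imageio.v3 as iio

    out = Path(dump_dir) / eye
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in layers.items():
        clipped = np.clip(np.abs(arr), 0, 255).astype(np.uint8)
        iio.imwrite(out / f"{t:06d}_{name}.png", clipped)
        if arr.size <= 10_000:
            np.savetxt(out / f"{t:06d}_{name}.csv", arr, delimiter=",", fmt="%.6g")


def process_stereo(
    seq: StereoFrameSequence,
    rig: CameraRig,
    channel_params: ChannelParams,
    search: DisparitySearch,
    collect_g: bool = False,
    dump_dir=None,
):
    """Run both channels and the disparity layer over a stereo stream.

    Returns a :class:`DisparityTrace` (and, when ``collect_g`` is set, the
    per-frame left-eye Ĝ maps for the monocular baseline read-out).
    ``dump_dir`` writes per-layer debug images for every frame and eye.
    """
    shape = seq.frame_shape
    left_ch = Channel(channel_params, shape)
    right_ch = Channel(channel_params, shape)
    dps, scores, valids, depths = [], [], [], []
    g_left_maps = []
    prev_dp = None
    n_invalid = 0
    for t in range(len(seq)):
        if dump_dir is not None:
            layers_l = left_ch.step_layers(seq.left[t])
            layers_r = right_ch.step_layers(seq.right[t])
            _dump_layer_maps(dump_dir, t, "left", layers_l)
            _dump_layer_maps(dump_dir, t, "right", layers_r)
            g_l, g_r = layers_l["G"], layers_r["G"]
        else:
            g_l = left_ch.step(seq.left[t])
            g_r = right_ch.step(seq.right[t])
        if collect_g:
            g_left_maps.append(g_l)
        dp, score, valid = compute_disparity(g_l, g_r, search, prev_dp)
        if valid:
            prev_dp = dp
        else:
            n_invalid += 1
        dps.append(dp)
        scores.append(score)
        valids.append(valid)
        depths.append(disparity_to_depth(dp, rig) if valid else np.inf)
    if n_invalid:
        logger.info("%d of %d frames had no moving contour (invalid disparity)",
                    n_invalid, len(seq))
    trace = DisparityTrace(
        dp_px=np.array(dps, dtype=int),
        score=np.array(scores, dtype=float),
        valid=np.array(valids, dtype=bool),
        depth_m=np.array(depths, dtype=float),
    )
    return (trace, g_left_maps) if collect_g else trace


def run_model(
    seq: StereoFrameSequence,
    rig: CameraRig,
    channel_params: ChannelParams | None = None,
    search: DisparitySearch | None = None,
    decision_params: DecisionParams | None = None,
    baseline_params: BaselineParams | None = None,
    dump_dir=None,
) -> pd.DataFrame:
    """Run the full Bi-LGMD model over a stereo stream.

    Library entry point: returns the ordered per-frame record table.  The
    optional baseline columns (``smp``, ``fired``) use the left-eye Ĝ maps.
    """
    channel_params = channel_params or ChannelParams()
    search = search or DisparitySearch(d_max=rig.cols // 3)
    decision_params = decision_params or DecisionParams()

    want_baseline = baseline_params is not None
    out = process_stereo(
        seq, rig, channel_params, search, collect_g=want_baseline, dump_dir=dump_dir
    )
    trace, g_left = out if want_baseline else (out, None)

    decision = evaluate_depth_trace(trace.depth_m, decision_params, valid=trace.valid)
    records = trace.to_dataframe()
    records["D_W_m"] = decision.warning_m
    records["approaching"] = decision.approaching
    records["lgmd"] = decision.lgmd
    if want_baseline:
        smp = [sigmoid_membrane_potential(g, baseline_params.alpha) for g in g_left]
        records["smp"] = smp
        records["fired"] = [fire(s, baseline_params.firing_threshold) for s in smp]
    return records


def run(config: RunConfig, out_csv=None, dump_dir=None) -> pd.DataFrame:
    """Execute a configured run and optionally write the trace CSV."""
    seq = config.build_input()
    logger.info(
        "running Bi-LGMD on %d frames of %dx%d", len(seq), *seq.frame_shape
    )
    records = run_model(
        seq,
        config.rig,
        config.channel,
        config.search,
        config.decision,
        config.baseline,
        dump_dir=dump_dir,
    )
    if out_csv is not None:
        records.to_csv(out_csv, index=False)
    return records
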