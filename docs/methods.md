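# Methods

## Model

The package implements a binocular looming detector inspired by the
locust's lobula giant movement detector (LGMD).  Two identical monocular
channels convert each eye's luminance stream into a motion-contour map;
a disparity layer cross-matches the two maps; an LGMD decision layer
converts the recovered metric depth into a binary collision alarm.

### Monocular cascade (P, E, I, S, G)

Luminance is on the 0–255 scale throughout.  For each eye:

* **P (photoreceptor)** — temporal difference with a short persistence
  memory: `P_t = L_t − L_{t−1} + Σ_{i=1..n_p} a_i · P_{t−i}`, with decay
  `a_i = (1 + e^i)^{-1}` (so `a_1 ≈ 0.269`).  The first frame only primes
  the luminance buffer; all state is zero-initialised.
* **E** — the identity pass of P (not materialised).
* **I (lateral inhibition)** — the previous P map convolved with a 3×3
  kernel with zero centre, 0.25 edge and 0.125 corner weights
  (one-frame delay, zero padding).
* **S (summation)** — `S = max(0, |P| − W_I·|I|)`.  The absolute values
  make the cascade blind to contrast polarity: a dark object on a bright
  background and its brightness-swapped twin produce the same S.
* **G (grouping)** — a passing coefficient `Ce` (3×3 uniform mean of S,
  zero padded) rescales each cell: `G = S·Ce/w` with
  `w = max(Ce)/C_w + Δ_c`, then entries below the decay threshold `T_de`
  are zeroed.  Clustered excitation is amplified by roughly `C_w`;
  isolated pixels fall below `T_de` and vanish.

### Disparity and depth

The per-frame integer disparity is the column shift maximising
`Σ_x Σ_y Ĝ_l(x, y+d)·Ĝ_r(x, y)` (rectified rig, left-eye columns lead;
ties break to the smallest `d`, i.e. the farther interpretation).
Depth follows the pinhole relation `D = b·f/(d·pixelsize)`; zero
disparity maps to infinite depth.  Frames where either map is all-zero
are invalid: the previous disparity is carried forward for reporting and
the decision layer treats the frame as non-approaching.

The search is warm-started: each frame examines
`prev_dp ± warm_window` (an exhaustive flag searches `[0, d_max]`).
Besides speed, the warm window matters under noise — see Limitations.

### Decision rule

`D_W(t) = C_T·(D(t−1) − D(t))` and the neuron outputs 1 iff
`D(t) < D_W(t)` and `D(t) < D(t−1)`.  `C_T` is in frames (15 frames ≈
0.5 s at 30 Hz): if the object keeps its speed, the alarm starts `C_T`
frames before contact.  Invalid or infinite depths yield `D_W = 0`, no
activation, and leave the depth reference untouched.  No temporal
smoothing is applied to the depth trace.

### Monocular baseline

For comparison, the classic sigmoid read-out
`SMP = (1 + exp(−ΣΣĜ/(α·R·C)))^{-1}` with a fixed firing threshold
`T_fir` (default 0.7) runs on the left eye's Ĝ maps.  `α` has no
universal default; the experiments use `α = 1` unless stated.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `n_p` | persistence depth (frames) | 1 | range 0–2 |
| `W_I` | global inhibition weight | 0.3 | |
| `C_w` | grouping gain | 4 | cluster amplification |
| `Δ_c` | grouping epsilon | 0.01 | keeps `w > 0` |
| `T_de` | decay threshold | 30 | 8-bit luminance-change units |
| `C_T` | warning horizon (frames) | 15 | recommended 10–20 at 30 Hz |
| `d_max` | disparity search cap (px) | cols/3 | presets set it per scenario |
| `warm_window` | search half-width (px) | 2–3 | must cover the per-frame disparity step |
| `T_fir` | baseline firing threshold | 0.7 | |

## Synthetic stimuli

The simulator renders axis-aligned rectangles on a solid background
(default mid-grey 0.5) through an ideal rectified pinhole pair: shared
intrinsics, parallel axes, horizontal baseline.  Intensities live on the
0–1 scale and are quantised to 8 bits with round-half-up; the network
consumes the resulting 0–255 stream.  Projected coordinates round half
up, and the left-eye rectangle is the right-eye rectangle shifted by the
rounded disparity, so the two eyes see congruent shapes and the
ground-truth disparity sidecar `round(b·f/(D·pixelsize))` is exact.
Motion modes: constant-speed approach/recede, constant-depth
translation, elongation/shortening (one edge parked outside the view),
drifting grating stripes (rendered identically in both eyes at zero
disparity), and three approach patterns — constant speed, inverse-depth
linear (projected size grows linearly), and geometrically decelerating
(size increments shrink; ratio 0.9 per frame).  All three patterns take
a 15-frame stationary prefix and suffix.  White Gaussian noise of a
given variance (0–1 scale) is added independently per pixel, frame and
eye from a seeded generator, clamped to [0, 1] before re-quantisation.

What the simulator does **not** emulate: textured backgrounds, camera
ego-motion, lens distortion, vergence, photometric mismatch between
eyes, shadows or reflections.  Passing tests on these stimuli therefore
demonstrate the model's selectivity and robustness for idealised
laboratory stimuli, not performance on natural footage.

## Scenario geometry

Object sizes, depth ranges and speeds are free parameters of the
protocols; the presets derive them from three *a-priori* constraints
rather than from tuning:

1. **Super-pixel motion.** Pixel-level contour matching is only
   well-defined while the projected edges move at least ~1 px per frame
   in both eyes.  Below that rate a frame's luminance change reduces to
   partial, one-eye edge updates whose best match can sit at a wrong
   offset (e.g. pairing opposite object edges, `d ≈ dp + 2·halfwidth`).
   The rigs therefore operate in the regime *object ≫ baseline* — large
   congruent contours with disparities of tens of pixels — and each
   depth-motion preset keeps all edge rates ≥ 1 px/frame for its whole
   run, or is evaluated only on frames with a fresh moving contour in
   both eyes.
2. **Field of view and search range.** The disparity stays below
   `d_max` and the object inside both images for the whole run.
3. **Quantisation margin.** An approaching object crosses the warning
   distance `C_T·v` several frames before the run ends, so one-pixel
   depth quantisation cannot suppress the alarm.

Two rigs are bundled.  Small: 200×200 px, `b·f/pixelsize = 10 m·px`
(b = 2 cm, f = 4 mm, 8 µm pixels) — used by the selectivity, contrast,
noise and disparity-recovery protocols; a run takes well under a second.
Full: 600×600 px, `b·f/pixelsize = 135 m·px` — used by the
warning-horizon sweep, which needs fine disparity resolution: the
first-fire frame is sharp to about `C_T²·v·(b·f/pixelsize)^{-1}·D*²`…
in practice, to about `C_T/k` frames where `k` is the per-frame
disparity step at the crossing.  The sweep's geometry places the C_T=10
crossing where `k ≈ 22` (timing exact to one frame); larger C_T values
cross where steps are coarser and alarm a few frames *early* — a
conservative bias inherent to quantised closing-speed estimates.

The disparity-recovery scenario additionally phase-locks rounding
events: the object approaches along the right camera's optical axis
(lateral offset `b/2`, so the right image has no lateral drift) with
half-size exactly four baselines, which makes every disparity-rounding
event coincide with a size-rounding event in both eyes.

## Numerical choices

* Floating point throughout the cascade; no intermediate quantisation.
* Zero padding for both 3×3 convolutions (no excitation outside the
  image).
* Round-half-up (`floor(x + 0.5)`) for all pixel coordinates and for
  8-bit quantisation.
* Argmax ties in the disparity search break toward the smallest shift.
* `max(Ce)` in the grouping scale is the frame-wide maximum.
* A mid-grey background quantises to 128 while 255/2 = 127.5, so a dark
  object (contrast 128) and its bright twin (contrast 127) give match
  scores and sigmoid potentials differing in the last digit; every
  integer output (disparity, validity, alarm) is identical.

## Known limitations

* **Sub-pixel regimes.** Far or slow objects move less than a pixel per
  frame; frames then carry persistence residues or one-eye-only edge
  updates, and the matched disparity can deviate by a few pixels.  On a
  receding trace such deviations can even produce isolated spurious
  alarms.  The bundled presets avoid this regime; real-world use should
  treat disparities from barely-moving contours with caution.
* **Quantised closing speed.** The apparent per-frame depth change is
  quantised to whole disparity steps, so warning timing is only as
  sharp as `C_T/k` frames (see above) and is biased toward earlier
  alarms.
* **Heavy noise.** White Gaussian noise of variance ≥ 0.01 floods the
  grouping layer (the decay threshold passes a large fraction of noise
  pixels).  The matching objective sums fewer terms at larger shifts,
  which under flooding biases an exhaustive search toward zero
  disparity; the warm-started window search is what keeps tracking
  robust (verified at variances up to 0.05).  A noisy scene with no
  moving object yields near-zero disparity, i.e. a distant, harmless
  percept.
* **Single object, fronto-parallel, horizontal epipolar geometry** are
  assumed throughout; multi-object scenes and oblique approach angles
  are out of scope.
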