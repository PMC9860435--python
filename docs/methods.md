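# Methods

This note describes the models and procedures implemented by
`octotrigger`, the parameters that matter, the choices made where the
design was genuinely open, and what the synthetic benchmarks do and do
not establish.

## The trigger pipeline

Every `motion_detect_interval` seconds (default 1 s) in triggered mode,
a 320×240 monochrome trigger-evaluation image (TEI) passes through:

1. **Gaussian blur**, 5×5 separable kernel, σ = 0.3·((k−1)/2 − 1) + 0.8
   = 1.1 (the convention common to imaging toolkits), reflected borders,
   rounded back to 8-bit. The blur suppresses sensor noise before
   background comparison.
2. **ROI crop** to `trigger_roi` = (left, bottom, width, height), default
   (20, 20, 280, 200), specified with a bottom-left origin on the TEI
   grid and converted internally to top-left row order
   (`row = H − bottom − height`). The ROI keeps frame edges — where
   drift and vignetting are worst — out of the decision.
3. **MOG classification** (below) at `foreground_threshold` grey levels.
4. **Morphological closing** of the binary mask: one dilation then one
   erosion with a 3×3 square element, merging fragmented detections of a
   single animal. The mask is treated as embedded in an infinite zero
   background, which makes the operation exactly idempotent and
   border-consistent.
5. **Decision.** `pixel_total`: trigger iff the post-close foreground
   count strictly exceeds `min_pixel_count` (default 10,000).
   `object_size`: trigger iff any 8-connected component strictly exceeds
   `min_object_size` (default 500). "Exceeds" is read as strict
   inequality; both boundary cases are pinned by tests. The closing is
   applied before counting in *both* rules, so the two rules see the
   same mask. Components are labelled by run-length encoding rows and
   union-find across adjacent rows, which keeps the cost proportional to
   the number of runs rather than pixels. 8-connectivity was chosen
   because it merges diagonal fragments, consistent with the closing's
   purpose.

On a trigger: a full-resolution frame is requested at the configured
tier (L = 1024×768, M = 2048×1520, H = 4056×3040), optionally
CLAHE-enhanced (`auto_contrast`), encoded per `image_type` /
`image_quality`, and stored. The strobe envelope turns on
`pre_strobe_fire` s (default 0.1) before the exposure and off at
`min(exposure end, on + strobe_duration)`; the `strobe_duration` cap
(default 0.5 s, range 0.5–2) is an LED-overheating guard and is never
exceeded. When `exposure` = 0 the (simulated) camera reports the
exposure it chose, and that value feeds the envelope.

CLAHE uses clip limit 2.0 and an 8×8 tile grid by default: per-tile
256-bin histograms are clipped at `clip_limit × tile_area / 256`, the
excess is redistributed evenly (remainder spread at an even stride), and
per-tile equalization mappings are blended bilinearly. Only the
full-resolution capture path uses CLAHE; the trigger path never does.

## The background model

Each pixel carries K = 3 Gaussian components (weight w, mean μ, variance
σ²). The learning rate is α = 1/`frame_history` (default 1/25). A new
frame is classified against the *pre-update* model — a target must not
suppress its own detection — then the model updates in place:

* **Matching band**: value x matches component k iff
  |x − μ_k| ≤ max(`foreground_threshold`, 2.5 σ_k). The configured
  threshold (grey levels, 0–255) is a floor on the band, combined with
  the conventional 2.5σ rule; this honours both the threshold's printed
  units and mixture adaptivity. It is the single riskiest semantic in
  the engine and is pinned by its own fixtures (a +4 step at threshold 8
  stays background; +50 is foreground).
* **Background set**: components sorted by w/σ; a component is
  background iff the cumulative weight of the components before it is
  < T = 0.9 (the set includes the component that crosses T). A pixel is
  background iff it matches some background-set component.
* **Update**: the best matching component absorbs the sample with rate
  ρ = α (w ← (1−α)w + α; μ, σ² pulled toward the sample); a pixel with
  no match replaces its weakest component with a fresh component at the
  sample value, σ² = 15², weight α; weights are renormalized each step
  (kept within 1e-9 of 1, in float64). σ² is floored at 4.

K, T, σ²_init and σ²_min are not dictated by the engine's configuration
schema; the values follow common choices in the mixture-background
literature and are exposed as keyword arguments of `init_model`.

**Absorption arithmetic, and what it implies for detection.** A fresh
component's weight follows w(t) = 1 − (1 − w₀)(1 − α)^t, and it joins
the background set once the displaced component's weight falls below
T — with α = 1/25, after roughly 3 frames of persistence. A *stationary*
intruder therefore vanishes from the mask within a few evaluation
intervals, and a *moving* target keeps only its freshly covered trail:
about 3 × speed × diameter pixels. An animal crossing the view at
16 px/frame with a 20-px body height sustains ≈ 900 foreground pixels
(comfortably above `min_object_size` = 500); a 2 px/frame crawl sustains
≈ 150 and does not trigger at the default threshold. This is inherent to
short-history mixture models, not an artifact of this implementation:
detection is of *arrival and motion*, not of continued presence.

## The deployment state machine

A deployment is one power-up-to-shutdown run. It creates
`<DMMDDYYYY-Thhmmss>/` (named from the deployment clock's calendar time)
with a `settings.cfg` snapshot, `log.csv`, `full/` and `tei/`. After
`initial_wait` minutes, triggered mode burns in the background model on
the first `frame_history` TEIs, then evaluates every
`motion_detect_interval` seconds; a trigger captures a full-resolution
image and suspends sensing for `post_detection_rest` minutes (default
5). Intervalometer mode captures every `image_interval` seconds up to
`max_images`. Exit conditions are checked each tick in fixed priority:
`low_voltage` (measured volts strictly below `low_voltage_cutoff`,
default 11 V for a 12 V battery bank), `disk_full` (free space below one
worst-case image: width × height × channels + header), `max_runtime`
(cumulative sensing seconds strictly above the limit; rests do not
count), `max_images`, plus `end_of_input` when a finite frame source is
exhausted. Voltage is logged at boot and at every capture, so the
discharge profile can be read off the log. `shutdown_at_end` = false
only flags the request instead of powering anything down (bench
testing); `shutdown_wifi_on_collection` is recorded but is a no-op
against simulated hardware.

All timing comes from a simulated clock — never real sleeps — so runs
are deterministic: a fixed scene seed and settings give bit-identical
folder contents, and the log alone suffices to replay the state
sequence (verified by a replay test).

Every evaluated TEI is stored under `tei/` with its decision in the log,
so any trigger decision can be re-derived offline from the stored inputs.

## The synthetic scene generator

The generator stands in for field footage with ground truth attached:

* **Background**: a static smooth texture (coarse uniform field,
  bilinearly upsampled, amplitude 20 grey levels by default) around a
  mean of 120, plus a slow sinusoidal luminance drift (amplitude 10,
  period 3600 s) emulating tidal-current and lighting variation, plus
  per-frame Gaussian sensor noise (sd 2), clipped to [0, 255]. The
  parameters are validated so the background never actually clips,
  keeping target contrast exact.
* **Targets**: hard-edged ellipses (semi-axes a, b) of exact signed
  contrast against the local background, entering at a frame index and
  moving linearly (or dwelling then leaving). Hard edges mean the truth
  masks are exact — testability was chosen over realism. Rasterized
  areas stay within 2% of πab for a, b ≥ 5.
* **Determinism**: frame i's noise is drawn from a generator keyed on
  (seed, i), so frames render identically on demand and out of order.
* **Ground truth**: per-frame presence flags, per-target areas, optional
  union masks, and *expected trigger windows*: maximal presence
  intervals, with windows that fall entirely inside the rest shadow of
  an earlier window flagged unmatchable (the engine provably cannot
  evaluate during a rest).

Scoring matches triggers to truth windows greedily in time order with a
tolerance of one `motion_detect_interval` on each side (the engine's
sampling granularity); greedy earliest-ending assignment attains the
maximum matching for this interval structure (cross-checked against an
exhaustive assignment oracle). Sensitivity is matched/matchable;
triggers overlapping no window are false, reported per hour. The
capture-economics yardstick is
`intervalometer_equivalent(duration_h, interval_s) = floor(duration_h·3600/interval_s)`
— e.g. 785 hours at a 2-s cadence is 1,413,000 frames, the scale of
screening work a trigger system avoids.

## Benchmark problem sizes

The end-to-end benchmark in the acceptance suite is a 2-simulated-hour
scene (7,200 frames at 1 s cadence) with five fast target passes
(ellipse 20×10, contrast 60, 16 px/frame) over the default drifting,
noisy background, with `max_runtime` raised to 120 minutes so sensing
covers the whole scene; everything else is at packaged defaults. The
suite's other simulated deployments use 150–950-frame scenes. These
sizes keep the full test run in a few minutes on one core while leaving
every pipeline stage (burn-in, trigger, rest, exit) exercised at its
real per-frame cost.

## What passing tests do and do not show

The synthetic scenes establish *mechanism*: correct defaults, correct
pipeline arithmetic, exact rest behaviour, deterministic replay,
sensitivity 1.0 with ≤1 false trigger under the stated scene. They do
not establish field performance: real footage has moving texture
(swaying algae, sediment transport), heavy-tailed and spatially
correlated noise, fish schooling through the ROI, and biofouling — none
of which the generator emulates (its noise is i.i.d. Gaussian and its
drift is a global offset; both are parameters precisely so harder
regimes can be added without API change).

## Known limitations

* **Stale model after rest.** The background model is frozen during the
  post-trigger rest. Global drift fast enough to move the scene by more
  than the matching band within one rest period produces a spurious
  trigger at rest end (pinned by a dedicated test with a 15-minute
  drift period). Mitigations — longer `frame_history`, higher threshold,
  shorter rests — trade against sensitivity and battery.
* **Slow movers.** As derived above, targets moving well under
  ~`min_object_size`/(3 × diameter) pixels per interval are invisible to
  the `object_size` rule after burn-in.
* **No shadow handling, no colour mixtures, fixed K.** The trigger path
  is strictly 8-bit luminance.
* **Directory frame sources** upscale the stored frame for
  "full-resolution" capture; only the simulated camera renders genuinely
  at the requested tier.
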