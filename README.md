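# octotrigger

A hardware-independent re-implementation of the triggered-acquisition
engine used by open-source underwater camera traps, built so the whole
pipeline — background modelling, trigger evaluation, deployment control —
can be developed, tested and tuned on a desk instead of on the seafloor.

Underwater camera traps cannot use the passive-infrared triggers of
terrestrial traps (infrared attenuates within centimetres of water), so
they trigger on *vision*: a low-resolution **trigger evaluation image**
(TEI, 320×240 monochrome) is taken every `motion_detect_interval` seconds
and compared against a per-pixel **mixture-of-Gaussians (MOG)** background
model. Pixels not explained by the background become a foreground mask;
after a Gaussian blur, a crop to the trigger region of interest, and a
morphological closing, the mask either

* exceeds `min_pixel_count` foreground pixels (*pixel_total* rule), or
* contains an 8-connected component larger than `min_object_size`
  (*object_size* rule),

and a full-resolution image is captured with a strobe fired around the
exposure envelope. The engine then rests `post_detection_rest` minutes
before sensing again. All of this is driven by an INI `settings.cfg`
whose defaults are pinned by the test suite, and by a deployment state
machine (boot → initial wait → sensing ⇄ resting → shutdown) that runs
against *simulated* hardware: a synthetic benthic scene renderer, a
battery-voltage ramp, a byte-counting storage model, and a simulated
clock, so a 72-hour deployment replays in seconds, bit-reproducibly.

The package is aimed at people building or tuning camera traps for
benthic ecology (octopus dens, baited stations, macrofauna surveys) who
need to answer: *will this threshold catch my animal, and how many false
triggers will the currents cost me?* — before committing a three-day
battery to the question.

## Worked example

Simulate a short deployment over a drifting, noisy seafloor with one
fast target pass, then score it against the generator's ground truth:

```sh
cat > scene.cfg << 'EOF'
[scene]
duration_frames = 300
seed = 44
[target1]
entry_frame = 150
velocity = (16, 0)
start_center = (-25, 120)
contrast = 60
EOF

octotrigger run --source sim:scene.cfg --out runs/
octotrigger evaluate --deployment runs/D07042022-T120000
```

which prints (numbers from this exact invocation):

```
deployment D07042022-T120000: 1 images, 95 TEIs, exit=end_of_input
ground-truth windows written to runs/D07042022-T120000/truth.json
expected events:            1
matchable events:           1
matched events:             1
sensitivity:                1.000
false triggers:             0
false-trigger rate (/h):    0.000
images captured:            1
intervalometer equivalent:  454
duration (h):               0.13
```

One target pass, one trigger, one stored full-resolution image — against
the 454 a fixed-interval time-lapse at the same sensing cadence would
have taken over the same span. `octotrigger replay --deployment <dir>` reconstructs the state
trace (waiting → sensing → resting → sensing → shutdown) from the
deployment log alone. The same machinery is available as a library:

```python
from octotrigger import default_settings, run_deployment, HardwareContract
from octotrigger import SimulatedCamera, SceneSpec, TargetSpec

s = default_settings()                      # every packaged default
hw = HardwareContract(camera=SimulatedCamera(
    SceneSpec(duration_frames=900, seed=22),
    [TargetSpec(entry_frame=200, velocity=(16, 0),
                start_center=(-25, 120), contrast=60)]))
rec = run_deployment(hw, s, "runs/")
print(rec.images_captured, rec.exit_reason)   # -> 1 end_of_input
```

Each deployment folder contains `settings.cfg` (the snapshot), `log.csv`
(every boot/evaluation/capture/rest/shutdown event with voltage and free
space), `full/` (triggered captures) and `tei/` (the evaluated TEI
sequence, kept so trigger decisions can be re-derived offline).

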