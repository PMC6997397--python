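"""Quantify a rendered time-lapse frame by frame.

Simulates a heated spheroid, renders two-channel frames, then runs the
measurement stack — segmentation, 36-diameter shape metrics, whole-image
mean PI and the angle-averaged radial PI profile — on a selection of days.
"""

import numpy as np

from spheroquant import (
    RenderConfig,
    SimConfig,
    TreatmentSpec,
    generate_timelapse,
    quantify_frame,
    radial_profile,
)

tl = generate_timelapse(
    SimConfig(seed=3),
    TreatmentSpec.heat(160.0),
    RenderConfig(),
    frame_interval_h=24.0,
)

print(f"{'day':>4s} {'truth um':>9s} {'measured um':>11s} {'mean PI':>8s}")
for rf in tl.frames[:8:2] + tl.frames[8::6]:
    metrics, pi_mean, mask = quantify_frame(rf.frame)
    day = rf.state.t / 24
    print(f"{day:4.0f} {rf.diameter_um:9.1f} {metrics.mean_diameter:11.1f} "
          f"{pi_mean:8.4f}")
# measured diameters track the simulator's ground truth within ~1%;
# mean PI rises sharply in the first days after heating and fades as
# dead cells are shed into the corona.

# radial PI distribution on day 2: heat-killed cells stain centre-weighted
rf = tl.frames[2]
metrics, _, _ = quantify_frame(rf.frame)
prof = radial_profile(rf.frame, metrics.centroid, gaussian_sigma=2.0)
r = prof.radius
inner = prof.intensity[r <= 0.3 * rf.state.radius_um].mean()
outer = prof.intensity[(r >= 0.7 * rf.state.radius_um)
                       & (r <= rf.state.radius_um)].mean()
print(f"day 2 radial PI: inner mean {inner:.3f} vs outer mean {outer:.3f}")
# the inner/outer contrast > 1 reflects the centre-enhanced staining seen
# after heating, the opposite of the edge-weighted pattern after radiation.
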