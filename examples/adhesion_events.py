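"""Adhesion metrics and unbinding events on a retract curve.

Builds a retract with a 1 nN adhesion dip and three discrete unbinding
events, then measures the detachment force, distance, work and events.
"""

from cardioafm.adhesion import adhesion_metrics, detect_unbinding_events
from cardioafm.synthetic import gen_retract_with_adhesion

curve, truth = gen_retract_with_adhesion(
    peak_force=-1e-9, peak_distance=0.3e-6, detach_distance=1e-6,
    event_kinds=("rupture", "tether", "rupture"), noise_sd=5e-12, seed=2)

res = adhesion_metrics(curve, use_separation=False)
# a wider slope window steadies the rupture/tether call against noise
events = detect_unbinding_events(curve, min_step=0.1e-9, use_separation=False,
                                 slope_window=40)

print(f"max adhesion force: {res.max_adhesion_force * 1e9:.2f} nN")
print(f"distance at max:    {res.distance_at_max * 1e6:.2f} um")
print(f"work of adhesion:   {res.work_of_adhesion * 1e15:.2f} fJ")
for ev in events:
    print(f"  {ev.kind:8s} at {ev.position * 1e6:.2f} um, "
          f"step {ev.force_step * 1e9:.2f} nN")
# Ruptures (loading ramp before the step) are receptors anchored to the
# cytoskeleton; tethers (force plateau) are membrane nanotubes pulled from
# unanchored receptors.
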