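"""The spherical parameter map: bifurcation curves and brain-state regions.

Loads the packaged curve cache for the default sphere (radius 0.4), lists
the located onset/offset curves, and classifies a few parameter points into
rest / bursting / bistable regions with the deterministic attractor probe.
"""

from dynamotypes import SpherePoint, classify_region, load_packaged_curves

curves = load_packaged_curves()
print(f"sphere radius R = {curves.R}, curve resolution {curves.resolution} rad\n")
for c in curves.curves:
    print(f"  {c.label:5s} {len(c):4d} samples, arc {c.arc_lengths()[-1]:.2f} rad, "
          f"role: {c.role}")

print("\nregion classification (theta = colatitude, phi = longitude):")
for theta, phi, note in [
    (0.5, 3.0, "northern rest region"),
    (1.8, 1.5, "interior of the bursting region"),
    (2.1, 0.175, "bistable sliver between the SH and SN curves"),
]:
    label = classify_region(SpherePoint(theta, phi, curves.R))
    print(f"  ({theta:4.2f}, {phi:5.3f}) -> {label.value:9s} ({note})")
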