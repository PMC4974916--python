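"""Dipole directivity of a communicating tag pair.

Two harness-mounted tags behave as tilted dipole antennas; their relative
in-plane orientation (theta for the transmitter, phi for the receiver)
adds between -6 and 0 dB to the received signal strength.
"""

import numpy as np

from proxcal import propagation

print("In-plane radiation pattern I(theta) = (1 + cos^2 theta)/2")
for theta in (0, 45, 90):
    print(f"  I({theta:3d}) = {propagation.in_plane_pattern(theta):.3f}")
print("  -> broadside radiates twice the front/back power:",
      propagation.in_plane_pattern(0) / propagation.in_plane_pattern(90))

print("\nPairwise directivity delta(theta, phi) in dB")
for theta, phi, label in [
    (0, 90, "side by side (maximum)"),
    (90, 0, "parallel along line of sight (minimum)"),
    (90, 180, "antiparallel (same minimum)"),
    (45, 45, "oblique"),
]:
    print(f"  delta({theta:3d},{phi:3d}) = {propagation.directivity_db(theta, phi):7.3f} dB   {label}")

print(f"\nOrientation average (power scale): {propagation.mean_directivity_db():.3f} dB")
print("With unknown, uniformly random orientations a pulse loses ~2.5 dB on")
print("average relative to the best-case side-by-side geometry.")

params = propagation.PropagationParams(kappa=20.0, beta=-0.2)
print("\nExpected RSSI, kappa=20 dB, beta=-0.2 dB/m (open-habitat-like):")
for r in (1, 5, 10, 20):
    print(f"  r = {r:2d} m -> {propagation.expected_rssi(r, params):7.2f} dB")
print("RSSI falls fastest at short range, which is why close encounters")
print("are the best-resolved by a proximity logger.")
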