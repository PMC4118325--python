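"""How fast can the cart travel and still scan every stem enough times?

The scanner sweeps a vertical plane at a fixed rate, so forward speed sets
the along-track spacing of scan planes.  A 10 mm stem must be crossed by at
least three planes to survive the detection pipeline's presence filtering.
"""

from stemsense import max_travel_speed

for min_scans in (1, 2, 3, 5):
    v = max_travel_speed(stem_diameter_mm=10, scan_rate_hz=10, min_scans=min_scans)
    print(f"stem 10 mm, 10 Hz, >= {min_scans} scans per stem: "
          f"max speed {v:.3f} km/h ({v / 0.036:.0f} cm/s)")

print()
print("The 3-scan requirement gives the operating speed used in the field:")
print(f"  {max_travel_speed(10, 10, 3):.3f} km/h")
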