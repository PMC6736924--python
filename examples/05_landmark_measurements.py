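"""Tape-measure landmark spans before and after insufflation.

Mirrors the intraoperative feasibility measurements: distances between
palpable abdominal landmarks (umbilicus to each anterior superior iliac
spine, xiphisternum to pubic symphysis), along the skin surface (tape)
or straight-line (calipers), in cm.  On the phantom the insufflated
skin is the analytic ground truth, so the spans grow ventrally.
"""

from pneumosim import PhantomSpec, generate_phantom, landmark_report

pair = generate_phantom(PhantomSpec(seed=3))
report = landmark_report(
    pair.deflated["skin"], pair.inflated_truth["skin"],
    pair.landmarks, pair.landmark_positions("inflated"), mode="surface")

print(f"surface-path (tape measure) spans, cm:")
for name, row in report.rows.items():
    print(f"  {name:34s} {row['normal']:6.2f} -> {row['insufflated']:6.2f} "
          f"(change {row['change']:+.2f})")

chord = landmark_report(
    pair.deflated["skin"], pair.inflated_truth["skin"],
    pair.landmarks, pair.landmark_positions("inflated"), mode="chord")
print("chord (caliper) spans, cm:")
for name, row in chord.rows.items():
    print(f"  {name:34s} {row['normal']:6.2f} -> {row['insufflated']:6.2f} "
          f"(change {row['change']:+.2f})")
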