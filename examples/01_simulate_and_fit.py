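"""Simulate one stance-phase recording and recover its material properties.

A heel pad with known elastic modulus E, viscous modulus eta and
unloaded thickness h0 is walked through one simulated step; the
pipeline then re-derives the six clinical properties from the recorded
thickness / force / area channels alone.
"""

from heelpad import GaitParams, KVParams, extract_properties, simulate_stance

truth = KVParams(E=265.5, eta=66.59, h0=14.85)  # healthy-group central values
gait = GaitParams(noise_sd_thickness=0.1, noise_sd_force=2.0, seed=42)

recording = simulate_stance(truth, gait)
props = extract_properties(recording)

print(f"true parameters:   E={truth.E:.1f} kPa  eta={truth.eta:.2f} kPa*s  "
      f"h0={truth.h0:.2f} mm")
print(f"fitted parameters: E={props.E:.1f} kPa  eta={props.eta:.2f} kPa*s  "
      f"h0={props.h0:.2f} mm")
print(f"peak strain {props.peak_strain:.1f} %   peak stress "
      f"{props.peak_stress:.1f} kPa   EDR {props.edr:.1f} %")
print(f"fit residual RMS {props.residual_rms:.2f} kPa")
print()
print("The fitted moduli land within a few per cent of the generating values")
print("despite realistic measurement noise (0.1 mm thickness, 2 N force);")
print("peak stress sits at the ~140 kPa scale reported for healthy heels.")
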