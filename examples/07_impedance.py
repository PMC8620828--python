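"""Skin-electrode impedance from voltage-divider bench readings.

With a 1 kOhm series resistor, the oscilloscope peak amplitudes across
the resistor (VA) and the skin-electrode interface (VB) give the
impedance magnitude Z = R * VA / VB.
"""

from ecgpair import compute_impedance

readings = [  # (VA volts, VB volts, frequency Hz)
    (0.61, 0.10, 31.41),
    (1.00, 0.04, 26.51),
    (0.90, 0.06, 80.65),
]
for va, vb, f in readings:
    m = compute_impedance(R=1.0, VA=va, VB=vb, frequency=f)
    print(f"VA={m.VA:5.2f} V  VB={m.VB:5.2f} V  @ {m.frequency:6.2f} Hz"
          f"   ->   Z = {m.Z:6.1f} kOhm")
# Dry leather electrodes run tens of kOhm — higher than gelled Ag/AgCl,
# which is why contact quality dominates the signal-loss budget.
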