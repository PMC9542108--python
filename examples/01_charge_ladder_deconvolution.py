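"""Deconvolve an intact mass from a charge-reduced product-ion ladder.

Proton-transfer charge reduction moves a protein cation to lower charges
(higher m/z). Two adjacent product peaks are enough to fix the charges
without isotope resolution, and each member then projects to the same
neutral mass M = z*(m/z) - z*p.
"""

from tptcr import (
    ChargeLadder,
    deconvolve_mass,
    infer_charge_pair,
    mz_from_mass,
    predict_reduced_ladder,
)

# the two charge-reduced products of the FABP1-bezafibrate complex
mz_low, mz_high = 2097.5, 2446.9

z_low, z_high = infer_charge_pair(mz_low, mz_high)
print(f"inferred charges: {z_low}+ and {z_high}+")

mass, spread = deconvolve_mass(ChargeLadder(((mz_low, z_low), (mz_high, z_high))))
print(f"deconvolved neutral mass: {mass:.1f} Da (member disagreement {spread:.2f} Da)")

precursor = mz_from_mass(mass, 8)
print(f"back-projected 8+ precursor: m/z {precursor:.1f}")

ladder = predict_reduced_ladder(precursor, 8, 3)
print("predicted product ladder from that precursor:")
for mz, z in ladder:
    print(f"  {z}+  m/z {mz:.1f}")

# The two products agree on one mass to ~0.1 Da, which is what lets a
# low-resolution instrument report an intact mass; the 8+ precursor they
# imply sits at m/z 1835, inside the m/z 2000 quadrupole isolation limit.
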