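"""Identify the bound drug from the HCD neutral loss of the complex.

Collisional activation of the 8+ complex ejects the ligand as a *neutral*:
the free protein appears at the same charge, shifted down by the ligand
mass, and no ion shows up at the free drug's own m/z. The mass difference
between precursor and product, times the charge, is the ligand mass.
"""

from tptcr import HCDConfig, IonSpecies, assign_ligand, neutral_loss, small_molecule_ions
from tptcr.simulate import BEZAFIBRATE_FORMULA, COMPLEX_MASS, simulate_hcd

complex_ion = IonSpecies("FABP1+bezafibrate", COMPLEX_MASS, 8)
ms2 = simulate_hcd(complex_ion, BEZAFIBRATE_FORMULA, HCDConfig(nce=7.0))

print("HCD MS/MS peaks (7% NCE):")
for mz, inten in zip(ms2.mz, ms2.intensity):
    print(f"  m/z {mz:8.2f}  intensity {inten:.2f}")

delta = neutral_loss(ms2.mz.max(), ms2.mz.min(), z=8)
hit = assign_ligand(delta, tol=0.5)
print(f"neutral loss: {delta:.3f} Da -> assigned to {hit.name} ({hit.mass:.3f} Da)")

ions = small_molecule_ions(BEZAFIBRATE_FORMULA)
print(
    "free drug would appear at "
    f"[M+H]+ {ions.protonated:.3f}, [M+Na]+ {ions.sodiated:.3f}, [M+K]+ {ions.potassiated:.3f}"
    " - none of these are in the MS/MS spectrum (neutral departure)."
)
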