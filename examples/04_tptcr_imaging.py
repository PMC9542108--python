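"""Targeted-PTCR imaging on a liver phantom with a blood vessel.

Four precursors (free FABP1, the drug complex, heme-bound alpha-globin,
ACBP) are multiplexed, charge-reduced together, and imaged from their
product ions only. The vascular marker (globin) and the tissue-resident
complex light up complementary regions; a 2 h vs 6 h post-dose comparison
shows the drug clearing with its ~4.5 h half-life.
"""

import numpy as np
from scipy.stats import pearsonr

from tptcr import build_target_table, generate_phantom, product_ion_image, region_contrast
from tptcr.simulate import (
    ACBP_MASS,
    ALPHA_GLOBIN_HEME_MASS,
    APO_FABP1_MASS,
    COMPLEX_MASS,
)

table = build_target_table(
    [
        ("FABP1+bezafibrate", COMPLEX_MASS, 8),
        ("heme-alpha-globin", ALPHA_GLOBIN_HEME_MASS, 8),
        ("apo-FABP1", APO_FABP1_MASS, 8),
        ("ACBP", ACBP_MASS, 6),
    ],
    n_reduced=2,
)
print("target table (precursor -> monitored charge-reduced products):")
for row in table:
    products = ", ".join(f"{mz:.1f} ({z}+)" for mz, z in zip(row.product_mzs, row.product_charges))
    print(f"  {row.name:<20} {row.precursor_mz:7.1f} ({row.precursor_z}+) -> {products}")

dataset = generate_phantom(seed=11)  # 64x64, 2 h post-dose
truth = dataset.truth

img_complex = product_ion_image(dataset, table.row("FABP1+bezafibrate"))
img_globin = product_ion_image(dataset, table.row("heme-alpha-globin"))

r, _ = pearsonr(img_complex.data.ravel(), truth.abundance_maps["FABP1+bezafibrate"].ravel())
print(f"\ncomplex image vs ground truth: Pearson r = {r:.3f}")
v, b = truth.masks["vessel"], truth.masks["bulk"]
print(f"globin vessel/bulk contrast:  {region_contrast(img_globin, v, b)}")
print(f"complex vessel/bulk contrast: {region_contrast(img_complex, v, b)}")

m2 = img_complex.data[b].mean()
d6 = generate_phantom(seed=11, t_hours=6.0)
m6 = product_ion_image(d6, table.row("FABP1+bezafibrate")).data[b].mean()
print(f"bulk-mean complex intensity 2 h: {m2:.1f}, 6 h: {m6:.1f} (ratio {m2 / m6:.2f})")

# The complex maps to bulk tissue (absent from the vessel: contrast ~0)
# while globin maps to the vessel (contrast inf: zero bulk signal), and
# the 2 h image is ~1.85x brighter than 6 h - exponential clearance with
# a 4.5 h half-life over a 4 h interval.
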