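# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical choices that matter.

## Mass and charge arithmetic

All electrospray relations use the charge-carrier (cation) masses:
proton 1.007276 Da, Na+ 22.989218 Da, K+ 38.963158 Da. The electron mass
is folded into these cation masses and otherwise neglected — a <0.01 Da
per charge approximation, far below the precision of low-resolution
native spectra. Element masses ship as a versioned plain-text table
(C, H, N, O, P, S, Cl, Na, K, Fe; monoisotopic and average) that can be
overridden per call.

Protein masses are treated as average-mass centroids, which is what a
low-resolution analyser reports for an unresolved isotope envelope;
small-molecule (ligand) masses are monoisotopic by default. Both are
selectable per call. Bezafibrate's monoisotopic mass from its formula is
361.108 Da (average 361.82 Da); both round to the ~361 Da neutral loss
seen in complex dissociation.

**Adjacent-pair charge inference.** For two peaks assumed to be adjacent
charge states of one protonated species,
`z = round(1 + (mz_low − p)/(mz_high − mz_low))`. If the raw estimate is
more than 0.3 charge units from an integer the call raises an
ambiguous-charge error rather than guessing; spacings below 1 m/z are
rejected the same way. For exact adjacent pairs of masses 5–20 kDa at
z = 3–25 the inference is provably unique against brute-force enumeration
(tested).

**Reduced-ladder prediction.** From a precursor (m/z, z), products at
z−1 … z−k follow by projecting the deconvolved neutral mass back through
the m/z relation. Ladders are strictly increasing in m/z as charge falls.

Printed m/z values taken as *inputs* are treated as ±0.5 (a value such as
"m/z 1835" may be truncated or rounded); toolkit *outputs* are reported
to one decimal, matching the precision such values are usually quoted at.

## Synthetic-data generator

The generator emulates the data types of a targeted native ambient MS
experiment on liver tissue. It is ground truth for every downstream test,
so its defaults are the study conditions, fixed once:

- **Charge envelope**: Gaussian weights over integer charge, centre
  z0 = 8 for the ≈14.7 kDa species (native, folded proteins take few
  protons), width σ_z = 0.7 charges.
- **Peak shape**: Gaussian with FWHM = m/R; resolving power default
  R = 1000, the regime where isotope envelopes are unresolved and
  charge-reduced ladders are the only route to an intact mass. The
  rendered integral of each peak equals its centroid intensity (within
  1%, tested). Additive per-bin Gaussian noise is left unclipped
  (baseline-subtracted convention) so robust noise estimators see a
  symmetric distribution; optional sqrt-intensity shot noise is off by
  default.
- **SIM mode**: intensity gain g = 20 with unchanged noise floor — the
  ion-accumulation interpretation of narrow-window scanning. The
  alternative (noise-averaging) model was rejected for simplicity; the
  linear-SNR-in-g contract is tested to 20% over 50 replicates.
- **PTCR**: the number of proton transfers k per precursor follows a
  Poisson(μ) count conditioned on 1 ≤ k < z, with the Poisson zero class
  surviving at the precursor m/z; μ = 1.5 by default, which makes z−1 and
  z−2 the two strongest products. No kinetic data exist to calibrate μ,
  so it is exposed in the API. Intensities are redistributed by the
  *expected* fractions rather than sampled, so total ion current is
  conserved exactly and fixed seeds give bit-identical output; optional
  seeded m/z jitter and intensity CV model measurement noise.
- **HCD**: a fraction p_d(NCE) of the complex dissociates; default curve
  is a logistic in NCE centred at 5% with width 1.5%, giving p_d ≈ 0.79
  at the 7% NCE working point — monotone non-decreasing and bounded in
  [0, 1] as any activation curve must be. The ligand departs as a
  neutral (free protein at the same charge, no free-ligand ion), the
  experimentally observed, unusual pathway; the common charged-ligand
  pathway is implemented behind a flag, off by default.
- **Tissue phantom**: a 64×64 grid (100 µm pixels) of an elliptical
  tissue section containing a circular blood vessel (radius 6 px).
  Heme-bound α-globin localises to the vessel; FABP1 (base abundance
  1000), the drug complex (base 60), and ACBP (base 300) localise to
  bulk tissue. Complex abundance carries the clearance factor
  2^(−t/t_half) with t_half = 4.5 h, the midpoint of the 4–5 h plasma
  half-life reported for bezafibrate in rats; the default acquisition is
  2 h post-dose. Per-pixel log-normal heterogeneity (σ = 0.15) and m/z
  jitter (σ = 0.05) provide realistic spatial and spectral variation.
  Pixels are rastered row-major, mimicking line-scan acquisition.
  Untargeted "interferent" ions can be injected at arbitrary m/z — they
  are never charge-reduced, because only isolated precursors enter the
  PTCR reaction.

Randomness uses three independently spawned RNG streams (abundance,
spectral jitter, interferents), so adding an interferent provably cannot
perturb any other draw — the precursor-exclusion claim is testable
bit-exactly.

The phantom does *not* emulate: lipid/chemical background, ion mobility,
space charge, detector saturation, registration to optical images, or
real histology. Tests passing on the phantom demonstrate that the
*pipeline* is correct and specific under the stated noise model, not that
a given real tissue section would yield these images.

ACBP's neutral mass is set to a nominal 9913 Da (≈10 kDa); it serves as a
third bulk-tissue protein in the multiplexed panel and none of the
reported quantities depend on its exact value. The heme-bound α-globin
mass (15812.2 Da) is fixed by its 7+ product at m/z 2259.9.

## Deconvolution

- **Centroiding**: local maxima above `snr × σ̂` with matching prominence,
  where (baseline, σ̂) come from a two-pass median/MAD estimate — the
  second pass masks bins >3σ̂ above baseline so peaks occupying a large
  fraction of a narrow SIM window don't inflate the noise estimate.
  Apexes are refined by a parabolic fit to log-intensity over the upper
  half of the peak (exact for Gaussian shapes), falling back to the
  intensity-weighted centroid. Reported intensity is the FWHM-window area
  divided by 0.761 (the Gaussian area fraction inside the FWHM). Peaks
  wider than 1.12× the instrument FWHM (when the resolving power is
  supplied) are flagged as merged: an unresolved pair separated by
  FWHM/2 widens the apparent peak by ~13%.
- **Charge-series finding**: every peak pair is tested as an
  adjacent-charge hypothesis; consistent seeds grow greedily in both
  charge directions, accepting the nearest peak within mz_tol = 0.2
  (the low-resolution PTCR regime; configurable). Candidates score
  `members − λ·spread/mz_tol` with λ = 1 — simple and monotone in
  evidence. Candidates whose member peaks are a subset of a larger
  candidate's are dropped as aliases: a pair that skips a charge state
  (e.g. 8+ and 6+ read as 4+/3+) is internally consistent at a divided
  mass, but the maximal ladder explains strictly more evidence. Charges
  above z_max = 30 are not considered (native proteins well under
  100 kDa).
- **Mass estimate**: unweighted mean of per-member z·mz − z·p (product
  intensities reflect PTCR kinetics, not mass accuracy); the spread
  (max − min of member masses) is reported as an internal consistency
  measure. A mass needs ≥ 2 members.
- **Species matching**: nearest mass within 2 Da; exact ties break
  alphabetically and are flagged.

Under the default recovery conditions (14.7 kDa species, R = 1000, PTCR
μ = 1.5, weakest used ladder member at SNR ≈ 20) the deconvolved mass
lands within 0.5 Da of truth in ≥ 95 of 100 seeded runs, and 200
pure-noise scans produce no 3-member ladder with spread < 0.1 Da.

## Targeted imaging

Target tables store (name, neutral mass, precursor charge, product
charges); all m/z values are derived on access so table and masses cannot
drift apart. Precursors at or above the quadrupole isolation limit
(default m/z 2000, the instrument constraint on multiplexed isolation;
overridable) are rejected with an error naming every offender.

Ion images sum intensity over each target's *product* windows only
(half-width 0.5 m/z by default — the width of low-resolution
charge-reduced peaks), explicitly excluding the precursor window. Default
normalization is none: per-pixel TIC normalization is available but can
distort contrast when vessel and bulk chemistry differ. Composites
min–max scale each channel independently (absolute units are arbitrary in
the simulator and instrument-dependent in practice). Missing pixels are
flagged in a QC mask and render as 0. Region contrast is the ratio of
mask means, with +inf as the sentinel for zero-signal denominators.

## MS/MS

Neutral loss ΔM = z·(precursor − product) m/z at retained charge z;
ligand assignment is nearest-candidate within 0.5 Da (low-resolution
intact masses) over a shipped CSV of candidates (bezafibrate, the
endogenous fatty-acid ligands of FABP1, water). Adduct prediction gives
singly charged [M+H]+/[M+Na]+/[M+K]+ from the cation masses above.

Fragment generation covers b/y ions (no internal fragments, no PTMs) at
1–2 charges, monoisotopic, from the standard residue-mass table; matching
is greedy nearest-m/z within 10 ppm (high-resolution MS/MS), each
observed peak consumed once. Coverage counts backbone cleavage sites hit
by b_i or y_(L−i), over L−1 sites.

## I/O

mzML reading and writing are self-contained (64-bit little-endian floats,
base64; the reader also accepts 32-bit and zlib) and round-trip centroid
data bit-exactly. Imaging datasets use imzML via pyimzml: continuous mode
when all pixels share an m/z axis, processed mode otherwise (the phantom's
jittered centroid axes differ per pixel, so it writes as processed);
pixel (row, col) maps to 1-based (x = col+1, y = row+1). Pixels with
empty spectra are omitted on write and QC-flagged on read; duplicate
coordinates are an error naming the pixel. CSV files are comma-separated
UTF-8 with a mandatory header. Every CLI run writes a JSON manifest
(config, seed, input SHA-256 hashes) sufficient to reproduce outputs.

## Known limitations

- Charge inference assumes *adjacent* charge states; a pair that skips a
  state is only corrected when a third member exposes the alias.
- The scoring function is deliberately simple; in very dense multiplexed
  spectra with overlapping ladders, candidates should be reviewed rather
  than taken top-1.
- The simulator's SIM model ignores space-charge limits on accumulation,
  so SNR gain is exactly linear in g.
- No isotope modelling: the toolkit is for the low-resolution regime by
  design; isotope-resolved charge determination is out of scope.
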