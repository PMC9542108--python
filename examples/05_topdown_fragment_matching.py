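"""Confirm a protein identity from top-down b/y fragment matching.

Intact-protein MS/MS produces b ions (N-terminal prefixes) and y ions
(C-terminal suffixes). Matching observed product m/z against the
theoretical list and counting the backbone cleavage sites hit gives the
sequence coverage used to call an identification.
"""

from tptcr import fragment_ions, match_fragments

# a short FABP-like toy sequence
sequence = "MSFSGKYQLQSQENFEAF"
theoretical = fragment_ions(sequence, types=("b", "y"), max_charge=2)
print(f"{len(theoretical)} theoretical b/y fragments for {len(sequence)} residues")

# pretend the instrument recorded 60% of them, at +3 ppm mass error
observed = [f.mz * (1 + 3e-6) for i, f in enumerate(theoretical) if i % 5 != 0]
report = match_fragments(theoretical, observed, tol_ppm=10.0, sequence_length=len(sequence))

print(f"matched fragments: {len(report.matches)}")
print(f"sequence coverage: {report.coverage:.2f}")
for m in report.matches[:5]:
    f = m.fragment
    print(
        f"  {f.ion_type}{f.index}^{f.charge}+  theo {f.mz:.4f}  obs {m.observed_mz:.4f}"
        f"  ({m.delta_ppm:+.1f} ppm)"
    )

# Coverage near 1.0 means nearly every backbone cleavage site is
# supported by at least one matched fragment - strong evidence the
# spectrum comes from this sequence.
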