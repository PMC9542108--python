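"""Tandem-MS analysis: neutral-loss ligand assignment, small-molecule
adduct ions, and a minimal top-down b/y fragment matcher.

The neutral-loss path covers the unusual dissociation of the
FABP1-bezafibrate complex, where collisional activation ejects the drug
as a neutral so the free protein appears at the *same* charge state,
ΔM = z·(precursor m/z − product m/z) below the complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
from pyteomics import mass as _pt_mass

from .errors import InvalidInputError
from .masses import ADDUCT_MASSES, PROTON_MASS, MolecularFormula, molecular_mass

WATER_MASS = molecular_mass("H2O", "monoisotopic")

#: Monoisotopic residue masses, standard 20 amino acids (pyteomics table).
RESIDUE_MASSES = {
    aa: _pt_mass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}


def neutral_loss(precursor_mz: float, product_mz: float, z: int) -> float:
    """Neutral mass lost when precursor and product share charge z.

    ΔM = z·(precursor m/z − product m/z). Requires the product below the
    precursor; the retained charge makes ΔM independent of which charge
    state of the same dissociation is used.
    """
    if z < 1:
        raise InvalidInputError("charge must be >= 1")
    if product_mz >= precursor_mz:
        raise InvalidInputError("product m/z must be below precursor m/z")
    return z * (precursor_mz - product_mz)


@dataclass(frozen=True)
class LigandCandidate:
    """A small molecule that could account for an observed neutral loss."""

    name: str
    formula: MolecularFormula

    @property
    def mass(self) -> float:
        return molecular_mass(self.formula, "monoisotopic")


def load_ligand_candidates() -> list[LigandCandidate]:
    """Candidate table shipped with the package (drug plus endogenous
    fatty-acid ligands of FABP1 and water)."""
    ref = resources.files("tptcr.data").joinpath("ligand_candidates.csv")
    out = []
    for line in ref.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        name, formula = line.split(",")
        out.append(LigandCandidate(name.strip(), MolecularFormula.parse(formula.strip())))
    return out


def assign_ligand(
    delta_mass: float,
    candidates: Sequence[LigandCandidate] | None = None,
    tol: float = 0.5,
) -> LigandCandidate | None:
    """Candidate whose monoisotopic mass is nearest ΔM within tol, or None."""
    if tol <= 0:
        raise InvalidInputError("tolerance must be > 0")
    if candidates is None:
        candidates = load_ligand_candidates()
    ranked = sorted(candidates, key=lambda c: (abs(delta_mass - c.mass), c.name))
    if not ranked or abs(delta_mass - ranked[0].mass) > tol:
        return None
    return ranked[0]


class AdductIons(NamedTuple):
    protonated: float
    sodiated: float
    potassiated: float


def small_molecule_ions(formula: MolecularFormula | str) -> AdductIons:
    """Singly charged [M+H]+, [M+Na]+, [M+K]+ m/z for a neutral molecule."""
    m = molecular_mass(formula, "monoisotopic")
    return AdductIons(
        protonated=m + ADDUCT_MASSES["proton"],
        sodiated=m + ADDUCT_MASSES["sodium"],
        potassiated=m + ADDUCT_MASSES["potassium"],
    )


@dataclass(frozen=True)
class Fragment:
    ion_type: str  # 'b' | 'y'
    index: int
    charge: int
    mz: float


def fragment_ions(
    sequence: str,
    types: Sequence[str] = ("b", "y"),
    max_charge: int = 1,
) -> list[Fragment]:
    """Theoretical b/y fragment m/z values for a peptide/protein sequence.

    Singly charged: b_i = sum(residues 1..i) + p; y_i = sum(residues
    L−i+1..L) + H2O + p. Higher charges via (m + (c−1)·p)/c. The full-
    length b_L / y_L (no cleavage) are excluded, so each charge state
    contributes 2·(L−1) fragments when both types are requested.
    """
    if len(sequence) < 2:
        raise InvalidInputError("sequence must have at least 2 residues")
    bad = set(sequence) - set(RESIDUE_MASSES)
    if bad:
        raise InvalidInputError(f"unknown residues: {sorted(bad)}")
    if max_charge < 1:
        raise InvalidInputError("max_charge must be >= 1")
    masses = np.array([RESIDUE_MASSES[aa] for aa in sequence])
    prefix = np.cumsum(masses)
    L = len(sequence)
    frags = []
    for i in range(1, L):
        b1 = prefix[i - 1] + PROTON_MASS
        y1 = (prefix[-1] - prefix[L - i - 1]) + WATER_MASS + PROTON_MASS
        for c in range(1, max_charge + 1):
            if "b" in types:
                frags.append(Fragment("b", i, c, (b1 + (c - 1) * PROTON_MASS) / c))
            if "y" in types:
                frags.append(Fragment("y", i, c, (y1 + (c - 1) * PROTON_MASS) / c))
    return frags


@dataclass(frozen=True)
class FragmentMatch:
    fragment: Fragment
    observed_mz: float
    delta_ppm: float


@dataclass
class FragmentMatchReport:
    """Matched fragments plus sequence coverage.

    Coverage counts backbone cleavage sites (1..L−1) hit by a matched b_i
    or y_(L−i), divided by L−1.
    """

    matches: list[FragmentMatch]
    coverage: float
    sequence_length: int


def match_fragments(
    theoretical: Sequence[Fragment],
    observed_mzs: Sequence[float],
    tol_ppm: float = 10.0,
    sequence_length: int | None = None,
) -> FragmentMatchReport:
    """Greedy nearest-m/z fragment matching within a ppm tolerance.

    Each observed peak is consumed at most once. ``sequence_length``
    defaults to the largest fragment index + 1.
    """
    if tol_ppm <= 0:
        raise InvalidInputError("tol_ppm must be > 0")
    if sequence_length is None:
        sequence_length = max((f.index for f in theoretical), default=1) + 1
    observed = sorted(float(m) for m in observed_mzs)
    used = [False] * len(observed)
    matches: list[FragmentMatch] = []
    for frag in sorted(theoretical, key=lambda f: f.mz):
        k = int(np.searchsorted(observed, frag.mz))
        best, best_err = None, None
        for cand in (k - 1, k):
            if 0 <= cand < len(observed) and not used[cand]:
                err = abs(observed[cand] - frag.mz)
                if best_err is None or err < best_err:
                    best, best_err = cand, err
        if best is None:
            continue
        ppm = (observed[best] - frag.mz) / frag.mz * 1e6
        if abs(ppm) <= tol_ppm:
            used[best] = True
            matches.append(FragmentMatch(frag, observed[best], ppm))
    sites = set()
    L = sequence_length
    for m in matches:
        if m.fragment.ion_type == "b":
            sites.add(m.fragment.index)
        else:
            sites.add(L - m.fragment.index)
    sites = {s for s in sites if 1 <= s <= L - 1}
    coverage = len(sites) / (L - 1) if L > 1 else 0.0
    return FragmentMatchReport(matches=matches, coverage=coverage, sequence_length=L)
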