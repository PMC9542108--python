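"""Charge-state arithmetic and molecular mass computation.

All electrospray m/z relations in the toolkit go through this module.
The charge carrier is the proton at its *cation* mass (1.007276 Da);
the electron mass is neglected, a <0.01 Da-per-charge approximation
that is far below the precision of low-resolution native spectra.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Literal, Mapping

from .errors import AmbiguousChargeError, InvalidInputError

#: Mass of the charge carrier (proton cation), Da.
PROTON_MASS = 1.007276

#: Cation masses of the supported adducts, Da (neutral minus one electron).
ADDUCT_MASSES: Mapping[str, float] = {
    "proton": 1.007276,
    "sodium": 22.989218,
    "potassium": 38.963158,
}

MassKind = Literal["monoisotopic", "average"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementMassTable:
    """Monoisotopic and average masses per element symbol.

    The default table is shipped as a plain-text file with the package and
    covers the elements needed for proteins, common adducts and small-drug
    formulas (C, H, N, O, P, S, Cl, Na, K, Fe). A custom table may be
    loaded from any file in the same three-column format.
    """

    def __init__(self, masses: Mapping[str, tuple[float, float]]):
        for sym, (mono, avg) in masses.items():
            if mono <= 0 or avg <= 0:
                raise InvalidInputError(f"non-positive mass for element {sym!r}")
        self._masses = dict(masses)

    @classmethod
    def from_file(cls, path) -> "ElementMassTable":
        masses = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sym, mono, avg = line.split("\t")
                masses[sym] = (float(mono), float(avg))
        return cls(masses)

    @classmethod
    def default(cls) -> "ElementMassTable":
        ref = resources.files("tptcr.data").joinpath("element_masses.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._masses

    def monoisotopic(self, symbol: str) -> float:
        return self._lookup(symbol)[0]

    def average(self, symbol: str) -> float:
        return self._lookup(symbol)[1]

    def _lookup(self, symbol: str) -> tuple[float, float]:
        try:
            return self._masses[symbol]
        except KeyError:
            raise InvalidInputError(f"unknown element symbol {symbol!r}") from None


_DEFAULT_TABLE: ElementMassTable | None = None


def default_element_table() -> ElementMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ElementMassTable.default()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class MolecularFormula:
    """Element composition, e.g. ``MolecularFormula.parse("C19H20ClNO4")``."""

    counts: Mapping[str, int]

    def __post_init__(self):
        table = default_element_table()
        counts = dict(self.counts)
        for sym, n in counts.items():
            if sym not in table:
                raise InvalidInputError(f"unknown element symbol {sym!r}")
            if n < 0:
                raise InvalidInputError(f"negative count for element {sym!r}")
        if sum(counts.values()) == 0:
            raise InvalidInputError("empty molecular formula")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise InvalidInputError(f"cannot parse formula {text!r}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        if pos != len(text) or not counts:
            raise InvalidInputError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __str__(self) -> str:
        return "".join(
            f"{sym}{n if n != 1 else ''}" for sym, n in sorted(self.counts.items()) if n
        )


def molecular_mass(
    formula: MolecularFormula | str,
    kind: MassKind = "monoisotopic",
    table: ElementMassTable | None = None,
) -> float:
    """Sum of element masses times counts, monoisotopic or average."""
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    table = table or default_element_table()
    pick = table.monoisotopic if kind == "monoisotopic" else table.average
    if kind not in ("monoisotopic", "average"):
        raise InvalidInputError(f"unknown mass kind {kind!r}")
    return sum(pick(sym) * n for sym, n in formula.counts.items())


def mz_from_mass(mass: float, z: int, adduct: str = "proton") -> float:
    """Electrospray relation m/z = (M + z·m_adduct) / z.

    ``mass`` is the neutral mass in Da, ``z`` the (positive) charge, and
    ``adduct`` names the charge carrier (proton, sodium or potassium).
    """
    if mass <= 0:
        raise InvalidInputError(f"neutral mass must be positive, got {mass}")
    if z < 1:
        raise InvalidInputError(f"charge must be >= 1, got {z}")
    m_adduct = _adduct_mass(adduct)
    return (mass + z * m_adduct) / z


def mass_from_mz(mz: float, z: int, adduct: str = "proton") -> float:
    """Inverse of :func:`mz_from_mass`: M = z·mz − z·m_adduct."""
    if z < 1:
        raise InvalidInputError(f"charge must be >= 1, got {z}")
    m_adduct = _adduct_mass(adduct)
    if mz <= m_adduct:
        raise InvalidInputError(f"m/z {mz} not above adduct mass {m_adduct}")
    return z * mz - z * m_adduct


def _adduct_mass(adduct: str) -> float:
    try:
        return ADDUCT_MASSES[adduct]
    except KeyError:
        raise InvalidInputError(
            f"unknown adduct {adduct!r}; expected one of {sorted(ADDUCT_MASSES)}"
        ) from None


@dataclass(frozen=True)
class IonSpecies:
    """A charged form of a neutral species: (name, neutral mass M, z, adduct)."""

    name: str
    mass: float
    z: int
    adduct: str = "proton"

    def __post_init__(self):
        if self.mass <= 0:
            raise InvalidInputError("neutral mass must be positive")
        if self.z < 1:
            raise InvalidInputError("charge must be >= 1")
        _adduct_mass(self.adduct)

    @property
    def mz(self) -> float:
        return mz_from_mass(self.mass, self.z, self.adduct)


@dataclass(frozen=True)
class ChargeLadder:
    """Ordered (m/z, z) pairs attributed to one neutral species.

    Charges strictly decrease (so m/z strictly increases) along the ladder;
    this is the substrate for low-resolution intact-mass deconvolution.
    """

    entries: tuple[tuple[float, int], ...]
    provenance: Literal["observed", "predicted"] = "observed"

    def __post_init__(self):
        entries = tuple((float(mz), int(z)) for mz, z in self.entries)
        if len(entries) < 1:
            raise InvalidInputError("charge ladder needs at least one member")
        for (mz_a, z_a), (mz_b, z_b) in zip(entries, entries[1:]):
            if not (z_a > z_b):
                raise InvalidInputError("ladder charges must strictly decrease")
            if not (mz_a < mz_b):
                raise InvalidInputError("ladder m/z must strictly increase")
        if any(z < 1 for _, z in entries):
            raise InvalidInputError("ladder charges must be >= 1")
        if self.provenance not in ("observed", "predicted"):
            raise InvalidInputError(f"bad provenance {self.provenance!r}")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[float, int]]:
        return iter(self.entries)

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(mz for mz, _ in self.entries)

    @property
    def charges(self) -> tuple[int, ...]:
        return tuple(z for _, z in self.entries)


def infer_charge_pair(
    mz_low: float,
    mz_high: float,
    *,
    min_spacing: float = 1.0,
    ambiguity: float = 0.3,
    adduct: str = "proton",
) -> tuple[int, int]:
    """Infer the charges of two adjacent charge states of one species.

    For adjacent protonated charge states z and z−1 observed at m/z values
    ``mz_low`` < ``mz_high``, the charge of the lower-m/z member is

        z = round(1 + (mz_low − p) / (mz_high − mz_low))

    Returns ``(z, z−1)``. If the rounded estimate is farther than
    ``ambiguity`` charge units from an integer, raises
    :class:`AmbiguousChargeError` rather than guessing; spacings below
    ``min_spacing`` are rejected for the same reason.
    """
    if not mz_low < mz_high:
        raise InvalidInputError("mz_low must be below mz_high")
    spacing = mz_high - mz_low
    if spacing < min_spacing:
        raise AmbiguousChargeError(
            f"peak spacing {spacing:.3g} below minimum {min_spacing:.3g}"
        )
    p = _adduct_mass(adduct)
    z_est = 1.0 + (mz_low - p) / spacing
    z = round(z_est)
    if abs(z_est - z) > ambiguity:
        raise AmbiguousChargeError(
            f"charge estimate {z_est:.2f} not within {ambiguity} of an integer"
        )
    if z - 1 < 1:
        raise InvalidInputError(
            f"inferred pair ({z}, {z - 1}) invalid: charge must stay >= 1"
        )
    return z, z - 1


def predict_reduced_ladder(
    precursor_mz: float,
    z: int,
    n_steps: int,
    adduct: str = "proton",
) -> ChargeLadder:
    """Predict the charge-reduced product ladder of a precursor.

    Proton-transfer charge reduction moves a z+ precursor to z−1, z−2, ...
    at m/z values fixed by the neutral mass; the ladder of the first
    ``n_steps`` products is what a targeted product-ion method monitors.
    """
    if n_steps < 1:
        raise InvalidInputError("n_steps must be >= 1")
    if n_steps >= z:
        raise InvalidInputError(
            f"cannot reduce a {z}+ precursor by {n_steps} steps (charge floor is 1)"
        )
    mass = mass_from_mz(precursor_mz, z, adduct)
    entries = [
        (mz_from_mass(mass, z - k, adduct), z - k) for k in range(1, n_steps + 1)
    ]
    return ChargeLadder(tuple(entries), provenance="predicted")
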