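"""Targeted-PTCR method construction and product-ion imaging.

A target table lists each precursor (species, m/z, z) together with the
charge-reduced product m/z values it should yield. Ion images are built
from the *product* windows only: any background ion overlapping a
precursor m/z contributes nothing, which is the specificity advantage of
imaging on charge-reduced ions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, IsolationLimitError
from .masses import mz_from_mass
from .simulate import ImagingDataset
from .spectra import Spectrum

log = logging.getLogger(__name__)

#: Quadrupole isolation upper m/z limit of the reference instrument.
DEFAULT_ISOLATION_LIMIT = 2000.0


@dataclass(frozen=True)
class TargetRow:
    """One multiplexed precursor and its monitored charge-reduced products.

    Only the neutral mass, precursor charge and product charges are stored;
    all m/z values are derived on access so they can never drift apart.
    """

    name: str
    mass: float
    precursor_z: int
    product_charges: tuple[int, ...]

    def __post_init__(self):
        if self.mass <= 0 or self.precursor_z < 1:
            raise InvalidInputError("bad target row: mass > 0 and precursor_z >= 1 required")
        if any(z >= self.precursor_z or z < 1 for z in self.product_charges):
            raise InvalidInputError("product charges must satisfy 1 <= z < precursor_z")

    @property
    def precursor_mz(self) -> float:
        return mz_from_mass(self.mass, self.precursor_z)

    @property
    def product_mzs(self) -> tuple[float, ...]:
        return tuple(mz_from_mass(self.mass, z) for z in self.product_charges)


@dataclass(frozen=True)
class TargetTable:
    rows: tuple[TargetRow, ...]
    isolation_limit: float = DEFAULT_ISOLATION_LIMIT

    def __post_init__(self):
        offenders = [
            (r.name, r.precursor_mz) for r in self.rows if r.precursor_mz >= self.isolation_limit
        ]
        if offenders:
            raise IsolationLimitError(offenders)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def row(self, name: str) -> TargetRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)


def build_target_table(
    species: Sequence[tuple[str, float, int]],
    n_reduced: int = 2,
    isolation_limit: float = DEFAULT_ISOLATION_LIMIT,
) -> TargetTable:
    """Build the multiplexed PTCR target table.

    ``species`` rows are (name, neutral mass Da, precursor charge). For
    each, the first ``n_reduced`` charge-reduced product m/z values are
    derived. Precursors at or above the quadrupole isolation limit raise
    :class:`IsolationLimitError` naming every offender.
    """
    if n_reduced < 1:
        raise InvalidInputError("n_reduced must be >= 1")
    rows = []
    for name, mass, z in species:
        if n_reduced >= z:
            raise InvalidInputError(
                f"{name}: cannot take {n_reduced} reduction steps from charge {z}"
            )
        charges = tuple(range(z - 1, z - 1 - n_reduced, -1))
        rows.append(TargetRow(name, mass, z, charges))
    return TargetTable(tuple(rows), isolation_limit=isolation_limit)


def extract_window(spectrum: Spectrum | None, center: float, half_width: float) -> float:
    """Summed intensity in [center − hw, center + hw].

    Profile spectra are integrated (area); centroid spectra are summed.
    A window outside the scan range returns 0 with a warning log.
    """
    if half_width <= 0:
        raise InvalidInputError("half_width must be > 0")
    if spectrum is None or len(spectrum) == 0:
        return 0.0
    lo, hi = center - half_width, center + half_width
    if hi < spectrum.mz[0] or lo > spectrum.mz[-1]:
        log.warning("extraction window [%.2f, %.2f] outside scan range", lo, hi)
        return 0.0
    sel = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    if spectrum.mode == "profile":
        step = float(np.median(np.diff(spectrum.mz))) if len(spectrum) > 1 else 1.0
        return float(spectrum.intensity[sel].sum() * step)
    return float(spectrum.intensity[sel].sum())


@dataclass
class IonImage:
    """Per-pixel extracted intensity for one target."""

    data: np.ndarray
    target: str
    normalization: str = "none"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError("ion image must be 2-D")
        if np.any(self.data < 0):
            raise InvalidInputError("ion image intensities must be >= 0")
        if self.normalization not in ("none", "tic"):
            raise InvalidInputError(f"unknown normalization {self.normalization!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def product_ion_image(
    dataset: ImagingDataset,
    row: TargetRow,
    half_width: float = 0.5,
    normalization: str = "none",
) -> IonImage:
    """Image a target from its charge-reduced product windows only.

    Each pixel's value is the summed intensity over the row's product m/z
    windows; the precursor window is deliberately excluded so background
    ions overlapping the precursor cannot contribute. Optional per-pixel
    TIC normalization divides by the pixel's total ion current.
    """
    n_rows, n_cols = dataset.shape
    img = np.zeros(dataset.shape)
    for r in range(n_rows):
        for c in range(n_cols):
            spec = dataset.pixel(r, c)
            if spec is None:
                continue
            val = max(
                0.0, sum(extract_window(spec, mz, half_width) for mz in row.product_mzs)
            )
            if normalization == "tic":
                tic = spec.tic
                val = val / tic if tic > 0 else 0.0
            img[r, c] = val
    return IonImage(img, target=row.name, normalization=normalization)


def composite_image(image_red: IonImage, image_blue: IonImage) -> np.ndarray:
    """Two-channel composite: red and blue each min-max scaled to [0, 1].

    Returns an (n_rows, n_cols, 3) float RGB array (green left at zero),
    the rendering used to contrast a vascular marker against a
    tissue-localised target.
    """
    if image_red.shape != image_blue.shape:
        raise InvalidInputError("composite channels must share dimensions")
    out = np.zeros(image_red.shape + (3,))
    out[..., 0] = _minmax(image_red.data)
    out[..., 2] = _minmax(image_blue.data)
    return out


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def region_contrast(image: IonImage, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Ratio of mean intensity in mask_a over mask_b.

    Returns +inf when mask_b is all zero signal but mask_a is not.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if not mask_a.any() or not mask_b.any():
        raise InvalidInputError("contrast masks must be non-empty")
    if np.any(mask_a & mask_b):
        raise InvalidInputError("contrast masks must be disjoint")
    mean_a = float(image.data[mask_a].mean())
    mean_b = float(image.data[mask_b].mean())
    if mean_b == 0.0:
        return math.inf if mean_a > 0 else math.nan
    return mean_a / mean_b
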