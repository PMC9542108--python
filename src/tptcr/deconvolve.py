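"""Peak picking, charge-series detection and low-resolution intact-mass
deconvolution.

The key idea: a set of charge-reduced product ions of one species forms a
ladder of (m/z, z) pairs that all project to the same neutral mass via
M = z·mz − z·p. Adjacent pairs fix the charges without isotope resolution,
so an intact mass can be read out of low-resolution spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks as _find_peaks

from .errors import AmbiguousChargeError, InsufficientEvidenceError, InvalidInputError
from .masses import (
    ChargeLadder,
    infer_charge_pair,
    mass_from_mz,
    mz_from_mass,
)
from .spectra import CentroidPeakList, Peak, Spectrum

#: Fraction of a Gaussian's area inside its FWHM window.
_FWHM_AREA_FRACTION = 0.7610


def centroid(
    spectrum: Spectrum,
    snr_threshold: float = 3.0,
    resolving_power: float | None = None,
) -> CentroidPeakList:
    """Pick peaks from a profile spectrum.

    Local maxima above ``snr_threshold`` times a robust (median absolute
    deviation based) noise estimate are refined by an intensity-weighted
    centroid over their FWHM window; the reported intensity is the peak
    area estimated from that window. If ``resolving_power`` is given,
    peaks measurably wider than the instrument FWHM are flagged as merged
    (unresolved overlaps).

    An all-zero spectrum yields an empty list, not an error.
    """
    if spectrum.mode != "profile":
        raise InvalidInputError("centroid() expects a profile spectrum")
    if len(spectrum) < 3:
        raise InvalidInputError("profile spectrum needs at least 3 samples")
    mz, inten = spectrum.mz, spectrum.intensity
    if not np.any(inten > 0):
        return CentroidPeakList([], source=str(spectrum.metadata.get("scan_type", "")))
    baseline, noise = _robust_noise(inten)
    height = baseline + snr_threshold * noise if noise > 0 else baseline + np.finfo(float).tiny
    # prominence on the same scale as the height threshold suppresses noise
    # ripple on top of broad peaks (which would split one peak into many)
    prominence = snr_threshold * noise if noise > 0 else None
    idx, _ = _find_peaks(inten, height=height, prominence=prominence)
    step = float(np.median(np.diff(mz)))
    peaks: list[Peak] = []
    for i in idx:
        apex = inten[i] - baseline
        half = baseline + apex / 2.0
        lo = i
        while lo > 0 and inten[lo - 1] > half:
            lo -= 1
        hi = i
        while hi < inten.size - 1 and inten[hi + 1] > half:
            hi += 1
        window = slice(lo, hi + 1)
        w = np.clip(inten[window] - baseline, 0.0, None)
        if w.sum() <= 0:
            continue
        c = float(np.sum(mz[window] * w) / w.sum())
        c = _refine_apex(mz[window], w, c)
        area = float(w.sum() * step / _FWHM_AREA_FRACTION)
        fwhm = _interp_fwhm(mz, inten, lo, hi, half)
        merged = False
        if resolving_power is not None:
            # an unresolved pair separated by ~FWHM/2 widens the apparent
            # peak by ~13%; beyond 1.12x the instrument width is suspicious
            merged = fwhm > 1.12 * c / resolving_power
        snr = apex / noise if noise > 0 else float("inf")
        peaks.append(Peak(c, area, snr=snr, merged=merged))
    return CentroidPeakList(peaks, source=str(spectrum.metadata.get("scan_type", "")))


def _interp_fwhm(mz: np.ndarray, inten: np.ndarray, lo: int, hi: int, half: float) -> float:
    """Full width at half maximum with linear interpolation at the crossings."""
    left = mz[lo]
    if lo > 0 and inten[lo] > half >= inten[lo - 1]:
        f = (inten[lo] - half) / (inten[lo] - inten[lo - 1])
        left = mz[lo] - f * (mz[lo] - mz[lo - 1])
    right = mz[hi]
    if hi < inten.size - 1 and inten[hi] > half >= inten[hi + 1]:
        f = (inten[hi] - half) / (inten[hi] - inten[hi + 1])
        right = mz[hi] + f * (mz[hi + 1] - mz[hi])
    return float(right - left)


def _robust_noise(inten: np.ndarray) -> tuple[float, float]:
    """(baseline, noise sigma) via two-pass MAD.

    The second pass masks bins more than 3 sigma above baseline so that
    peaks occupying a sizeable fraction of a narrow scan (SIM windows)
    do not inflate the noise estimate.
    """
    baseline = float(np.median(inten))
    noise = 1.4826 * float(np.median(np.abs(inten - baseline)))
    if noise > 0:
        quiet = inten[inten < baseline + 3 * noise]
        if quiet.size >= 16:
            baseline = float(np.median(quiet))
            noise = 1.4826 * float(np.median(np.abs(quiet - baseline)))
    return baseline, noise


def _refine_apex(mzs: np.ndarray, heights: np.ndarray, fallback: float) -> float:
    """Parabolic fit on log-intensity — exact for a Gaussian peak shape.

    Falls back to the weighted centroid when the window is too small or
    the fit is not concave.
    """
    pos = heights > 0.5 * heights.max()
    if pos.sum() < 3:
        return fallback
    x, y = mzs[pos], np.log(heights[pos])
    a, b, _ = np.polyfit(x - x.mean(), y, 2)
    if a >= 0:
        return fallback
    vertex = float(x.mean() - b / (2 * a))
    if not (mzs[0] <= vertex <= mzs[-1]):
        return fallback
    return vertex


@dataclass
class Deconvolution:
    """A charge-series hypothesis: ladder, neutral mass, spread and score.

    ``spread`` is the max pairwise disagreement (Da) among the per-member
    masses — a ladder-internal consistency measure. A mass is only
    reported for ladders with at least two members.
    """

    ladder: ChargeLadder
    mass: float
    spread: float
    score: float
    species: str | None = None
    delta_mass: float | None = None

    def __post_init__(self):
        if self.spread < 0 or self.mass <= 0:
            raise InvalidInputError("bad deconvolution: mass must be > 0, spread >= 0")
        if len(self.ladder) < 2:
            raise InvalidInputError("a reported mass needs >= 2 ladder members")


def deconvolve_mass(ladder: ChargeLadder, adduct: str = "proton") -> tuple[float, float]:
    """Neutral mass and spread from a charge ladder.

    The mass is the unweighted mean of the per-member estimates z·mz − z·p
    (unweighted because product-ion intensities reflect charge-reduction
    kinetics, not mass accuracy); the spread is their max − min.
    """
    if len(ladder) < 2:
        raise InsufficientEvidenceError("need >= 2 ladder members to deconvolve a mass")
    per_member = [mass_from_mz(mz, z, adduct) for mz, z in ladder]
    return float(np.mean(per_member)), float(max(per_member) - min(per_member))


def find_charge_series(
    peaks: CentroidPeakList | Sequence[Peak],
    z_max: int = 30,
    mz_tol: float = 0.2,
    score_lambda: float = 1.0,
) -> list[Deconvolution]:
    """Detect charge-reduced ladders among centroided peaks.

    Every peak pair is tested as an adjacent-charge hypothesis via
    :func:`infer_charge_pair`; consistent seeds are grown greedily in both
    charge directions by predicting the next member's m/z from the current
    mass estimate and accepting the nearest peak within ``mz_tol``.
    Candidates are scored ``members − λ·spread/mz_tol`` and returned in
    descending score order; overlapping ladders from multiplexed species
    are all reported. Zero candidates is a valid result.
    """
    plist = list(peaks)
    if len(plist) < 2:
        return []
    mzs = np.array([p.mz for p in plist])
    order = np.argsort(mzs)
    mzs = mzs[order]
    found: dict[frozenset[int], Deconvolution] = {}
    n = mzs.size
    for i in range(n):
        for j in range(i + 1, n):
            try:
                z_i, z_j = infer_charge_pair(mzs[i], mzs[j])
            except (AmbiguousChargeError, InvalidInputError):
                continue
            if z_i > z_max:
                continue
            m_i = mass_from_mz(mzs[i], z_i)
            if abs(mz_from_mass(m_i, z_j) - mzs[j]) > mz_tol:
                continue
            members = {z_i: i, z_j: j}
            _grow(members, mzs, z_max, mz_tol)
            key = frozenset(members.values())
            if key in found:
                continue
            entries = sorted(
                ((mzs[idx], z) for z, idx in members.items()), key=lambda e: -e[1]
            )
            try:
                ladder = ChargeLadder(tuple(entries), provenance="observed")
            except InvalidInputError:
                continue
            mass, spread = deconvolve_mass(ladder)
            score = len(ladder) - score_lambda * spread / mz_tol
            found[key] = Deconvolution(ladder, mass, spread, score)
    return _drop_subset_aliases(found)


def _drop_subset_aliases(found: dict[frozenset[int], Deconvolution]) -> list[Deconvolution]:
    """Remove candidates built from a subset of a larger candidate's peaks.

    A pair that skips a charge state (e.g. 8+ and 6+ read as 4+/3+) is
    internally consistent at a divided mass; the maximal ladder over the
    same peaks explains strictly more evidence, so subsets are aliases.
    """
    keep: list[tuple[frozenset[int], Deconvolution]] = []
    for key, cand in sorted(found.items(), key=lambda kv: (-len(kv[0]), -kv[1].score)):
        if any(key < kept_key for kept_key, _ in keep):
            continue
        keep.append((key, cand))
    return sorted((c for _, c in keep), key=lambda d: -d.score)


def _grow(members: dict[int, int], mzs: np.ndarray, z_max: int, mz_tol: float) -> None:
    """Greedy bidirectional ladder extension, in place."""
    while True:
        zs = sorted(members)
        mass = float(
            np.mean([mass_from_mz(mzs[idx], z) for z, idx in members.items()])
        )
        extended = False
        for z_next in (zs[0] - 1, zs[-1] + 1):
            if z_next < 1 or z_next > z_max or z_next in members:
                continue
            target = mz_from_mass(mass, z_next)
            k = int(np.searchsorted(mzs, target))
            best, best_err = None, mz_tol
            for cand in (k - 1, k):
                if 0 <= cand < mzs.size and cand not in members.values():
                    err = abs(mzs[cand] - target)
                    if err <= best_err:
                        best, best_err = cand, err
            if best is not None:
                members[z_next] = best
                extended = True
        if not extended:
            return


@dataclass(frozen=True)
class SpeciesMatch:
    name: str
    mass: float
    delta: float
    tie: bool = False


def match_species(
    mass: float,
    species_table: Mapping[str, float],
    mass_tol: float = 2.0,
) -> SpeciesMatch | None:
    """Nearest-mass species within tolerance, or None.

    Ties (equal |Δmass| within machine precision) are broken
    alphabetically and flagged.
    """
    if not species_table:
        raise InvalidInputError("species table must be non-empty")
    ranked = sorted(
        ((abs(mass - m), name, m) for name, m in species_table.items()),
        key=lambda t: (t[0], t[1]),
    )
    delta, name, m = ranked[0]
    if delta > mass_tol:
        return None
    tie = len(ranked) > 1 and abs(ranked[1][0] - delta) < 1e-9
    return SpeciesMatch(name=name, mass=m, delta=mass - m, tie=tie)


def annotate_candidates(
    candidates: Sequence[Deconvolution],
    species_table: Mapping[str, float],
    mass_tol: float = 2.0,
) -> list[Deconvolution]:
    """Attach species assignments to deconvolution candidates."""
    out = []
    for cand in candidates:
        match = match_species(cand.mass, species_table, mass_tol)
        out.append(
            Deconvolution(
                cand.ladder,
                cand.mass,
                cand.spread,
                cand.score,
                species=match.name if match else None,
                delta_mass=match.delta if match else None,
            )
        )
    return out
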