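"""In-memory containers for scans and centroid peak lists."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import InvalidInputError


@dataclass
class Peak:
    """A single centroided peak, optionally annotated with charge/SNR/labels."""

    mz: float
    intensity: float
    z: int | None = None
    snr: float = float("inf")
    label: str | None = None
    merged: bool = False


@dataclass
class Spectrum:
    """One scan: parallel m/z and intensity arrays plus scan metadata.

    ``mode`` distinguishes profile (continuous trace) from centroid
    (stick) data; ``metadata`` carries scan type (full / SIM / MS2 / PTCR),
    seed, and acquisition parameters.
    """

    mz: np.ndarray
    intensity: np.ndarray
    mode: Literal["profile", "centroid"] = "profile"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise InvalidInputError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.mode not in ("profile", "centroid"):
            raise InvalidInputError(f"bad spectrum mode {self.mode!r}")

    def __len__(self) -> int:
        return self.mz.size

    @property
    def tic(self) -> float:
        """Total ion current (sum of intensities)."""
        return float(self.intensity.sum())

    def slice(self, lo: float, hi: float) -> "Spectrum":
        sel = (self.mz >= lo) & (self.mz <= hi)
        return Spectrum(self.mz[sel], self.intensity[sel], self.mode, dict(self.metadata))

    @classmethod
    def from_peaks(cls, peaks: Sequence[Peak], metadata: dict | None = None) -> "Spectrum":
        peaks = sorted(peaks, key=lambda p: p.mz)
        return cls(
            np.array([p.mz for p in peaks]),
            np.array([p.intensity for p in peaks]),
            mode="centroid",
            metadata=metadata or {},
        )


@dataclass
class CentroidPeakList:
    """Sorted centroid peaks from one source scan."""

    peaks: list[Peak]
    source: str = ""

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        if any(p.snr < 0 for p in self.peaks):
            raise InvalidInputError("peak SNR must be >= 0")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])
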