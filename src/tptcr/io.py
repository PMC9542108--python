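"""Standard-format I/O: mzML, imzML, CSV target tables, images, manifests.

mzML support is self-contained: a minimal conformant serializer (64-bit
little-endian floats, base64, no compression) and a reader for the same
standard subset (32/64-bit floats, optional zlib) that round-trip
bit-exactly for centroid data. Imaging datasets go through pyimzml:
continuous mode when all pixels share an m/z axis, processed mode
otherwise.
"""

from __future__ import annotations

import base64
import hashlib
import json
import struct
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

from .errors import InvalidInputError
from .masses import mass_from_mz
from .simulate import ImagingDataset
from .spectra import Spectrum
from .targeted import IonImage, TargetRow, TargetTable, DEFAULT_ISOLATION_LIMIT

_MZML_NS = "http://psi.hupo.org/ms/mzml"


@dataclass
class RunConfig:
    """Reproducibility bundle serialized into every output manifest."""

    seed: int = 0
    mz_tol: float = 0.2
    half_width: float = 0.5
    mass_tol: float = 2.0
    tol_ppm: float = 10.0
    isolation_limit: float = DEFAULT_ISOLATION_LIMIT
    normalization: str = "none"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("mz_tol", "half_width", "mass_tol", "tol_ppm"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# mzML


def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *np.asarray(values, dtype="<f8"))
    return base64.b64encode(raw).decode("ascii")


def write_spectrum(spectra: Spectrum | list[Spectrum], path) -> None:
    """Serialize one or more scans to mzML."""
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    root = ET.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    cv_list = ET.SubElement(root, "cvList", count="1")
    ET.SubElement(
        cv_list, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = ET.SubElement(root, "run", id="run1")
    slist = ET.SubElement(run, "spectrumList", count=str(len(spectra)))
    for i, spec in enumerate(spectra):
        sp = ET.SubElement(
            slist, "spectrum", index=str(i), id=f"scan={i + 1}",
            defaultArrayLength=str(len(spec)),
        )
        mode_acc, mode_name = (
            ("MS:1000128", "profile spectrum")
            if spec.mode == "profile"
            else ("MS:1000127", "centroid spectrum")
        )
        _cv(sp, mode_acc, mode_name)
        _cv(sp, "MS:1000511", "ms level", value=str(spec.metadata.get("ms_level", 1)))
        bl = ET.SubElement(sp, "binaryDataArrayList", count="2")
        for arr, acc, name in (
            (spec.mz, "MS:1000514", "m/z array"),
            (spec.intensity, "MS:1000515", "intensity array"),
        ):
            payload = _b64(arr)
            bda = ET.SubElement(bl, "binaryDataArray", encodedLength=str(len(payload)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name)
            ET.SubElement(bda, "binary").text = payload
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _cv(parent, accession: str, name: str, value: str = "") -> None:
    ET.SubElement(parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value)


def _decode_binary(bda) -> np.ndarray:
    accessions = {cv.get("accession") for cv in bda.iter(f"{{{_MZML_NS}}}cvParam")}
    accessions |= {cv.get("accession") for cv in bda.iter("cvParam")}
    binary = bda.find(f"{{{_MZML_NS}}}binary")
    if binary is None:
        binary = bda.find("binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_spectrum(path) -> list[Spectrum]:
    """Read all scans from an mzML file.

    Handles the standard encoding subset: 32/64-bit little-endian floats,
    base64, zlib or no compression. Malformed files raise a parse error
    with position context from the XML parser.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise InvalidInputError(f"cannot parse mzML file {path}: {exc}") from exc
    root = tree.getroot()
    ns = f"{{{_MZML_NS}}}" if root.tag.startswith("{") else ""
    out = []
    for sp in root.iter(f"{ns}spectrum"):
        accessions = {
            cv.get("accession"): cv.get("value", "")
            for cv in sp.findall(f"{ns}cvParam")
        }
        mode = "profile" if "MS:1000128" in accessions else "centroid"
        arrays = {}
        for bda in sp.iter(f"{ns}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.findall(f"{ns}cvParam")}
            values = _decode_binary(bda)
            if "MS:1000514" in accs:
                arrays["mz"] = values
            elif "MS:1000515" in accs:
                arrays["intensity"] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise InvalidInputError(
                f"spectrum {sp.get('id')!r} in {path} lacks m/z or intensity arrays"
            )
        out.append(
            Spectrum(
                arrays["mz"],
                arrays["intensity"],
                mode=mode,
                metadata={
                    "id": sp.get("id", ""),
                    "ms_level": int(accessions.get("MS:1000511", "1") or 1),
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# imzML


def write_imaging(dataset: ImagingDataset, path) -> None:
    """Write an imaging dataset to imzML (+ .ibd).

    Continuous mode when every pixel shares one m/z axis, processed mode
    otherwise; pixel (row, col) maps to 1-based imzML (x=col+1, y=row+1).
    """
    specs = [s for s in dataset.spectra if s is not None]
    if not specs:
        raise InvalidInputError("imaging dataset has no spectra")
    first = specs[0].mz
    continuous = all(
        len(s) == len(first) and np.array_equal(s.mz, first) for s in specs
    )
    mode = "continuous" if continuous else "processed"
    n_rows, n_cols = dataset.shape
    with ImzMLWriter(str(path), mode=mode) as writer:
        for r in range(n_rows):
            for c in range(n_cols):
                spec = dataset.pixel(r, c)
                if spec is None or len(spec) == 0:
                    # empty pixels are omitted; readers flag them in QC
                    continue
                writer.addSpectrum(spec.mz, spec.intensity, (c + 1, r + 1))


def read_imaging(path) -> ImagingDataset:
    """Read an imzML dataset into a row-major grid.

    Non-rectangular coordinate sets are padded to the bounding box with
    the missing pixels flagged in the QC mask; duplicate coordinates are
    an error naming the pixel.
    """
    parser = ImzMLParser(str(path))
    coords = [(x, y) for x, y, *_ in parser.coordinates]
    seen = set()
    for xy in coords:
        if xy in seen:
            raise InvalidInputError(f"coordinate collision at pixel (x={xy[0]}, y={xy[1]})")
        seen.add(xy)
    xs = [x for x, _ in coords]
    ys = [y for _, y in coords]
    n_cols, n_rows = max(xs), max(ys)
    spectra: list[Spectrum | None] = [None] * (n_rows * n_cols)
    qc = np.ones((n_rows, n_cols), dtype=bool)
    for i, (x, y) in enumerate(coords):
        mzs, intens = parser.getspectrum(i)
        r, c = y - 1, x - 1
        spectra[r * n_cols + c] = Spectrum(mzs, intens, mode="centroid")
        qc[r, c] = False
    return ImagingDataset(
        shape=(n_rows, n_cols),
        pixel_size_um=float("nan"),
        spectra=spectra,
        qc_mask=qc,
        metadata={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Target tables (CSV)


def write_target_table(table: TargetTable, path) -> None:
    """CSV schema: name, precursor_mz, precursor_z, product_charges (';'-joined)."""
    df = pd.DataFrame(
        {
            "name": [r.name for r in table],
            "precursor_mz": [r.precursor_mz for r in table],
            "precursor_z": [r.precursor_z for r in table],
            "product_charges": [";".join(map(str, r.product_charges)) for r in table],
        }
    )
    df.to_csv(path, index=False)


def read_target_table(path, isolation_limit: float = DEFAULT_ISOLATION_LIMIT) -> TargetTable:
    df = pd.read_csv(path)
    required = {"name", "precursor_mz", "precursor_z", "product_charges"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"target table must have columns {sorted(required)}")
    rows = []
    for rec in df.itertuples(index=False):
        z = int(rec.precursor_z)
        mass = mass_from_mz(float(rec.precursor_mz), z)
        charges = tuple(int(t) for t in str(rec.product_charges).split(";") if t)
        rows.append(TargetRow(str(rec.name), mass, z, charges))
    return TargetTable(tuple(rows), isolation_limit=isolation_limit)


def read_species_table(path) -> list[tuple[str, float, int]]:
    """CSV (name, mass, z) rows for target-table construction."""
    df = pd.read_csv(path)
    required = {"name", "mass", "z"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"species table must have columns {sorted(required)}")
    return [(str(r.name), float(r.mass), int(r.z)) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Images and manifests


def write_image(image: IonImage, path) -> None:
    """16-bit grayscale PNG plus a plain-text matrix alongside."""
    path = Path(path)
    data = image.data
    hi = data.max()
    scaled = (data / hi * 65535.0).astype(np.uint16) if hi > 0 else data.astype(np.uint16)
    Image.fromarray(scaled).save(path)  # uint16 -> 16-bit grayscale PNG
    np.savetxt(path.with_suffix(".txt"), data, fmt="%.6g")


def write_composite_png(rgb: np.ndarray, path) -> None:
    Image.fromarray((np.clip(rgb, 0, 1) * 255).astype(np.uint8), mode="RGB").save(path)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: RunConfig, inputs: list[str | Path] = ()) -> None:
    """JSON manifest: full config, seed and input hashes, for bit-exact reruns."""
    manifest = {
        "config": asdict(config),
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
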