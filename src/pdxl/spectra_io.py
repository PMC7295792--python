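"""Uniform spectrum model over mzML and MGF readers.

Only centroided MS2 spectra are represented: parallel numpy arrays of
m/z (sorted ascending on load) and non-negative intensity, plus the
precursor metadata the search needs (m/z, charge, retention time).
Retention times are normalized to seconds regardless of file dialect.
"""

from __future__ import annotations

import base64
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

UNKNOWN_CHARGE = 0


@dataclass
class Spectrum:
    run_id: str
    scan_id: str
    precursor_mz: float
    precursor_charge: int  # UNKNOWN_CHARGE when unassigned
    rt: float              # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must be parallel")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        order = np.argsort(self.mz, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def neutral_mass(self) -> float:
        """Observed neutral precursor mass; NaN for unknown charge."""
        from . import chem

        if self.precursor_charge == UNKNOWN_CHARGE:
            return math.nan
        return chem.mass_from_mz(self.precursor_mz, self.precursor_charge)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self.intensity) else 0.0

    @property
    def total_ion_current(self) -> float:
        return float(self.intensity.sum())


@dataclass
class SpectrumRun:
    run_id: str
    condition: str  # "irradiated" | "control"
    spectra: list[Spectrum] = field(default_factory=list)
    source_path: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("irradiated", "control"):
            raise ValueError(f"condition must be irradiated/control, got {self.condition!r}")
        self.spectra.sort(key=lambda s: (s.rt, s.scan_id))

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


def _parse_mgf_charge(params: dict) -> int:
    charges = params.get("charge")
    if not charges:
        return UNKNOWN_CHARGE
    return int(charges[0])


def _rt_seconds_mgf(params: dict) -> float:
    return float(params.get("rtinseconds", 0.0))


def read_spectra(path: str | Path, condition: str, run_id: str | None = None) -> SpectrumRun:
    """Load all MS2 spectra of an mzML or MGF file into a SpectrumRun.

    Unknown precursor charges are preserved as
    :data:`UNKNOWN_CHARGE`; peak lists are sorted on load.
    """
    path = Path(path)
    rid = run_id or path.stem
    spectra: list[Spectrum] = []
    suffix = path.name.lower()
    if suffix.endswith((".mgf", ".mgf.gz")):
        with _mgf.read(str(path)) as reader:
            for i, entry in enumerate(reader):
                params = entry["params"]
                spectra.append(
                    Spectrum(
                        run_id=rid,
                        scan_id=str(params.get("title", f"index={i}")),
                        precursor_mz=float(params["pepmass"][0]),
                        precursor_charge=_parse_mgf_charge(params),
                        rt=_rt_seconds_mgf(params),
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                    )
                )
    elif suffix.endswith((".mzml", ".mzml.gz")):
        spectra.extend(_read_mzml(path, rid))
    else:
        raise ValueError(f"unsupported spectrum format: {path.name}")
    return SpectrumRun(run_id=rid, condition=condition, spectra=spectra,
                       source_path=str(path))


# mzML CV accessions used by the reader
_CV_MS_LEVEL = "MS:1000511"
_CV_SCAN_START = "MS:1000016"
_CV_SELECTED_MZ = "MS:1000744"
_CV_CHARGE = "MS:1000041"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_PROFILE = "MS:1000128"


def _decode_binary_array(node) -> tuple[str, np.ndarray]:
    """Decode one <binaryDataArray> into (kind, values)."""
    accessions = {
        p.get("accession") for p in node.iter("{*}cvParam")
    }
    kind = (
        "mz" if _CV_MZ_ARRAY in accessions
        else "intensity" if _CV_INTENSITY_ARRAY in accessions
        else "other"
    )
    binary = node.find("{*}binary")
    raw = base64.b64decode(binary.text or "")
    if _CV_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV_F32 in accessions else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path, run_id: str, force_profile: bool = False) -> list[Spectrum]:
    """Minimal mzML MS2 reader (iterparse over <spectrum> elements)."""
    spectra: list[Spectrum] = []
    for _, elem in etree.iterparse(str(path), events=("end",), tag="{*}spectrum"):
        params = {
            p.get("accession"): p
            for p in elem.findall("{*}cvParam")
        }
        level = params.get(_CV_MS_LEVEL)
        if level is None or int(level.get("value")) != 2:
            elem.clear()
            continue
        if _CV_PROFILE in params and not force_profile:
            warnings.warn(
                f"profile-mode spectrum {elem.get('id')!r} skipped; "
                "centroid the data or pass force_profile",
                stacklevel=3,
            )
            elem.clear()
            continue
        rt_s = 0.0
        for p in elem.iter("{*}cvParam"):
            if p.get("accession") == _CV_SCAN_START:
                rt_s = float(p.get("value"))
                if p.get("unitName", "minute") == "minute":
                    rt_s *= 60.0
                break
        pre_mz, charge = 0.0, UNKNOWN_CHARGE
        ion = elem.find(
            "{*}precursorList/{*}precursor/{*}selectedIonList/{*}selectedIon"
        )
        if ion is not None:
            for p in ion.findall("{*}cvParam"):
                if p.get("accession") == _CV_SELECTED_MZ:
                    pre_mz = float(p.get("value"))
                elif p.get("accession") == _CV_CHARGE:
                    charge = int(p.get("value"))
        arrays: dict[str, np.ndarray] = {}
        for node in elem.findall("{*}binaryDataArrayList/{*}binaryDataArray"):
            kind, values = _decode_binary_array(node)
            arrays[kind] = values
        spectra.append(
            Spectrum(
                run_id=run_id,
                scan_id=str(elem.get("id", elem.get("index"))),
                precursor_mz=pre_mz,
                precursor_charge=charge,
                rt=rt_s,
                mz=arrays.get("mz", np.empty(0)),
                intensity=arrays.get("intensity", np.empty(0)),
            )
        )
        elem.clear()
    return spectra


def write_mgf(run: SpectrumRun, path: str | Path) -> None:
    """Write a run as MGF (TITLE/RTINSECONDS/PEPMASS/CHARGE)."""
    entries = []
    for s in run:
        params = {
            "title": s.scan_id,
            "pepmass": s.precursor_mz,
            "rtinseconds": s.rt,
        }
        if s.precursor_charge != UNKNOWN_CHARGE:
            params["charge"] = s.precursor_charge
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")


def filter_precursors(
    run: SpectrumRun, charge_min: int = 2, charge_max: int = 6
) -> SpectrumRun:
    """Drop spectra with unknown or out-of-range precursor charge."""
    if charge_min < 1 or charge_max < charge_min:
        raise ValueError("invalid charge range")
    kept = [
        s
        for s in run.spectra
        if s.precursor_charge != UNKNOWN_CHARGE
        and charge_min <= s.precursor_charge <= charge_max
    ]
    return SpectrumRun(
        run_id=run.run_id,
        condition=run.condition,
        spectra=kept,
        source_path=run.source_path,
    )
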