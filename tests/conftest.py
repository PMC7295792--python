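"""Shared fixtures: toy proteins, synthetic spectra, toy structures."""

from __future__ import annotations

import numpy as np
import pytest

from pdxl import chem, simulate
from pdxl.adducts import AdductComposition
from pdxl.proteolysis import ModifiedPeptide, Peptide, ProteinRecord
from pdxl.spectra_io import Spectrum


def make_peptide(sequence: str, accession: str = "P1") -> Peptide:
    return Peptide(
        sequence=sequence,
        parents=(accession,),
        positions=((1, len(sequence)),),
        missed_cleavages=0,
    )


def make_modified(sequence: str, placements=()) -> ModifiedPeptide:
    return ModifiedPeptide(peptide=make_peptide(sequence), placements=tuple(placements))


def synthetic_spectrum(
    peptide: ModifiedPeptide,
    adduct: AdductComposition | None,
    site: int | None,
    charge: int = 2,
    rt: float = 600.0,
    scan_id: str = "syn",
    extra_peaks: list[tuple[float, float]] | None = None,
    b_range=None,
    y_range=None,
) -> Spectrum:
    """Noise-free spectrum of a crosslinked peptide with full b/y series.

    Fragments spanning ``site`` carry the full adduct mass; ``b_range``
    / ``y_range`` restrict which ion indices are emitted.
    """
    seq = peptide.sequence
    L = len(seq)
    deltas = [0.0] * (L + 1)
    for pos, spec in peptide.placements:
        deltas[pos] += spec.delta_mass
    adduct_mass = adduct.mass if adduct is not None else 0.0
    peaks: list[tuple[float, float]] = []
    prefix = 0.0
    prefixes = []
    for i, aa in enumerate(seq, start=1):
        prefix += chem.RESIDUE_MASSES[aa] + deltas[i]
        prefixes.append(prefix)
    total = prefixes[-1] + deltas[0]
    for i in range(1, L):
        if b_range is None or i in b_range:
            b = prefixes[i - 1] + deltas[0]
            if site is not None and i >= site:
                b += adduct_mass
            peaks.append((chem.mz_from_mass(b, 1), 1e5))
        j = L - i  # complementary y ion index
        if y_range is None or j in y_range:
            y = total - prefixes[i - 1] + chem.WATER
            if site is not None and site > i:
                y += adduct_mass
            peaks.append((chem.mz_from_mass(y, 1), 1e5))
    if extra_peaks:
        peaks.extend(extra_peaks)
    peaks.sort()
    precursor = total + chem.WATER + adduct_mass
    return Spectrum(
        run_id="syn",
        scan_id=scan_id,
        precursor_mz=chem.mz_from_mass(precursor, charge),
        precursor_charge=charge,
        rt=rt,
        mz=np.array([p[0] for p in peaks]),
        intensity=np.array([p[1] for p in peaks]),
    )


@pytest.fixture(scope="session")
def sim_pair():
    config = simulate.SimulationConfig(seed=11, n_crosslinks=10, n_background=40)
    return config, *simulate.simulate_pair(config)


@pytest.fixture
def toy_proteins():
    return [
        ProteinRecord("P1", "P1 toy protein one", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQK"),
        ProteinRecord("P2", "P2 toy protein two", "AAGKLLGRAAAAKPLLEKRMNPQR"),
    ]
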