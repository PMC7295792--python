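"""Monoisotopic mass bookkeeping.

All masses in the package flow through the tables defined here: element
monoisotopic masses, amino-acid residue masses, variable/static
modification deltas with their diagnostic neutral losses, and the
deoxynucleotide mass hierarchy (dNMP free acid, deoxynucleoside,
nucleobase) together with the low-mass marker ions each base produces
under HCD.

Tables are loaded once from plain-text resources shipped with the
package and are immutable afterwards.  m/z arithmetic uses the
electron-corrected proton mass, so singly protonated cations come out on
the scale a high-resolution instrument reports (e.g. the dehydrated
deoxyribose oxocarbenium after CO loss at m/z 89.06).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from types import MappingProxyType
from typing import Mapping, Sequence

PROTON = 1.00727646688  # mass of H+ (electron-corrected), Da
ELECTRON = 0.00054857991

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _load_table(name: str) -> list[list[str]]:
    text = resources.files("pdxl.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


ELEMENTS: Mapping[str, float] = MappingProxyType(
    {sym: float(m) for sym, m in _load_table("elements.tsv")}
)


class FormulaError(ValueError):
    """Raised for malformed chemical formulas or unknown element symbols."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``"C10H14N5O6P"`` into an element→count dict.

    Counts are non-negative integers; an omitted count means 1.  The
    empty string parses to the empty composition.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"unparseable formula {formula!r} at offset {pos}")
        if not match.group(0):
            break
        sym, num = match.group(1), match.group(2)
        if sym not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r} at offset {pos}")
    return counts


def formula_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a chemical formula string.

    Additive over concatenation: ``formula_mass(a + b) ==
    formula_mass(a) + formula_mass(b)``.
    """
    return sum(ELEMENTS[sym] * n for sym, n in parse_formula(formula).items())


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a [M + zH]^z+ ion from the neutral mass."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    if neutral_mass < 0:
        raise ValueError(f"neutral mass must be non-negative, got {neutral_mass}")
    return (neutral_mass + charge * PROTON) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass from observed m/z and charge; inverse of mz_from_mass."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return charge * (mz - PROTON)


# --- residues and peptides -------------------------------------------------

RESIDUE_FORMULAS: Mapping[str, str] = MappingProxyType(
    {code: f for code, f in _load_table("residues.tsv")}
)
RESIDUE_MASSES: Mapping[str, float] = MappingProxyType(
    {code: formula_mass(f) for code, f in RESIDUE_FORMULAS.items()}
)
WATER = formula_mass("H2O")

# neutral-loss molecules seen in HCD spectra of crosslinked peptides
NEUTRAL_LOSSES: Mapping[str, float] = MappingProxyType(
    {
        "H2O": WATER,
        "NH3": formula_mass("NH3"),
        "CO": formula_mass("CO"),
        "HPO3": formula_mass("HPO3"),
        "H3PO4": formula_mass("H3PO4"),
        "H2SO3": formula_mass("H2SO3"),
        "H2O2": formula_mass("H2O2"),
        "CH4SO": formula_mass("CH4SO"),
    }
)


@dataclass(frozen=True)
class ModificationSpec:
    """A residue modification with its mass delta and diagnostic losses.

    ``targets`` holds one-letter residue codes and/or the token
    ``"nterm"``; ``mode`` is ``"variable"`` or ``"static"``;
    ``neutral_losses`` lists (formula, mass) pairs the modified residue
    can shed during fragmentation (e.g. H2SO3 from cysteic acid).
    """

    name: str
    delta_mass: float
    targets: frozenset[str]
    mode: str = "variable"
    neutral_losses: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"modification {self.name!r} has no targets")
        if self.mode not in ("variable", "static"):
            raise ValueError(f"bad mode {self.mode!r}")
        for f, m in self.neutral_losses:
            if m <= 0:
                raise ValueError(f"neutral loss {f} of {self.name} has mass {m}")


OXIDATION_M = ModificationSpec(
    "Oxidation", formula_mass("O"), frozenset("M"),
    neutral_losses=(("CH4SO", NEUTRAL_LOSSES["CH4SO"]),),
)
TRIOXIDATION_C = ModificationSpec(
    "Trioxidation", formula_mass("O3"), frozenset("C"),
    neutral_losses=(("H2SO3", NEUTRAL_LOSSES["H2SO3"]), ("H2O2", NEUTRAL_LOSSES["H2O2"])),
)
CARBAMYL_K = ModificationSpec("Carbamyl", formula_mass("HCNO"), frozenset({"K", "nterm"}))
CARBAMIDOMETHYL_C = ModificationSpec(
    "Carbamidomethyl", formula_mass("C2H3NO"), frozenset("C"), mode="static"
)

#: Named variable/static-modification profiles.  ``invitro`` is the
#: recombinant-complex profile (Met oxidation, Cys trioxidation to
#: cysteic acid, Lys/N-terminal carbamylation); ``exvivo`` the cellular
#: one (Met oxidation variable, Cys carbamidomethylation static).
MOD_PROFILES: Mapping[str, tuple[ModificationSpec, ...]] = MappingProxyType(
    {
        "invitro": (OXIDATION_M, TRIOXIDATION_C, CARBAMYL_K),
        "exvivo": (OXIDATION_M, CARBAMIDOMETHYL_C),
        "none": (),
    }
)


def peptide_mass(sequence: str, mods: Sequence[ModificationSpec] = ()) -> float:
    """Neutral monoisotopic mass of a peptide with modification deltas applied.

    ``mods`` lists one ModificationSpec per placement (a spec placed
    twice appears twice); placement legality against positions is the
    caller's concern — use :func:`pdxl.proteolysis.expand_modifications`
    for combinatorial expansion with position checks.
    """
    try:
        mass = sum(RESIDUE_MASSES[aa] for aa in sequence) + WATER
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r} in {sequence!r}") from None
    return mass + sum(m.delta_mass for m in mods)


# --- deoxynucleotides -------------------------------------------------------

DEOXYRIBOSE = formula_mass("C5H10O4")
#: dehydrated deoxyribose cation C5H9O3+, the sugar marker of DNA adducts
OXOCARBENIUM_MZ = DEOXYRIBOSE - WATER + PROTON
OXOCARBENIUM_MINUS_CO_MZ = OXOCARBENIUM_MZ - NEUTRAL_LOSSES["CO"]


@dataclass(frozen=True)
class NucleotideSpec:
    """Mass hierarchy and diagnostic ions of one deoxynucleotide."""

    base: str
    dnmp_mass: float        # deoxynucleoside-5'-monophosphate, free acid
    nucleoside_mass: float
    nucleobase_mass: float
    marker_mz: tuple[float, ...] = ()
    base_neutral_losses: tuple[tuple[str, float], ...] = ()

    @property
    def marker_ions(self) -> tuple[tuple[str, float], ...]:
        """Labelled low-mass marker ions (singly charged) for this base."""
        b = self.base
        ions = [
            (f"{b}'", self.nucleobase_mass + PROTON),
            (f"{b}'-H2O", self.nucleobase_mass - WATER + PROTON),
            (f"d{b}-H2O", self.nucleoside_mass - WATER + PROTON),
            (f"d{b}", self.nucleoside_mass + PROTON),
            (f"d{b}-CO", self.nucleoside_mass - NEUTRAL_LOSSES["CO"] + PROTON),
            (f"{b}p", self.dnmp_mass + PROTON),
            ("sugar", OXOCARBENIUM_MZ),
            ("sugar-CO", OXOCARBENIUM_MINUS_CO_MZ),
        ]
        for loss, lmass in self.base_neutral_losses:
            ions.append((f"{b}'-{loss}", self.nucleobase_mass - lmass + PROTON))
        return tuple(ions)


def _make_nucleotides() -> Mapping[str, NucleotideSpec]:
    specs = {}
    for base, dnmp_f, nucleoside_f, base_f in _load_table("nucleotides.tsv"):
        base_losses: list[tuple[str, float]] = []
        if base in "ACG":  # exocyclic amine -> ammonia loss
            base_losses.append(("NH3", NEUTRAL_LOSSES["NH3"]))
        if base == "T":    # thymine ring CO loss
            base_losses.append(("CO", NEUTRAL_LOSSES["CO"]))
        spec = NucleotideSpec(
            base=base,
            dnmp_mass=formula_mass(dnmp_f),
            nucleoside_mass=formula_mass(nucleoside_f),
            nucleobase_mass=formula_mass(base_f),
            base_neutral_losses=tuple(base_losses),
        )
        specs[base] = NucleotideSpec(
            **{**spec.__dict__, "marker_mz": tuple(mz for _, mz in spec.marker_ions)}
        )
    return MappingProxyType(specs)


NUCLEOTIDES: Mapping[str, NucleotideSpec] = _make_nucleotides()
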