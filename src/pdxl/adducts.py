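"""Enumeration of the DNA adduct search space.

A UV crosslink is zero-length: the precursor of a crosslinked peptide is
shifted by exactly the mass of the attached oligonucleotide.  Because
nucleases leave mono- to short oligonucleotides on the peptide, the
precursor-level search space is every multiset of 1..max_len
deoxynucleotides (composition only — the base order is not observable at
MS1), condensed with one water loss per phosphodiester bond, crossed
with a terminal mass variant: intact, -H2O, -HPO3, -H3PO4 or +HPO3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import chem

#: terminal variant label -> mass delta (Da)
TERMINAL_VARIANTS: Mapping[str, float] = {
    "": 0.0,
    "-H2O": -chem.NEUTRAL_LOSSES["H2O"],
    "-HPO3": -chem.NEUTRAL_LOSSES["HPO3"],
    "-H3PO4": -chem.NEUTRAL_LOSSES["H3PO4"],
    "+HPO3": +chem.NEUTRAL_LOSSES["HPO3"],
}

_BASE_ORDER = "ACGT"


@dataclass(frozen=True)
class AdductComposition:
    """A multiset of deoxynucleotides with one terminal mass variant.

    ``counts`` maps base -> multiplicity; ``variant`` is a key of
    :data:`TERMINAL_VARIANTS`.  The canonical ``label`` writes bases in
    fixed A<C<G<T order followed by the variant, e.g. ``"TT-HPO3"``.
    """

    counts: tuple[tuple[str, int], ...]  # sorted, positive counts only
    variant: str = ""

    def __post_init__(self) -> None:
        if self.variant not in TERMINAL_VARIANTS:
            raise ValueError(f"unknown terminal variant {self.variant!r}")
        if self.length < 1:
            raise ValueError("adduct must contain at least one nucleotide")
        for base, n in self.counts:
            if base not in chem.NUCLEOTIDES or n < 1:
                raise ValueError(f"bad adduct count entry ({base!r}, {n})")

    @classmethod
    def from_bases(cls, bases: str, variant: str = "") -> "AdductComposition":
        counts = tuple(
            (b, bases.count(b)) for b in _BASE_ORDER if bases.count(b) > 0
        )
        return cls(counts=counts, variant=variant)

    @property
    def length(self) -> int:
        return sum(n for _, n in self.counts)

    @property
    def bases(self) -> str:
        """Bases in canonical order, with multiplicity (e.g. ``"ACT"``)."""
        return "".join(b * n for b, n in self.counts)

    @property
    def label(self) -> str:
        return self.bases + self.variant

    @property
    def mass(self) -> float:
        return adduct_mass(self)

    def sub_adducts(self) -> list["AdductComposition"]:
        """All non-empty sub-multisets, with the intact terminal variant.

        These are the pieces of the adduct that can survive on a
        backbone fragment ion after partial dissociation.
        """
        ranges = [range(n + 1) for _, n in self.counts]
        subs = []
        for combo in itertools.product(*ranges):
            if sum(combo) == 0:
                continue
            counts = tuple(
                (base, k) for (base, _), k in zip(self.counts, combo) if k > 0
            )
            subs.append(AdductComposition(counts=counts, variant=""))
        return subs

    def __str__(self) -> str:  # pragma: no cover
        return self.label


def adduct_mass(composition: AdductComposition) -> float:
    """Neutral monoisotopic mass of an adduct composition.

    Sum of dNMP free-acid masses, minus one water per phosphodiester
    bond (length - 1), plus the terminal variant delta.
    """
    total = sum(chem.NUCLEOTIDES[b].dnmp_mass * n for b, n in composition.counts)
    total -= (composition.length - 1) * chem.WATER
    return total + TERMINAL_VARIANTS[composition.variant]


def enumerate_adducts(
    max_length: int = 4,
    bases: str = _BASE_ORDER,
    variants: Iterable[str] = TERMINAL_VARIANTS,
) -> list[AdductComposition]:
    """Enumerate every (multiset, terminal variant) pair, sorted by mass.

    One entry per pair; for the default four bases, lengths 1-4 and all
    five variants this is 69 compositions x 5 = 345 entries.
    """
    variants = list(variants)
    if not variants:
        raise ValueError("variant set must not be empty (use [''] for intact)")
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    base_list = [b for b in _BASE_ORDER if b in set(bases)]
    if not base_list:
        raise ValueError("base set must not be empty")
    out = []
    for k in range(1, max_length + 1):
        for combo in itertools.combinations_with_replacement(base_list, k):
            for variant in variants:
                out.append(AdductComposition.from_bases("".join(combo), variant))
    out.sort(key=lambda a: (a.mass, a.label))
    return out


def isobaric_groups(
    adducts: Sequence[AdductComposition],
    tolerance_ppm: float = 10.0,
    reference_mass: float = 1500.0,
) -> list[list[AdductComposition]]:
    """Partition adducts into groups indistinguishable at precursor level.

    Compositions whose masses differ by less than ``tolerance_ppm`` of
    ``reference_mass`` (a typical crosslinked-precursor mass) cannot be
    told apart by the precursor alone and are grouped; single-linkage
    over the sorted mass list.  Downstream MS2 annotation may still
    resolve a group via base-specific shifted ions.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    window = tolerance_ppm * 1e-6 * reference_mass
    ordered = sorted(adducts, key=lambda a: a.mass)
    groups: list[list[AdductComposition]] = []
    for adduct in ordered:
        if groups and adduct.mass - groups[-1][-1].mass < window:
            groups[-1].append(adduct)
        else:
            groups.append([adduct])
    return groups


def adduct_table(adducts: Sequence[AdductComposition]):
    """Adduct space as a pandas DataFrame (label, bases, variant, mass)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [a.label for a in adducts],
            "bases": [a.bases for a in adducts],
            "variant": [a.variant or "none" for a in adducts],
            "mass": [a.mass for a in adducts],
        }
    )
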