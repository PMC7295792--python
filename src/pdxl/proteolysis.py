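"""Protein database handling: FASTA I/O, digestion, modifications, decoys.

The digest models a combined trypsin + Lys-C protocol: cleavage
C-terminal to K and R, with the proline suppression rule applied only
to R|P sites (Lys-C cleaves K-P bonds that trypsin alone would skip).
Variable-modification expansion produces every combination of up to
``max_variable`` placements from a named profile; decoys are
full-protein sequence reversals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import fasta as _fasta

from . import chem

DECOY_PREFIX = "REV_"
_STANDARD_AA = set(chem.RESIDUE_MASSES)


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        bad = set(self.sequence) - _STANDARD_AA - {"X"}
        if bad:
            raise ValueError(
                f"non-standard residues {sorted(bad)} in {self.accession!r}"
            )


@dataclass(frozen=True)
class Peptide:
    """A digestion product, possibly shared between several parents."""

    sequence: str
    parents: tuple[str, ...]                  # accessions
    positions: tuple[tuple[int, int], ...]    # 1-based inclusive, per parent
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if len(self.parents) != len(self.positions):
            raise ValueError("parents and positions must be parallel")


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with a concrete placement of variable + static mods."""

    peptide: Peptide
    placements: tuple[tuple[int, chem.ModificationSpec], ...] = ()
    # position 0 encodes the N-terminus; 1..len(sequence) are residues

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    @property
    def mass(self) -> float:
        return chem.peptide_mass(self.sequence, [m for _, m in self.placements])

    @property
    def is_decoy(self) -> bool:
        return any(p.startswith(DECOY_PREFIX) for p in self.peptide.parents)

    def mod_at(self, position: int) -> chem.ModificationSpec | None:
        for pos, spec in self.placements:
            if pos == position:
                return spec
        return None

    @property
    def label(self) -> str:
        tags = "".join(
            f"[{spec.name}@{pos}]" for pos, spec in sorted(self.placements)
        )
        return self.sequence + tags


def read_fasta(path: str | Path, decoy: bool = False) -> list[ProteinRecord]:
    """Read a FASTA database; accession = first whitespace-separated token."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_headers = sum(
        1 for line in open(path) if line.startswith(">")
    )
    with _fasta.read(str(path)) as reader:
        for description, sequence in reader:
            accession = description.split()[0] if description.split() else ""
            if not accession:
                raise ValueError(f"malformed FASTA header {description!r}")
            if accession in seen:
                raise ValueError(f"duplicate accession {accession!r}")
            seen.add(accession)
            records.append(
                ProteinRecord(
                    accession=accession,
                    description=description,
                    sequence="".join(sequence.split()).upper(),
                    is_decoy=decoy or accession.startswith(DECOY_PREFIX),
                )
            )
    if len(records) != n_headers:
        # the parser silently merges/drops entries without a sequence
        raise ValueError(
            f"{path}: {n_headers} headers but {len(records)} parseable records "
            "(empty sequence or malformed header)"
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    _fasta.write(
        [(r.description, r.sequence) for r in records],
        str(path),
        file_mode="w",
    )


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices after which the chain is cut (K/R rule, R|P suppressed)."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa == "K":
            sites.append(i)
        elif aa == "R" and sequence[i + 1] != "P":
            sites.append(i)
    return sites


def digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    min_length: int = 1,
    max_length: int | None = None,
) -> list[Peptide]:
    """In-silico trypsin+Lys-C digest with up to ``max_missed`` missed cleavages.

    Positions are 1-based inclusive within the parent.  With
    ``max_missed=0`` the concatenation of products reconstructs the
    protein.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    cuts = [0] + [s + 1 for s in cleavage_sites(seq)] + [len(seq)]
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            start, end = cuts[i], cuts[j]
            sub = seq[start:end]
            if len(sub) < min_length:
                continue
            if max_length is not None and len(sub) > max_length:
                continue
            peptides.append(
                Peptide(
                    sequence=sub,
                    parents=(protein.accession,),
                    positions=((start + 1, end),),
                    missed_cleavages=j - i - 1,
                )
            )
    return peptides


def digest_database(
    db: Sequence[ProteinRecord],
    max_missed: int = 2,
    min_length: int = 6,
    max_length: int = 40,
) -> list[Peptide]:
    """Digest every record and merge identical sequences across parents."""
    merged: dict[str, dict] = {}
    for protein in db:
        for pep in digest(protein, max_missed, min_length, max_length):
            entry = merged.setdefault(
                pep.sequence,
                {"parents": [], "positions": [], "mc": pep.missed_cleavages},
            )
            entry["parents"].append(pep.parents[0])
            entry["positions"].append(pep.positions[0])
            entry["mc"] = min(entry["mc"], pep.missed_cleavages)
    return [
        Peptide(
            sequence=seq,
            parents=tuple(e["parents"]),
            positions=tuple(e["positions"]),
            missed_cleavages=e["mc"],
        )
        for seq, e in sorted(merged.items())
    ]


def expand_modifications(
    peptide: Peptide,
    profile: str | Sequence[chem.ModificationSpec] = "invitro",
    max_variable: int = 3,
    nterm_carbamyl: bool = True,
) -> list[ModifiedPeptide]:
    """All modification variants of a peptide under a named profile.

    Includes the unmodified form; static mods are applied to every
    variant; variable mods are placed in every combination of at most
    ``max_variable`` legal sites.  ``nterm_carbamyl=False`` restricts
    carbamylation (and any other terminus-capable variable mod) to side
    chains only.
    """
    specs = chem.MOD_PROFILES[profile] if isinstance(profile, str) else tuple(profile)
    seq = peptide.sequence

    static: list[tuple[int, chem.ModificationSpec]] = []
    variable_sites: list[tuple[int, chem.ModificationSpec]] = []
    for spec in specs:
        sites: list[int] = []
        if "nterm" in spec.targets and nterm_carbamyl:
            sites.append(0)
        sites.extend(
            i + 1 for i, aa in enumerate(seq) if aa in spec.targets
        )
        if spec.mode == "static":
            static.extend((s, spec) for s in sites if s > 0)
        else:
            variable_sites.extend((s, spec) for s in sites)

    variants = []
    for k in range(0, max_variable + 1):
        for combo in itertools.combinations(variable_sites, k):
            positions = [pos for pos, _ in combo]
            if len(set(positions)) != len(positions):
                continue  # one mod per site
            variants.append(
                ModifiedPeptide(
                    peptide=peptide,
                    placements=tuple(sorted(combo + tuple(static))),
                )
            )
    return variants


def make_decoys(db: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target, accession-prefixed."""
    if not db:
        raise ValueError("cannot build decoys from an empty database")
    return [
        ProteinRecord(
            accession=DECOY_PREFIX + r.accession,
            description=DECOY_PREFIX + r.description,
            sequence=r.sequence[::-1],
            is_decoy=True,
        )
        for r in db
    ]


def with_decoys(db: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    return list(db) + make_decoys(db)
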