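"""Residue–nucleotide contact distances in protein–DNA structures.

Curated crosslink sites are validated against 3D structures by
measuring the minimum interatomic distance between the crosslinked
residue's side chain and a nucleotide.  Distances within the
``direct`` threshold (default 16 Å) are consistent with a zero-length
photo-crosslink in the crystallized conformation; larger distances
flag conformational flexibility (e.g. transient DNA unwrapping) rather
than a contact the static structure can explain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

DIRECT_THRESHOLD = 16.0  # Å; beyond this a crosslink needs conformational change

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class StructureContact:
    structure_id: str
    protein_chain: str
    protein_residue: int
    protein_resname: str
    nucleotide_chain: str
    nucleotide_residue: int
    nucleotide_resname: str
    distance: float
    atom_pair: tuple[str, str]
    classification: str  # "direct" | "distant"

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def load_structure(path: str | Path) -> gemmi.Structure:
    """Read a PDB or mmCIF file; first model, highest-occupancy altlocs."""
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    structure.remove_alternative_conformations()
    structure.remove_hydrogens()
    while len(structure) > 1:
        del structure[1]
    if len(structure) == 0 or len(structure[0]) == 0:
        raise ValueError(f"no chains in {path}")
    return structure


def _find_residue(
    model: gemmi.Model, chain_name: str, seqid: int
) -> gemmi.Residue:
    chain = model.find_chain(chain_name)
    if chain is None:
        raise ValueError(f"chain {chain_name!r} not in structure")
    for residue in chain:
        if residue.seqid.num == seqid:
            return residue
    raise ValueError(f"residue {seqid} not in chain {chain_name!r}")


def _atom_coords(
    residue: gemmi.Residue, scope: str, is_protein: bool
) -> tuple[list[str], np.ndarray]:
    """Heavy-atom names and coordinates under an atom scope.

    ``sidechain`` drops protein backbone atoms (N/CA/C/O); ``all``
    keeps every heavy atom; ``cbeta`` keeps CB only (CA for Gly).
    Nucleotides always contribute all heavy atoms.
    """
    names, xyz = [], []
    for atom in residue:
        if atom.is_hydrogen():
            continue
        name = atom.name
        if is_protein:
            if scope == "sidechain" and name in BACKBONE_ATOMS:
                continue
            if scope == "cbeta" and name != ("CB" if residue.name != "GLY" else "CA"):
                continue
        names.append(name)
        xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not names:
        raise ValueError(
            f"no atoms for {residue.name} {residue.seqid.num} under scope {scope!r}"
        )
    return names, np.asarray(xyz)


def min_distance(
    structure: gemmi.Structure,
    protein_chain: str,
    protein_residue: int,
    nucleotide_chain: str,
    nucleotide_residue: int,
    atom_scope: str = "sidechain",
    threshold: float = DIRECT_THRESHOLD,
) -> StructureContact:
    """Minimum heavy-atom distance between one residue and one nucleotide.

    Default scope pairs the residue's side-chain heavy atoms against
    all nucleotide heavy atoms; scopes ``all`` and ``cbeta`` are
    available.  Deterministic: ties resolve to the first atom pair in
    file order.
    """
    if atom_scope not in ("sidechain", "all", "cbeta"):
        raise ValueError(f"unknown atom scope {atom_scope!r}")
    model = structure[0]
    res_p = _find_residue(model, protein_chain, protein_residue)
    res_n = _find_residue(model, nucleotide_chain, nucleotide_residue)
    names_p, xyz_p = _atom_coords(res_p, atom_scope, is_protein=True)
    names_n, xyz_n = _atom_coords(res_n, "all", is_protein=False)
    d = np.linalg.norm(xyz_p[:, None, :] - xyz_n[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    dist = float(d[i, j])
    return StructureContact(
        structure_id=structure.name or "",
        protein_chain=protein_chain,
        protein_residue=protein_residue,
        protein_resname=res_p.name,
        nucleotide_chain=nucleotide_chain,
        nucleotide_residue=nucleotide_residue,
        nucleotide_resname=res_n.name,
        distance=dist,
        atom_pair=(names_p[i], names_n[j]),
        classification="direct" if dist <= threshold else "distant",
    )


def nearest_nucleotide(
    structure: gemmi.Structure,
    protein_chain: str,
    protein_residue: int,
    nucleotide_resnames: Iterable[str] | None = None,
    atom_scope: str = "sidechain",
    threshold: float = DIRECT_THRESHOLD,
) -> StructureContact:
    """Closest nucleotide (optionally restricted by residue name) to a residue.

    ``nucleotide_resnames`` like {"DT"} restricts to thymidines, etc.;
    by default any standard deoxynucleotide (DA/DC/DG/DT) qualifies.
    """
    wanted = set(nucleotide_resnames) if nucleotide_resnames else {"DA", "DC", "DG", "DT"}
    model = structure[0]
    best: StructureContact | None = None
    for chain in model:
        for residue in chain:
            if residue.name not in wanted:
                continue
            contact = min_distance(
                structure, protein_chain, protein_residue,
                chain.name, residue.seqid.num,
                atom_scope=atom_scope, threshold=threshold,
            )
            if best is None or contact.distance < best.distance:
                best = contact
    if best is None:
        raise ValueError(f"no nucleotide {sorted(wanted)} found in structure")
    return best


def classify_contacts(
    contacts: Sequence[StructureContact], threshold: float = DIRECT_THRESHOLD
) -> tuple[list[StructureContact], dict[str, int]]:
    """Re-label contacts at a threshold; distance == threshold is direct."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = [
        StructureContact(
            **{
                **c.__dict__,
                "classification": "direct" if c.distance <= threshold else "distant",
            }
        )
        for c in contacts
    ]
    counts = {
        "direct": sum(c.classification == "direct" for c in out),
        "distant": sum(c.classification == "distant" for c in out),
    }
    return out, counts
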