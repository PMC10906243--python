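"""Amino-acid building blocks and combinatorial tripeptide library enumeration.

Building blocks are described by a residue SMILES with two annotated
attachment points: a dummy atom mapped ``[*:1]`` bonded to the backbone
amine nitrogen and a dummy atom mapped ``[*:2]`` bonded to the backbone
carbonyl carbon.  For example glycine is ``[*:1]NCC(=O)[*:2]`` and
L-alanine is ``[*:1]N[C@@H](C)C(=O)[*:2]``.  Explicit attachment points
(rather than template matching of the backbone) are used because
noncanonical residues such as piperidine-2-carboxylic acid or
alpha-methyl-proline break backbone inference.

Tripeptide catalysts follow the H-Xaa-Yaa-Zaa-NH2 pattern: a free
N-terminal amine, three residues joined N->C by amide bonds, and a
C-terminal cap that is a primary amide by default (a free acid is also
supported).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import rdmolops

from .errors import ChemistryError, ConfigurationError, ValidationError

__all__ = [
    "AminoAcid",
    "PeptideSpec",
    "CatalystLibrary",
    "load_building_blocks",
    "enumerate_library",
    "assemble_peptide",
    "residue_to_molecule",
]

AMINE_MAP = 1  # atom-map number of the dummy on the backbone nitrogen
CARBONYL_MAP = 2  # atom-map number of the dummy on the backbone carbonyl carbon

STEREO_TAGS = ("L", "D", "achiral")
C_TERMINI = ("amide", "acid")

REQUIRED_COLUMNS = ("id", "name", "residue_smiles", "stereo_tag", "manual_addition")


@dataclass(frozen=True)
class AminoAcid:
    """One building block of the combinatorial library.

    Parameters
    ----------
    id:
        Short unique token used in peptide labels (e.g. ``dPro``).
    name:
        Free-text description.
    residue_smiles:
        Residue connectivity with ``[*:1]`` on the backbone amine and
        ``[*:2]`` on the backbone carbonyl carbon.
    stereo_tag:
        ``"L"``, ``"D"`` or ``"achiral"``.
    manual_addition:
        Whether the residue entered the training set by expert choice
        rather than by clustering.
    """

    id: str
    name: str
    residue_smiles: str
    stereo_tag: str
    manual_addition: bool = False

    def __post_init__(self) -> None:
        if self.stereo_tag not in STEREO_TAGS:
            raise ValidationError(
                f"stereo_tag of {self.id!r} must be one of {STEREO_TAGS}, "
                f"got {self.stereo_tag!r}"
            )
        mol = Chem.MolFromSmiles(self.residue_smiles)
        if mol is None:
            raise ValidationError(
                f"residue_smiles of {self.id!r} does not parse: "
                f"{self.residue_smiles!r}"
            )
        maps = [a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        for required in (AMINE_MAP, CARBONYL_MAP):
            if maps.count(required) != 1:
                raise ValidationError(
                    f"residue {self.id!r} must carry exactly one [*:{required}] "
                    f"attachment point (found {maps.count(required)})"
                )

    def to_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.residue_smiles)


@dataclass(frozen=True)
class PeptideSpec:
    """An assembled-tripeptide definition (residues listed N->C)."""

    residues: tuple[str, str, str]
    c_terminus: str = "amide"
    n_terminus: str = "free amine"

    def __post_init__(self) -> None:
        if len(self.residues) != 3:
            raise ValidationError(
                f"a tripeptide needs exactly 3 residues, got {len(self.residues)}"
            )
        if self.c_terminus not in C_TERMINI:
            raise ValidationError(
                f"c_terminus must be one of {C_TERMINI}, got {self.c_terminus!r}"
            )

    @property
    def label(self) -> str:
        cap = "NH2" if self.c_terminus == "amide" else "OH"
        return "H-" + "-".join(self.residues) + "-" + cap


@dataclass(frozen=True)
class CatalystLibrary:
    """An enumerated in-silico library of tripeptide catalysts."""

    members: tuple[PeptideSpec, ...]
    pool_size: int
    provenance: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.members]


def load_building_blocks(path) -> list[AminoAcid]:
    """Read and validate a building-block table (CSV).

    Required columns: ``id, name, residue_smiles, stereo_tag,
    manual_addition``.  Rows with unparsable structures are rejected with
    their row numbers; duplicate ids are a validation error.
    """
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ConfigurationError(f"{path}: empty building-block table")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ConfigurationError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        blocks: list[AminoAcid] = []
        seen: dict[str, int] = {}
        bad_rows: list[tuple[int, str]] = []
        for row_number, row in enumerate(reader, start=2):  # 1-based + header
            block_id = row["id"].strip()
            if block_id in seen:
                raise ValidationError(
                    f"duplicate building-block id {block_id!r} "
                    f"(rows {seen[block_id]} and {row_number})"
                )
            seen[block_id] = row_number
            try:
                blocks.append(
                    AminoAcid(
                        id=block_id,
                        name=row["name"].strip(),
                        residue_smiles=row["residue_smiles"].strip(),
                        stereo_tag=row["stereo_tag"].strip(),
                        manual_addition=_parse_bool(row["manual_addition"]),
                    )
                )
            except ValidationError as err:
                bad_rows.append((row_number, str(err)))
        if bad_rows:
            detail = "; ".join(f"row {n}: {msg}" for n, msg in bad_rows)
            raise ValidationError(f"{path}: invalid building-block row(s): {detail}")
    return blocks


def _parse_bool(token: str) -> bool:
    return str(token).strip().lower() in ("1", "true", "yes")


def enumerate_library(
    fixed_first: AminoAcid,
    pool: Sequence[AminoAcid],
    c_terminus: str = "amide",
) -> CatalystLibrary:
    """Enumerate every tripeptide with ``fixed_first`` at position 1.

    Positions 2 and 3 each draw independently from ``pool``, so the
    library has exactly ``len(pool) ** 2`` members.  Ordering is
    lexicographic by (position-2 id, position-3 id) so library indices
    are reproducible.
    """
    if not pool:
        raise ValidationError("building-block pool is empty")
    ids = sorted({b.id for b in pool})
    if len(ids) != len(pool):
        raise ValidationError("building-block pool contains duplicate ids")
    members = tuple(
        PeptideSpec(residues=(fixed_first.id, mid, last), c_terminus=c_terminus)
        for mid in ids
        for last in ids
    )
    labels = [m.label for m in members]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate peptide labels in enumerated library")
    return CatalystLibrary(
        members=members,
        pool_size=len(ids),
        provenance={"fixed_first": fixed_first.id, "c_terminus": c_terminus},
    )


def _find_attachment(mol: Chem.Mol, map_num: int) -> tuple[int, int]:
    """Return (dummy atom index, anchor atom index) for an attachment point."""
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == map_num:
            neighbors = atom.GetNeighbors()
            if len(neighbors) != 1:
                raise ChemistryError(
                    f"attachment dummy [*:{map_num}] must have exactly one neighbor"
                )
            return atom.GetIdx(), neighbors[0].GetIdx()
    raise ChemistryError(f"attachment point [*:{map_num}] not found")


def assemble_peptide(
    spec: PeptideSpec, blocks: Iterable[AminoAcid]
) -> Chem.Mol:
    """Assemble a tripeptide molecular graph from its residues.

    Residues are joined N->C by amide bonds (the carbonyl carbon of
    residue *i* bonds the amine nitrogen of residue *i+1*; one dummy pair
    is consumed per bond, which is the graph equivalent of losing one
    water per condensation).  The N-terminus is left as a free amine and
    the C-terminus is capped as a primary amide or free acid.
    """
    by_id = {b.id: b for b in blocks}
    unknown = [r for r in spec.residues if r not in by_id]
    if unknown:
        raise ValidationError(
            f"unknown residue id(s) {', '.join(repr(u) for u in unknown)} "
            f"in {spec.label}"
        )

    peptide = by_id[spec.residues[0]].to_mol()
    for residue_id in spec.residues[1:]:
        incoming = by_id[residue_id].to_mol()
        offset = peptide.GetNumAtoms()
        combined = Chem.RWMol(Chem.CombineMols(peptide, incoming))
        # carbonyl attachment of the growing chain, restricted to existing atoms
        c_dummy, c_anchor = _find_attachment(
            combined, CARBONYL_MAP
        )
        if c_dummy >= offset:  # first map-2 found belongs to the incoming residue
            c_dummy, c_anchor = _find_attachment_in_range(
                combined, CARBONYL_MAP, 0, offset
            )
        n_dummy, n_anchor = _find_attachment_in_range(
            combined, AMINE_MAP, offset, combined.GetNumAtoms()
        )
        combined.AddBond(c_anchor, n_anchor, Chem.BondType.SINGLE)
        for idx in sorted((c_dummy, n_dummy), reverse=True):
            combined.RemoveAtom(idx)
        peptide = combined.GetMol()

    editable = Chem.RWMol(peptide)
    # free N-terminal amine: drop the map-1 dummy, nitrogen picks up an H
    n_dummy, _ = _find_attachment(editable, AMINE_MAP)
    editable.RemoveAtom(n_dummy)
    # C-terminal cap: turn the map-2 dummy into NH2 (amide) or OH (acid)
    c_dummy_idx, _ = _find_attachment(editable, CARBONYL_MAP)
    cap_atom = editable.GetAtomWithIdx(c_dummy_idx)
    cap_atom.SetAtomicNum(7 if spec.c_terminus == "amide" else 8)
    cap_atom.SetAtomMapNum(0)
    cap_atom.SetNoImplicit(False)  # dummies carry no implicit Hs; the cap must

    assembled = editable.GetMol()
    try:
        Chem.SanitizeMol(assembled)
    except Exception as err:  # pragma: no cover - rdkit raises various types
        raise ChemistryError(f"assembly of {spec.label} failed sanitization: {err}")
    rdmolops.AssignStereochemistry(assembled, cleanIt=True, force=True)
    assembled.SetProp("_Name", spec.label)
    return assembled


def _find_attachment_in_range(
    mol: Chem.Mol, map_num: int, start: int, stop: int
) -> tuple[int, int]:
    for atom in mol.GetAtoms():
        if not (start <= atom.GetIdx() < stop):
            continue
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == map_num:
            return atom.GetIdx(), atom.GetNeighbors()[0].GetIdx()
    raise ChemistryError(
        f"attachment point [*:{map_num}] not found in atom range [{start}, {stop})"
    )


def residue_to_molecule(block: AminoAcid) -> Chem.Mol:
    """Convert a residue into its free amino acid (H2N-...-COOH).

    Used when building blocks themselves (rather than assembled
    peptides) are represented by descriptors, as in training-set design.
    """
    editable = Chem.RWMol(block.to_mol())
    n_dummy, _ = _find_attachment(editable, AMINE_MAP)
    editable.RemoveAtom(n_dummy)
    c_dummy_idx, _ = _find_attachment(editable, CARBONYL_MAP)
    cap = editable.GetAtomWithIdx(c_dummy_idx)
    cap.SetAtomicNum(8)
    cap.SetAtomMapNum(0)
    cap.SetNoImplicit(False)
    mol = editable.GetMol()
    Chem.SanitizeMol(mol)
    mol.SetProp("_Name", block.id)
    return mol
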