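"""Conformer ensemble generation, pruning, and core alignment.

Grid descriptors are averaged over an ensemble of low-energy conformers,
so every catalyst must be represented by (a) a set of locally minimized
3D structures within an energy window of the global minimum and (b) a
rigid alignment of each conformer onto a shared reference frame defined
by a common structural motif (for Pro-Xaa-Yaa peptides, the N-terminal
proline backbone).

Ensembles are stored as plain numpy arrays (symbols + one coordinate
block per conformer) so that downstream descriptor code and test oracles
never need a chemistry toolkit; the originating RDKit molecule is kept
alongside when available (needed for substructure-based alignment and
partial charges).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import ChemistryError, ValidationError

__all__ = [
    "ConformerEnsemble",
    "generate_ensemble",
    "prune_ensemble",
    "align_to_core",
    "align_ensemble",
    "core_geometry",
    "kabsch",
    "kabsch_rmsd",
    "PROLINE_CORE_SMARTS",
]

# N-terminal proline ring plus its backbone carbonyl carbon.
PROLINE_CORE_SMARTS = "C1CCNC1C=O"


@dataclass(frozen=True)
class ConformerEnsemble:
    """Aligned conformers of one molecule with relative energies.

    Attributes
    ----------
    symbols:
        Element symbol per atom (defines the atom count).
    coords:
        Array of shape ``(n_conf, n_atoms, 3)`` in Angstrom.
    energies:
        Relative force-field energies in kcal/mol, shape ``(n_conf,)``.
    mol:
        Optional RDKit molecule (same atom order) for substructure
        queries and charges.
    label:
        Catalyst label for error messages and provenance.
    """

    symbols: tuple[str, ...]
    coords: np.ndarray
    energies: np.ndarray
    mol: Chem.Mol | None = None
    label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        energies = np.asarray(self.energies, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_conf, n_atoms, 3)")
        if coords.shape[1] != len(self.symbols):
            raise ValidationError(
                f"coordinate rows ({coords.shape[1]}) != atom count "
                f"({len(self.symbols)})"
            )
        if coords.shape[0] < 1:
            raise ValidationError("an ensemble needs at least one conformer")
        if energies.shape != (coords.shape[0],) or not np.all(np.isfinite(energies)):
            raise ValidationError("energies must be finite, one per conformer")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "energies", energies)

    @property
    def n_conf(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (proper rotation only).

    Returns ``(rotation, translation)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to
    ``target``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (mobile - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = mu_t - rotation @ mu_m
    return rotation, translation


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition, fixed atom correspondence."""
    rotation, translation = kabsch(a, b)
    moved = a @ rotation.T + translation
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))


def _mol_to_ensemble(mol: Chem.Mol, energies: Sequence[float], label: str) -> ConformerEnsemble:
    symbols = tuple(a.GetSymbol() for a in mol.GetAtoms())
    coords = np.stack(
        [mol.GetConformer(cid).GetPositions() for cid in range(mol.GetNumConformers())]
    )
    return ConformerEnsemble(
        symbols=symbols,
        coords=coords,
        energies=np.asarray(energies, float),
        mol=mol,
        label=label,
    )


def generate_ensemble(
    mol: Chem.Mol,
    n_embed: int = 200,
    seed: int = 42,
    energy_window: float = 5.0,
    rmsd_threshold: float = 0.5,
    max_attempts: int = 3,
) -> ConformerEnsemble:
    """Generate a pruned conformer ensemble for one molecule.

    Distance-geometry embedding (ETKDGv3, fixed random seed) followed by
    MMFF94 minimization (UFF fallback for atoms outside MMFF coverage);
    the raw ensemble is then pruned to ``energy_window`` kcal/mol above
    the minimum and deduplicated at ``rmsd_threshold`` Angstrom.
    """
    if n_embed < 1:
        raise ValidationError("n_embed must be >= 1")
    label = mol.GetProp("_Name") if mol.HasProp("_Name") else Chem.MolToSmiles(mol)
    work = Chem.AddHs(Chem.Mol(mol))

    conf_ids: list[int] = []
    for attempt in range(max_attempts):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + 7919 * attempt
        params.useRandomCoords = attempt > 0
        conf_ids = list(AllChem.EmbedMultipleConfs(work, numConfs=n_embed, params=params))
        if conf_ids:
            break
    if not conf_ids:
        raise ChemistryError(f"conformer embedding failed for {label!r}")

    if AllChem.MMFFHasAllMoleculeParams(work):
        results = AllChem.MMFFOptimizeMoleculeConfs(work, maxIters=2000)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(work, maxIters=2000)
    energies = np.array([energy for _converged, energy in results], dtype=float)
    keep = np.isfinite(energies)
    if not keep.any():
        raise ChemistryError(f"force-field minimization failed for {label!r}")

    conf_ids = [cid for cid, ok in zip(conf_ids, keep) if ok]
    energies = energies[keep]
    energies = energies - energies.min()

    pruned_mol = Chem.Mol(work)
    pruned_mol.RemoveAllConformers()
    for cid in conf_ids:
        pruned_mol.AddConformer(work.GetConformer(cid), assignId=True)
    ensemble = _mol_to_ensemble(pruned_mol, energies, label)
    return prune_ensemble(ensemble, energy_window, rmsd_threshold)


def prune_ensemble(
    ensemble: ConformerEnsemble,
    energy_window: float,
    rmsd_threshold: float,
) -> ConformerEnsemble:
    """Energy-window filter plus greedy RMSD deduplication.

    Conformers are visited in order of increasing energy; one is kept if
    it lies within ``energy_window`` of the minimum and differs by more
    than ``rmsd_threshold`` (best-fit RMSD) from every conformer already
    kept.  The RMSD is computed over heavy atoms (hydrogen labels are
    arbitrary under e.g. methyl rotation, which would defeat
    deduplication).  The minimum-energy conformer is always retained, so
    the result is never empty.
    """
    if energy_window < 0 or rmsd_threshold < 0:
        raise ValidationError("energy window and RMSD threshold must be >= 0")
    heavy = np.array(
        [i for i, s in enumerate(ensemble.symbols) if s != "H"], dtype=int
    )
    if heavy.size == 0:
        heavy = np.arange(ensemble.n_atoms)
    order = np.argsort(ensemble.energies, kind="stable")
    e_min = ensemble.energies[order[0]]
    kept: list[int] = []
    for idx in order:
        if ensemble.energies[idx] - e_min > energy_window:
            continue
        duplicate = any(
            kabsch_rmsd(ensemble.coords[idx][heavy], ensemble.coords[j][heavy])
            <= rmsd_threshold
            for j in kept
        )
        if not duplicate:
            kept.append(int(idx))
    kept_arr = np.sort(np.array(kept, dtype=int))  # preserve input ordering

    mol = None
    if ensemble.mol is not None:
        mol = Chem.Mol(ensemble.mol)
        mol.RemoveAllConformers()
        for idx in kept_arr:
            conf = Chem.Conformer(ensemble.n_atoms)
            for a in range(ensemble.n_atoms):
                conf.SetAtomPosition(a, ensemble.coords[idx, a].tolist())
            mol.AddConformer(conf, assignId=True)
    return ConformerEnsemble(
        symbols=ensemble.symbols,
        coords=ensemble.coords[kept_arr],
        energies=ensemble.energies[kept_arr],
        mol=mol,
        label=ensemble.label,
    )


def _resolve_core_match(mol: Chem.Mol, core: Chem.Mol, label: str) -> tuple[int, ...]:
    matches = mol.GetSubstructMatches(core, uniquify=True)
    if not matches:
        raise ChemistryError(f"core motif not found in {label!r}")
    if len(matches) == 1:
        return matches[0]
    # Peptides can contain several prolines; assembly orders atoms N->C,
    # so the match with the lexicographically smallest index tuple is the
    # N-terminal residue.
    return min(matches, key=lambda m: tuple(sorted(m)))


def align_ensemble(
    ensemble: ConformerEnsemble,
    core_indices: np.ndarray,
    reference_coords: np.ndarray,
) -> ConformerEnsemble:
    """Rigidly align every conformer so its core atoms best fit a reference.

    The index-based workhorse behind :func:`align_to_core`; usable
    directly on ensembles that carry no molecule object.
    """
    core_indices = np.asarray(core_indices, dtype=int)
    reference_coords = np.asarray(reference_coords, float)
    if reference_coords.shape != (core_indices.size, 3):
        raise ValidationError(
            f"reference core geometry must have shape ({core_indices.size}, 3)"
        )
    aligned = np.empty_like(ensemble.coords)
    for c in range(ensemble.n_conf):
        rotation, translation = kabsch(
            ensemble.coords[c][core_indices], reference_coords
        )
        aligned[c] = ensemble.coords[c] @ rotation.T + translation
    return replace(ensemble, coords=aligned)


def align_to_core(
    ensemble: ConformerEnsemble,
    core: str | Chem.Mol = PROLINE_CORE_SMARTS,
    reference_coords: np.ndarray | None = None,
) -> ConformerEnsemble:
    """Rigidly align every conformer on a common core motif.

    Each conformer is rotated/translated so that the RMSD of its matched
    core atoms to ``reference_coords`` is minimal; non-core atoms are
    carried along.  When no reference is given, the core geometry of the
    ensemble's lowest-energy conformer serves as the reference (the
    convention used for the first library member processed).
    """
    if ensemble.mol is None:
        raise ValidationError("core alignment requires the RDKit molecule")
    core_mol = Chem.MolFromSmarts(core) if isinstance(core, str) else core
    if core_mol is None:
        raise ValidationError(f"core query does not parse: {core!r}")
    match = _resolve_core_match(ensemble.mol, core_mol, ensemble.label)
    core_idx = np.array(match, dtype=int)
    if reference_coords is None:
        ref_conf = int(np.argmin(ensemble.energies))
        reference_coords = ensemble.coords[ref_conf][core_idx]
    return align_ensemble(ensemble, core_idx, reference_coords)


def core_geometry(
    ensemble: ConformerEnsemble, core: str | Chem.Mol = PROLINE_CORE_SMARTS
) -> np.ndarray:
    """Core-atom coordinates of the lowest-energy conformer.

    Persist this for the first library member processed and pass it as
    ``reference_coords`` when aligning the rest of the library.
    """
    if ensemble.mol is None:
        raise ValidationError("core geometry requires the RDKit molecule")
    core_mol = Chem.MolFromSmarts(core) if isinstance(core, str) else core
    match = _resolve_core_match(ensemble.mol, core_mol, ensemble.label)
    ref_conf = int(np.argmin(ensemble.energies))
    return ensemble.coords[ref_conf][np.array(match, dtype=int)]
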