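"""Shared fixtures: canonical residues, toy ensembles, and a peptide ensemble."""

import numpy as np
import pytest

from pepcat import building_blocks as bb
from pepcat import conformers as conf


@pytest.fixture(scope="session")
def canonical_blocks() -> list[bb.AminoAcid]:
    """D-Pro, L-Pro, Gly, L-Glu — enough to build the classic catalysts."""
    return [
        bb.AminoAcid("dPro", "D-proline", "[*:1]N1CCC[C@@H]1C(=O)[*:2]", "D"),
        bb.AminoAcid("Pro", "L-proline", "[*:1]N1CCC[C@H]1C(=O)[*:2]", "L"),
        bb.AminoAcid("Gly", "glycine", "[*:1]NCC(=O)[*:2]", "achiral"),
        bb.AminoAcid("Glu", "L-glutamic acid", "[*:1]N[C@@H](CCC(=O)O)C(=O)[*:2]", "L"),
    ]


@pytest.fixture(scope="session")
def peptide_ensemble(canonical_blocks) -> conf.ConformerEnsemble:
    """A small aligned ensemble of H-dPro-Pro-Glu-NH2 (session-cached: slow)."""
    spec = bb.PeptideSpec(("dPro", "Pro", "Glu"))
    mol = bb.assemble_peptide(spec, canonical_blocks)
    ensemble = conf.generate_ensemble(mol, n_embed=8, seed=7)
    return conf.align_to_core(ensemble)


def random_toy_ensemble(
    rng: np.random.Generator,
    n_atoms: int = 5,
    n_conf: int = 4,
    box: float = 4.0,
) -> conf.ConformerEnsemble:
    """A chemistry-free ensemble with random coordinates for descriptor oracles."""
    symbols = tuple(rng.choice(["C", "N", "O", "H"], size=n_atoms))
    coords = rng.uniform(-box / 2, box / 2, size=(n_conf, n_atoms, 3))
    energies = rng.uniform(0.0, 3.0, size=n_conf)
    return conf.ConformerEnsemble(symbols=symbols, coords=coords, energies=energies)
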