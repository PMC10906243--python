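"""Synthetic building blocks, selectivity landscapes, and trial datasets.

Every stage of the workflow is testable without downloads because this
module generates inputs with the statistical structure the workflow
assumes:

* toy amino-acid building blocks — chemically valid residues with
  systematically varied side chains (length, polarity, charge,
  halogenation) and L/D stereocenters;
* selectivity landscapes — free energies that are a noisy linear
  function of the reduced descriptor coordinates (so latent-structure
  models can in principle recover them), optionally with one member
  planted as the global optimum;
* trial datasets — catalysts x reactions tables whose conversions
  follow a bimodal three-component mixture (about a quarter of runs
  nearly dead, half partial, a quarter near-quantitative) and whose ee
  and dr span the ranges typical of peptide-catalyzed conjugate
  additions (ee 10-98 %, dr 58:42 to 98:2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .building_blocks import AminoAcid
from .errors import ValidationError
from .selectivity_modeling import (
    DEFAULT_TEMPERATURE,
    SelectivityRecord,
    ddg_to_ee,
)

__all__ = [
    "LandscapeSpec",
    "LandscapeSimulator",
    "make_toy_building_blocks",
    "simulate_selectivity",
    "make_trial_dataset",
]

EE_CAP = 0.999  # keeps the log-ratio energy transform finite

# Side-chain grammar: a linear carbon chain capped by a terminal group.
_TERMINAL_GROUPS = (
    ("", "alkyl"),
    ("O", "hydroxyl"),
    ("N", "amino"),
    ("F", "fluoro"),
    ("Cl", "chloro"),
    ("Br", "bromo"),
    ("S", "thiol"),
    ("C(=O)O", "carboxyl"),
    ("C(=O)N", "amide"),
    ("c1ccccc1", "phenyl"),
)


def _side_chain(variant: int) -> tuple[str, str]:
    """Deterministic, structurally distinct side chain for a variant index."""
    terminal, term_name = _TERMINAL_GROUPS[variant % len(_TERMINAL_GROUPS)]
    length = 1 + variant // len(_TERMINAL_GROUPS)
    return "C" * length + terminal, f"{term_name}-C{length}"


def make_toy_building_blocks(n: int, seed: int = 0) -> list[AminoAcid]:
    """Generate ``n`` distinct, chemically valid toy residues.

    The first residue is glycine-like (no side chain, achiral); the rest
    carry systematically varied side chains on the alpha carbon with
    stereo labels alternating pseudo-randomly between L and D under the
    seed.  Identical (n, seed) always reproduce the same set.
    """
    if n < 1:
        raise ValidationError("need n >= 1 building blocks")
    rng = np.random.default_rng(seed)
    blocks = [
        AminoAcid(
            id="AA000",
            name="glycine-like",
            residue_smiles="[*:1]NCC(=O)[*:2]",
            stereo_tag="achiral",
        )
    ]
    seen = {Chem.CanonSmiles(blocks[0].residue_smiles)}
    variant = 0
    while len(blocks) < n:
        side, side_name = _side_chain(variant)
        variant += 1
        stereo = "L" if rng.random() < 0.5 else "D"
        chirality = "[C@@H]" if stereo == "L" else "[C@H]"
        smiles = f"[*:1]N{chirality}({side})C(=O)[*:2]"
        canonical = Chem.CanonSmiles(smiles)
        if canonical in seen:
            continue
        seen.add(canonical)
        blocks.append(
            AminoAcid(
                id=f"AA{len(blocks):03d}",
                name=f"{stereo}-{side_name}",
                residue_smiles=smiles,
                stereo_tag=stereo,
            )
        )
    return blocks


@dataclass(frozen=True)
class LandscapeSpec:
    """A latent-linear selectivity landscape over reduced descriptor space."""

    weights: np.ndarray
    noise_sd: float = 0.0
    planted_optimum: bool = False
    planted_ddg: float | None = None
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or not np.all(np.isfinite(w)):
            raise ValidationError("weights must be a finite 1-D vector")
        if self.noise_sd < 0:
            raise ValidationError("noise SD must be >= 0")
        object.__setattr__(self, "weights", w)


class LandscapeSimulator:
    """Measurement oracle over a fixed landscape (for campaign replay).

    ``true_ddg`` holds the noiseless free energies; :meth:`measure`
    returns noisy observations, reproducibly under the spec's seed.
    """

    def __init__(self, labels, features: np.ndarray, spec: LandscapeSpec):
        features = np.asarray(features, dtype=float)
        if features.shape[0] != len(labels):
            raise ValidationError("one feature row per label required")
        if features.shape[1] != spec.weights.size:
            raise ValidationError(
                f"feature dimension {features.shape[1]} != weight dimension "
                f"{spec.weights.size}"
            )
        self.labels = list(labels)
        self.spec = spec
        self._index = {lbl: i for i, lbl in enumerate(self.labels)}
        self.true_ddg = features @ spec.weights
        if spec.planted_optimum:
            target = spec.planted_ddg
            if target is None:
                target = float(np.max(np.abs(self.true_ddg))) + 0.5
            planted = int(np.argmax(np.abs(self.true_ddg)))
            self.true_ddg = self.true_ddg.copy()
            self.true_ddg[planted] = target
            self.planted_label = self.labels[planted]
        else:
            self.planted_label = None
        self._rng = np.random.default_rng(spec.seed)

    def measure(self, labels: list[str]) -> dict[str, float]:
        idx = [self._index[lbl] for lbl in labels]
        noise = self._rng.normal(0.0, self.spec.noise_sd, size=len(idx))
        return {
            lbl: float(self.true_ddg[i] + e) for lbl, i, e in zip(labels, idx, noise)
        }


def simulate_selectivity(
    labels,
    features: np.ndarray,
    spec: LandscapeSpec,
    reaction_id: str = "sim",
) -> list[SelectivityRecord]:
    """Draw one noisy selectivity observation per library member.

    ddG = weights . features + Gaussian noise, converted to ee through
    the inverse free-energy transform and capped at +/-0.999.
    """
    sim = LandscapeSimulator(labels, features, spec)
    measured = sim.measure(list(labels))
    records = []
    for lbl in labels:
        ee = float(
            np.clip(ddg_to_ee(measured[lbl], spec.temperature), -EE_CAP, EE_CAP)
        )
        records.append(
            SelectivityRecord(
                catalyst_label=lbl,
                reaction_id=reaction_id,
                conversion_pct=100.0,
                ee=ee,
                dr=(50.0, 50.0),
                temperature=spec.temperature,
            )
        )
    return records


def make_trial_dataset(
    n_catalysts: int = 50,
    n_reactions: int = 4,
    seed: int = 0,
) -> list[SelectivityRecord]:
    """Full catalysts x reactions cross with trial-screen statistics.

    Conversions come from a three-component mixture (25 % below 10 %,
    50 % between 10 and 90 %, 25 % above 90 %); ee is uniform on
    [0.10, 0.98] and the syn fraction of dr uniform on [0.58, 0.98].
    """
    if n_catalysts < 1 or n_reactions < 1:
        raise ValidationError("need at least one catalyst and one reaction")
    rng = np.random.default_rng(seed)
    records = []
    for c in range(n_catalysts):
        label = f"cat{c:03d}"
        for r in range(n_reactions):
            component = rng.choice(3, p=(0.25, 0.50, 0.25))
            if component == 0:
                conversion = rng.uniform(0.0, 10.0)
            elif component == 1:
                conversion = rng.uniform(10.0, 90.0)
            else:
                conversion = rng.uniform(90.0, 100.0)
            ee = rng.uniform(0.10, 0.98)
            syn = rng.uniform(0.58, 0.98)
            records.append(
                SelectivityRecord(
                    catalyst_label=label,
                    reaction_id=f"rxn{r + 1}",
                    conversion_pct=float(conversion),
                    ee=float(ee),
                    dr=(float(100 * syn), float(100 * (1 - syn))),
                )
            )
    return records
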