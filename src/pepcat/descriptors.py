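"""Conformer-averaged grid descriptors and the reduced feature space.

Two fields are computed on a shared rectangular grid enclosing the
aligned ensembles:

* **ASO** (average steric occupancy): at grid point *g*, the fraction of
  conformers in which at least one atom's van der Waals sphere covers
  *g*.  Values lie in [0, 1]; a single-conformer ensemble yields a
  binary field.

* **AEIF** (average electronic indicator field): at grid point *g*, the
  conformer average of the partial charge of the nearest atom whose vdW
  sphere covers *g* (zero where no atom covers the point).  This
  nearest-covering-atom realization is one admissible form of the
  electronic indicator; it is swappable behind this module's interface.

Per-catalyst fields are flattened, concatenated (ASO then AEIF),
standardized column-wise, pruned of zero-variance and highly correlated
columns, and projected onto principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import AllChem
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .conformers import ConformerEnsemble
from .errors import ConfigurationError, ValidationError

__all__ = [
    "BONDI_RADII",
    "Grid",
    "CatalystFields",
    "FeatureMatrix",
    "ReducedSpace",
    "compute_aso",
    "compute_aeif",
    "gasteiger_charges",
    "assemble_feature_matrix",
    "reduce_features",
]

# Bondi van der Waals radii, Angstrom.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}


@dataclass(frozen=True)
class Grid:
    """A rectangular grid of probe points.

    ``origin`` is the lowest corner; points sit at
    ``origin + spacing * (i, j, k)`` for ``0 <= i < dims[0]`` etc.,
    flattened in C order (k fastest).
    """

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValidationError("grid spacing must be > 0")
        if any(d < 1 for d in self.dims):
            raise ValidationError("grid dims must all be >= 1")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        axes = [
            np.asarray(self.origin)[i] + self.spacing * np.arange(self.dims[i])
            for i in range(3)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    @classmethod
    def from_ensembles(
        cls,
        ensembles: list[ConformerEnsemble],
        spacing: float = 1.0,
        margin: float = 3.0,
    ) -> "Grid":
        """Build a grid enclosing all aligned calibration ensembles plus a margin."""
        if not ensembles:
            raise ValidationError("at least one ensemble is required")
        all_xyz = np.concatenate([e.coords.reshape(-1, 3) for e in ensembles])
        lo = all_xyz.min(axis=0) - margin
        hi = all_xyz.max(axis=0) + margin
        dims = tuple(int(np.floor((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
        return cls(origin=tuple(float(x) for x in lo), spacing=spacing, dims=dims)


def _radii_for(ensemble: ConformerEnsemble, radii: dict[str, float]) -> np.ndarray:
    missing = sorted({s for s in ensemble.symbols if s not in radii})
    if missing:
        raise ConfigurationError(
            f"no van der Waals radius for element(s): {', '.join(missing)}"
        )
    return np.array([radii[s] for s in ensemble.symbols], dtype=float)


def compute_aso(
    ensemble: ConformerEnsemble,
    grid: Grid,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Average steric occupancy: fraction of conformers covering each point."""
    r = _radii_for(ensemble, radii if radii is not None else BONDI_RADII)
    pts = grid.points()
    occupancy = np.zeros(grid.n_points)
    for c in range(ensemble.n_conf):
        dists = cdist(pts, ensemble.coords[c])
        occupancy += (dists <= r[None, :]).any(axis=1)
    return occupancy / ensemble.n_conf


def compute_aeif(
    ensemble: ConformerEnsemble,
    grid: Grid,
    charges: np.ndarray,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Average electronic indicator: conformer-mean charge of the nearest covering atom."""
    charges = np.asarray(charges, dtype=float)
    if charges.shape != (ensemble.n_atoms,):
        raise ValidationError(
            f"need one charge per atom ({ensemble.n_atoms}), got shape {charges.shape}"
        )
    r = _radii_for(ensemble, radii if radii is not None else BONDI_RADII)
    pts = grid.points()
    total = np.zeros(grid.n_points)
    for c in range(ensemble.n_conf):
        dists = cdist(pts, ensemble.coords[c])
        covering = dists <= r[None, :]
        masked = np.where(covering, dists, np.inf)
        nearest = np.argmin(masked, axis=1)
        any_cover = covering.any(axis=1)
        total += np.where(any_cover, charges[nearest], 0.0)
    return total / ensemble.n_conf


def gasteiger_charges(mol) -> np.ndarray:
    """Gasteiger-Marsili partial charges (fast empirical model), one per atom."""
    work = AllChem.Mol(mol)
    AllChem.ComputeGasteigerCharges(work)
    q = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in work.GetAtoms()], dtype=float
    )
    return np.nan_to_num(q)


@dataclass(frozen=True)
class CatalystFields:
    """ASO + AEIF fields of one catalyst on a shared grid."""

    label: str
    grid: Grid
    aso: np.ndarray
    aeif: np.ndarray

    def __post_init__(self) -> None:
        for name, values in (("aso", self.aso), ("aeif", self.aeif)):
            v = np.asarray(values, dtype=float)
            if v.shape != (self.grid.n_points,):
                raise ValidationError(
                    f"{name} field of {self.label!r} has shape {v.shape}, "
                    f"expected ({self.grid.n_points},)"
                )
            object.__setattr__(self, name, v)
        if np.any(self.aso < 0) or np.any(self.aso > 1):
            raise ValidationError(f"ASO of {self.label!r} outside [0, 1]")


@dataclass(frozen=True)
class FeatureMatrix:
    """Standardized flattened descriptor matrix with reusable scaling.

    ``values[i] = (raw[i] - means) / scales`` where raw rows are
    ``concat(ASO, AEIF)``.  Columns with zero variance get scale 1 so
    standardization is always invertible; they are dropped later by
    :func:`reduce_features`.
    """

    values: np.ndarray
    labels: tuple[str, ...]
    column_provenance: tuple[tuple[str, int], ...]
    means: np.ndarray
    scales: np.ndarray
    grid: Grid = field(compare=False, default=None)

    @property
    def n_catalysts(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def transform(self, raw_rows: np.ndarray) -> np.ndarray:
        """Apply the stored scaling to new raw descriptor rows."""
        raw_rows = np.atleast_2d(np.asarray(raw_rows, dtype=float))
        if raw_rows.shape[1] != self.n_features:
            raise ValidationError(
                f"expected {self.n_features} columns, got {raw_rows.shape[1]}"
            )
        return (raw_rows - self.means) / self.scales


def assemble_feature_matrix(fields: list[CatalystFields]) -> FeatureMatrix:
    """Flatten, concatenate, and standardize per-catalyst fields."""
    if not fields:
        raise ValidationError("no catalyst fields supplied")
    grid = fields[0].grid
    for f in fields[1:]:
        if f.grid != grid:
            raise ValidationError(
                f"grid of {f.label!r} differs from {fields[0].label!r}; "
                "all catalysts must share one grid"
            )
    raw = np.stack([np.concatenate([f.aso, f.aeif]) for f in fields])
    means = raw.mean(axis=0)
    stds = raw.std(axis=0)
    scales = np.where(stds > 0, stds, 1.0)
    provenance = tuple(
        [("aso", i) for i in range(grid.n_points)]
        + [("aeif", i) for i in range(grid.n_points)]
    )
    return FeatureMatrix(
        values=(raw - means) / scales,
        labels=tuple(f.label for f in fields),
        column_provenance=provenance,
        means=means,
        scales=scales,
        grid=grid,
    )


@dataclass(frozen=True)
class ReducedSpace:
    """Pruned, PCA-projected descriptor space.

    ``coordinates`` are the training catalysts' positions on the first
    ``n_components`` principal components; ``retained_columns`` indexes
    into the standardized feature matrix so new catalysts can be
    projected with :meth:`transform`.
    """

    coordinates: np.ndarray
    labels: tuple[str, ...]
    retained_columns: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    center: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def transform(self, standardized_rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(standardized_rows, dtype=float))
        pruned = rows[:, self.retained_columns]
        return (pruned - self.center) @ self.loadings.T


def _prune_columns(
    values: np.ndarray, var_tol: float, corr_threshold: float
) -> np.ndarray:
    """Indices of columns surviving variance and correlation pruning.

    Columns are scanned in index order; the later member of any pair
    with |Pearson r| >= corr_threshold is dropped (deterministic greedy
    rule).
    """
    variances = values.var(axis=0)
    candidates = np.flatnonzero(variances > var_tol)
    if candidates.size == 0:
        return candidates
    # unit-normalized columns make the pairwise correlation a dot product
    sub = values[:, candidates]
    centered = sub - sub.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    unit = centered / norms
    kept: list[int] = []
    for j in range(candidates.size):
        if kept:
            corr = np.abs(unit[:, kept].T @ unit[:, j])
            if np.any(corr >= corr_threshold):
                continue
        kept.append(j)
    return candidates[np.array(kept, dtype=int)]


def reduce_features(
    matrix: FeatureMatrix,
    var_tol: float = 1e-12,
    corr_threshold: float = 0.95,
    n_pc: int = 20,
) -> ReducedSpace:
    """Variance/correlation pruning followed by PCA projection."""
    if matrix.n_catalysts < 2:
        raise ValidationError("feature reduction needs at least 2 catalysts")
    retained = _prune_columns(matrix.values, var_tol, corr_threshold)
    max_pc = min(len(retained), matrix.n_catalysts - 1)
    if n_pc > max_pc:
        raise ValidationError(
            f"n_pc={n_pc} exceeds the {max_pc} components supported by "
            f"{len(retained)} retained columns and {matrix.n_catalysts} catalysts"
        )
    pruned = matrix.values[:, retained]
    pca = PCA(n_components=n_pc, svd_solver="full")
    coords = pca.fit_transform(pruned)
    return ReducedSpace(
        coordinates=coords,
        labels=matrix.labels,
        retained_columns=retained,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        center=pca.mean_,
    )
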