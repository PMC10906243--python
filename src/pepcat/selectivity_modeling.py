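"""Free-energy targets, catalyst-out validation splits, and PLS models.

Stereoselectivities are modeled on the free-energy scale: an observed
enantiomeric excess *ee* (signed fraction, the sign encoding which
enantiomer predominates) maps to the difference in activation free
energies of the competing pathways,

    ddG = R * T * ln((1 + ee) / (1 - ee)),

and a diastereomeric ratio syn:anti maps to ddG = R * T * ln(syn/anti).
Both transforms are strictly monotone and antisymmetric, so modeling on
the energy scale preserves ranking while linearizing the saturating ee
scale.

Models are Projection-to-Latent-Structures (PLS) regressions on the
descriptor features, with the reaction identity one-hot encoded so one
model can span several trial reactions.  Validation is catalyst-out:
held-out catalysts contribute no training rows at all, which is the
honest test for predicting an unseen catalyst.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GroupKFold

from .errors import ValidationError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "SelectivityRecord",
    "SplitPlan",
    "ModelReport",
    "PLSModel",
    "ee_to_ddg",
    "ddg_to_ee",
    "dr_to_ddg",
    "make_catalyst_split",
    "fit_pls",
    "evaluate",
    "build_design_matrix",
    "load_selectivity_csv",
    "write_selectivity_csv",
]

GAS_CONSTANT_KCAL = 1.987e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 293.15  # K; trial reactions run at 20 C


def ee_to_ddg(ee: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a signed ee fraction to ddG in kcal/mol."""
    ee = float(ee)
    if not -1.0 < ee < 1.0:
        raise ValidationError(f"ee must lie strictly inside (-1, 1), got {ee}")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    # 2*atanh(ee) == ln((1+ee)/(1-ee)), exact for tiny ee where 1+ee rounds to 1
    return GAS_CONSTANT_KCAL * temperature * 2.0 * float(np.arctanh(ee))


def ddg_to_ee(ddg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`ee_to_ddg` (a scaled tanh)."""
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    return float(np.tanh(np.asarray(ddg, dtype=float) / (2.0 * GAS_CONSTANT_KCAL * temperature)))


def dr_to_ddg(syn: float, anti: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a syn:anti diastereomeric ratio to ddG in kcal/mol."""
    if syn <= 0 or anti <= 0:
        raise ValidationError(f"dr components must be positive, got {syn}:{anti}")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * float(np.log(syn / anti))


@dataclass(frozen=True)
class SelectivityRecord:
    """One experimental observation of a catalyst in a reaction."""

    catalyst_label: str
    reaction_id: str
    conversion_pct: float
    ee: float
    dr: tuple[float, float]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_pct <= 100.0:
            raise ValidationError(
                f"conversion must be in [0, 100] %, got {self.conversion_pct}"
            )
        if not -1.0 < self.ee < 1.0:
            raise ValidationError(f"ee must be strictly inside (-1, 1), got {self.ee}")
        if self.dr[0] <= 0 or self.dr[1] <= 0:
            raise ValidationError(f"dr components must be positive, got {self.dr}")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")

    @property
    def ddg_ee(self) -> float:
        return ee_to_ddg(self.ee, self.temperature)

    @property
    def ddg_dr(self) -> float:
        return dr_to_ddg(self.dr[0], self.dr[1], self.temperature)


@dataclass(frozen=True)
class SplitPlan:
    """Catalyst-out train/test partition (all of a catalyst's rows move together)."""

    held_out_catalysts: tuple[str, ...]
    train_catalysts: tuple[str, ...]
    seed: int
    pinned: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.held_out_catalysts) & set(self.train_catalysts)
        if overlap:
            raise ValidationError(
                f"catalysts in both partitions: {sorted(overlap)}"
            )


def make_catalyst_split(
    records: list[SelectivityRecord],
    n_random: int,
    pinned: list[str] | None = None,
    seed: int = 0,
) -> SplitPlan:
    """Hold out ``n_random`` random catalysts plus any pinned labels.

    Pinned labels (e.g. the top performer, deliberately held out to test
    extrapolation to the best catalyst) are always in the test set; the
    random draw is uniform without replacement over the remainder.
    """
    pinned = list(pinned or [])
    catalysts = sorted({r.catalyst_label for r in records})
    missing = [p for p in pinned if p not in catalysts]
    if missing:
        raise ValidationError(f"pinned catalyst(s) not in records: {missing}")
    eligible = [c for c in catalysts if c not in pinned]
    if n_random < 0 or n_random + len(pinned) > len(catalysts):
        raise ValidationError(
            f"cannot hold out {n_random} random + {len(pinned)} pinned from "
            f"{len(catalysts)} catalysts"
        )
    rng = np.random.default_rng(seed)
    drawn = sorted(rng.choice(eligible, size=n_random, replace=False).tolist())
    held = tuple(sorted(drawn + pinned))
    train = tuple(c for c in catalysts if c not in held)
    return SplitPlan(held_out_catalysts=held, train_catalysts=train, seed=seed, pinned=tuple(pinned))


def build_design_matrix(
    records: list[SelectivityRecord],
    feature_lookup: dict[str, np.ndarray],
    reaction_ids: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Stack per-record rows: catalyst features plus reaction one-hot indicators.

    Returns the matrix and the reaction-id ordering used for the
    indicator block (reuse it when encoding new records).
    """
    if reaction_ids is None:
        reaction_ids = sorted({r.reaction_id for r in records})
    missing = sorted({r.catalyst_label for r in records} - set(feature_lookup))
    if missing:
        raise ValidationError(f"no features for catalyst(s): {missing}")
    rows = []
    for r in records:
        onehot = np.zeros(len(reaction_ids))
        if r.reaction_id in reaction_ids:
            onehot[reaction_ids.index(r.reaction_id)] = 1.0
        rows.append(np.concatenate([np.asarray(feature_lookup[r.catalyst_label], float), onehot]))
    return np.stack(rows), list(reaction_ids)


class PLSModel:
    """A fitted PLS regression with its component count and training scope."""

    def __init__(self, pls: PLSRegression, n_latent: int, train_labels: tuple[str, ...]):
        self._pls = pls
        self.n_latent = n_latent
        self.train_labels = train_labels

    @property
    def coef_(self) -> np.ndarray:
        """Flattened regression coefficients in the original feature space."""
        return np.ravel(self._pls.coef_)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.ravel(self._pls.predict(np.atleast_2d(np.asarray(features, float))))


def fit_pls(
    features: np.ndarray,
    targets: np.ndarray,
    n_latent: int | None = None,
    max_latent: int = 10,
    groups: np.ndarray | None = None,
    train_labels: tuple[str, ...] = (),
) -> PLSModel:
    """Fit a PLS regression, optionally choosing components by grouped CV.

    When ``n_latent`` is None the component count (1..max_latent) is
    selected by leave-catalyst-group-out cross-validation on MAE; pass
    ``groups`` as the per-row catalyst labels.  Without groups, rows are
    grouped singly (plain K-fold).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValidationError("features must be 2-D with one target per row")
    cap = min(max_latent, X.shape[1], X.shape[0] - 1)
    if cap < 1:
        raise ValidationError(
            f"cannot fit PLS: {X.shape[0]} rows x {X.shape[1]} features "
            "support no latent components"
        )
    if n_latent is not None:
        if not 1 <= n_latent <= cap:
            raise ValidationError(
                f"n_latent={n_latent} outside the supported range [1, {cap}]"
            )
        chosen = n_latent
    else:
        if groups is None:
            groups = np.arange(X.shape[0])
        groups = np.asarray(groups)
        n_groups = len(np.unique(groups))
        n_splits = min(5, n_groups)
        if n_splits < 2:
            chosen = cap
        else:
            cv = GroupKFold(n_splits=n_splits)
            best_mae, chosen = np.inf, 1
            for k in range(1, cap + 1):
                errors = []
                for tr, te in cv.split(X, y, groups):
                    if len(tr) <= k:
                        continue
                    m = PLSRegression(n_components=k, scale=False).fit(X[tr], y[tr])
                    errors.append(np.mean(np.abs(np.ravel(m.predict(X[te])) - y[te])))
                if errors and np.mean(errors) < best_mae - 1e-12:
                    best_mae, chosen = float(np.mean(errors)), k
    pls = PLSRegression(n_components=chosen, scale=False).fit(X, y)
    return PLSModel(pls, chosen, tuple(train_labels))


@dataclass(frozen=True)
class ModelReport:
    """Train/test MAE in kcal/mol plus per-record predicted/observed pairs."""

    mae_train: float
    mae_test: float
    n_latent: int
    predictions: list[dict] = field(compare=False, default_factory=list)


def evaluate(
    model: PLSModel,
    split: SplitPlan,
    records: list[SelectivityRecord],
    feature_lookup: dict[str, np.ndarray],
    target: str = "ee",
    reaction_ids: list[str] | None = None,
) -> ModelReport:
    """Score a fitted model on the catalyst-out split.

    ``target`` selects the enantio- (``"ee"``) or diastereoselectivity
    (``"dr"``) free-energy observable.  Raises if any held-out catalyst
    leaked into the model's training scope.
    """
    if target not in ("ee", "dr"):
        raise ValidationError("target must be 'ee' or 'dr'")
    leaked = set(split.held_out_catalysts) & set(model.train_labels)
    if leaked:
        raise ValidationError(f"held-out catalyst(s) were used in training: {sorted(leaked)}")
    train_rows = [r for r in records if r.catalyst_label in split.train_catalysts]
    test_rows = [r for r in records if r.catalyst_label in split.held_out_catalysts]
    if not train_rows:
        raise ValidationError("split leaves no training rows")

    def observed(r: SelectivityRecord) -> float:
        return r.ddg_ee if target == "ee" else r.ddg_dr

    preds = []
    maes = {}
    for part, rows in (("train", train_rows), ("test", test_rows)):
        if not rows:
            maes[part] = float("nan")
            continue
        X, _ = build_design_matrix(rows, feature_lookup, reaction_ids)
        y = np.array([observed(r) for r in rows])
        yhat = model.predict(X)
        maes[part] = float(np.mean(np.abs(yhat - y)))
        preds.extend(
            {
                "catalyst": r.catalyst_label,
                "reaction": r.reaction_id,
                "partition": part,
                "observed_ddg": float(obs),
                "predicted_ddg": float(p),
            }
            for r, obs, p in zip(rows, y, yhat)
        )
    return ModelReport(
        mae_train=maes["train"],
        mae_test=maes["test"],
        n_latent=model.n_latent,
        predictions=preds,
    )


SELECTIVITY_COLUMNS = (
    "catalyst_label",
    "reaction_id",
    "conversion_pct",
    "ee",
    "dr_syn",
    "dr_anti",
    "temperature_K",
)


def load_selectivity_csv(path) -> list[SelectivityRecord]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        missing = [c for c in SELECTIVITY_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")
        return [
            SelectivityRecord(
                catalyst_label=row["catalyst_label"],
                reaction_id=row["reaction_id"],
                conversion_pct=float(row["conversion_pct"]),
                ee=float(row["ee"]),
                dr=(float(row["dr_syn"]), float(row["dr_anti"])),
                temperature=float(row["temperature_K"]),
            )
            for row in reader
        ]


def write_selectivity_csv(path, records: list[SelectivityRecord]) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(SELECTIVITY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.catalyst_label,
                    r.reaction_id,
                    f"{r.conversion_pct:.4f}",
                    f"{r.ee:.6f}",
                    f"{r.dr[0]:.4f}",
                    f"{r.dr[1]:.4f}",
                    f"{r.temperature:.2f}",
                ]
            )
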