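"""Iterative, uncertainty-aware optimization over the in-silico library.

Each round fits a configurable zoo of regressors on the accumulated
measurements, scores every unmeasured library member on the free-energy
scale, and selects the next batch either greedily (highest predicted
|ddG|) or after discarding candidates whose ensemble prediction spread
exceeds a certainty quantile.  Greedy selection with a flexible model is
the "high-risk, high-reward" strategy; certainty filtering trades some
predicted upside for predictions the ensemble actually agrees on, which
matters when candidates lie in sparsely populated regions of descriptor
space where flexible models extrapolate wildly.

The certainty score implemented here is the population standard
deviation of the predictions of all ensemble members (every model family
refit on every cross-validation fold), in kcal/mol; 0 means unanimous.
It is one documented realization of a prediction-confidence metric and
is swappable behind :func:`prediction_certainty`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .errors import ValidationError
from .selectivity_modeling import ddg_to_ee

__all__ = [
    "MODEL_FAMILIES",
    "FittedZoo",
    "CandidateScore",
    "RoundPlan",
    "CampaignState",
    "fit_model_zoo",
    "prediction_certainty",
    "rank_candidates",
    "run_campaign",
]


def _make_family(name: str, n_features: int, n_rows: int, seed: int):
    if name == "pls":
        return PLSRegression(
            n_components=min(5, n_features, max(1, n_rows - 2)), scale=False
        )
    if name == "kernel_ridge":
        return KernelRidge(kernel="rbf", alpha=0.1, gamma=1.0 / max(n_features, 1))
    if name == "random_forest":
        return RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "mlp":
        # lbfgs converges tightly and deterministically at desk-scale n
        return MLPRegressor(
            hidden_layer_sizes=(min(64, 2 * n_features),),
            solver="lbfgs",
            random_state=seed,
            max_iter=5000,
        )
    raise ValidationError(f"unknown model family {name!r}")


MODEL_FAMILIES = ("pls", "kernel_ridge", "random_forest", "mlp")


@dataclass
class FittedZoo:
    """Per-family full fits plus per-fold member models and CV scores."""

    families: tuple[str, ...]
    full_models: dict[str, object]
    fold_models: dict[str, list[object]]
    cv_mae: dict[str, float]
    failures: dict[str, str]
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Ensemble point prediction: mean over the families' full fits."""
        X = np.atleast_2d(np.asarray(X, float))
        preds = [np.ravel(m.predict(X)) for m in self.full_models.values()]
        return np.mean(preds, axis=0)

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        """Matrix (n_members, n_candidates) over all (family, fold) models."""
        X = np.atleast_2d(np.asarray(X, float))
        members = []
        for fam in self.families:
            if fam in self.failures:
                continue
            for m in self.fold_models[fam]:
                members.append(np.ravel(m.predict(X)))
        if not members:
            raise ValidationError("no fitted ensemble members")
        return np.stack(members)


def fit_model_zoo(
    X: np.ndarray,
    y: np.ndarray,
    families: Sequence[str] = MODEL_FAMILIES,
    seed: int = 0,
    n_folds: int = 5,
    min_rows: int = 20,
) -> FittedZoo:
    """Fit every configured family under K-fold cross-validation.

    A family that raises during fitting is recorded in ``failures`` and
    excluded rather than aborting the round.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < min_rows:
        raise ValidationError(
            f"model zoo needs >= {min_rows} training records, got {X.shape[0]}"
        )
    full_models: dict[str, object] = {}
    fold_models: dict[str, list[object]] = {}
    cv_mae: dict[str, float] = {}
    failures: dict[str, str] = {}
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(splitter.split(X))
    for fam in families:
        try:
            members, errors = [], []
            for tr, te in folds:
                m = _make_family(fam, X.shape[1], len(tr), seed)
                m.fit(X[tr], y[tr])
                members.append(m)
                errors.append(np.mean(np.abs(np.ravel(m.predict(X[te])) - y[te])))
            full = _make_family(fam, X.shape[1], X.shape[0], seed)
            full.fit(X, y)
            full_models[fam] = full
            fold_models[fam] = members
            cv_mae[fam] = float(np.mean(errors))
        except Exception as err:
            failures[fam] = f"{type(err).__name__}: {err}"
    if not full_models:
        raise ValidationError(f"every model family failed: {failures}")
    return FittedZoo(
        families=tuple(families),
        full_models=full_models,
        fold_models=fold_models,
        cv_mae=cv_mae,
        failures=failures,
        seed=seed,
    )


def prediction_certainty(zoo: FittedZoo, X: np.ndarray) -> np.ndarray:
    """Prediction spread (population SD over ensemble members), per candidate."""
    members = zoo.member_predictions(X)
    if members.shape[0] < 2:
        raise ValidationError(
            "certainty needs >= 2 ensemble member predictions; use greedy mode "
            "for single-member ensembles"
        )
    return members.std(axis=0, ddof=0)


@dataclass(frozen=True)
class CandidateScore:
    """One library member's predicted selectivity and ensemble agreement."""

    label: str
    predicted_ddg: float
    predicted_ee: float
    certainty: float
    model: str


def rank_candidates(
    labels: Sequence[str],
    X: np.ndarray,
    zoo: FittedZoo,
    mode: str = "greedy",
    certainty_quantile: float = 0.5,
    exclude: set[str] | None = None,
    temperature: float = 293.15,
) -> list[CandidateScore]:
    """Score and rank the unmeasured library by predicted |ddG|.

    ``mode="greedy"`` sorts purely by predicted magnitude;
    ``mode="certainty"`` first discards candidates whose prediction
    spread lies above the given quantile of the candidate pool, then
    sorts.  Already-measured catalysts are excluded before either step.
    """
    if mode not in ("greedy", "certainty"):
        raise ValidationError(f"unknown selection mode {mode!r}")
    exclude = exclude or set()
    X = np.atleast_2d(np.asarray(X, float))
    if len(labels) != X.shape[0]:
        raise ValidationError("labels and feature rows disagree")
    keep = [i for i, lbl in enumerate(labels) if lbl not in exclude]
    if not keep:
        raise ValidationError("no unmeasured candidates remain")
    keep = np.array(keep, dtype=int)
    preds = zoo.predict(X[keep])
    spread = prediction_certainty(zoo, X[keep])
    if mode == "certainty":
        cutoff = np.quantile(spread, certainty_quantile)
        admitted = spread <= cutoff if certainty_quantile > 0 else spread < cutoff
        if not admitted.any():
            raise ValidationError(
                "certainty filter removed every candidate; loosen the quantile"
            )
        keep, preds, spread = keep[admitted], preds[admitted], spread[admitted]
    provenance = "+".join(sorted(zoo.full_models))
    scored = [
        CandidateScore(
            label=labels[i],
            predicted_ddg=float(p),
            predicted_ee=float(
                np.clip(ddg_to_ee(p, temperature), -1 + 1e-12, 1 - 1e-12)
            ),
            certainty=float(s),
            model=provenance,
        )
        for i, p, s in zip(keep, preds, spread)
    ]
    return sorted(scored, key=lambda c: (-abs(c.predicted_ddg), c.label))


@dataclass
class RoundPlan:
    """Configuration and realized picks of one optimization round."""

    round_index: int
    families: tuple[str, ...]
    mode: str
    certainty_quantile: float
    picks: tuple[str, ...] = ()
    predicted_ddg: tuple[float, ...] = ()
    realized_ddg: tuple[float, ...] = ()


@dataclass
class CampaignState:
    """Accumulated measurements and per-round history of a campaign."""

    measured: dict[str, float] = field(default_factory=dict)
    rounds: list[RoundPlan] = field(default_factory=list)
    best_trace: list[float] = field(default_factory=list)

    @property
    def best_ddg(self) -> float:
        return max(self.measured.values(), key=abs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "measured": self.measured,
                "rounds": [asdict(r) for r in self.rounds],
                "best_trace": self.best_trace,
            },
            indent=2,
        )


DEFAULT_ROUNDS = (
    {"families": ("mlp",), "mode": "greedy", "certainty_quantile": 1.0},
    {"families": ("pls", "kernel_ridge", "random_forest"), "mode": "certainty",
     "certainty_quantile": 0.5},
    {"families": ("pls", "kernel_ridge", "random_forest"), "mode": "certainty",
     "certainty_quantile": 0.5},
)


def run_campaign(
    labels: Sequence[str],
    X: np.ndarray,
    initial_measurements: dict[str, float],
    oracle: Callable[[list[str]], dict[str, float]],
    rounds: Sequence[dict] = DEFAULT_ROUNDS,
    batch_size: int = 5,
    seed: int = 0,
    temperature: float = 293.15,
) -> CampaignState:
    """Run an iterative optimization campaign over the library.

    Per round: fit the round's model zoo on every measurement so far,
    rank the unmeasured library, pick the top ``batch_size`` candidates,
    acquire their outcomes from ``oracle`` (a simulator, or a lookup
    into a measurement file in real campaigns), and append them to the
    training data.  The default schedule mirrors a greedy neural-network
    first round followed by certainty-filtered rounds with simpler
    models.
    """
    if not initial_measurements:
        raise ValidationError("campaign needs nonempty initial measurements")
    unknown = set(initial_measurements) - set(labels)
    if unknown:
        raise ValidationError(f"initial measurements not in library: {sorted(unknown)}")
    X = np.atleast_2d(np.asarray(X, float))
    index = {lbl: i for i, lbl in enumerate(labels)}
    state = CampaignState(measured=dict(initial_measurements))
    state.best_trace.append(abs(state.best_ddg))
    for r, cfg in enumerate(rounds):
        plan = RoundPlan(
            round_index=r,
            families=tuple(cfg["families"]),
            mode=cfg["mode"],
            certainty_quantile=float(cfg.get("certainty_quantile", 0.5)),
        )
        if batch_size > 0:
            train_labels = sorted(state.measured)
            Xtr = X[[index[lbl] for lbl in train_labels]]
            ytr = np.array([state.measured[lbl] for lbl in train_labels])
            zoo = fit_model_zoo(Xtr, ytr, families=plan.families, seed=seed + r)
            ranked = rank_candidates(
                labels,
                X,
                zoo,
                mode=plan.mode,
                certainty_quantile=plan.certainty_quantile,
                exclude=set(state.measured),
                temperature=temperature,
            )
            picks = ranked[:batch_size]
            outcomes = oracle([c.label for c in picks])
            missing = [c.label for c in picks if c.label not in outcomes]
            if missing:
                raise ValidationError(f"oracle returned no outcome for: {missing}")
            plan.picks = tuple(c.label for c in picks)
            plan.predicted_ddg = tuple(c.predicted_ddg for c in picks)
            plan.realized_ddg = tuple(float(outcomes[c.label]) for c in picks)
            for c in picks:
                state.measured[c.label] = float(outcomes[c.label])
        state.rounds.append(plan)
        state.best_trace.append(abs(state.best_ddg))
    return state
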