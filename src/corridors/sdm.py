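"""Ensemble habitat-suitability modelling.

Per-species presence/pseudo-absence data are fit with a configurable
registry of learner families; each family is scored by repeated
stratified holdout AUC, families above a retention threshold are refit
on all data, and the ensemble prediction is the AUC-weighted mean of
the retained families' occurrence probabilities. Per-species maps are
stacked (cell-wise summed) into a multi-species habitat index.

The central object is :class:`EnsembleSuitabilityModel`, a
scikit-learn-compatible classifier (``fit`` / ``predict_proba``,
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) usable inside sklearn pipelines and model selection; the
raster-level helpers (`fit_ensemble`, `stack_suitability`) are thin
wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .raster import PredictorStack, PresenceSet, RasterGrid

__all__ = [
    "LEARNER_REGISTRY",
    "DEFAULT_FAMILIES",
    "ThinningConfig",
    "LearnerResult",
    "EnsembleModel",
    "SuitabilityMap",
    "EnsembleSuitabilityModel",
    "auc",
    "collinearity_screen",
    "thin_points",
    "generate_pseudo_absences",
    "fit_ensemble",
    "stack_suitability",
]


# --------------------------------------------------------------------------
# learner registry
# --------------------------------------------------------------------------

def _logistic(rs: int):
    return make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=2000, random_state=rs)
    )


def _boosted_trees(rs: int):
    return GradientBoostingClassifier(n_estimators=100, random_state=rs)


def _random_forest(rs: int):
    return RandomForestClassifier(n_estimators=200, random_state=rs)


def _maxent_like(rs: int):
    # exponential-family model on linear + quadratic features, the usual
    # GLM approximation to a maximum-entropy occurrence model
    return make_pipeline(
        StandardScaler(),
        PolynomialFeatures(degree=2, include_bias=False),
        LogisticRegression(max_iter=4000, C=1.0, random_state=rs),
    )


#: Extensible registry: family name -> factory(random_state) -> estimator.
LEARNER_REGISTRY: dict[str, Callable[[int], BaseEstimator]] = {
    "logistic": _logistic,
    "boosted_trees": _boosted_trees,
    "random_forest": _random_forest,
    "maxent": _maxent_like,
}

DEFAULT_FAMILIES: tuple[str, ...] = tuple(LEARNER_REGISTRY)


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class ThinningConfig:
    """Minimum inter-point distance (m) for geographic thinning."""

    min_distance: float = 0.0

    def __post_init__(self) -> None:
        if self.min_distance < 0:
            raise ValueError("min_distance must be nonnegative")


@dataclass
class LearnerResult:
    family: str
    rep_aucs: list[float]
    mean_auc: float
    retained: bool
    predictor_contributions: dict[str, float] = field(default_factory=dict)


@dataclass
class EnsembleModel:
    """Fitted per-species ensemble with per-learner holdout diagnostics."""

    species: str
    learners: list[LearnerResult]
    weights: dict[str, float]
    estimator: "EnsembleSuitabilityModel"

    def report(self) -> pd.DataFrame:
        """Learner report table: family, mean AUC, retention, contributions."""
        rows = []
        for lr in self.learners:
            row = {
                "species": self.species,
                "family": lr.family,
                "mean_auc": lr.mean_auc,
                "retained": lr.retained,
                "weight": self.weights.get(lr.family, 0.0),
            }
            for name, c in lr.predictor_contributions.items():
                row[f"contrib_{name}"] = c
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SuitabilityMap:
    """Per-species suitability in [0, 1], or a stacked index in [0, S]."""

    grid: RasterGrid
    species_label: str
    n_species: int = 1

    def __post_init__(self) -> None:
        v = self.grid.values[self.grid.valid_mask]
        if v.size and (v.min() < -1e-9 or v.max() > self.n_species + 1e-9):
            raise ValueError(
                f"suitability values outside [0, {self.n_species}] for "
                f"'{self.species_label}'"
            )


# --------------------------------------------------------------------------
# primitive operations
# --------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute one half.

    Equals the probability that a random presence outscores a random
    absence, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def collinearity_screen(predictors: PredictorStack,
                        threshold: float = 0.7) -> pd.DataFrame:
    """All pairwise Pearson correlations between predictor layers.

    Computed over jointly valid cells; pairs with |r| above the threshold
    are flagged but never dropped automatically. A constant layer makes
    the pair's r undefined (NaN, ``defined=False``).
    """
    if len(predictors) < 2:
        raise ValueError("collinearity screen needs at least two layers")
    valid = predictors.valid_mask
    rows = []
    names = predictors.names
    for i, a in enumerate(names):
        for b in names[i:]:
            va = predictors.layers[a].values[valid]
            vb = predictors.layers[b].values[valid]
            if va.std() == 0 or vb.std() == 0:
                r, defined = np.nan, False
            else:
                r, defined = float(np.corrcoef(va, vb)[0, 1]), True
            rows.append(
                {
                    "layer_a": a,
                    "layer_b": b,
                    "r": r,
                    "defined": defined,
                    "flagged": defined and abs(r) > threshold,
                }
            )
    return pd.DataFrame(rows)


def thin_points(points: PresenceSet, cfg: ThinningConfig,
                seed: int = 0) -> PresenceSet:
    """Geographic thinning: greedy seeded minimum-distance filter.

    Points are shuffled with the seed, then accepted iff no previously
    accepted point lies within ``cfg.min_distance``; the result satisfies
    the pairwise minimum-distance property exactly.
    """
    if cfg.min_distance == 0 or len(points) <= 1:
        return PresenceSet(points.species, points.points.copy(), points.source_label)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(points))
    accepted: list[int] = []
    pts = points.points
    for idx in order:
        p = pts[idx]
        ok = True
        for j in accepted:
            if np.hypot(*(p - pts[j])) < cfg.min_distance:
                ok = False
                break
        if ok:
            accepted.append(idx)
    return PresenceSet(points.species, pts[np.array(accepted, dtype=int)],
                       points.source_label)


def generate_pseudo_absences(
    grid: RasterGrid,
    presences: PresenceSet,
    strategy: str = "random_equal",
    n: int | None = None,
    seed: int = 0,
) -> PresenceSet:
    """Pseudo-absence points sampled uniformly over valid non-presence cells.

    ``strategy='random_equal'`` draws as many absences as there are
    presences (the usual default for tree/ML learners); ``'random'``
    draws ``n`` points (e.g. a large background sample for
    regression-family learners). Sampling is without replacement over
    cells; points are placed at cell centres.
    """
    if strategy == "random_equal":
        n = len(presences)
    elif strategy == "random":
        if n is None:
            raise ValueError("strategy 'random' requires n")
    else:
        raise ValueError(f"unknown pseudo-absence strategy '{strategy}'")
    if n < 1:
        raise ValueError("need at least one pseudo-absence")
    candidates = grid.valid_mask.copy()
    if len(presences):
        rows, cols = grid.cell_of(presences.points[:, 0], presences.points[:, 1])
        inside = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
        candidates[rows[inside], cols[inside]] = False
    flat = np.flatnonzero(candidates.ravel())
    if n > len(flat):
        raise ValueError(
            f"requested {n} pseudo-absences but only {len(flat)} valid "
            "non-presence cells are available"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(flat, size=n, replace=False)
    rows, cols = np.unravel_index(picks, grid.shape)
    x, y = grid.cell_center(rows, cols)
    return PresenceSet(presences.species, np.column_stack([x, y]),
                       source_label="absence")


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------

class EnsembleSuitabilityModel(ClassifierMixin, BaseEstimator):
    """AUC-thresholded, AUC-weighted ensemble of occurrence classifiers.

    For each learner family, ``reps`` stratified random holdout splits
    (train fraction ``1 - holdout_fraction``) yield per-rep AUCs on the
    held-out data; families whose mean holdout AUC reaches
    ``retention_auc`` are retained and refit on all data. The ensemble
    probability is the weighted mean of the retained families'
    probabilistic predictions (weights proportional to mean holdout AUC,
    or uniform).

    Parameters
    ----------
    families : tuple of str
        Learner-family names from :data:`LEARNER_REGISTRY`.
    retention_auc : float, default 0.90
        Minimum mean holdout AUC for a family to enter the ensemble.
    holdout_fraction : float, default 0.30
        Fraction of the data held out for evaluation in each repetition.
    reps : int, default 10
        Number of stratified holdout repetitions.
    weighting : {"auc", "uniform"}
        Ensemble weighting scheme.
    random_state : int or None
        Seed controlling splits, learner randomness and permutation
        importance.

    Attributes
    ----------
    learners_ : list of LearnerResult
        Per-family holdout AUCs, retention flags and permutation-based
        predictor contributions (percent, summing to 100).
    weights_ : dict
        Normalized ensemble weight per retained family.
    models_ : dict
        Retained family name -> refitted estimator.
    predictor_contributions_ : ndarray
        Ensemble-level permutation importances, percent summing to 100.
    """

    def __init__(
        self,
        families: tuple[str, ...] = DEFAULT_FAMILIES,
        retention_auc: float = 0.90,
        holdout_fraction: float = 0.30,
        reps: int = 10,
        weighting: str = "auc",
        random_state: int | None = None,
    ):
        self.families = families
        self.retention_auc = retention_auc
        self.holdout_fraction = holdout_fraction
        self.reps = reps
        self.weighting = weighting
        self.random_state = random_state

    # sklearn API ------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = y.astype(int)
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("y must contain both classes, coded 0/1")
        if not self.families:
            raise ValueError("at least one learner family is required")
        unknown = set(self.families) - set(LEARNER_REGISTRY)
        if unknown:
            raise ValueError(f"unknown learner families: {sorted(unknown)}")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")

        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(seed)
        splitter = StratifiedShuffleSplit(
            n_splits=self.reps, test_size=self.holdout_fraction,
            random_state=seed % (2**31),
        )
        splits = list(splitter.split(X, y))

        self.learners_ = []
        self.models_ = {}
        means: dict[str, float] = {}
        for family in self.families:
            factory = LEARNER_REGISTRY[family]
            rep_aucs = []
            for train, test in splits:
                est = factory(seed % (2**31))
                est.fit(X[train], y[train])
                scores = est.predict_proba(X[test])[:, 1]
                rep_aucs.append(auc(scores, y[test]))
            mean_auc = float(np.mean(rep_aucs))
            retained = mean_auc >= self.retention_auc
            self.learners_.append(
                LearnerResult(family, [float(a) for a in rep_aucs], mean_auc, retained)
            )
            means[family] = mean_auc
            if retained:
                final = factory(seed % (2**31))
                final.fit(X, y)
                self.models_[family] = final

        if not self.models_:
            best = max(means.values())
            raise ValueError(
                f"no learner family reached retention AUC {self.retention_auc:.2f} "
                f"(best mean AUC {best:.3f}); lower retention_auc to proceed"
            )

        if self.weighting == "auc":
            raw = {f: means[f] for f in self.models_}
        elif self.weighting == "uniform":
            raw = {f: 1.0 for f in self.models_}
        else:
            raise ValueError(f"unknown weighting '{self.weighting}'")
        total = sum(raw.values())
        self.weights_ = {f: w / total for f, w in raw.items()}

        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self._compute_contributions(X, y, rng)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "models_")
        X = check_array(X)
        p = np.zeros(X.shape[0])
        for family, model in self.models_.items():
            p += self.weights_[family] * model.predict_proba(X)[:, 1]
        p = np.clip(p, 0.0, 1.0)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # contributions ----------------------------------------------------
    def _compute_contributions(self, X, y, rng) -> None:
        """Permutation importance: drop in training-data AUC when one
        predictor is shuffled, floored at 0, normalized to sum 100."""
        p = X.shape[1]
        ens_drops = np.zeros(p)
        per_family: dict[str, np.ndarray] = {}
        for family, model in self.models_.items():
            base = auc(model.predict_proba(X)[:, 1], y)
            drops = np.zeros(p)
            for j in range(p):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                drops[j] = base - auc(model.predict_proba(Xp)[:, 1], y)
            drops = np.maximum(drops, 0.0)
            per_family[family] = drops
            ens_drops += self.weights_[family] * drops

        def normalize(d: np.ndarray) -> np.ndarray:
            s = d.sum()
            return d / s * 100.0 if s > 0 else np.full(p, 100.0 / p)

        self.predictor_contributions_ = normalize(ens_drops)
        for lr in self.learners_:
            if lr.family in per_family:
                contrib = normalize(per_family[lr.family])
                lr.predictor_contributions = {
                    str(j): float(c) for j, c in enumerate(contrib)
                }


# --------------------------------------------------------------------------
# raster-level wrappers
# --------------------------------------------------------------------------

def fit_ensemble(
    presences: PresenceSet,
    absences: PresenceSet,
    predictors: PredictorStack,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    retention_auc: float = 0.90,
    holdout_fraction: float = 0.30,
    reps: int = 10,
    seed: int = 0,
) -> tuple[EnsembleModel, SuitabilityMap]:
    """Fit a per-species ensemble and predict suitability over the grid.

    Presence and pseudo-absence points are sampled from the predictor
    stack, the :class:`EnsembleSuitabilityModel` is fit, and the retained
    ensemble predicts occurrence probability for every valid cell.
    """
    if len(presences) < 2 or len(absences) < 2:
        raise ValueError("need at least two presences and two absences")
    Xp = predictors.sample(presences.points)
    Xa = predictors.sample(absences.points)
    X = np.vstack([Xp, Xa])
    y = np.concatenate([np.ones(len(Xp), dtype=int), np.zeros(len(Xa), dtype=int)])

    est = EnsembleSuitabilityModel(
        families=families,
        retention_auc=retention_auc,
        holdout_fraction=holdout_fraction,
        reps=reps,
        random_state=seed,
    ).fit(X, y)

    valid = predictors.valid_mask
    rows, cols = np.nonzero(valid)
    probs = est.predict_proba(predictors.as_matrix(rows, cols))[:, 1]
    values = np.zeros(predictors.grid.shape)
    values[rows, cols] = probs
    grid = predictors.grid.with_values(values, nodata_mask=~valid)

    for lr in est.learners_:
        lr.predictor_contributions = {
            name: lr.predictor_contributions.get(str(j), 0.0)
            for j, name in enumerate(predictors.names)
        }
    model = EnsembleModel(
        species=presences.species,
        learners=est.learners_,
        weights=est.weights_,
        estimator=est,
    )
    return model, SuitabilityMap(grid=grid, species_label=presences.species)


def stack_suitability(maps: list[SuitabilityMap]) -> SuitabilityMap:
    """Cell-wise sum of per-species suitability maps (multi-species index).

    Nodata propagates: a cell missing in any input is missing in the
    stack. Output values lie in [0, S] for S input maps.
    """
    if not maps:
        raise ValueError("no maps to stack")
    ref = maps[0].grid
    total = np.zeros(ref.shape)
    nodata = np.zeros(ref.shape, dtype=bool)
    for m in maps:
        ref.require_compatible(m.grid, f"suitability map '{m.species_label}'")
        v = m.grid.values[m.grid.valid_mask]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError(
                f"map '{m.species_label}' is not in [0, 1]; stack per-species maps"
            )
        total += np.where(m.grid.nodata_mask, 0.0, m.grid.values)
        nodata |= m.grid.nodata_mask
    total[nodata] = 0.0
    return SuitabilityMap(
        grid=ref.with_values(total, nodata_mask=nodata),
        species_label="stacked",
        n_species=len(maps),
    )


def min_pairwise_distance(points: np.ndarray) -> float:
    """Smallest pairwise Euclidean distance (helper for thinning checks)."""
    if len(points) < 2:
        return np.inf
    return float(pdist(points).min())
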