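"""PMPSO feature selection: modified binary PSO + Pearson redundancy filter.

Stage 1 (MPSO) is a wrapper selector: a swarm of binary particles encodes
candidate feature subsets, the fitness of a subset is the internal
cross-validated accuracy of a classifier trained on it, and the velocity
update is damped by the Clerc-Kennedy constriction factor

    phi = 2 / |2 - c - sqrt(c^2 - 4c)|,   c = c1 + c2 > 4,

which keeps the swarm dynamics bounded and the search collaborative.  Ties
in fitness between candidate and personal/global bests are broken in favour
of the *smaller* subset.  After the run, a per-feature importance weight is
aggregated from the recorded personal bests (selection frequency weighted by
fitness, normalized to max 1) and the top-k features are retained.

Stage 2 removes redundancy: scanning the retained features in descending
importance, a feature is kept only if its absolute Pearson correlation with
every already-kept feature is <= delta (default 0.6).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .evaluation import ModelSpec, make_classifier

_ACC_TOL = 1e-12


@dataclass(frozen=True)
class FitnessSpec:
    """How subset fitness is computed: classifier kind, internal CV folds,
    and the classifier/CV seed.  A small random forest keeps the wrapper
    cheap while ranking subsets consistently.  ``max_rows`` caps the rows the
    wrapper sees (a stratified subsample drawn once from the fitness seed),
    which keeps large swarms affordable on big segment sets."""

    classifier: str = "rf"
    cv_folds: int = 3
    seed: int = 0
    params: dict = field(default_factory=lambda: {"n_estimators": 15})
    max_rows: int | None = None


@dataclass
class SwarmConfig:
    """All PMPSO hyperparameters (every one configurable)."""

    n_particles: int = 30
    max_iters: int = 50
    c1: float = 2.05
    c2: float = 2.05
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    v_max: float = 4.0
    seed: int = 0
    stall_window: int = 15
    top_k: int = 10
    delta: float = 0.6
    constriction: bool = True  # False = baseline PSO (phi forced to 1)
    fitness: FitnessSpec = field(default_factory=FitnessSpec)

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.max_iters < 1:
            raise ValueError("need at least 1 iteration")
        if not (0 < self.delta < 1):
            raise ValueError("delta must lie in (0, 1)")


@dataclass
class PbestRecord:
    """One particle's personal best at one iteration (for importance)."""

    mask: np.ndarray
    fitness: float
    size: int


@dataclass
class SelectionResult:
    """Full output of the two-stage selector."""

    importance: dict[str, float]
    ranked_top_k: list[str]
    r_table: list[tuple[str, str, float]]
    final_subset: list[str]
    gbest_mask: np.ndarray
    gbest_fitness: float
    n_iters: int = 0

    def to_dict(self) -> dict:
        return {
            "importance": {k: float(v) for k, v in self.importance.items()},
            "ranked_top_k": list(self.ranked_top_k),
            "r_table": [[x, y, float(r)] for x, y, r in self.r_table],
            "final_subset": list(self.final_subset),
            "gbest_mask": [int(b) for b in self.gbest_mask],
            "gbest_fitness": float(self.gbest_fitness),
            "n_iters": int(self.n_iters),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def constriction_factor(c1: float, c2: float) -> float:
    """Clerc-Kennedy constriction factor; inactive (1.0, with a warning)
    when c1 + c2 <= 4."""
    c = c1 + c2
    if c <= 4:
        warnings.warn(
            f"constriction factor inactive: c1 + c2 = {c} <= 4", stacklevel=2
        )
        return 1.0
    return 2.0 / abs(2.0 - c - np.sqrt(c * c - 4.0 * c))


def update_velocity(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest_mask: np.ndarray,
    gbest_mask: np.ndarray,
    w: float,
    phi: float,
    c1: float,
    c2: float,
    v_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """v' = w v + phi [c1 r1 (pbest - x) + c2 r2 (gbest - x)], elementwise
    clamped to [-v_max, v_max]; r1, r2 drawn per dimension."""
    d = position.size
    r1 = rng.random(d)
    r2 = rng.random(d)
    v = w * velocity + phi * (
        c1 * r1 * (pbest_mask - position) + c2 * r2 * (gbest_mask - position)
    )
    return np.clip(v, -v_max, v_max)


def binarize_position(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic sigmoid transfer: bit j is 1 with probability
    sigmoid(position_j).  An all-zero mask is re-drawn once, then forced to
    select the single dimension with the largest position value."""
    prob = 1.0 / (1.0 + np.exp(-np.asarray(position, dtype=float)))
    mask = (rng.random(position.size) < prob).astype(int)
    if mask.sum() == 0:
        mask = (rng.random(position.size) < prob).astype(int)
        if mask.sum() == 0:
            mask[int(np.argmax(position))] = 1
    return mask


class FitnessEvaluator:
    """Cached wrapper fitness: mean internal-CV accuracy of the fitness
    classifier on the masked feature columns."""

    def __init__(self, X: np.ndarray, y: np.ndarray, spec: FitnessSpec):
        self.X = np.asarray(X, dtype=float)
        classes, self.y = np.unique(np.asarray(y), return_inverse=True)
        if classes.size < 2:
            raise ValueError("fitness needs at least 2 classes")
        if spec.max_rows is not None and spec.max_rows < self.y.size:
            # stratified subsample, fixed once per evaluator
            rng = np.random.default_rng(spec.seed)
            keep = []
            for c in range(classes.size):
                idx = np.flatnonzero(self.y == c)
                n_c = max(spec.cv_folds,
                          int(round(spec.max_rows * idx.size / self.y.size)))
                keep.append(rng.choice(idx, size=min(n_c, idx.size), replace=False))
            keep = np.sort(np.concatenate(keep))
            self.X, self.y = self.X[keep], self.y[keep]
        if np.bincount(self.y).min() < spec.cv_folds:
            raise ValueError(
                f"smallest class smaller than the {spec.cv_folds} internal CV folds"
            )
        self.spec = spec
        self._cache: dict[bytes, float] = {}
        self._cv = StratifiedKFold(
            n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed
        )

    def __call__(self, mask: np.ndarray) -> tuple[float, int]:
        mask = np.asarray(mask, dtype=int)
        size = int(mask.sum())
        if size == 0:
            return 0.0, 0
        key = mask.astype(np.uint8).tobytes()
        if key not in self._cache:
            clf = make_classifier(
                ModelSpec(self.spec.classifier, self.spec.params), self.spec.seed
            )
            scores = cross_val_score(
                clf, self.X[:, mask.astype(bool)], self.y, cv=self._cv, n_jobs=1
            )
            self._cache[key] = float(scores.mean())
        return self._cache[key], size


def evaluate_fitness(mask, features, labels, fitness_spec: FitnessSpec | None = None):
    """One-shot convenience wrapper around :class:`FitnessEvaluator`."""
    X = features.to_numpy() if hasattr(features, "to_numpy") else features
    return FitnessEvaluator(X, labels, fitness_spec or FitnessSpec())(np.asarray(mask))


def better_than(candidate: tuple[float, int], incumbent: tuple[float, int]) -> bool:
    """Candidate beats incumbent on accuracy, or ties on accuracy (within
    1e-12) with a strictly smaller subset."""
    c_acc, c_size = candidate
    i_acc, i_size = incumbent
    if c_acc > i_acc + _ACC_TOL:
        return True
    return abs(c_acc - i_acc) <= _ACC_TOL and c_size < i_size


def run_mpso(
    features, labels, cfg: SwarmConfig
) -> tuple[list[list[PbestRecord]], dict]:
    """Run the modified binary PSO.

    Returns ``(history, gbest)`` where history[t] is the list of per-particle
    personal-best records after iteration t, and gbest is a dict with keys
    ``mask``, ``fitness``, ``size``, ``n_iters``.  Fully reproducible from
    ``cfg.seed``.
    """
    X = features.to_numpy() if hasattr(features, "to_numpy") else np.asarray(features)
    d = X.shape[1]
    if d < 2:
        raise ValueError("need at least 2 feature columns")
    fit = FitnessEvaluator(X, labels, cfg.fitness)
    phi = constriction_factor(cfg.c1, cfg.c2) if cfg.constriction else 1.0
    rng = np.random.default_rng(cfg.seed)

    pos = rng.uniform(-1.0, 1.0, size=(cfg.n_particles, d))
    vel = np.zeros((cfg.n_particles, d))
    pbest_mask = np.zeros((cfg.n_particles, d), dtype=int)
    pbest_key = [(-np.inf, d + 1)] * cfg.n_particles
    gbest_mask = np.zeros(d, dtype=int)
    gbest_key = (-np.inf, d + 1)

    history: list[list[PbestRecord]] = []
    stall = 0
    n_iters = 0
    for t in range(cfg.max_iters):
        n_iters = t + 1
        if cfg.max_iters > 1:
            w = cfg.inertia_start + (cfg.inertia_end - cfg.inertia_start) * t / (cfg.max_iters - 1)
        else:
            w = cfg.inertia_start
        improved = False
        for i in range(cfg.n_particles):
            mask = binarize_position(pos[i], rng)
            key = fit(mask)
            if better_than(key, pbest_key[i]):
                pbest_key[i] = key
                pbest_mask[i] = mask
            if better_than(key, gbest_key):
                gbest_key = key
                gbest_mask = mask.copy()
                improved = True
        history.append(
            [PbestRecord(pbest_mask[i].copy(), pbest_key[i][0], pbest_key[i][1])
             for i in range(cfg.n_particles)]
        )
        stall = 0 if improved else stall + 1
        if stall >= cfg.stall_window:
            break
        for i in range(cfg.n_particles):
            vel[i] = update_velocity(
                vel[i], pos[i], pbest_mask[i], gbest_mask, w, phi,
                cfg.c1, cfg.c2, cfg.v_max, rng,
            )
        pos += vel
    gbest = {
        "mask": gbest_mask,
        "fitness": gbest_key[0],
        "size": gbest_key[1],
        "n_iters": n_iters,
    }
    return history, gbest


def feature_importance(
    history: list[list[PbestRecord]], names: list[str]
) -> dict[str, float]:
    """Fitness-weighted selection frequency of each feature over all recorded
    personal bests, normalized so the largest weight is 1."""
    if not history:
        raise ValueError("empty swarm history")
    d = len(names)
    acc = np.zeros(d)
    for snapshot in history:
        for rec in snapshot:
            if rec.fitness > 0:
                acc += rec.fitness * rec.mask
    top = acc.max()
    if top > 0:
        acc = acc / top
    return {name: float(acc[j]) for j, name in enumerate(names)}


def top_k(importance: dict[str, float], k: int) -> list[str]:
    """The k highest-weight feature names, descending; ties broken by the
    canonical (insertion) order of the importance map."""
    if k <= 0:
        raise ValueError("k must be positive")
    names = list(importance)
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} available features")
    order = sorted(range(len(names)), key=lambda j: (-importance[names[j]], j))
    return [names[j] for j in order[:k]]


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def redundancy_filter(
    features, ranked: list[str], delta: float = 0.6
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy Pearson redundancy filter.

    Scanning ``ranked`` in order, a feature is kept iff its |r| with every
    already-kept feature is <= delta.  The first feature is always kept.
    Returns ``(final_subset, r_table)`` with every examined pair recorded.
    Zero-variance columns are dropped with a warning.
    """
    if not ranked:
        raise ValueError("ranked feature list is empty")
    if not (0 < delta < 1):
        raise ValueError("delta must lie in (0, 1)")
    df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(features)
    kept: list[str] = []
    r_table: list[tuple[str, str, float]] = []
    for name in ranked:
        col = df[name].to_numpy(dtype=float)
        if np.std(col) == 0:
            warnings.warn(f"dropping zero-variance feature {name!r}", stacklevel=2)
            continue
        ok = True
        for prev in kept:
            r = pearson_r(df[prev].to_numpy(dtype=float), col)
            r_table.append((prev, name, r))
            if abs(r) > delta:
                ok = False
        if ok:
            kept.append(name)
    return kept, r_table


def pmpso(features, labels, cfg: SwarmConfig | None = None) -> SelectionResult:
    """The full two-stage selector: MPSO -> importance -> top-k -> Pearson
    redundancy filter."""
    cfg = cfg or SwarmConfig()
    df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(
        np.asarray(features), columns=[f"f{j}" for j in range(np.asarray(features).shape[1])]
    )
    history, gbest = run_mpso(df, labels, cfg)
    importance = feature_importance(history, list(df.columns))
    k = min(cfg.top_k, df.shape[1])
    ranked = top_k(importance, k)
    final, r_table = redundancy_filter(df, ranked, cfg.delta)
    return SelectionResult(
        importance=importance,
        ranked_top_k=ranked,
        r_table=r_table,
        final_subset=final,
        gbest_mask=gbest["mask"],
        gbest_fitness=gbest["fitness"],
        n_iters=gbest["n_iters"],
    )


class PMPSOSelector(SelectorMixin, BaseEstimator):
    """Sklearn-compatible wrapper feature selector.

    ``fit(X, y)`` runs the two-stage PMPSO selection; ``transform`` keeps the
    final subset's columns.  Composes with sklearn pipelines and model
    selection.

    Parameters mirror :class:`SwarmConfig`; ``random_state`` seeds the swarm.

    Attributes
    ----------
    selection_result_ : SelectionResult
    support_mask_ : boolean array over input columns
    n_iters_ : swarm iterations actually used
    """

    def __init__(
        self,
        n_particles: int = 30,
        max_iters: int = 50,
        c1: float = 2.05,
        c2: float = 2.05,
        inertia_start: float = 0.9,
        inertia_end: float = 0.4,
        v_max: float = 4.0,
        stall_window: int = 15,
        top_k: int = 10,
        delta: float = 0.6,
        constriction: bool = True,
        fitness_classifier: str = "rf",
        fitness_cv_folds: int = 3,
        fitness_n_estimators: int = 15,
        random_state: int = 0,
    ):
        self.n_particles = n_particles
        self.max_iters = max_iters
        self.c1 = c1
        self.c2 = c2
        self.inertia_start = inertia_start
        self.inertia_end = inertia_end
        self.v_max = v_max
        self.stall_window = stall_window
        self.top_k = top_k
        self.delta = delta
        self.constriction = constriction
        self.fitness_classifier = fitness_classifier
        self.fitness_cv_folds = fitness_cv_folds
        self.fitness_n_estimators = fitness_n_estimators
        self.random_state = random_state

    def _config(self) -> SwarmConfig:
        return SwarmConfig(
            n_particles=self.n_particles,
            max_iters=self.max_iters,
            c1=self.c1,
            c2=self.c2,
            inertia_start=self.inertia_start,
            inertia_end=self.inertia_end,
            v_max=self.v_max,
            seed=self.random_state,
            stall_window=self.stall_window,
            top_k=self.top_k,
            delta=self.delta,
            constriction=self.constriction,
            fitness=FitnessSpec(
                classifier=self.fitness_classifier,
                cv_folds=self.fitness_cv_folds,
                seed=self.random_state,
                params={"n_estimators": self.fitness_n_estimators},
            ),
        )

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            df = X
        else:
            X = np.asarray(X, dtype=float)
            names = [f"f{j}" for j in range(X.shape[1])]
            df = pd.DataFrame(X, columns=names)
        self.n_features_in_ = df.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.selection_result_ = pmpso(df, np.asarray(y), self._config())
        final = set(self.selection_result_.final_subset)
        self.support_mask_ = np.array([n in final for n in names])
        self.n_iters_ = self.selection_result_.n_iters
        return self

    def _get_support_mask(self):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "support_mask_")
        return self.support_mask_
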