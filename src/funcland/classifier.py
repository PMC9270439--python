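"""Per-term binary classifiers and hierarchy-consistent scoring.

One random-forest classifier is trained per eligible term (the local,
classifier-per-node approach to hierarchical multi-label classification).
Training sets follow the siblings policy: positives are training genes
annotated with the target term; negatives are training genes annotated
with a sibling or uncle of the target but not with the target itself —
functionally nearby genes that make the discrimination non-trivial.
Hyperparameters are chosen by grid search with stratified k-fold cross
validation.  Raw per-term scores are then post-processed so that no child
term ever scores above a parent (the true-path constraint), implemented as
top-down min-propagation from the root.
"""

from __future__ import annotations

import logging
import random
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .annotations import AnnotationStore
from .ontology import OntologyGraph, relatives

logger = logging.getLogger(__name__)

#: Default hyperparameter grid (config-exposed; scikit-learn naming).
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 200, 500],
    "max_depth": [5, 10, None],
    "criterion": ["gini", "entropy"],
}


class ClassifierError(ValueError):
    pass


@dataclass
class TrainingSet:
    target: str
    positives: set[str]
    negatives: set[str]
    fallback_used: bool = False


@dataclass
class TermModel:
    target: str
    estimator: RandomForestClassifier
    params: dict
    cv_score: float
    seed: int
    feature_names: list[str] = field(default_factory=list)


@dataclass
class ScoreMatrix:
    genes: list[str]
    terms: list[str]
    scores: np.ndarray  # shape (len(genes), len(terms)), values in [0, 1]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.genes), len(self.terms)):
            raise ClassifierError("score matrix shape mismatch")
        if self.scores.size and (
            self.scores.min() < 0 or self.scores.max() > 1
        ):
            raise ClassifierError("scores outside [0, 1]")

    def copy(self) -> "ScoreMatrix":
        return ScoreMatrix(list(self.genes), list(self.terms), self.scores.copy())


def seed_for_term(master_seed: int, term: str) -> int:
    """Stable per-term seed so parallel training order cannot change results."""
    return (master_seed * 1_000_003 + zlib.crc32(term.encode())) % (2**31)


def siblings_training_set(
    graph: OntologyGraph, store_T: AnnotationStore, target: str
) -> TrainingSet:
    """Siblings-policy training set from the T-only propagated store.

    Positives: T genes annotated with the target.  Negatives: T genes
    annotated with at least one sibling or uncle of the target and not
    with the target.  When no sibling/uncle negatives exist, a documented
    fallback samples negatives from T genes not annotated with the
    target.
    """
    if not store_T.propagated:
        raise ClassifierError("siblings policy requires a propagated store")
    near = relatives(graph, target, "siblings") | relatives(graph, target, "uncles")
    positives, negatives = set(), set()
    for g, ts in store_T.assoc.items():
        if target in ts:
            positives.add(g)
        elif ts & near:
            negatives.add(g)
    fallback = False
    if not negatives:
        fallback = True
        pool = sorted(g for g, ts in store_T.assoc.items() if target not in ts)
        k = min(len(pool), max(len(positives), 10))
        rng = random.Random(seed_for_term(0, target))
        negatives = set(rng.sample(pool, k)) if pool else set()
        logger.warning(
            "no sibling/uncle negatives for %s; sampled %d fallback negatives",
            target,
            len(negatives),
        )
    return TrainingSet(target, positives, negatives, fallback_used=fallback)


def fit_term_model(
    features: np.ndarray,
    labels: np.ndarray,
    grid: dict[str, list] | None = None,
    folds: int = 3,
    seed: int = 0,
    target: str = "",
    class_weight: str | None = None,
    n_jobs: int = 1,
) -> TermModel:
    """Fit a random forest, selecting grid hyperparameters by CV F1.

    The grid point maximising mean binary-F1 across stratified folds is
    refit on all data.  Deterministic given the seed.  With a single-point
    grid and folds < 2 the model is fit directly (no CV score reported).
    """
    grid = DEFAULT_GRID if grid is None else grid
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ClassifierError(
            f"single-class labels for term {target or '<unnamed>'}"
        )
    if np.min(np.bincount(labels.astype(int))) < 2:
        raise ClassifierError(
            f"need >= 2 examples per class for term {target or '<unnamed>'}"
        )
    base = RandomForestClassifier(
        random_state=seed, class_weight=class_weight, n_jobs=n_jobs
    )
    n_points = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if folds < 2:
        if n_points > 1:
            raise ClassifierError("folds < 2 requires a single-point grid")
        params = {k: v[0] for k, v in grid.items()}
        est = base.set_params(**params)
        est.fit(features, labels)
        return TermModel(target, est, params, float("nan"), seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, scoring="f1", cv=cv, n_jobs=n_jobs)
    search.fit(features, labels)
    return TermModel(
        target,
        search.best_estimator_,
        dict(search.best_params_),
        float(search.best_score_),
        seed,
    )


def score_genes(
    models: list[TermModel],
    feature_provider,
    genes: list[str],
) -> ScoreMatrix:
    """Positive-class probability for every (gene, modeled term).

    ``feature_provider(target)`` must return the feature matrix for the
    listed genes in the layout the term's model was trained on.
    """
    terms = [m.target for m in models]
    scores = np.zeros((len(genes), len(terms)))
    for j, m in enumerate(models):
        X = feature_provider(m.target)
        if X.shape[0] != len(genes):
            raise ClassifierError(
                f"feature rows ({X.shape[0]}) != genes ({len(genes)})"
            )
        if X.shape[1] != m.estimator.n_features_in_:
            raise ClassifierError(
                f"feature columns mismatch for {m.target}: "
                f"{X.shape[1]} != {m.estimator.n_features_in_}"
            )
        proba = m.estimator.predict_proba(X)
        pos_idx = list(m.estimator.classes_).index(1)
        scores[:, j] = proba[:, pos_idx]
    return ScoreMatrix(list(genes), terms, scores)


def enforce_hierarchy(scores: ScoreMatrix, graph: OntologyGraph) -> ScoreMatrix:
    """Cap each term's score at the minimum of its parents' corrected scores.

    Processes terms in topological order from the root (implicit score 1);
    a parent without a trained model contributes no constraint (score 1).
    Idempotent; never increases a score.  The result satisfies the
    true-path constraint s(child) <= s(parent), so thresholded prediction
    sets are ancestor-closed at every threshold.
    """
    for t in scores.terms:
        if t not in graph.terms:
            raise ClassifierError(f"scored term not in graph: {t!r}")
    term_idx = {t: j for j, t in enumerate(scores.terms)}
    corrected = scores.scores.copy()

    # topological order over the scored terms' ancestor closure
    order: list[str] = []
    seen: set[str] = set()

    def visit(t: str, stack: set[str]) -> None:
        if t in seen:
            return
        if t in stack:
            raise ClassifierError(f"cycle detected at {t!r}")
        stack.add(t)
        for p in graph.parents(t):
            visit(p, stack)
        stack.discard(t)
        seen.add(t)
        order.append(t)

    for t in scores.terms:
        visit(t, set())

    # effective score: corrected column if modeled, else implicit 1
    # (a parent without a trained model imposes no constraint)
    eff: dict[str, np.ndarray] = {}
    ones = np.ones(len(scores.genes))
    for t in order:
        if t not in term_idx:
            continue
        cap = ones.copy()
        for p in graph.parents(t):
            cap = np.minimum(cap, eff.get(p, ones))
        j = term_idx[t]
        corrected[:, j] = np.minimum(corrected[:, j], cap)
        eff[t] = corrected[:, j]
    return ScoreMatrix(list(scores.genes), list(scores.terms), corrected)


def write_scores(scores: ScoreMatrix, path, header_extra: str = "") -> None:
    """Three-column layout (gene, term, score), one row per pair."""
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("# gene_id\tterm_id\tscore\n")
        for i, g in enumerate(scores.genes):
            for j, t in enumerate(scores.terms):
                fh.write(f"{g}\t{t}\t{scores.scores[i, j]:.6f}\n")


def read_scores(path) -> ScoreMatrix:
    rows: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            g, t, s = line.rstrip("\n").split("\t")[:3]
            rows.setdefault(g, {})[t] = float(s)
    genes = sorted(rows)
    terms = sorted({t for d in rows.values() for t in d})
    mat = np.zeros((len(genes), len(terms)))
    for i, g in enumerate(genes):
        for j, t in enumerate(terms):
            mat[i, j] = rows[g].get(t, 0.0)
    return ScoreMatrix(genes, terms, mat)
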