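"""Hierarchical evaluation: hPrec/hRec/hF1 curves, null model, predictions.

For a threshold t in [0, 1], each gene i has a predicted term set P_i(t)
(every term scored >= t, plus the ontology root, which is always assumed
predicted) and a true set T_i (its propagated annotations, plus the root).
Hierarchical precision and recall are micro-averaged over genes:

    hPrec(t) = sum_i |P_i(t) & T_i| / sum_i |P_i(t)|
    hRec(t)  = sum_i |P_i(t) & T_i| / sum_i |T_i|

and hF1 is their harmonic mean (0 when both vanish).  hF-max, the maximum
of hF1 over a threshold grid, summarises a model.  The null ("random")
model scores every gene with each term's training-set frequency; the
ratio of trained to null hF1 measures how far from random the spatial
distribution of gene function is.  On a one-level ontology these
quantities reduce to classical micro precision and recall.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import AnnotationStore
from .classifier import ScoreMatrix
from .ontology import OntologyGraph, relatives, term_depth

logger = logging.getLogger(__name__)

#: Default threshold grid, 0.00 .. 1.00 inclusive.
DEFAULT_THETA_GRID = tuple(np.round(np.arange(0, 101) / 100, 2))


class EvaluationError(ValueError):
    pass


@dataclass
class EvalCurve:
    thetas: np.ndarray
    hprec: np.ndarray
    hrec: np.ndarray
    hf1: np.ndarray

    @property
    def hf_max(self) -> float:
        return float(self.hf1.max())

    @property
    def theta_at_hf_max(self) -> float:
        # ties resolved toward the smallest threshold
        return float(self.thetas[int(np.argmax(self.hf1))])


@dataclass(frozen=True)
class PredictionRecord:
    gene: str
    term: str
    score: float
    depth: int


@dataclass
class PredictionSet:
    records: list[PredictionRecord]
    threshold: float
    provenance: str = ""


def _truth_matrix(
    truth: AnnotationStore, scores: ScoreMatrix, graph: OntologyGraph
) -> tuple[np.ndarray, np.ndarray]:
    """(genes x scored-terms truth bools, per-gene |T_i| incl. root).

    The root is never a scored column; it is accounted for separately in
    _prf_at (one guaranteed match per gene on both sides).  |T_i| counts
    each gene's non-root truth terms plus the root, counted once.
    """
    for t in scores.terms:
        if graph.is_root(t):
            raise EvaluationError("root must not appear among scored terms")
    term_idx = {t: j for j, t in enumerate(scores.terms)}
    tmat = np.zeros((len(scores.genes), len(scores.terms)), dtype=bool)
    t_sizes = np.zeros(len(scores.genes))
    for i, g in enumerate(scores.genes):
        if g not in truth.assoc:
            raise EvaluationError(f"gene {g!r} missing from truth store")
        ts = truth.assoc[g]
        t_sizes[i] = sum(1 for t in ts if not graph.is_root(t)) + 1
        for t in ts:
            j = term_idx.get(t)
            if j is not None:
                tmat[i, j] = True
    return tmat, t_sizes


def _prf_at(
    pred: np.ndarray,
    tmat: np.ndarray,
    t_sizes: np.ndarray,
) -> tuple[float, float, float]:
    n_genes = pred.shape[0]
    # root is in every P_i and every T_i, contributing one match per gene
    tp = float(np.logical_and(pred, tmat).sum()) + n_genes
    p_size = float(pred.sum()) + n_genes
    t_size = float(t_sizes.sum())
    hprec = tp / p_size if p_size else 0.0
    hrec = tp / t_size if t_size else 0.0
    hf1 = (
        2 * hprec * hrec / (hprec + hrec) if (hprec + hrec) > 0 else 0.0
    )
    return hprec, hrec, hf1


def hierarchical_prf(
    truth: AnnotationStore,
    scores: ScoreMatrix,
    theta: float,
    graph: OntologyGraph,
) -> tuple[float, float, float]:
    """hPrec, hRec, hF1 at a single threshold.

    Truth must be propagated and cover every scored gene; scores should
    be hierarchy-consistent so that P_i(theta) is ancestor-closed.
    """
    if not truth.propagated:
        raise EvaluationError("truth store must be propagated")
    tmat, t_sizes = _truth_matrix(truth, scores, graph)
    pred = scores.scores >= theta
    return _prf_at(pred, tmat, t_sizes)


def hf_curve(
    truth: AnnotationStore,
    scores: ScoreMatrix,
    graph: OntologyGraph,
    grid: tuple[float, ...] = DEFAULT_THETA_GRID,
) -> EvalCurve:
    """hPrec/hRec/hF1 over an ascending threshold grid."""
    if len(grid) == 0:
        raise EvaluationError("empty threshold grid")
    grid_arr = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid_arr) < 0) or grid_arr.min() < 0 or grid_arr.max() > 1:
        raise EvaluationError("grid must be ascending within [0, 1]")
    if not truth.propagated:
        raise EvaluationError("truth store must be propagated")
    tmat, t_sizes = _truth_matrix(truth, scores, graph)
    hprec = np.zeros(len(grid_arr))
    hrec = np.zeros(len(grid_arr))
    hf1 = np.zeros(len(grid_arr))
    for idx, theta in enumerate(grid_arr):
        pred = scores.scores >= theta
        hprec[idx], hrec[idx], hf1[idx] = _prf_at(pred, tmat, t_sizes)
    return EvalCurve(grid_arr, hprec, hrec, hf1)


def random_scores(
    store_T: AnnotationStore, genes_E: list[str], terms: list[str]
) -> ScoreMatrix:
    """Null model: every gene scores each term at its T-set frequency.

    A term annotated on 25% of training genes scores every evaluation
    gene exactly 0.25.  Columns are constant by construction.
    """
    n_T = len(store_T.assoc)
    if n_T == 0:
        raise EvaluationError("empty training store")
    freqs = np.array(
        [store_T.term_count(t) / n_T for t in terms], dtype=float
    )
    scores = np.tile(freqs, (len(genes_E), 1))
    return ScoreMatrix(list(genes_E), list(terms), scores)


def ratio_curve(
    trained: EvalCurve, null: EvalCurve
) -> tuple[np.ndarray, float, float]:
    """hF1 ratio trained/null over the shared grid.

    Grid points where the null hF1 is 0 are undefined (NaN) and excluded
    from the argmax.  Returns (ratios, theta_star, max_ratio) with
    theta_star the smallest argmax.
    """
    if trained.thetas.shape != null.thetas.shape or np.any(
        trained.thetas != null.thetas
    ):
        raise EvaluationError("threshold grids differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(null.hf1 > 0, trained.hf1 / null.hf1, np.nan)
    if np.all(np.isnan(ratios)):
        raise EvaluationError("null hF1 is zero on the whole grid")
    best = np.nanmax(ratios)
    theta_star = float(trained.thetas[int(np.nanargmax(ratios))])
    return ratios, theta_star, float(best)


def finalize_predictions(
    scores: ScoreMatrix,
    theta_star: float,
    graph: OntologyGraph,
    truth_T_only: AnnotationStore | None = None,
) -> PredictionSet:
    """Most-specific predictions at or above the chosen threshold.

    Keeps (gene, term) pairs with score >= theta_star, then drops any
    kept term that is an ancestor of another kept term for the same gene,
    so each gene's output is the antichain of most specific predictions.
    The root is never emitted.  If a training-time annotation store is
    given, pairs already annotated there are dropped (only new
    associations are reported).
    """
    anc_cache: dict[str, set[str]] = {}

    def anc(t: str) -> set[str]:
        if t not in anc_cache:
            anc_cache[t] = relatives(graph, t, "ancestors")
        return anc_cache[t]

    records: list[PredictionRecord] = []
    for i, g in enumerate(scores.genes):
        kept = [
            (t, scores.scores[i, j])
            for j, t in enumerate(scores.terms)
            if scores.scores[i, j] >= theta_star and not graph.is_root(t)
        ]
        if truth_T_only is not None:
            kept = [
                (t, s) for t, s in kept if t not in truth_T_only.terms_for(g)
            ]
        ancestors_of_kept: set[str] = set()
        for t, _ in kept:
            ancestors_of_kept |= anc(t)
        for t, s in kept:
            if t in ancestors_of_kept:
                continue
            records.append(
                PredictionRecord(g, t, float(s), term_depth(graph, t))
            )
    return PredictionSet(records, float(theta_star))


def predictions_by_depth(
    preds: PredictionSet, graph: OntologyGraph
) -> dict[int, int]:
    """Histogram of emitted records by term depth, zero-filled to max depth."""
    max_depth = max(
        (term_depth(graph, t) for t in graph.terms), default=0
    )
    hist = {d: 0 for d in range(max_depth + 1)}
    for r in preds.records:
        hist[r.depth] += 1
    return hist


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_curves(
    trained: EvalCurve,
    null: EvalCurve,
    ratios: np.ndarray,
    path: str | Path,
    header_extra: str = "",
) -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("# theta\thPrec\thRec\thF1\thF1_random\tratio\n")
        for i, theta in enumerate(trained.thetas):
            r = ratios[i]
            r_out = "NA" if np.isnan(r) else f"{r:.6f}"
            fh.write(
                f"{theta:.2f}\t{trained.hprec[i]:.6f}\t{trained.hrec[i]:.6f}\t"
                f"{trained.hf1[i]:.6f}\t{null.hf1[i]:.6f}\t{r_out}\n"
            )


def write_predictions(preds: PredictionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# threshold={preds.threshold:.6f}\n")
        fh.write("# gene_id\tterm_id\tscore\tdepth\n")
        for r in sorted(preds.records, key=lambda r: (r.gene, r.term)):
            fh.write(f"{r.gene}\t{r.term}\t{r.score:.6f}\t{r.depth}\n")


def write_summary(
    path: str | Path,
    trained: EvalCurve,
    null: EvalCurve,
    theta_star: float,
    max_ratio: float,
    extra: dict | None = None,
) -> None:
    payload = {
        "hF_max": round(trained.hf_max, 6),
        "theta_at_hF_max": trained.theta_at_hf_max,
        "hF_max_random": round(null.hf_max, 6),
        "max_ratio": round(max_ratio, 6),
        "theta_star": theta_star,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")
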