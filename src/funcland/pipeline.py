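"""End-to-end orchestration and the synthetic signal-recovery experiment.

The full procedure: build the genome model, read and up-propagate
annotations, split genes 80/20 into train (T) and eval (E), select
eligible terms, train one random forest per term on siblings-policy
training sets with FLA features computed from the E-masked store, score
the E genes, enforce hierarchy consistency, evaluate hF1 curves against
the term-frequency null model, pick the threshold maximising the
trained/null hF1 ratio, and emit the most specific predictions with a
depth histogram.  Every stage writes its output under a run directory
stamped with a config hash and is skipped on resume when already done.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import annotations as ann
from . import classifier as clf
from . import evaluation as ev
from . import features as feat
from . import genome as gen
from . import ontology as onto
from . import synthetic as syn
from .enrichment import DEFAULT_HALF_WIDTHS, EnrichmentEngine

logger = logging.getLogger(__name__)

STAGES = (
    "genome",
    "ontology",
    "annotations",
    "split",
    "eligible",
    "train",
    "score",
    "curves",
    "predict",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    genome_path: str = ""
    obo_path: str = ""
    annotations_path: str = ""
    outdir: str = "run"
    namespace: str = "BP"
    half_widths: tuple[int, ...] = DEFAULT_HALF_WIDTHS
    split_fraction: float = 0.8
    min_T: int = 40
    min_E: int = 10
    fla_mode: str = "relatives_down"
    grid: dict = field(
        default_factory=lambda: {k: list(v) for k, v in clf.DEFAULT_GRID.items()}
    )
    cv_folds: int = 3
    theta_step: float = 0.01
    map_min_genes: int = 20
    include_part_of: bool = True
    master_seed: int = 0

    def theta_grid(self) -> tuple[float, ...]:
        n = int(round(1 / self.theta_step))
        return tuple(np.round(np.arange(n + 1) * self.theta_step, 10))

    def hash(self) -> str:
        # outdir is excluded: it cannot influence any numeric output
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "half_widths" in raw:
            raw["half_widths"] = tuple(raw["half_widths"])
        return cls(**raw)


def _stage_marker(outdir: Path, stage: str) -> Path:
    return outdir / f".stage_{stage}.done"


def _stage_done(outdir: Path, stage: str, cfg_hash: str) -> bool:
    marker = _stage_marker(outdir, stage)
    return marker.exists() and marker.read_text().strip() == cfg_hash


def _mark_done(outdir: Path, stage: str, cfg_hash: str) -> None:
    _stage_marker(outdir, stage).write_text(cfg_hash + "\n")


class Runner:
    """Executes pipeline stages over one run directory, resumably."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.hash = config.hash()
        with open(self.outdir / "config.json", "w") as fh:
            json.dump(
                {"hash": self.hash, **asdict(config)},
                fh,
                sort_keys=True,
                indent=2,
                default=list,
            )
            fh.write("\n")
        # in-memory state shared across stages within one process
        self._state: dict = {}

    # -- stage helpers -----------------------------------------------------

    def _load_genome(self) -> gen.GenomeModel:
        if "model" not in self._state:
            p = self.cfg.genome_path
            if p.endswith((".gff3", ".gff")):
                model = gen.read_gff3(p)
            elif p.endswith(".gtf"):
                model = gen.read_gtf(p)
            else:
                model = gen.read_gene_order_tsv(p)
            self._state["model"] = model
        return self._state["model"]

    def _load_graph(self) -> onto.OntologyGraph:
        if "graph" not in self._state:
            self._state["graph"] = onto.parse_obo(
                self.cfg.obo_path, include_part_of=self.cfg.include_part_of
            )
        return self._state["graph"]

    def _load_annotations(self) -> ann.AnnotationStore:
        if "store" not in self._state:
            store = ann.read_annotations(
                self.cfg.annotations_path,
                self._load_graph(),
                namespace=self.cfg.namespace,
            )
            self._state["store"] = ann.propagate(store, self._load_graph())
        return self._state["store"]

    def _load_split(self) -> ann.Split:
        if "split" not in self._state:
            path = self.outdir / "split.tsv"
            if path.exists():
                self._state["split"] = ann.read_split(path)
            else:
                self._state["split"] = ann.split_train_eval(
                    self._load_genome(),
                    self.cfg.split_fraction,
                    self.cfg.master_seed,
                )
        return self._state["split"]

    # -- stages ------------------------------------------------------------

    def stage_genome(self) -> None:
        gen.write_gene_order(self._load_genome(), self.outdir / "gene_order.tsv")

    def stage_ontology(self) -> None:
        onto.write_graph_summary(
            self._load_graph(), self.outdir / "ontology_summary.tsv"
        )

    def stage_annotations(self) -> None:
        syn.write_annotation_tsv(
            self._load_annotations(), self.outdir / "annotations_propagated.tsv"
        )

    def stage_split(self) -> None:
        ann.write_split(self._load_split(), self.outdir / "split.tsv")

    def stage_eligible(self) -> None:
        terms = ann.eligible_terms(
            self._load_annotations(),
            self._load_split(),
            self._load_graph(),
            self.cfg.min_T,
            self.cfg.min_E,
        )
        self._state["eligible"] = terms
        with open(self.outdir / "eligible_terms.tsv", "w") as fh:
            fh.write(f"# config={self.hash} seed={self.cfg.master_seed}\n")
            for t in terms:
                fh.write(t + "\n")

    def _eligible(self) -> list[str]:
        if "eligible" not in self._state:
            path = self.outdir / "eligible_terms.tsv"
            if path.exists():
                self._state["eligible"] = [
                    line.strip()
                    for line in path.read_text().splitlines()
                    if line.strip() and not line.startswith("#")
                ]
            else:
                self.stage_eligible()
        return self._state["eligible"]

    def _masked_engine(self) -> tuple[ann.AnnotationStore, EnrichmentEngine]:
        if "masked" not in self._state:
            split = self._load_split()
            masked = ann.mask(self._load_annotations(), set(split.E))
            self._state["masked"] = masked
            self._state["engine"] = EnrichmentEngine(self._load_genome(), masked)
        return self._state["masked"], self._state["engine"]

    def stage_train(self) -> None:
        model = self._load_genome()
        graph = self._load_graph()
        split = self._load_split()
        store = self._load_annotations()
        store_T = ann.restrict(store, split.T)
        masked, engine = self._masked_engine()
        models_dir = self.outdir / "models"
        models_dir.mkdir(exist_ok=True)
        manifest_rows = []
        trained: list[clf.TermModel] = []
        for target in self._eligible():
            try:
                ts = clf.siblings_training_set(graph, store_T, target)
                genes = sorted(ts.positives) + sorted(ts.negatives)
                labels = np.array(
                    [1] * len(ts.positives) + [0] * len(ts.negatives)
                )
                X, names = feat.build_feature_matrix(
                    model,
                    masked,
                    genes,
                    target,
                    graph,
                    tuple(self.cfg.half_widths),
                    self.cfg.fla_mode,
                    engine,
                )
                seed = clf.seed_for_term(self.cfg.master_seed, target)
                tm = clf.fit_term_model(
                    X,
                    labels,
                    self.cfg.grid,
                    folds=self.cfg.cv_folds,
                    seed=seed,
                    target=target,
                )
                tm.feature_names = names
                trained.append(tm)
                manifest_rows.append(
                    (
                        target,
                        json.dumps(tm.params, sort_keys=True),
                        f"{tm.cv_score:.6f}",
                        len(ts.positives),
                        len(ts.negatives),
                        seed,
                    )
                )
                joblib.dump(tm, models_dir / f"{target.replace(':', '_')}.joblib")
            except (clf.ClassifierError, feat.FeatureError) as exc:
                logger.warning("skipping term %s: %s", target, exc)
        if not trained:
            raise PipelineError("no term model could be trained")
        self._state["models"] = trained
        with open(self.outdir / "models_manifest.tsv", "w") as fh:
            fh.write(f"# config={self.hash} seed={self.cfg.master_seed}\n")
            fh.write("# term\tparams\tcv_score\tn_pos\tn_neg\tseed\n")
            for row in manifest_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")

    def _models(self) -> list[clf.TermModel]:
        if "models" not in self._state:
            models_dir = self.outdir / "models"
            if not models_dir.is_dir():
                raise PipelineError(
                    "no trained models found; run the train stage first"
                )
            loaded = [
                joblib.load(p) for p in sorted(models_dir.glob("*.joblib"))
            ]
            order = {t: i for i, t in enumerate(self._eligible())}
            loaded.sort(key=lambda m: order.get(m.target, len(order)))
            self._state["models"] = loaded
        return self._state["models"]

    def stage_score(self) -> None:
        model = self._load_genome()
        graph = self._load_graph()
        split = self._load_split()
        masked, engine = self._masked_engine()
        genes_E = sorted(split.E)

        def provider(target: str) -> np.ndarray:
            X, _ = feat.build_feature_matrix(
                model,
                masked,
                genes_E,
                target,
                graph,
                tuple(self.cfg.half_widths),
                self.cfg.fla_mode,
                engine,
            )
            return X

        raw = clf.score_genes(self._models(), provider, genes_E)
        consistent = clf.enforce_hierarchy(raw, graph)
        self._state["scores"] = consistent
        clf.write_scores(
            raw, self.outdir / "scores_raw.tsv", f"config={self.hash}"
        )
        clf.write_scores(
            consistent,
            self.outdir / "scores_consistent.tsv",
            f"config={self.hash}",
        )

    def _scores(self) -> clf.ScoreMatrix:
        if "scores" not in self._state:
            path = self.outdir / "scores_consistent.tsv"
            if not path.exists():
                raise PipelineError(
                    "no scores found; run the train and score stages first"
                )
            self._state["scores"] = clf.read_scores(path)
        return self._state["scores"]

    def stage_curves(self) -> None:
        graph = self._load_graph()
        split = self._load_split()
        store = self._load_annotations()
        scores = self._scores()
        truth_E = ann.restrict(store, scores.genes)
        store_T = ann.restrict(store, split.T)
        grid = self.cfg.theta_grid()
        trained = ev.hf_curve(truth_E, scores, graph, grid)
        null = ev.hf_curve(
            truth_E,
            ev.random_scores(store_T, scores.genes, scores.terms),
            graph,
            grid,
        )
        ratios, theta_star, max_ratio = ev.ratio_curve(trained, null)
        self._state["curves"] = (trained, null, ratios, theta_star, max_ratio)
        ev.write_curves(
            trained,
            null,
            ratios,
            self.outdir / "curves.tsv",
            f"config={self.hash} seed={self.cfg.master_seed}",
        )
        ev.write_summary(
            self.outdir / "summary.json",
            trained,
            null,
            theta_star,
            max_ratio,
            extra={"config_hash": self.hash, "seed": self.cfg.master_seed},
        )

    def _curves(self):
        if "curves" not in self._state:
            self.stage_curves()
        return self._state["curves"]

    def stage_predict(self) -> None:
        graph = self._load_graph()
        split = self._load_split()
        store = self._load_annotations()
        _, _, _, theta_star, _ = self._curves()
        store_T = ann.restrict(store, split.T)
        preds = ev.finalize_predictions(
            self._scores(), theta_star, graph, store_T
        )
        ev.write_predictions(preds, self.outdir / "predictions.tsv")
        hist = ev.predictions_by_depth(preds, graph)
        with open(self.outdir / "depth_histogram.tsv", "w") as fh:
            fh.write(f"# config={self.hash}\n# depth\tcount\n")
            for d in sorted(hist):
                fh.write(f"{d}\t{hist[d]}\n")

    # -- driver ------------------------------------------------------------

    def run_all(self) -> Path:
        outputs = {
            "genome": ["gene_order.tsv"],
            "ontology": ["ontology_summary.tsv"],
            "annotations": ["annotations_propagated.tsv"],
            "split": ["split.tsv"],
            "eligible": ["eligible_terms.tsv"],
            "train": ["models_manifest.tsv"],
            "score": ["scores_raw.tsv", "scores_consistent.tsv"],
            "curves": ["curves.tsv", "summary.json"],
            "predict": ["predictions.tsv", "depth_histogram.tsv"],
        }
        for stage in STAGES:
            if _stage_done(self.outdir, stage, self.hash):
                logger.info("stage %s: already done, skipping", stage)
                continue
            logger.info("stage %s: running", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise PipelineError(f"stage {stage} failed: {exc}") from exc
            _mark_done(self.outdir, stage, self.hash)
        manifest = {
            "config_hash": self.hash,
            "seed": self.cfg.master_seed,
            "stages": {s: outputs[s] for s in STAGES},
        }
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=2)
            fh.write("\n")
        return self.outdir


def run_all(config: RunConfig) -> Path:
    """Execute every stage of the procedure under config.outdir."""
    return Runner(config).run_all()


# ---------------------------------------------------------------------------
# Synthetic signal-recovery experiment
# ---------------------------------------------------------------------------

#: Single-point forest configuration for desk-scale experiments: small
#: enough to keep a many-seed experiment fast, deep enough to use the
#: multi-scale FLA columns.
FAST_GRID: dict[str, list] = {
    "n_estimators": [60],
    "max_depth": [10],
    "criterion": ["gini"],
}


def run_synthetic_experiment(
    seed: int,
    spec: syn.SyntheticSpec | None = None,
    shuffle: bool = False,
    grid: dict | None = None,
    folds: int = 0,
    min_T: int = 40,
    min_E: int = 10,
    fraction: float = 0.8,
) -> dict:
    """Train-vs-null comparison on one clustered synthetic genome.

    Generates a toy ontology and a clustered genome from the spec (seeded
    by ``seed``), optionally shuffles the annotations first (the spatial
    null), then runs the complete procedure and returns the trained and
    null hF-max and their ratio.
    """
    spec = spec or syn.SyntheticSpec(seed=seed)
    if spec.seed != seed:
        spec = syn.SyntheticSpec(**{**asdict(spec), "seed": seed})
    grid = FAST_GRID if grid is None else grid
    graph = syn.make_toy_ontology(spec.levels, spec.branching, seed=seed)
    model, leaf_store = syn.make_clustered_genome(spec, graph)
    if shuffle:
        leaf_store = syn.shuffle_annotations(model, leaf_store, seed + 10_007)
    store = ann.propagate(leaf_store, graph)
    split = ann.split_train_eval(model, fraction, seed)
    eligible = ann.eligible_terms(store, split, graph, min_T, min_E)
    if not eligible:
        raise PipelineError("no eligible terms in synthetic run")
    masked = ann.mask(store, set(split.E))
    store_T = ann.restrict(store, split.T)
    engine = EnrichmentEngine(model, masked)
    models = []
    for target in eligible:
        try:
            ts = clf.siblings_training_set(graph, store_T, target)
            genes = sorted(ts.positives) + sorted(ts.negatives)
            labels = np.array([1] * len(ts.positives) + [0] * len(ts.negatives))
            X, _ = feat.build_feature_matrix(
                model, masked, genes, target, graph, engine=engine
            )
            tm = clf.fit_term_model(
                X,
                labels,
                grid,
                folds=folds,
                seed=clf.seed_for_term(seed, target),
                target=target,
            )
            models.append(tm)
        except clf.ClassifierError as exc:
            logger.warning("synthetic run: skipping %s: %s", target, exc)
    if not models:
        raise PipelineError("no model trained in synthetic run")
    genes_E = sorted(split.E)

    def provider(target: str) -> np.ndarray:
        X, _ = feat.build_feature_matrix(
            model, masked, genes_E, target, graph, engine=engine
        )
        return X

    raw = clf.score_genes(models, provider, genes_E)
    consistent = clf.enforce_hierarchy(raw, graph)
    truth_E = ann.restrict(store, genes_E)
    trained_curve = ev.hf_curve(truth_E, consistent, graph)
    null_scores = ev.random_scores(store_T, genes_E, consistent.terms)
    null_curve = ev.hf_curve(truth_E, null_scores, graph)
    ratio = (
        trained_curve.hf_max / null_curve.hf_max
        if null_curve.hf_max > 0
        else float("nan")
    )
    return {
        "hf_max_trained": trained_curve.hf_max,
        "hf_max_random": null_curve.hf_max,
        "hf_max_ratio": ratio,
        "n_eligible_terms": len(eligible),
        "n_models": len(models),
        "seed": seed,
        "shuffled": shuffle,
    }
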