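# Methods

## Genome model

Each genome is a collection of chromosomal arms in which protein-coding
genes sit one next to the other; a gene's position is the rank of its
strand-aware transcription start site (start for `+`, end for `-`)
within its arm, and the distance between genes is the number of genes
between them. Physical distances are deliberately discarded: the method
is about relative order. Ties in TSS coordinate are broken
lexicographically by gene id (an explicit, documented rule; overlapping
genes are otherwise out of scope). When arm labels are absent each
chromosome is one arm; an optional centromere table (chromosome → bp)
splits chromosomes into `L`/`R` arms. Internally ranks are 0-based; all
file outputs report 1-based positions and say so in their headers.

## Local enrichment

For gene *j*, term *x* and half-width *w*, E = (k/n)/(M/N) over the
gene's arm. Conventions, all chosen to keep the statistic well defined
everywhere along an arm:

- **Focal gene excluded** from its own window, on both *n* and *k*. A
  training gene's own annotation would otherwise leak its label into
  its feature, and evaluation genes are annotation-masked, which would
  create a train/eval feature shift. The exclusion is uniform, so the
  statistic remains comparable across genes.
- **Windows truncate** at arm ends rather than wrap or pad; *n* is the
  truncated count, so the ratio stays meaningful near telomeres and
  centromeres. Windows never cross arms.
- **M = 0 ⇒ E = 0** (not NaN): *k* is then necessarily 0 and "no
  signal" is the semantically correct feature value; it also keeps FLA
  matrices numeric.
- A single-gene arm has an empty window; its enrichment is undefined
  (a logged sentinel) and its FLA is all-zero.

No hypergeometric p-value is computed: the ratio itself is the
statistic. Internally a prefix-sum engine makes each window count O(1);
an independent brute-force recount oracle in the test suite checks
exact agreement to 1e-12.

**Enrichment maps** evaluate E at every gene rank of every arm for all
half-widths; in map mode only terms annotating ≥ 20 genes are mapped
(sparser terms produce noise-dominated maps and are skipped with a
notice).

## Functional landscape arrays

The FLA of a gene for a target term is the matrix of local enrichments
with rows = half-widths (5, 10, 20, 50, 100 genes per side) and
columns = an ordered term set derived from the target. Two modes exist
because the natural choices differ:

- `relatives_down` (default): target ∪ parents ∪ siblings ∪
  descendants;
- `relatives_up`: target ∪ siblings ∪ ancestors.

The column order is the target first, then lexicographic — identical
for every gene sharing a target, which classifier reproducibility
requires. Flattening is row-major (width-major) and documented for the
same reason. An optional cap on very large descendant sets is exposed
in principle through the term-set mode but not imposed by default; the
toy ontologies used in testing never need one. Features are always
computed from a store in which evaluation genes are masked: they keep
their genome positions (counting toward *n* and *N*) but contribute
nothing to *k* or *M*. No scaling or selection is applied — random
forests need neither.

## Per-term classifiers

Positives for a target term are training genes annotated with it (after
up-propagation); negatives follow the siblings policy — training genes
annotated with a sibling or uncle (sibling of a parent) of the target
and not with the target. These are functionally nearby genes, making
the discrimination harder and more informative than random negatives.
If a term has no siblings or uncles (e.g. an only child of the root),
the documented fallback samples negatives uniformly from training genes
not carrying the target, up to max(|positives|, 10).

Each term gets a random-forest binary classifier; the default
hyperparameter grid is trees ∈ {100, 200, 500}, max depth ∈ {5, 10,
unlimited}, impurity ∈ {gini, entropy}, selected by mean binary F1 over
3-fold stratified cross-validation and refit on all data. The grid is
config-exposed. No resampling is used for class imbalance; class-weight
balancing exists behind a flag, default off. Per-term seeds are derived
from the master seed and a CRC of the term id, so training order or
parallelism cannot change results.

Terms are eligible for training when they annotate ≥ 40 training and
≥ 10 evaluation genes, counted on propagated annotations (training
positives are defined on propagated sets, so eligibility must count the
same way); the root is never eligible.

## Hierarchy consistency

Independent per-term scores can violate the true-path rule (a child
scored above its parent). Scores are corrected by top-down
min-propagation: processing terms in topological order from the root
(implicit score 1), each term's score is capped at the minimum of its
parents' corrected scores; a parent without a trained model imposes no
constraint. This is the minimal correction achieving zero violations;
it never increases a score, is idempotent, and makes every thresholded
prediction set ancestor-closed — the property the hierarchical metrics
assume. It sits behind a small interface so an alternative correction
could be plugged in.

## Evaluation

Hierarchical precision/recall are micro-averaged over evaluation genes
with the ontology root included in both the predicted set P_i(θ) and
the true set T_i. Root inclusion on the predicted side is part of the
metric's definition; including it symmetrically in T_i keeps hPrec ≤ 1
trivially and avoids rewarding or punishing the root, matching common
practice in function-prediction assessment. hF1 uses the 0/0 → 0
convention. The threshold grid is 0.00–1.00 in steps of 0.01.

The null model scores every gene with each term's relative frequency
among training genes (the information available at training time; a
genome-wide base is selectable). Its columns are constant and, because
propagated child frequencies never exceed parent frequencies, already
hierarchy-consistent. The ratio curve hF1_trained/hF1_null is undefined
(excluded, not clamped) where the null hF1 is 0; θ\* is the smallest
argmax of the defined ratios.

Final predictions keep (gene, term) pairs scoring ≥ θ\*, drop pairs
already annotated at training time, and then keep only the most
specific term per branch (no emitted term is an ancestor of another
emitted term for the same gene); the root is never emitted. Predictions
are reported with term depth = shortest directed path to the root
(longest-path depth available by flag; the shortest path is the
conventional reading and is stable under added diamond edges).

## Synthetic data

The generator emulates the one statistical property the method
exploits: local over-representation of functionally related genes. A
toy ontology is a rooted tree (levels ℓ, branching b; optional random
diamond edges). Each leaf term draws a gene count (Poisson with mean
terms_per_gene × n_genes / n_leaves, floored at 2); a fraction ρ of its
genes is placed in contiguous runs at random arm positions, the rest
uniformly; terms may overlap on a gene. Annotations are generated at
leaves and up-propagated through the ordinary propagation code path.
Synthesized TSS coordinates are rank × 1000 bp so file writers
round-trip through the real readers.

Defaults define the study conditions used throughout: n_genes = 2000
over 4 arms, a 3-level branching-3 ontology (40 terms), terms_per_gene
= 0.6 (≈ 130 genes per leaf term, comfortably above the 40/10
eligibility floors after an 80/20 split), ρ = 0.8 — strong but not
perfect clustering, one cluster per term. `shuffle_annotations`
permutes annotation *sets* over gene positions, preserving marginal
term frequencies exactly while destroying spatial structure; it is the
null against which signal recovery is judged.

What the generator does **not** emulate: realistic chromosome-length
and term-size distributions, evidence-code structure, annotation bias
toward well-studied genes, correlated multi-term clusters, or any
sequence-level signal. Passing the synthetic recovery test therefore
shows the pipeline can detect planted spatial signal of realistic
strength — not that real genomes carry signal of that strength.

## Experiment and problem sizes

The signal-recovery experiment trains the full pipeline per seed on the
default conditions above. It uses a single-point forest configuration
(60 trees, depth 10, gini) without cross-validation: with a one-point
grid CV would only add reporting cost, and a modest forest is ample for
35-dimensional FLAs with hundreds of training genes. This keeps a
50-seed experiment (plus 50 shuffled counterparts) in a few minutes on
one CPU while leaving the scientific conditions untouched. The pipeline
round-trip checks run at 500–600 genes with eligibility floors 20/5 —
smaller genomes need proportionally smaller floors for any term to be
eligible, and byte-level reproducibility does not depend on size.

## Numerical choices and degenerate inputs

- Split size |T| = round(fraction × total) with round-half-even
  (Python's `round`), seed recorded in output headers.
- Enrichment equality is asserted to 1e-12 (pure ratio arithmetic in
  double precision).
- Ratio-curve ties break toward the smallest threshold; hF-max ties
  likewise.
- Degenerate cases: empty annotation files are an error; terms whose
  training set collapses to one class are skipped and logged, not
  fatal (a hierarchical run over many terms should survive individual
  degeneracies); single-gene arms yield zero FLAs with a warning.

## Known limitations

- Per-term models are independent; no global multi-output classifier.
- The hierarchy correction is score capping only; it cannot raise a
  parent supported by strong children.
- Evaluation is gene-centric (hF1); per-term AUROC is out of scope.
- GAF reading uses the DB object id column as the gene id; mapping to
  genome gene ids is the caller's responsibility.
- Real-genome reproduction of published figures requires external
  genome and annotation releases and long training runs; the package's
  evidence is oracle agreement plus synthetic signal recovery.
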