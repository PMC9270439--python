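# funcland

Gene function prediction from gene relative location.

Most automated function prediction leans on sequence similarity, yet
functionally related genes are not scattered at random along eukaryotic
chromosomes: clusters of co-expressed, co-regulated or functionally
related genes are well documented. `funcland` asks how much of a gene's
function can be predicted from *where it sits* — using only the order of
protein-coding genes along chromosomal arms and the annotations of its
neighbours, never its sequence. It is aimed at computational biologists
who want location-derived features for function prediction, or who want
to quantify how far from random the functional organisation of a genome
is.

## Method

The genome is modelled as strings of protein-coding genes per
chromosomal arm, ordered by transcription start site; only gene order is
kept. For a gene *j*, an ontology term *x* and a window of *w* genes to
each side, the **local enrichment** is

```
E_jxw = (k / n) / (M / N)
```

with *N* genes on the arm, *M* of them annotated with *x*, *n* genes in
the window (truncated at arm ends, focal gene excluded) and *k* of those
annotated with *x*. Stacking enrichments over half-widths
w ∈ {5, 10, 20, 50, 100} and over the terms related to a target term
(the target, its parents, siblings and descendants) gives the gene's
**functional landscape array (FLA)** — the only predictive feature used.

One random-forest classifier is trained per ontology term that
annotates ≥ 40 training and ≥ 10 evaluation genes (the genes are split
80/20). Positives are training genes carrying the term; negatives
follow the *siblings policy* (genes carrying a sibling or uncle term but
not the target). FLAs are always computed with evaluation-gene
annotations masked, so held-out labels cannot leak into features. The
per-term scores are made hierarchy-consistent (child score ≤ parent
score, by top-down min-propagation), and the combined predictor is
evaluated with hierarchical precision/recall/F1 over a threshold grid:

```
hPrec(θ) = Σ_i |P_i(θ) ∩ T_i| / Σ_i |P_i(θ)|
hRec(θ)  = Σ_i |P_i(θ) ∩ T_i| / Σ_i |T_i|
```

where P_i(θ) is gene *i*'s predicted term set at threshold θ and T_i its
true (up-propagated) set, both including the ontology root. The model is
compared with a **term-frequency null** that scores every gene with each
term's training-set frequency; the threshold maximising the
trained/null hF1 ratio selects the final, most-specific predictions.

Because real-genome runs need large annotation downloads, the package
ships a first-class synthetic generator: toy ontologies and genomes
whose annotated terms cluster spatially with tunable strength ρ, plus a
shuffling null that destroys spatial signal while preserving term
frequencies exactly.

## Worked example

```python
from funcland import run_synthetic_experiment

res = run_synthetic_experiment(seed=5)
print(res)
```

prints

```
{'hf_max_trained': 0.80248833592535, 'hf_max_random': 0.5270092226613965,
 'hf_max_ratio': 1.5227216174183518, 'n_eligible_terms': 15,
 'n_models': 15, 'seed': 5, 'shuffled': False}
```

On a 2000-gene genome whose annotations cluster with strength ρ = 0.8,
the location-trained model reaches an hF-max of 0.80 on held-out genes,
versus 0.53 for the term-frequency null — a ratio of 1.52, meaning gene
location alone carries substantial functional signal. Re-running with
`shuffle=True` (annotations permuted over positions) drives the ratio to
≈ 1.0: the model finds nothing once spatial structure is destroyed.

The same pipeline runs from files via the CLI:

```
funcland simulate --n-genes 2000 --rho 0.8 --seed 5 --outdir sim
funcland run-all --config run.yaml         # or: train / evaluate / predict
funcland enrich-map T.1.0 --config run.yaml
```

`run-all` writes gene order, split, eligible terms, per-term models,
raw and hierarchy-consistent scores, hF1/ratio curves, a summary JSON
and the most-specific predictions with their ontology depths under the
configured output directory, each stage resumable and stamped with the
config hash.

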