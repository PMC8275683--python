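# implinet

Boolean implication networks for disease-continuum modeling of gene
expression, with a target-vetting layer on top.

The pipeline:

1. **stepminer** — fit a one-step function to each gene's sorted expression;
   the midpoint of the two level means is the binarization threshold, and
   values within a noise margin (default 0.5 log2 units) are *intermediate*.
2. **implication** — for every gene pair, count the 2×2 low/high quadrant
   table (intermediates excluded) and test each quadrant for sparseness
   (`e = row·col/n`, `S = (e−a)/√e`, `p = 0.5(a/row + a/col)`; sparse iff
   `S > 3` and `p < 0.1` by default). The sparse pattern maps to one of six
   relations: four asymmetric implications (e.g. "A low ⇒ B low") and two
   symmetric ones (Equivalent, Opposite).
3. **network_builder** — group mutually equivalent genes into clusters,
   connect cluster pairs whose cross-gene relations overwhelmingly agree
   (support ≥ 0.5 by default) with directed labeled edges, and orient
   clusters healthy- or disease-side from labeled samples.
4. **path_engine** — enumerate continuum paths through the cluster network,
   compute a composite per-sample score (side-signed weighted cluster means
   of threshold-centered expression), select the most discriminative path by
   OLS of the class label on the score, and evaluate signatures by ROC-AUC
   and two-sided Fisher exact tests.
5. **target_vetting** — druggability tag filtering, the success rule for
   candidate targets (on both continuum paths AND a strong anchor-high ⇒
   target-low implication; anchor-high ⇒ target-high is contraindicated),
   pairwise equivalence association among targets, and organoid
   barrier-response binning by percent TEER increase (≤25 / >25–75 / >75).
6. **synthetic_data** — seeded cohorts with planted module structure and
   ground truth for every stage.

## CLI

```sh
# generate a synthetic cohort
implinet simulate --spec spec.json --out-dir sim/

# full pipeline: binarize -> pairs -> network -> path selection -> report
implinet run --expr sim/expr.tsv --ann sim/ann.tsv --out results/

# or stage by stage
implinet binarize --in expr.tsv --margin 0.5 --out ternary.tsv --fits fits.tsv
implinet pairs    --ternary ternary.tsv --sthr 3 --pthr 0.1 --out pairs.tsv
implinet network  --pairs pairs.tsv --expr expr.tsv --ann ann.tsv --out network.json
implinet paths    --network network.json --expr expr.tsv --ann ann.tsv --out selection.json
implinet score    --signature sig.gmt --expr expr.tsv --out scores.tsv
implinet evaluate --scores scores.tsv --ann ann.tsv

# target vetting and organoid response binning
implinet vet  --anchor GENE --targets targets.tsv --ternary ternary.tsv --out verdicts.tsv
implinet teer --out categories.tsv
```

Expression tables are TSV (genes × samples, first row sample ids, first
column gene ids, log2 scale; `--log2` applies log2(x+1) to raw counts).
Annotations are TSV with a `class_label` column; gene sets are GMT;
networks are JSON or GraphML.

## Layout

```
src/implinet/
  core_io.py          shared data model + TSV/GMT/JSON/GraphML readers & writers
  stepminer.py        one-step fits, ternary labels, dynamic-range filter
  implication.py      quadrant statistics and the six-relation classifier
  network_builder.py  equivalence clustering, cluster network, orientation
  path_engine.py      path enumeration, scoring, selection, AUC/Fisher
  target_vetting.py   druggability filter, vetting rules, TEER binning
  synthetic_data.py   seeded generators with planted ground truth
  pipeline.py         end-to-end runner with a serializable config
  cli.py              click entry point (`implinet`)
tests/                pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py acceptance-target report
```
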