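# lncsift

Separating **true full-length lncRNAs** from fragments and transcriptional
noise among the putative lncRNAs that RNA-seq transcript assemblies produce.

The conventional route to novel lncRNAs — assemble transcripts, drop
everything with protein-coding potential, keep what is > 200 nt — has a high
false-discovery rate: a large share of the survivors are transcript
fragments or noise rather than genuine transcripts with a real
transcription start site. Matched H3K4me3 ChIP-seq resolves this (the mark
flags active TSSs), but most public RNA-seq series have no matched
chromatin data. `lncsift` closes that gap with a supervised approach: it
learns the true/false distinction from H3K4me3-labeled benchmarks using
four RNA-seq-derivable genomic feature types, then applies it to stand-alone
RNA-seq assemblies.

For transcript *i* with label \(y_i \in \{\text{true},\text{false}\}\), the
model inputs are six features
\(x_i = (\ell_i, p_i, m_i, d_i, a_i, g_i)\):

* \(\ell_i \in [0,1]\) — exon-summed transcript length, log-transformed,
  clipped at mean ± 3σ and min–max scaled per dataset;
* \(p_i\) — promoter signature within ±1 kb of the 5′ end;
* \(m_i\) — multi-exon flag (exon count ≥ 2);
* \((d_i, a_i, g_i)\) — one-hot genomic location: **divergent** (5′ end
  within ±2 kb of an opposite-strand protein-coding TSS), **antisense**
  (≥ 1 bp opposite-strand overlap with a protein-coding gene), or
  **intergenic**.

Seven classifiers (logistic regression, KNN, decision tree, random forest,
naive Bayes, linear and RBF SVM) are each tuned by 10-fold cross-validation
maximizing mean F1 and refitted on the full training set; an **ensemble**
mode calls a lncRNA true only when all seven models agree, trading
sensitivity for precision. Ground-truth labels come from the benchmark rule
\(y_i = \text{true} \iff \min_k \mathrm{dist}(\text{5′ end}_i,
\text{peak}_k) \le 1\,\text{kb}\).

The package covers the full downstream workflow — putative-lncRNA filtering
cascade, H3K4me3 benchmark labeling, feature extraction, model training /
prediction / ensembling, permutation feature importance, transcript- and
locus-level evaluation — plus a synthetic-data module (class-conditional
feature generator with a closed-form Bayes-optimal score, and a
deterministic toy-genome fixture) so everything is testable without
downloads. Upstream alignment, assembly, peak calling and coding-potential
tools are out of scope; their standard outputs (GTF, broadPeak/BED, TSVs)
are the inputs.

## Worked example

Train a random forest on synthetic benchmark-shaped data and evaluate it on
a held-out draw:

```python
from lncsift import (compute_metrics, default_config, generate_feature_table,
                     permutation_importance, predict, train_selected)
from lncsift.ml_models import default_algorithm_specs

cfg = default_config()                       # P(true)=0.39, promoter 0.80/0.20, ...
train = generate_feature_table(cfg, 10_000, seed=1)
test = generate_feature_table(cfg, 2_000, seed=2)

spec = next(s for s in default_algorithm_specs() if s.name == "random_forest")
model, cv = train_selected(train, spec, k=10, seed=1)
print(cv.selected_setting, round(cv.selected_mean_f1, 3))

out = predict(model, test.drop(columns=["label"]))
panel = compute_metrics(test["label"], out["label"], out["score"])
print(round(panel.f1, 3), round(panel.auroc, 3))
print(permutation_importance(model, test, n_repeats=10, seed=1))
```

prints

```
{'n_estimators': 300, 'max_depth': 10} 0.84
0.833 0.934
{'length_scaled': 1.0, 'promoter': 0.72, 'multiexon': 0.11,
 'divergent': 0.2, 'antisense': 0.005, 'intergenic': 0.005}
```

Cross-validation selects depth-limited forests (mean F1 0.84); the held-out
F1 of 0.833 and AUROC of 0.934 sit just under the generator's Bayes-optimal
AUROC of ≈ 0.952 (`bayes_optimal_auroc(cfg)`), and the permutation
importances say the scaled length and promoter signature carry most of the
signal, with the top feature pinned at 1.0 by the scaling rule.

The same workflow is available from the shell; `lncsift simulate --mode
fixture` writes a tiny deterministic genome bundle on which the
interval-level subcommands run end to end:

```bash
lncsift simulate --mode fixture --out fix/
lncsift filter --transcripts fix/transcripts.gtf --annotation fix/annotation.gtf \
    --coding fix/coding_calls.tsv --expression fix/expression.tsv \
    --out putative.gtf --report report.tsv
lncsift label --transcripts putative.gtf --peaks fix/peaks.broadPeak --out labels.tsv
lncsift features --transcripts putative.gtf --annotation fix/annotation.gtf \
    --promoters fix/promoters.bed --out features.tsv
```

Subcommands: `filter`, `label`, `features`, `train`, `predict`, `evaluate`,
`importance`, `simulate`; all accept a shared YAML config (`--config`) whose
values individual flags override, and every run writes a provenance JSON
(config hash, seed, library versions) beside its output.

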