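# grnbench

Benchmarking de-novo reverse-engineering of gene regulatory networks
against gold standards built from transcription-factor knockout and
binding data, in the style of genome-scale *S. cerevisiae* studies.

## The problem

Inferring which transcription factor (TF) directly regulates which gene
from expression data alone is a central problem of systems biology — and
judging *how well* any method does it requires a trustworthy gold
standard. Knockout experiments reveal *regulatory* targets (genes that
respond when a TF is deleted), but responses can be indirect; ChIP
binding assays reveal *binding* targets, but binding can be
non-functional. The intersection of the two — TF→gene pairs supported by
both perturbation response and physical binding — defines the **direct
regulatory interactions** that form a gold standard.

`grnbench` implements that construction and a complete evaluation
harness around it, for people who build or assess network-inference
methods:

* **Gold standards** — per-mutant Benjamini–Hochberg thresholding of
  knockout differential-expression p-values (5% FDR), binding-score
  filtering at three nested stringency levels (p ≤ 0.001 & conservation
  in 2 species; p ≤ 0.005 & 1; p ≤ 0.005 & 0), intersection, and a
  log-space hypergeometric overlap test.
* **18 inference approaches** — bivariate association screening and
  Generalized Local Learning (GLL) neighborhood search with conditioning
  on up to 1–3 genes, each with Fisher's Z on continuous data or the G²
  statistic on ternary-discretized data, thresholded at 5% alpha or 5%
  FDR and assembled with AND/OR rules. All approaches output undirected
  networks.
* **7 accuracy metrics** — sensitivity, specificity, PPV, NPV, and the
  three combined Euclidean distances from the optimal point,
  d = √((1−m₁)² + (1−m₂)²) ∈ [0, √2], for the antagonistic pairs
  sensitivity/specificity, PPV/NPV and recall/precision; hypergeometric
  network significance with BH adjustment over the full benchmarking
  grid; Pareto-frontier ROC/AUROC summaries.
* **Sub-network analysis** — per-TF reconstruction accuracy and its
  Spearman correlation with TF connectivity, tested with an exact
  permutation null (gene identifiers relabeled on a fixed topology).
* **A synthetic-data generator** — hub-heavy acyclic TF→gene ground
  truths and linear-Gaussian expression under the four standard study
  designs (wild-type replicates, environment/time, compendium,
  perturbation), plus knockout DE tables and noisy nested binding calls,
  so the whole pipeline is testable end to end without any downloads.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

Simulate a 30-gene world with 5 TFs, build a gold standard from its
knockout and binding evidence, infer a network from the perturbation
dataset, and score it:

```sh
grnbench simulate --n-genes 30 --n-tfs 5 --mean-out-degree 3 \
    --noise-sd 0.2 --n-samples 120 --seed 7 --out-dir demo
grnbench build-gold --de demo/mutant_de.tsv --binding demo/binding_scores.tsv \
    --threshold 0.001 --min-conservation 2 --out demo/gold.tsv
grnbench infer --data demo/expression_perturbation.tsv \
    --test z --rule fdr --combine or --out demo/inferred.tsv
grnbench evaluate --inferred demo/inferred.tsv --gold demo/gold.tsv \
    --out demo/metrics.tsv
```

which prints

```
gold standard: 11 edges over 4 TFs -> demo/gold.tsv
BIVARIATE_Z_FDR_OR: 63 edges -> demo/inferred.tsv
```

and writes `demo/metrics.tsv`:

```
tp 11   fp 10   tn 19   fn 0
sensitivity 1        specificity 0.655
ppv         0.524    npv         1
d_ss 0.345   d_pn 0.476   d_rp 0.476
hypergeometric_p 0.000153
```

Reading: all 11 gold edges were recovered (sensitivity 1) at the cost of
10 false positives among the 40 candidate TF→gene pairs (PPV 0.52), an
overlap far beyond chance (hypergeometric p ≈ 1.5×10⁻⁴). The combined
sensitivity/specificity distance 0.345 is the Euclidean distance from
the perfect corner (1, 1) — smaller is better, √2 is worst.

The TF-connectivity analysis on the same networks,

```sh
grnbench subnet --inferred demo/inferred.tsv --gold demo/gold.tsv \
    --metric d_rp --n-perm 999 --seed 3 --out demo/subnet.tsv
```

prints `rho=-0.3162 perm_p=0.771 (n_perm=999)`: the observed negative
correlation between a TF's degree and its sub-network distance is not
distinguishable from the relabeling null on a world this small.

`grnbench all --seed 1 --out-dir out/` runs the full grid — four data
designs × 18 approaches × three nested gold standards — and writes the
metric-pair and distance tables, the Pareto-ROC summary and the
significant-correlation count table.

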