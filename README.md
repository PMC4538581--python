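# declamp

Differential-expression calling for bulk RNA-seq built around a
**per-transcript Poisson depth clamp** and a **Gaussian naive Bayes gene
scorer**.

## The problem

Read counts along a transcript are not always the clean, uniformly scattered
signal that count-based differential-expression (DE) statistics assume.
PCR and mapping artifacts can pile thousands of read starts onto a handful of
bases of one sample. Such a peak inflates that gene's count in one condition
only, fakes a large fold change, and produces a false positive no amount of
library-size normalization can fix — the bias is *within* the transcript, not
between libraries.

`declamp` is for analysts with aligned reads (SAM) and an annotation
(GTF/GFF3) for two conditions who want gene-level DE calls that are robust to
this within-transcript positional bias, including designs without replicates.

## Method

For each gene, reads are assigned in union mode (a read counts only if it
overlaps the exon union of exactly one gene) and the per-position read-start
counts $r_i$, $i = 1,\dots,TL$, are collected over the concatenated union
exons.

**Local normalization (the core step).** Model $r_i \sim \mathrm{Poisson}
(\lambda_T)$ with $\hat\lambda_T = \tfrac{1}{TL}\sum_i r_i$, and clamp each
position to the central confidence band of that fitted distribution,

$$
r_i^0 = \begin{cases}
\mathrm{UCL} & r_i > \mathrm{UCL} \\
\mathrm{LCL} & r_i < \mathrm{LCL} \\
r_i & \text{otherwise,}
\end{cases}
\qquad R^0 = \sum_i r_i^0 ,
$$

where UCL and LCL are the exact 97.5% and 2.5% Poisson quantiles of
$\mathrm{Poisson}(\hat\lambda_T)$. Artifact peaks are cut down to UCL; the
clamped total $R^0$ replaces the raw count downstream. On uniformly placed
reads the clamp removes almost nothing (see *Reproducing the results*).

**Global normalization.** $R^0$ counts are scaled between samples with
median-of-ratios size factors (default) or TMM (`--method tmm`), then genes
with mean count below 5 in both conditions are dropped.

**Three bounded attributes** per gene, each mapped onto $(0, 1]$ ($M_1, M_2$
are normalized condition means, $c$/$C$ the gene/global mean read GC
fraction):

$$
\mathrm{FC} = \frac{1}{1 + |\log_2 (M_1/M_2)|},\qquad
\mathrm{ARPK} = \frac{1}{1 + \max\!\big(0, \log_2 \tfrac{1000 (M_1+M_2)}{2\,TL}\big)},\qquad
\mathrm{GCC} = \frac{1}{1 + c/C}.
$$

**Naive Bayes scoring.** With a labeled training table (DE/NDE genes), one
univariate Gaussian per class and attribute plus class-frequency priors give
each gene a posterior score $p(\mathrm{DE} \mid \mathrm{FC}, \mathrm{ARPK},
\mathrm{GCC})$; genes are ranked by it. Evaluation helpers provide
leave-one-out cross-validation, ROC/AUC (tie-corrected, equal to the
Mann–Whitney statistic), and attribute ablation.

A seeded simulator generates annotation + SAM + ground truth under the
uniform-placement null, with injectable depth spikes, true fold changes and
GC composition, so the entire pipeline is testable without external data.

## Worked example

Simulate a 30-gene study (2 replicates/condition): 10 genes truly DE
(|log2FC| 2–3) and 2 non-DE genes carrying a 50× artifact spike over 10 bp in
condition 1 only — then run the pipeline.

```python
from declamp import (RunConfig, SimConfig, run_pipeline,
                     report_with_without_localnorm, simulate_training_table,
                     simulate_uniform_reads)

cfg = SimConfig(seed=42, n_genes=30, replicates=2, length_range=(250, 400),
                lambda_range=(1.0, 1.0), lambda_law="constant",
                spike_fraction=0.1, de_fraction=0.3, de_log2fc_range=(2.0, 3.0))
res = simulate_uniform_reads(cfg, "demo/sim")
truth = res["truth"]
sam_by_cond = {c: [res["sam"][s] for s in truth.samples
                   if truth.conditions[s] == c] for c in ("cond1", "cond2")}

rc = RunConfig(sam_by_condition=sam_by_cond, annotation=res["gtf"],
               outdir="demo/out", min_mean=0.0)
training = simulate_training_table(150, 150, seed=7)
out = run_pipeline(rc, training)
print(out["ranked"].head(12))
```

```
                score  rank
gene_id
G28      1.000000e+00     1
G25      1.000000e+00     2
G29      1.000000e+00     3
G02      1.000000e+00     4
G05      1.000000e+00     5
G04      1.000000e+00     6
G06      1.000000e+00     7
G14      1.000000e+00     8
G23      1.000000e+00     9
G13      1.000000e+00    10
G00      6.066059e-27    11
G12      1.547690e-29    12
```

The ten true DE genes occupy ranks 1–10 with posterior ≈ 1. The two spiked
genes, G00 and G12, fall to ranks 11–12 with posteriors ~1e-27: the clamp
removed their fake fold change. The side-by-side report shows what the clamp
did to them:

```python
print(report_with_without_localnorm(rc).loc[["G00", "G12"]].round(3))
```

```
     log2FC_without  log2FC_with
G00           1.519        0.185
G12           1.282        0.144
```

Without clamping both spiked genes would look like >2.4-fold changes
(|log2FC| > 1.2); with it their estimates return to ~0.15–0.19, close to
their true value of 0. The same study is available from the shell via the
`declamp` command (`declamp simulate`, `declamp run`, `declamp
compare-localnorm`, …; see `declamp --help`).

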