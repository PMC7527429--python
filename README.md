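# metprog

Metabolic-gene prognostic index pipeline for tumour expression cohorts.

Ovarian serous cystadenocarcinoma (and solid tumours generally) reprogram
cell metabolism, and the expression of metabolism-related genes carries
prognostic information. `metprog` implements the full analysis chain used
to turn a tumour/normal expression cohort, a weighted gene-interaction
network and a set of metabolic gene sets into a validated survival risk
index:

1. **Gene-set restriction & differential expression** — the expression
   matrix is restricted to metabolic gene-set members and filtered
   tumour-vs-normal at *p* < 0.05 (two-sided Wilcoxon rank-sum) and
   |log2 FC| > 1.
2. **Network prioritization** — a random walk with restart (RWR) on the
   weighted interaction network scores candidates by diffusion proximity
   to disease seed genes, iterating
   `P(l+1) = (1 − b) Y P(l) + b P0`, where `Y` is the column-normalised
   connection matrix, `b` the restart probability (default 0.7) and `P0`
   puts mass 1/T on each of T seeds (default seeds ACOT7, CERK, EHMT2,
   MTAP, PDE8A). The top-200 non-seed genes go forward.
3. **Cox screening & lasso** — univariate Cox proportional-hazards
   screening (Efron ties, Newton–Raphson) keeps genes with Wald
   *p* < 0.05; an L1-penalized Cox fit (coordinate descent, penalty by
   10-fold cross-validated partial-likelihood deviance) yields a sparse
   linear risk index `score = Σ_g β_g · x_g`.
4. **Stratification & evaluation** — patients split at the cohort-median
   score into low/high risk; groups are compared by Kaplan–Meier curves
   and the log-rank test, and discrimination is measured by IPCW
   time-dependent ROC AUC at 1/3/5 time-unit horizons.
5. **IHC association** — semi-quantitative immunohistochemistry scoring
   (intensity 0–2 × extent 0–4, positive at ≥ 5) and Pearson chi-square
   association of marker status with clinical covariates.

A first-class synthetic-data module generates cohorts with planted
differential genes, a seed-adjacent network module, proportional-hazards
survival driven by a known gene subset, and clinical tables with planted
odds ratios — so every stage is testable against ground truth.

## Worked example

Simulate a planted study (200 metabolic genes, 40 differential, 8 of them
prognostic; 400 tumours, 60 normals) and run the whole pipeline:

```sh
$ metprog simulate --seed 1 --out-dir study
planted bundle written to study

$ cat > config.yaml <<EOF
expression: study/expression.tsv
annotation: study/annotation.tsv
network: study/network.tsv
gene_sets: study/gene_sets.gmt
out_dir: study/results
seed: 1
EOF

$ metprog run-all --config config.yaml
risk model genes: G0020, G0000, G0001, G0022, G0003, G0002, G0021, G0023
log-rank p = 6.51e-58; AUC(1) = 0.946; AUC(3) = 0.929; AUC(5) = 0.938
```

The eight genes in the fitted risk model are exactly the eight planted
prognostic genes (`study/truth.json` lists them), the high-risk half of
the cohort has dramatically worse survival (log-rank *p* ≈ 7·10⁻⁵⁸), and
the risk score discriminates events at every horizon (AUC ≈ 0.93–0.95;
the planted effects are strong, so discrimination is far above what
real cohorts show). Stage-by-stage tables (DE results, RWR ranking,
univariate Cox, model JSON, risk scores, log-rank, AUC) and a manifest
with content hashes land in `study/results/`.

Each stage is also exposed on its own (`metprog de`, `rwr`, `cox`,
`lasso`, `evaluate`, `ihc`) and as library functions
(`metprog.netprop.rwr`, `metprog.signature.lasso_cox`, ...).

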