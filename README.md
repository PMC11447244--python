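# rxsig — pharmacogenomic resistance signatures and polygenic drug-response scores

`rxsig` implements a complete pipeline for discovering multi-drug resistance
gene signatures in cancer cell-line panels and turning them into a
prognostic polygenic score for patient cohorts.  It is aimed at
computational pharmacogenomics: the inputs are a genes × samples matrix of
per-gene z-scored expression, a long-format drug-response table (ln IC50 or
AUC, higher = more resistant) such as a GDSC- or CTRP-style export, and
clinical follow-up tables for scored cohorts.

## The method

1. **Correlation screen.** For every gene *g* and drug *d*, compute the
   Spearman correlation coefficient (SCC) of z-scored expression with
   response across the shared cell lines, with BH-adjusted two-sided
   p-values per drug and per-drug ranks by descending ρ.
2. **Signature selection.** A gene joins the resistance signature when it is
   significantly positively correlated (adjusted *P* < 0.05) and ranked in
   the top 50 for at least 20 drugs; an independent panel validates the
   signature with a top-2% cutoff.  The mirror procedure (significantly
   negative in two panels) yields sensitivity markers for a single drug.
3. **Polygenic score.** In a fixed context (one drug, one cancer lineage
   with ≥ 9 cell lines) each signature gene's weight is its SCC with
   response, and a sample's score is

   score<sub>c</sub> = Σ<sub>g=1..n</sub> SCC<sub>g</sub> · exp<sub>cg</sub>

   Genes missing from a cohort's platform are dropped without
   re-normalization.  For cross-context comparison, correlations are
   variance-stabilized as Z = √((N−3)/1.06) · arctanh(ρ) (the Fieller
   correction for Spearman coefficients).
4. **Survival evaluation.** Cohorts are stratified by score quartiles
   (Q1 = low vs Q4 = high) or the median; groups are compared with
   Kaplan–Meier curves and the two-sided Mantel log-rank test, and adjusted
   effects come from Cox proportional-hazards regression (Efron ties) with
   clinical covariates.
5. **Ablation.** Signature-minus-*k*: delete gene subsets from the score
   (no refit), re-stratify, refit the multivariate Cox model and report the
   hazard-ratio shift of each removal — a necessity test for every gene.

A synthetic-data module generates cell-line panels (latent drug-class
factors, planted resistance/sensitivity genes with known loadings) and
patient cohorts (Weibull proportional hazards driven by the true score)
so the whole pipeline is testable with known ground truth and no downloads.
See `docs/methods.md` for the generative models and numerical choices.

## Worked example

```python
import rxsig
from rxsig.simulate import PanelConfig, CohortConfig, simulate_panel, simulate_cohort

expr, resp, annot, truth = simulate_panel(PanelConfig(seed=1))
screens = rxsig.screen_all(expr, resp)
sel = rxsig.select_resistance_genes(screens, top_k=50, min_drugs=20, alpha=0.05)
print(f"selected {len(sel.selected_genes)} genes; "
      f"{len(set(sel.selected_genes) & set(truth.resistance_genes))} are planted")

w = rxsig.fit_weights(expr, resp, sel.selected_genes, "DRUG000", "LINEAGE0", annot)
cohort_expr, clinical, _ = simulate_cohort(CohortConfig(seed=1), w)
score = rxsig.compute_score(w, cohort_expr)
res = rxsig.score_group_cox(clinical, score.scores, covariates=["age", "stage", "grade"])
print(f"median-split HR (high vs low) = {res.hazard_ratio('score_high'):.2f}, "
      f"p = {res.p_value('score_high'):.2e}")
```

prints

```
selected 40 genes; 40 are planted
median-split HR (high vs low) = 1.48, p = 2.92e-07
```

i.e. the screen recovers every planted resistance gene with no false
positives, and in an independent synthetic cohort whose hazard tracks the
true score, patients above the median score carry a 1.48-fold adjusted
hazard.  The quartile split gives a log-rank χ² of 23.7 (p = 1.1e-06).

The polygenic score is also exposed as a scikit-learn transformer:

```python
from rxsig import PolygenicScorer
est = PolygenicScorer().fit(X, y)   # X: samples x genes (z-scored), y: ln IC50
scores = est.transform(X_cohort)    # weights in est.weights_
```

The same stages are available from a shell via the `rxsig` CLI
(`correlate`, `select`, `validate`, `weights`, `score`, `survival`,
`ablate`, `geneset`, `simulate`, `run`); `rxsig run --config pipeline.yaml`
executes all six stages and writes a JSON run manifest.

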