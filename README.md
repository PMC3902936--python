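# remsig

Re-engineering drug response from expression signatures.

`remsig` implements, as a tested offline pipeline, the logic behind a
pharmacogenomic signature-matching analysis on NCI-60-style data: given a
panel of cell lines screened against many compounds (log10 GI50 values) and
the panel's transcriptomes, it

1. **classifies** cell lines as *resistant* (high GI50) or *sensitive*
   (low GI50) per drug, by either the ±0.8·SD rule or the ≥6-fold rule,
   keeping drugs with at least six cells in each group;
2. **derives** per-gene signed differential statistics between the two
   groups — the **v statistic** `v = s·(1 − P)`, where `P` is the two-sided
   Student's t-test P-value and `s` the sign of the mean difference, so
   `v ∈ [−1, 1]` with ±1 for strongly up-/down-regulated genes — plus
   Storey–Tibshirani q-values;
3. **builds** each drug's **response engineering module**
   (REM, *resistance-minus-sensitive*): the genes that both separate the
   resistant from the sensitive group (t-test, p < α) **and** correlate
   with GI50 across the grouped cells (Pearson, p < α);
4. **tests** candidate gene sets (e.g. metastasis suppressor genes in GMT
   format) against a *random expectation* — the mean number of nominally
   differential genes over random same-size sets — with a 1-df chi-square;
5. **scores** a factor-induction signature (induced vs control replicates)
   against each REM by Pearson correlation of the paired v-vectors: a
   significant **negative** r predicts that inducing the factor pushes
   cells toward the sensitive state (engineered re-sensitization).

Because the original drug screen and microarrays are not publicly
deposited, the package ships a first-class synthetic-data module
(`remsig.simulate`) that generates dose–response, expression and induction
data with planted, recorded ground truth, so every stage is verifiable.

## Worked example

```sh
remsig simulate --n-drugs 20 --n-cells 60 --n-genes 1000 --n-planted 100 \
    --seed 11 --out sim
remsig run --dose sim/dose.tsv --expr sim/expression.tsv \
    --genesets sim/genesets.gmt \
    --induction sim/induction.tsv --induction-labels sim/induction.labels.tsv \
    --seed 11 --out run
```

From `run/summary.json` of this exact invocation:

* 20 of 20 drugs pass the ≥6 resistant / ≥6 sensitive filter;
* REM sizes range 25–56 genes (median 42) at α = 0.05;
* the induction contrast reports 218 genes up and 217 down
  (P < 0.01, FDR < 10%);
* the top of `run/comparisons.tsv`:

```
factor_id  drug_id   n_genes  r              p_r            call
induction  DRUG0001  39       -0.9986230434  5.610721087e-49  predict_sensitization_on_induction
induction  DRUG0007  46       -0.5513361214  7.155169671e-05  predict_sensitization_on_induction
```

`DRUG0001` is the drug whose signature the synthetic induction experiment
was generated against (target correlation −0.85): the pipeline recovers a
strong negative correlation over its 39 REM genes and calls sensitization
on induction. Unrelated drugs drift toward `no_call`.

The library surface mirrors the CLI (`classify_by_sd`, `make_signature`,
`build_rem`, `gene_set_null_test`, `correlate_signatures`,
`cluster_heatmap`, `run_pipeline`, …); see the module docstrings.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the desk-scale synthetic world (60 cell lines × 200 drugs ×
2000 genes, planted GI50 tails and REM genes, induction experiment at
target correlation −0.85) and runs every pipeline stage end to end —
classification, per-drug signatures, REM construction, gene-set
chi-square tests and induction matching — writing the summary JSON to
`--out`. All randomness derives from `--seed`; repeated runs are
byte-identical.

## Scope

Inputs are assumed to be already-normalized log-scale matrices; the
package does no microarray preprocessing, no GI50 curve fitting, and no
gene-set enrichment beyond the random-expectation test. See
`docs/methods.md` for the statistical model, defaults and limitations.
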