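# ectomark

Discovery and validation of ectopic-gene-activation prognostic biomarkers in
oral squamous cell carcinoma (OSCC), as a tested, reusable Python pipeline.

Tumours frequently activate genes that are silent in every normal adult
somatic tissue (classically testis- or placenta-restricted genes). Because
such genes have essentially zero background expression, a simple threshold on
their transcriptomic signal separates "activated" from "silent" tumours — and
the same on/off call can later be read out by immunohistochemistry (IHC) on
routine pathology sections. `ectomark` implements the full discovery
procedure around this idea:

1. **Tissue catalog** — from a normal-tissue expression panel, select genes
   with predominant expression in one tissue and silence (or very low
   expression) in all non-germline somatic tissues, and derive per-gene
   somatic background ceilings.
2. **Biomarker screen** — for each candidate gene in a tumour cohort with
   overall survival, apply three selection criteria:
   (1) univariate Cox association of expression with shorter survival,
   p < 0.05 with HR > 1; (2) existence of expression thresholds splitting
   patients into groups with different survival (log-rank p < 0.05); and
   (3) a *stability* requirement — the longest contiguous run of significant
   threshold percentiles must span more than 50 percentile points.
3. **Activation calls and panel classification** — binary per-gene activation
   calls (expression above a background-derived or percentile threshold), the
   per-patient activation count over a small marker panel, and the risk
   grouping: 0–1 activated genes = good prognosis, 2–3 = poor. Kaplan–Meier,
   log-rank, Cox (count as covariate), TNM-stage/HPV/site subgroup analyses
   and multivariate Cox models mirror the validation analyses.
4. **IHC scoring** — the per-antibody composite rules for the AREG / CCNA1 /
   DDX20 panel (intensity 0–3 × proportion category, "high" iff the product
   ≥ 3; AREG by >50 % positive cells alone) and the three-marker IHC panel
   test.
5. **Signature & GSEA** — Welch t-test differential expression of
   panel-positive vs negative tumours on log2(x+1) values, signature gene
   sets at |fold change| > 2 and p < 0.01, signature correlation between
   cohorts, and a weighted running-sum gene-set enrichment engine with a
   seeded permutation null.

All survival primitives (product-limit estimator, k-group log-rank with the
hypergeometric variance, Cox partial likelihood with Efron/Breslow tie
handling and Newton iterations) are implemented in the package and verified
against independent oracles and `lifelines` in the test suite.

A fully seeded synthetic-data module generates normal-tissue panels with
planted germline-predominant genes, tumour cohorts whose survival follows a
proportional-hazards model driven by planted activations, and IHC tables
coupled to the activation truth — so every stage is testable as a
parameter-recovery problem.

## Worked example

Run the built-in synthetic demo (300 genes, 40 planted tissue-specific
candidates of which 3 are truly prognostic with hazard ratio 2.5 per
activation, 300 patients):

```bash
ectomark run --out demo --seed 1
```

This writes versioned reports into `demo/run_0001/`. With seed 1:

* `catalog.json` — 40 tissue-predominant silent genes selected (exactly the
  planted set).
* `screen.json` — of the 40 candidates (259 events among 300 patients), 2
  genes pass all three criteria: `G00003`, `G00001`. The third planted gene
  narrowly misses the >50-point threshold-stability interval at this cohort
  size.
* `classification.json` — risk groups good n=254 / poor n=46; two-group
  log-rank χ² = 39.8, p = 2.8e-10; Cox hazard ratio per additional activated
  gene 2.14 (p = 4.3e-15). The multivariate model keeps both the panel
  (HR 2.93, p = 8.4e-10) and late TNM stage (HR 2.01, p = 6.4e-07) as
  independent predictors — the qualitative behaviour expected when both
  truly drive hazard.
* `ihc_report.json` — the three-marker IHC panel (simulated staining coupled
  to the true activations) stratifies survival with log-rank p = 5.3e-12.
* `signature.json` — differential signature of panel-positive vs negative
  tumours and its self-enrichment by GSEA (up-signature ES = 1.0).

Identical config + seed reproduces every report byte-for-byte.

The same stages are available as subcommands on explicit TSV/GMT inputs:
`simulate`, `catalog`, `screen`, `activate`, `classify`, `ihc-score`,
`signature`, `run` (see `ectomark <cmd> --help`).

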