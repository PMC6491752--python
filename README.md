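# sdindex — Stroke Dysbiosis Index

`sdindex` builds and evaluates a **Stroke Dysbiosis Index (SDI)**: a single
per-sample score that condenses the broad case-control differences between
the gut microbiota of acute ischemic-stroke patients and healthy controls
into one number usable in clinical analyses. It is aimed at microbiome
researchers who have genus-level 16S rRNA abundance tables with case/control
labels and clinical covariates, and want a tested, reproducible pipeline
from raw counts to clinical association statistics.

## The model

Given a case-control cohort, the pipeline is:

1. **Preprocess** the samples × genera count table: drop genera whose total
   count is below 0.1% of the table's grand total, rarefy every sample
   without replacement to 4,800 reads (dropping shallower samples), and
   convert to relative abundance in percent.
2. **Select the signature**: per genus, a two-sided Wilcoxon rank-sum
   (Mann-Whitney U) test between patients and controls, Benjamini-Hochberg
   adjusted; genera with FDR-adjusted *P* < 0.1 enter the signature, directed
   by which group has the larger mean relative abundance. This yields a
   stroke-enriched set *S* and a control-enriched set *C* (the packaged
   published signature has |S| = 7 and |C| = 11, 18 genera total).
3. **Score** each sample:

   SDI = ( Σ<sub>i∈S</sub> a<sub>i</sub> / |S| − Σ<sub>j∈C</sub> a<sub>j</sub> / |C| ) × 100

   where a<sub>g</sub> is the genus's relative abundance in percent; a
   signature genus absent from a sample contributes 0. Higher SDI = more
   stroke-like (dysbiotic) community.
4. **Stratify** patients at their median SDI (ties to the high stratum,
   SDI-H) and **evaluate**: case/control ROC AUC, Spearman correlation with
   stroke severity (NIHSS at admission) and outcome (mRS at discharge),
   unweighted-UniFrac distance of each stratum to the controls with
   PCoA/PERMANOVA, and a univariate *P* < 0.20 screen feeding a
   multivariable logistic model of severe stroke (NIHSS ≥ 8) or unfavorable
   outcome (mRS > 2).

A synthetic-cohort generator (Dirichlet-multinomial counts, a planted
directional signature, clinical scores coupled to each subject's true index)
makes the whole pipeline testable without any sequencing data.

## Worked example

```python
import sdindex as sd

spec = sd.CohortSpec(seed=1)               # 104 patients / 90 controls
train = sd.generate_cohort(spec)
model = sd.StrokeDysbiosisIndex(train.table, train.clinical["group"])
res = model.fit(seed=1)
print(res.summary())
```

```
Stroke Dysbiosis Index — fit summary
====================================================
samples (post-rarefaction): 194  [stroke: 104, control: 90]
genera tested: 53
signature: 32 genera (7 case-enriched, 25 control-enriched)
median SDI: 286.00 (stroke) vs -80.63 (control), rank-sum p = 3.61e-33
ROC AUC (case vs control): 100.0%
patient median threshold: 286.00  (SDI-H: 52, SDI-L: 52)
```

The synthetic cohort plants a strong 18-genus effect (log2 fold change 1.5),
so the fitted signature recovers the planted genera (plus compositional
spill-over into correlated genera), the patient and control score
distributions separate completely, and the 104 patients split 52/52 at the
median threshold. Scoring a held-out cohort from the same population with
the *training* signature, and correlating patient scores with severity:

```python
val = sd.generate_cohort(sd.validation_spec(spec))   # 83 / 70
vs = res.score(val.table, seed=2)
y = (val.clinical["group"] == "stroke").astype(int).loc[vs.sdi.index]
print(f"validation AUC: {100 * sd.roc_auc(vs.sdi, y).auc:.1f}%")
r, p = res.spearman_with(train.clinical.query("group=='stroke'")["nihss_in"])
print(f"Spearman SDI vs NIHSS(admission): r = {r:.3f}, p = {p:.3g}")
```

```
validation AUC: 100.0%
Spearman SDI vs NIHSS(admission): r = 0.265, p = 0.00661
```

The weak-but-significant severity correlation (r ≈ 0.2–0.45 depending on
seed) is by design: the generator couples NIHSS/mRS to the true index with
realistic noise, not deterministically.

The published 18-genus signature ships as a preset —
`sd.load_preset_signature()` — so existing cohorts can be scored without
refitting. The same pipeline is available from a shell via the `sdi`
command (`sdi simulate | prep | build-signature | score | ecology |
evaluate`; each subcommand has `--help`).

## Notes

- The published SDI-H poor-outcome percentage is internally inconsistent in
  the source tables (36.5% in the stratum table vs 34.6% in the text); this
  package follows the table's counts (19/52 → 36.5%).
- See `docs/methods.md` for modelling assumptions, parameter choices,
  numerical details and known limitations.
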