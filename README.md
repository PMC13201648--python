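# lumishift

Biomarker analysis pipeline for stratifying response to next-generation
selective estrogen receptor-α antagonist/degraders (SERDs) in ER+/HER2−
breast cancer.

Roughly 30–50% of patients with pretreated metastatic ER+ disease progress
by their first on-treatment scan on a next-generation SERD, while others
benefit for years. A recurring explanation is loss of *luminal lineage
identity*: tumors that shed expression of estrogen receptor-α (ERα) target
genes and luminal transcription factors lose their dependence on ERα and
stop responding to drugs that degrade it, instead upregulating orthogonal
proliferative programs (EGFR/MAPK, Hippo/TEAD, Wnt, JAK/STAT). `lumishift`
implements the quantitative machinery of that analysis as a tested,
reusable Python library for translational scientists:

- **Signature scoring and luminal classification** — gene-wise z-scores
  against an ER+ reference cohort; a signature score is the mean z over the
  signature's genes; a tumor is *Lum-high* iff it strictly exceeds the
  cohort median on both the ERα-activity score (21 estrogen-induced genes)
  and the luminal-TF score (15 lineage TFs). The four signature panels
  ship as constants.
- **Survival stratification** — non-responder (NR) = progression event with
  PFS < 2 months; responder (Resp) = PFS ≥ 2 months; Kaplan–Meier
  estimation and the log-rank test with an observed/expected hazard-ratio
  summary, HR = (O_a/E_a)/(O_b/E_b).
- **Mutation inference** — a (sample, gene) is *mutant* when any clinical
  hotspot variant (built-in *ESR1*/*PIK3CA* panels) reaches a variant
  allele fraction ≥ 5% at covered depth; CNV classes at log2 copy-ratio
  ≥ +1 (amplified) / ≤ −1 (loss).
- **Expression–response association** — paired differential expression,
  preranked GSEA (weighted running-sum ES, permutation NES/p), per-gene
  logistic regression of response on standardized expression with arm and
  subtype covariates (log2-odds units), and one-sided Fisher TF-target
  enrichment.
- **Chromatin/motif analysis** — differential peak classification
  (|log2FC| ≥ 1, FDR < 0.05; "unchanged" = |log2FC| < 1 at any FDR < 1),
  a 60,000-peak evaluation cap, %TP−%FP motif enrichment with Fisher
  p-values, ERα/FOXA1 motif co-occurrence partitions, TSS-proximity
  peak-to-gene mapping (3 kb window, >1 site), and paired expression-trend
  tests across parental / 2-month / resistant conditions.
- **Synthetic data** — generators for every input with planted group
  effects, planted allele fractions, and planted motif/expression
  structure, so the full pipeline is testable without patient data.

IHC H-scores are included as the pharmacodynamic readout:
`H = 1·(%1+) + 2·(%2+) + 3·(%3+)`, range 0–300.

## Worked example

Simulate a 200-patient cohort with planted signature effects (responders
carry a +1 z-unit shift on estrogen-induced and luminal-TF genes) and a
planted hazard ratio of 6/22, then run the scoring → classification →
survival pipeline:

```python
from lumishift import (
    CohortSimConfig, LUMINAL_TF, classify_luminal, era_activity,
    km_logrank, score_signature, simulate_cohort, zscore_to_reference,
)

d = simulate_cohort(CohortSimConfig(n_patients=200, seed=1))
z, rep = zscore_to_reference(d.expr_baseline, d.reference)
call = classify_luminal(era_activity(z).scores,
                        score_signature(z, LUMINAL_TF).scores)
clin = d.clinical.set_index("patient")
hi = call.labels[call.labels == "Lum-high"].index
lo = call.labels[call.labels == "Lum-low"].index
cmp = km_logrank(clin.loc[hi, "pfs_months"], clin.loc[hi, "event"],
                 clin.loc[lo, "pfs_months"], clin.loc[lo, "event"])
print(call.labels.value_counts().to_dict())
print(f"log-rank chi2={cmp.statistic:.2f} p={cmp.p:.2e} "
      f"HR={cmp.hazard_ratio:.3f} medians={cmp.median}")
```

Output:

```
{'Lum-low': 103, 'Lum-high': 97}
log-rank chi2=74.41 p=6.33e-18 HR=0.309 medians=(34.2, 6.5)
```

Lum-high tumors have a ~0.31 hazard ratio relative to Lum-low — close to
the planted 6/22 ≈ 0.27 (slightly attenuated by classification noise) —
with median PFS 34 vs 6.5 months, i.e. the classifier recovers the planted
survival contrast.

The same stages are scriptable from a shell:

```sh
lumishift simulate --preset cohort --seed 1 --out demo
lumishift score --expr demo/expr_baseline.tsv --reference demo/reference.tsv --out demo/scores
lumishift survival --clinical demo/clinical.csv --groups demo/groups.tsv --out demo/surv
```

Run `lumishift --help` for the remaining subcommands (`hscore`,
`call-mutations`, `enrich`, `tf-enrich`, `chromatin`).

## Documentation

See `docs/methods.md` for the statistical methods, the synthetic-data
model and its limitations, and the numerical conventions (tie handling,
sentinels, exact-vs-asymptotic switchovers).
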