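# chemosig

Targeted-proteomics signature selection for predicting platinum response
in advanced high-grade serous ovarian carcinoma (HGSC).

Patients whose tumours recur within 6 months of the last platinum dose
(treatment-free interval to platinum, TFIp < 6) are chemoresistant;
identifying them at diagnosis from archival (FFPE) tumour tissue would
let them be steered toward alternative regimens. `chemosig` implements
the full analysis chain for this problem, for computational proteomicists
and biostatisticians working with parallel-reaction-monitoring (PRM)
panels:

1. **Discovery** — protein abundance as the mean of the three most
   intense peptides, equalised-median normalization, a 4-of-7 per-group
   presence filter, Welch tests with Benjamini–Hochberg adjustment
   (q < 0.05), and candidate selection by presence/absence criteria plus
   a literature list.
2. **PRM verification** — transition-level QC (interference by
   leave-one-fragment-out correlation against the heavy-standard pattern,
   retention-time windows, minimum trace counts), below-LOD replacement
   with a background estimate, internal-standard median normalization
   (exact removal of per-run scale biases), technical-CV reporting,
   best-peptide-per-protein rollup, and minimum-abundance imputation.
3. **Signature selection** — 500 stratified 8:10 training/validation
   splits; in each, greedy forward logistic selection seeded by the
   highest-AUC protein and gated by a > 0.02 training-AUC gain; the most
   frequent combination becomes the consensus signature, refit on the
   whole cohort.
4. **ROC machinery** — Mann–Whitney AUC, asymptotic (placement-value)
   confidence intervals with bootstrap fallback, paired two-curve tests,
   and Youden-optimal operating points; evaluation of the signature
   alone, of four clinical covariates (age, menopausal status, log CA125,
   primary treatment), and combined, including the chemoresistant vs
   partially-chemosensitive (TFIp 6–12 months) subgroup.

A synthetic-data module generates clinical cohorts and discovery/PRM
datasets with the statistical structure this design assumes (run biases,
intensity-dependent dropout, interfered transitions, correlated clinical
covariates, planted multi-protein effects), so the whole chain is
testable without any download. `docs/methods.md` describes the model and
every numerical choice.

## Worked example

The numbered drivers under `analysis/` run the full study on simulated
cohorts and write their tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py        # cohorts + raw datasets
python analysis/02_discovery_candidates.py    # discovery candidates
python analysis/03_prm_quantification.py      # QC, normalization, matrix
python analysis/04_signature_selection.py     # 500-repeat selection
python analysis/05_clinical_combination.py    # clinical + subgroup ROC
```

On the default seeds this prints (abridged):

```
PRM: 49827 transition rows, 58 peptides, 29 proteins, signal = PROT01+PROT02+PROT03
evaluated 5104 (run, peptide) trace sets; 5101 passed QC
technical variability (replicate subset): median CV 3.5% across 58 peptides
500/500 repeats succeeded; mean validation AUC 0.934; combination sizes {2: 325, 3: 146, 1: 16, 4: 13}
consensus: PROT01+PROT02 (selected 207/500)
whole-cohort AUC 0.973 (95% CI 0.942-1.000); Youden cutoff 0.441: sensitivity 0.88, specificity 0.95
  clinical only: AUC 0.797 (95% CI 0.696-0.899)
  combined: AUC 0.985 (95% CI 0.968-1.000)
  paired ROC comparison (proteins vs combined): p = 0.135
```

Read: the assay's technical noise is ~3%; the resampled selection almost
always builds its classifier from the planted signal proteins (the
> 0.02 gain rule prefers a two-protein subset of the planted trio at this
strong effect size — see `docs/methods.md`); the consensus signature
separates chemoresistant from chemosensitive patients with whole-cohort
AUC 0.97, and adding clinical covariates nudges it upward without a
significant paired difference.

The same pipeline runs end to end from a config with
`chemosig run --seed 11 --out results/run` (subcommands: `simulate`,
`discover`, `quantify`, `select`, `evaluate`, `run`); reruns are
byte-identical for a fixed seed. To apply the verification stage to a
real per-patient table (log2 areas per protein and patient plus a
clinical CSV), see `scripts/evaluate_published.py`.

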