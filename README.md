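# herbsynergy

In-silico screening of synergistic multi-compound anti-breast-cancer
combinations from the *Prunella vulgaris* L. (PVL) - *Taraxacum mongolicum*
Hand.-Mazz. (TH) herb pair, rebuilt as a tested, reusable Python pipeline.

Traditional Chinese medicine extracts act through many compounds hitting
many targets at once.  The question this package addresses is: *which small
subset of an extract's compounds carries its anti-tumor effect, and at what
ratio?*  The pipeline answers it in stages:

1. **Interaction expansion** (`interaction_space`) - compounds and protein
   targets are placed in a standardized, PCA-reduced molecular-descriptor
   space; a compound is predicted to bind a target when its Euclidean
   distance to the target's known-ligand centroid falls inside a per-target
   threshold (the 95% empirical quantile of known-ligand distances).
   Predicted and known edges merge into an expanded interaction network.
2. **De-redundancy** (`selection`) - compounds are clustered on their
   binary target profiles with within-groups linkage (the merge minimizing
   the average of *all* pairwise distances inside the merged cluster); one
   representative per cluster survives, preferring the compound with the
   most targets.
3. **Enumeration + featurization** (`combinations`) - every 1-5-compound
   subset of the representatives is enumerated (24 compounds give
   `sum_{k=1..5} C(24,k) = 55,454` combinations) and featurized as a
   1,308-vector: 1,093 target-union bits plus 215 cell-line genomic
   features.
4. **Synergy ranking** (`synergy_model`) - a feed-forward network
   (200/100 ReLU hidden layers, dropout, dual regression/classification
   heads, Adam, MSE + cross-entropy) maps feature vectors to a
   *pseudo-IC50*: a standardized potency score where lower means more
   synergistic.  Combinations are ranked ascending; expansion scans score
   a base combination as compounds are added one at a time.
5. **Pharmacology** (`pharmacology`) - CCK-8 viability, four-parameter
   logistic IC50 fits, and the Chou-Talalay combination index generalized
   to k components:

       CI = sum_i D_i / IC50_i,   D_i = IC50_mix * f_i

   with CI < 1 synergy, CI = 1 additive (Loewe), CI > 1 antagonism.
6. **Formulation** (`formulation`) - HPLC contents (mg per g crude drug)
   convert to µM at an extract dose via `uM = content * dose / MW * 1000`,
   giving the integer ratio strings (e.g. F973 = CA:ROA:PCA:ET at
   64:305:4:5, total 378 µM at 25 mg/mL) used to assay combinations at
   their natural extract proportions, and ranking lots from different
   geographic origins.
7. **Network report** (`network`) - tripartite compound-target-pathway
   graphs with exact node/edge arithmetic and target classes by pathway
   membership.

A `synthetic` module generates every input with known ground truth
(planted ligand-ball descriptor geometry, Hill/Loewe dose-response curves
with a tunable interaction parameter, and a latent-function synergy
corpus), so the whole chain is testable without any downloads.

## Worked example

```bash
$ herbsynergy ci --ratio 30:106:50 --mix-ic50 21.94 --singles 295.18:68.86:885.67
CI = 0.20 (synergy)
```

This is the T271 combination (chlorogenic : cichoric : caffeic acid) at its
natural ratio in the TH 50%-ethanol extract: the mixture inhibits half of
MCF-7 growth at 21.94 µM total, far below what Loewe additivity of the
single agents predicts — a strong synergy call (CI = 0.20).

```bash
$ herbsynergy enumerate 24
55454

$ herbsynergy demo --seed 1 --out runs/demo
{
  "network_summary": {"n_compounds": 26, "n_targets": 12, "n_edges": 26},
  "n_clusters": 3,
  "n_representatives": 3,
  "n_combinations": 7
}
```

The demo runs the all-synthetic pipeline end to end (descriptor world →
interaction expansion → clustering → enumeration → surrogate training →
ranking) and writes `edges.csv`, `clusters.csv`, `ranking.csv`, the golden
`ci_report.csv` / `formulation_report.csv`, and a `manifest.json` with
output hashes; reruns with the same seed are byte-identical.  The top of
`ranking.csv` lists combinations by ascending predicted pseudo-IC50, e.g.

```
rank,combination,pseudo_ic50,synergy_class,probability
1,C0000+C0001,-0.076063,positive,0.572766
2,C0001,0.018093,positive,0.578865
```

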