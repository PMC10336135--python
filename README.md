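# gliograph

Spatial cellular architecture statistics and survival modelling for
glioblastoma spot maps.

Glioblastoma tumors are mosaics of transcriptional cell states — NPC-like,
OPC-like, AC-like/reactive-astrocyte, MES-like and MES-hypoxia — and how
those states are *arranged* in the tissue carries prognostic information
beyond their abundance. `gliograph` implements, as a tested and reusable
library, the quantitative core of that analysis:

- **Tumor-content estimation from copy-number signal.** Per-spot expression is
  averaged over 100-gene chromosomal windows and compared to a normal-brain
  reference; after rescaling so normal scores span 0.98–1.02 around 1.00,
  windows with tumor-wide mean score > 1.05 (gain) or < 0.95 (loss) become
  signature events. The tumor cell content of spot *i* for an event is
  `C_i = (A_i − 1)/(max A − 1)` for gains and `C_i = (1 − A_i)/(1 − min A)`
  for losses, averaged over ≥ 3 events; spots with `C > 0.2` are malignant.
- **Subtype maps.** Control-bin module scores (mean log-normalized module
  expression minus bin-matched control genes) and top-scoring-module subtype
  assignment, plus geographically weighted (Gaussian-kernel) local correlation
  between module score fields.
- **Architecture statistics on the spatial neighborhood graph.** Patches
  within a two-patch Chebyshev distance are neighbors (24 per interior node).
  Per class *m*, the clustering coefficient
  `Cluster(m) = I(M,M) / (I(M,M) + I(M,K))` and the interaction matrix
  `Interaction(m,k) = I(M,K) / Σ I(malignant, malignant)`, and abstractive
  networks that collapse neighborhoods > 70 % dominated by one subtype.
- **Survival modelling and evaluation.** The Cox partial-likelihood loss
  `L = −Σ_{i:δ_i=1} [s_i − log Σ_{j:Y_j ≥ Y_i} e^{s_j}]` (Breslow ties), a
  Newton-Raphson linear Cox fit, a small feed-forward risk network trained on
  the mini-batch Cox loss with within-batch risk sets, Harrell's C-index, the
  IPCW integrated Brier score, and the composite score
  `CS = (C-index + (1 − IBS))/2`; Kaplan-Meier curves, the log-rank test and
  median high/low risk splits.
- **Cohort association.** Multivariate Cox regression of subtype proportions,
  clustering coefficients and interaction fractions against survival with
  gender/age/IDH/tissue-size covariates and Benjamini-Hochberg adjustment;
  rank-sum differential expression between aggressiveness groups
  (log2FC > 0.25, P < 0.01) and hypergeometric gene-set enrichment
  (P < 0.05, Q < 0.20).

Because the original study's cohorts are image- and sequencing-scale, the
package ships a first-class synthetic-data module (`gliograph.synth`) that
generates Visium-like spot grids with chromosome-ordered expression and
embedded gains/losses, Potts-model label maps with tunable spatial
clustering, and proportional-hazards survival linked to spatial features —
so every stage is testable end-to-end on a laptop.

## Worked example

```python
import numpy as np
import gliograph as gg

cfg = gg.synth.SynthConfig(grid_width=20, grid_height=20, n_genes=1600, seed=0)
adata, truth = gg.synth.generate_expression_sample(cfg, seed=0)
ref = gg.synth.generate_reference_sample(cfg, seed=100)

spots = gg.cna.qc_filter(adata, min_genes=100)
content, events, _ = gg.cna.estimate_content(spots, ref)
print(f"signature events: {len(events)}")
print(f"content vs truth r = {np.corrcoef(content, spots.obs['true_content'])[0, 1]:.3f}")
malignant = spots[gg.cna.malignant_mask(content).to_numpy()].copy()
print(f"malignant spots: {malignant.n_obs}/{spots.n_obs}")

scores = gg.scoring.score_modules(malignant, truth.module_defs, seed=0)
labels = gg.scoring.assign_subtypes(scores)
print(f"subtype accuracy = {(labels.to_numpy() == malignant.obs['true_subtype'].to_numpy()).mean():.3f}")

frame = malignant.obs[["x", "y"]].copy()
frame["label"] = labels.to_numpy()
feats = gg.graph.slide_features(gg.graph.nx_from_frame(frame))
print(f"CC(AC-like) = {feats['cc_AC-like']:.3f}, "
      f"Interaction(OPC-like, MES-hypoxia) = {feats['int_MES-hypoxia|OPC-like']:.3f}")
```

prints

```
signature events: 10
content vs truth r = 0.919
malignant spots: 271/400
subtype accuracy = 1.000
CC(AC-like) = 0.502, Interaction(OPC-like, MES-hypoxia) = 0.029
```

Ten planted gain/loss windows are recovered as signature events; the
estimated tumor content tracks the generator's truth (r = 0.92); 271 of 400
spots exceed the 0.2 malignancy cutoff; module scoring reassigns every
malignant spot to its true subtype; and the slide-level feature vector
reports the AC-like clustering coefficient and subtype interaction fractions
that the survival association consumes.

The same flow is scripted end-to-end (simulation → QC → CNA content →
subtypes → graph features → survival association → risk model → DE →
enrichment) by `gg.pipeline.run_pipeline(cfg, outdir, seed)`, which writes
every artifact plus a manifest, or from the shell:

```sh
gliograph run-all --seed 1 --out results/
gliograph simulate --seed 1 --out sim/           # individual stages
gliograph graph-stats --label-map sim/label_map.csv --out gs/
```

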