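# texlai

Texture-index construction and leaf-area-index (LAI) inversion for
multispectral canopy imagery.

## The problem

LAI — one-sided leaf area per unit ground area (cm² cm⁻²) — is the workhorse
descriptor of crop canopy development. UAV multispectral imagery estimates it
cheaply through vegetation indices (VIs), but ratio indices saturate as the
canopy closes, and gray-level co-occurrence (GLCM) texture features (TFs) of
single bands correlate only weakly with LAI on their own. `texlai` implements
the fusion strategy used in UAV phenotyping of winter oilseed rape at the
bolting stage: combine several texture features into algebraic *texture
indices*, find the best feature tuple for each index family by exhaustive
correlation search, and feed screened VIs, TFs and texture indices jointly
into machine-learning regressors.

## The method

1. **Texture features.** Per band, a normalized co-occurrence matrix
   P(i, j) of gray-level pairs at offset (1, 1) is built in each 7×7 sliding
   window (32 levels, symmetric), yielding the eight Haralick-style
   statistics MEA, VAR, HOM, CON, DIS, ENT, SEM, COR; a plot's feature is the
   window mean. Six bands × 8 features = 48 labeled features (MEA1 … COR6).
2. **Texture indices.** Eleven families combine features T_i, T_j (and T_k):
   two-term RTI = T_i/T_j, DTI = T_i−T_j, ATI = T_i+T_j,
   NDTI = (T_i−T_j)/(T_i+T_j), RDTI = 1/T_i−1/T_j, RATI = 1/T_i+1/T_j and
   their three-term analogues RTTI, DTTI, NDTTI = (T_i−T_j−T_k)/(T_i+T_j+T_k),
   RDTTI, RATTI. Each family is evaluated at **every** ordered tuple of the
   48 features (48² pairs, 48³ triples) and the tuple maximizing |Pearson r|
   with LAI is kept.
3. **Screening and estimation.** Variables with p < 0.05 enter the model
   pool; the 15 non-empty subsets of the blocks {VIs, TFs, TIs, TTIs} ×
   {SVM (poly kernel, C = 20, γ = 0.02), PLSR (latent variables by a 5 %
   explained-variance gain rule), XGBoost (100 trees, η = 0.03, depth 5)}
   form a 45-cell grid scored by validation R², RMSE and MRE on a random
   2/3 : 1/3 split. The best cell renders per-pixel LAI inversion maps.

No field dataset is distributed, so a first-class synthetic generator
(`texlai.synth`) emulates the underlying split-plot experiment — 3 mulching
treatments × 5 nitrogen rates × 3 replicates × 2 seasons = 90 plots — with a
treatment-driven latent LAI and a Beer–Lambert-style radiative model whose
spectral means and spatial texture both carry the LAI signal (see
`docs/methods.md`).

## Worked example

```bash
python examples/03_index_search.py
```

generates a 45-plot season, screens the VIs and runs the exhaustive search:

```
vegetation indices passing the p < 0.05 screen: 10/10

best tuple per index family (|r| with LAI):
family  abs_r      combination
   RTI  0.934       MEA5, CON5
  NDTI  0.948       CON5, MEA5
  ...
  RTTI  0.968 MEA5, SEM5, VAR5
 NDTTI  0.953 MEA5, CON5, DIS6

best two-term |r| = 0.948, best three-term |r| = 0.968
```

Every row is one index family: `abs_r` is the highest |Pearson correlation|
with true LAI over all ordered feature tuples, and `combination` names the
winning tuple (e.g. MEA5 = mean of band 5, the 750 nm red edge). Three-term
families search a strictly larger space and usually edge out their two-term
analogues. `examples/04_lai_model_grid.py` continues to the 45-cell grid and
prints validation R²/RMSE/MRE per input combination, e.g. XGBoost improving
from R² 0.861 (VIs alone) to 0.911 with VIs + TFs + TTIs.

The same stages are available from the shell:

```bash
texlai all --seed 42 --outdir run1        # or: simulate/extract/search/model
```

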