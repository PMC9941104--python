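# valveshape

Phylogenetic geometric morphometrics of paired ostracod valves.

Ostracod shells are bivalved: every individual carries a left and a right
valve, and in many lineages (Candonidae in particular) the two sides differ
consistently in both shape and size. `valveshape` implements the complete
landmark-based workflow for studying how such shells evolve across a
molecular phylogeny:

* **Ingestion** — TPS landmark files (48 two-dimensional landmarks per
  valve, with SEM scale factors), a specimen classifier CSV, Newick trees,
  aligned FASTA.
* **Superimposition** — explicit mirroring of one valve side into the
  other's orientation (*matching symmetry*), generalized Procrustes
  analysis (GPA), tangent-space projection, and outline resampling into
  2 anchors + 28 dorsal + 18 ventral equidistant pseudo-landmarks.
* **Asymmetry ANOVA** — a sequential mixed-design Procrustes ANOVA with
  effects species → sex → individual → side (directional asymmetry, DA) →
  individual × side (fluctuating asymmetry, FA), Goodall's F with the
  mixed-model error strata, and Pillai's trace.
* **Allometry** — multivariate regression of shape on log centroid size at
  three levels (total, pooled within species, evolutionary = on
  phylogenetically independent contrasts), permutation tests, and size
  correction.
* **Comparative analysis** — independent contrasts, squared-change
  parsimony ancestral shapes, a permutation test of phylogenetic signal,
  phylomorphospace plots, PCA with wireframe visualisation of shape
  extremes.
* **Molecular utilities** — simple indel coding of alignment gaps,
  supermatrix concatenation, within/between-clade p-distances.
* **Synthetic data** — a generator that reproduces the statistical
  structure of such a study (Yule tree, Brownian shape and log-size
  evolution, allometric, directional-asymmetry and sexual-dimorphism
  vectors, individual and fluctuating noise, arbitrary digitization
  transforms), so the whole pipeline can be exercised end to end.

## The statistics in brief

For k 2-D landmarks, centroid size is CS = √Σᵢ‖xᵢ − x̄‖², and GPA places
all configurations in a common frame (centred, unit CS, optimal proper
rotations against the consensus). Shape statistics operate in the tangent
space at the consensus, of dimension 2k − 4 (= 92 for k = 48); every shape
degree of freedom is its univariate df × (2k − 4). Goodall's F for effect A
tested over stratum B is

    F = (SS_A / df_A) / (SS_B / df_B),

with species and sex tested over the individual stratum, and individual and
side over the individual × side (FA) stratum. Evolutionary allometry
regresses independent contrasts of shape on contrasts of log CS through the
origin; squared-change parsimony minimises Σ (Δx)²/branch-length over
ancestral states (equal to the Brownian GLS reconstruction), and its
minimum — the "tree length" — is the phylogenetic-signal statistic, tested
by permuting species values across the tips.

## Worked example

Simulate a study-scale dataset (46 species, 202 individuals, 386 valves,
48 landmarks), superimpose, and run the analysis chain:

```python
import pandas as pd
import valveshape as vs

params = vs.SimulationParams.study_scale()
sim = vs.simulate_dataset(params=params, seed=1)
ds = sim.dataset()

configs = [vs.reflect_side(c, "left") for c in ds.configurations]
aligned = vs.tangent_project(vs.gpa(configs))
print(vs.ProcrustesANOVA(aligned, ds.metadata_frame()).fit("shape").summary())
```

```
Procrustes ANOVA (shape), n = 368 valves, k = 48 landmarks
Effect                                  SS                MS      df         F         p      PT     p(PT)
species                         1.19817752      0.0002894149    4140     29.24  < 0.0001   24.29  < 0.0001
sex                             0.00479787      0.0000521507      92      5.27  < 0.0001    0.92  < 0.0001
individual                      0.12476085      0.0000098985   12604      1.27  < 0.0001   43.41  < 0.0001
directional_asymmetry           0.04169264      0.0004531808      92     58.29  < 0.0001    0.98  < 0.0001
fluctuating_asymmetry           0.13089719      0.0000077748   16836
```

The 18 one-valved individuals are dropped from the asymmetry design
(368 = 386 − 18 valves analysed); directional asymmetry is ~58× the FA
mean square, so the two sides genuinely differ in shape. Species averages,
allometry, size-corrected PCA and phylogenetic signal follow:

```python
meta = ds.metadata_frame()
right = (meta["side"] == "right").to_numpy()
species, mshapes, mlogcs = vs.species_averages(
    aligned.shapes[right], aligned.centroid_sizes[right],
    meta.loc[right, "species"].to_numpy())

fit = vs.ShapeAllometry(mshapes, mlogcs, mode="total").fit(n_perm=9999, seed=1)
print(fit.summary())

model = vs.pca(vs.size_correct(mshapes, fit))
scores = pd.DataFrame(model.scores[:, :2], index=species)
tree = sim.tree.prune_to(species)
tl, p = vs.phylo_signal_permutation(tree, scores, n_perm=9999, seed=1)
print(f"phylogenetic signal: tree length = {tl:.4f}, permutation p = {p:.4f}")
```

```
Shape-on-log(CS) regression (total)
  n = 46, p = 96 coordinates
  predicted variation: 28.45%
  permutation p (9999 rounds): 0.0001
phylogenetic signal: tree length = 0.1594, permutation p = 0.0001
```

Size predicts 28% of among-species shape variation in this realisation, and
closely related species have significantly more similar (size-corrected)
shapes than a random relabelling — a clear phylogenetic signal. The PCA of
the corrected averages puts ~93% of variance on the first three components,
reflecting the generator's three integrated directions of shape evolution.

The same pipeline is scriptable from the shell:

```bash
valveshape --seed 7 --out-dir fixtures simulate
valveshape --out-dir out gpa --tps fixtures/valves.tps --classifier fixtures/classifier.csv
valveshape --out-dir out anova --tps fixtures/valves.tps --classifier fixtures/classifier.csv
valveshape --out-dir out seqdist --fasta 18S.fasta --groups clades.csv
```

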