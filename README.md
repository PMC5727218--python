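# nichepop

Macroecology meets population genetics for presence-only survey data — the
kind of analysis used to characterize crop wild relatives such as wild pea
(*Pisum fulvum* and *P. sativum* subsp. *elatius*) across the Mediterranean
Basin and the Fertile Crescent. The package bundles, as one tested library
with a CLI:

* **Maximum-entropy niche models** (`nichepop.enm`). For a taxon with
  presence localities and a stack of bioclimatic rasters (BIO1–BIO19), the
  suitability of a cell *x* is the Gibbs distribution
  `q(x) ∝ exp(w·f(x))` over a background sample, where f(x) are
  standardized linear and quadratic layer terms and w maximizes the
  L1-penalized presence log-likelihood (a convex problem solved to KKT
  tolerance 1e-6). Includes occurrence cleaning (duplicate collapse,
  coordinate validation, a 50-km distance-to-reference rule), rank-based
  AUC, permutation importance, and projection onto alternative climate
  stacks (e.g. Last Glacial Maximum or an RCP future scenario).
* **Niche-overlap testing** (`nichepop.overlap`). Schoener's
  `D = 1 − ½Σ|qA−qB|` and Hellinger-based `I = 1 − ½Σ(√qA−√qB)²`, plus the
  background-randomization similarity test: one taxon's occurrences are
  repeatedly replaced by draws from its Gaussian-smoothed background, the
  model refitted, and the observed overlap compared with the null
  distribution (two-sided verdict: similar / divergent / ns).
* **Per-cell Shannon diversity** (`nichepop.diversity`).
  `H′ = −Σ p_i ln p_i` across taxa's suitability surfaces, cell by cell,
  with scenario-difference summaries (where would diversity be
  impoverished under a different climate?).
* **SNP population genetics** (`nichepop.popgen`). Locus QC (missingness
  then MAF), per-individual heterozygosity, species-diagnostic SNPs by
  Fisher exact test at a genome-wide threshold, Ritland kinship with
  equal-pair-count distance classes and a permutation envelope, pairwise
  Weir & Cockerham Fst (θ, ratio of sums), and spatial distance-to-centroid
  summaries.
* **Haplotype networks** (`nichepop.haplotypes`). Indel-aware character
  coding (a multi-base gap run is one mutational step), haplotype
  collapsing with missing-matches-anything, and a minimum-spanning network
  (all edges occurring in any minimum spanning tree).
* **Synthetic data with ground truth** (`nichepop.synthetic_data`).
  Autocorrelated environmental layers, occurrences from a known parametric
  niche, Balding–Nichols island-model genotypes at a target Fst with
  optional isolation by distance and planted F1 hybrids, and alignments
  with planted SNPs and one multi-base indel — so every stage can be
  tested for parameter recovery without external data.

## Worked example

```python
import numpy as np
from nichepop.synthetic_data import SimConfig, gen_env_layers, gen_occurrences, gen_genotypes
from nichepop.enm import fit_maxent, project_model, auc, permutation_importance
from nichepop.overlap import schoener_D, hellinger_I
from nichepop.popgen import pairwise_fst, filter_snps

cfg = SimConfig(seed=42, grid_rows=40, grid_cols=40, n_layers=3)
env, scenario = gen_env_layers(cfg)
occ_a, _ = gen_occurrences(env, np.array([2.0, -1.0, 0.0]), 200, seed=1, taxon="taxonA")
occ_b, _ = gen_occurrences(env, np.array([-1.0, 2.0, 0.0]), 200, seed=2, taxon="taxonB")

model_a = fit_maxent(env, occ_a, background_size=1600, seed=3)
model_b = fit_maxent(env, occ_b, background_size=1600, seed=4)
map_a, map_b = project_model(model_a, env), project_model(model_b, env)

print("taxonA AUC:", round(auc(model_a, env, occ_a), 3))
imp = permutation_importance(model_a, env, occ_a, n_reps=10, seed=5)
print("taxonA importance:", {k: round(float(v), 1) for k, v in imp.items()})
print("D =", round(schoener_D(map_a, map_b), 3), " I =", round(hellinger_I(map_a, map_b), 3))

gm, _ = gen_genotypes(SimConfig(seed=42, n_populations=2, n_individuals=50,
                                n_loci=1000, target_fst=0.2, missing_fraction=0.05))
filtered, report = filter_snps(gm)
print("SNPs retained:", report["n_retained"], "of", report["n_input"])
print("pairwise Fst:", round(pairwise_fst(filtered).theta[0, 1], 3))
```

prints

```
taxonA AUC: 0.692
taxonA importance: {'BIO1': 80.0, 'BIO2': 20.0, 'BIO3': 0.0}
D = 0.584  I = 0.864
SNPs retained: 912 of 1000
pairwise Fst: 0.204
```

Reading the output: taxon A was simulated with a strong positive response to
BIO1 and a weaker negative one to BIO2, and the fitted model's AUC and
permutation importances reflect exactly that (BIO3, simulated with zero
effect, gets ~0% importance). The two taxa were given opposing niches, so
their suitability surfaces overlap only partially (D ≈ 0.58). The genotypes
were simulated under a Balding–Nichols island model with Fst = 0.2, and the
Weir–Cockerham estimate on the QC-filtered SNP panel recovers 0.204.

The same analysis runs from the shell:

```bash
nichepop simulate --config sim.yaml --out data/
nichepop enm fit --env-dir data/env_current --occurrences data/occurrences.csv \
    --taxon taxonA --out taxonA.model.json
nichepop pipeline run --config pipeline.yaml   # the whole thing, one manifest
```

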