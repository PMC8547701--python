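# te-ecology

Family-level "genomic ecology" of transposable elements (TEs), modeled on the
maize genome: most of a large plant genome is TE-derived, and different TE
families persist by exploiting different genomic niches — some hide in
heterochromatin, some tolerate methylation, some stay close to genes.  This
package treats the **age of each extant TE copy as a measure of its survival**
and asks which attributes of the copy and of its genomic neighborhood predict
that survival.

It is aimed at researchers analysing structural TE annotations who want a
tested, reusable implementation of the full chain from raw annotation layers
to an interpretable survival model, exercised end-to-end on a synthetic toy
genome with known ground truth.

## What it computes

1. **Nesting resolution** — TEs insert into each other; every annotated base
   is assigned to exactly one copy, the latest-arriving copy covering it
   (painting copies in arrival order).  Copies retaining < 50 bp are dropped
   from downstream analyses.
2. **Insertion ages** — two estimators:
   - *LTR–LTR*: the two long terminal repeats of an LTR retrotransposon are
     identical at insertion; their Kimura two-parameter divergence
     `d = -½·ln((1−2P−Q)·√(1−2Q))` converts to time as `T = d/(2μ)`;
   - *terminal branch length*: the leaf branch `b` (substitutions/site) of a
     copy in its superfamily tree gives `T = b/μ`;
   with the maize rate `μ = 3.3×10⁻⁸` substitutions·site⁻¹·year⁻¹.
3. **Genomic-environment features** — per copy: GC and methylatable-context
   densities (CG/CHG/CHH, both strands) and TG/CA proportion for the TE and
   its 1 kb flanks; distance to the closest (and closest syntenic) gene;
   recombination rate (cM/Mb) from a monotonic-polynomial genetic-map fit;
   MNase hypersensitivity counts/proportions; segregating-site density;
   subgenome assignment; 41-slot methylation profiles (TE body ± 20 × 100 bp
   flank windows per side, per context and tissue) with family-mean
   imputation; TE-family expression as per-copy RPM with median and the
   tissue-specificity index `τ = Σᵢ(1 − xᵢ/x_max)/(n−1)`.
4. **Survival model** — a 1000-tree random-forest regression of copy age on
   all features (missing coded −1, family capped at the 31 largest +
   "smaller"), trained on 50% of copies, with held-out permutation importance
   (ΔMSE scaled by its sd, and the RMSE increase in kya), importance
   aggregated into nine feature categories, per-family Pearson correlations
   of each feature with age, and ICE curves over the central 95% of each
   feature's observed values.

The synthetic-data module (`te_ecology.simulate`) generates a
multi-chromosome toy genome covering all 13 plant TE superfamilies with
nested insertions of known arrival order, sequences diverged under known
`μ·T` (ts:tv 2:1, so K2P is the matched estimator), and every data layer the
pipeline consumes — so all estimators can be validated by recovery.

## Worked example

```python
from te_ecology import SimConfig, generate_dataset, resolve_nesting, TEAgeModel
from te_ecology.simulate import generate_age_features

ds = generate_dataset(SimConfig(seed=1))
r = resolve_nesting(ds.te_copies)
print(len(ds.te_copies), sum(r.disrupted.values()))   # 101 copies, 16 disrupted

feat, ages, meta = generate_age_features(n=5000, seed=1)
res = TEAgeModel(feat, ages).fit(seed=1, n_trees=300)
print(res.summary())
imp, cat = res.permutation_importance(n_repeats=5)
print(imp.head(3)[["feature", "delta_rmse_kya"]])
```

prints

```
TE age random-forest model
==========================
copies (train/test):    2500/2500
features:               51
trees:                  300
seed:                   1
test MSE:               1.99176e+10 yr^2
test RMSE:              141.130 kya
variance explained:     0.9189
      feature  delta_rmse_kya
0  meth_cg_te      412.599201
1   length_bp      199.911697
2  family_rpm       71.238192
```

The forest explains 92% of held-out age variance on this harness, and the
three features that truly generate age (CG methylation: linear; length:
quadratic; family expression: threshold) dominate the permutation importance
— shuffling the methylation feature alone raises the held-out RMSE by
~410 kya, while the 47 decoy features sit near zero.

A shell workflow is available too:

```sh
te-ecology simulate --seed 1 --outdir simdata
te-ecology run --input-dir simdata --outdir run1 --seed 1
```

which writes `resolved_copies.tsv`, `ages.tsv`, `feature_table.tsv`,
`family_summary.tsv`, `importance.tsv` and `model_report.json` into `run1/`.

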