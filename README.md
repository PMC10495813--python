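# phylofee

Phylogenetic prediction of strain phenotypes, and functional-effect-equation
(FEE) prediction of microbial community function — with a fully synthetic
data generator standing in for the wet lab.

## The scientific problem

Designing a microbial consortium (for example, a yeast starter culture that
ferments grape must to dryness) runs into two combinatorial walls:

1. **Strains.** A collection of 60 strains phenotyped for 43 traits is still
   a sparse sample of the diversity one might deploy. Can a newcomer
   strain's phenotype be predicted from its position in a marker-gene
   phylogeny alone?
2. **Communities.** Even 12 strains span 2^12 − 1 = 4,095 possible
   consortia, and 60 strains span more than 10^18. Can the *function* of an
   unmeasured consortium be predicted from a small, structured set of
   measured ones?

This package implements both predictive layers and the statistical
machinery to evaluate them:

* **Phylogenetic signal** — Pagel's λ per trait by maximum likelihood, with
  a label-permutation significance test, plus a Mantel-style correlation
  between cophenetic and phenotypic distance matrices.
* **Phylogenetic imputation** — missing tip traits predicted as the
  conditional expectation of a Brownian-motion (BM) trait model on the tree
  (equivalently, reroot-and-reconstruct ancestral state estimation), with
  leave-one-out validation at four taxonomic exclusion radii (strain,
  marker group, species, genus).
* **FEEs** — per-strain linear models ΔF_i(B) = a_i + b_i·F(B) + θ_i(B)
  relating the functional effect of adding strain *i* to the function F of
  the background community B. Concatenating FEEs over the subset lattice
  between a measured anchor community and an unmeasured target, and solving
  the single-addition edge equations by weighted least squares, predicts the
  target's function. An additive baseline (monoculture + pairwise effects)
  provides the contrast.
* **Synthetic data** — Yule trees, MVN trait tables with per-trait λ, and a
  ground-truth community-function landscape built from a
  permutation-symmetric FEE recursion, all deterministic given a seed.

## Worked example

```python
import phylofee as pf

# a phenotyped strain collection (60 strains x 43 traits, known truth)
tree, traits, meta, truth = pf.simulate_collection(seed=1)

# is phenotype phylogenetically structured?
d_phy = pf.cophenetic_matrix(tree)
d_phe = pf.trait_distance_matrix(pf.scale_traits(traits))
pf.distance_correlation(d_phy, d_phe, n_perm=999, seed=0)["r"]
# 0.638 over 1,770 strain pairs (Mantel p ~ 0.001)

# per-trait Pagel's lambda + permutation test
sig = pf.signal_table(traits, tree, n_perm=199, seed=0)

# leave-one-out imputation, excluding progressively more relatives
for level in ("strain", "marker", "species", "genus"):
    r = pf.loocv_impute(tree, traits, meta, exclusion_level=level)
    print(level, round(r.per_trait_r.mean(), 3))
# strain 0.382  marker 0.354  species 0.252  genus 0.132

# a 606-assay consortium experiment over 12 strains, then predict the
# function of communities never measured
ds, truth = pf.simulate_community_experiment(tau=0.01, eps=0.01, seed=4)
fees = pf.fit_all_fees(ds)
pred = pf.predict_function(("ns01", "ns03", "ns05", "sc01"), ds, fees)
pred.F_pred  # in [0, 1]; compare truth.true_F(...)
```

On 120 held-out communities the lattice FEE model reaches Pearson r ≈ 0.99
with RMSE ≈ 0.03, while the additive baseline's RMSE grows from ≈ 0.13 at
richness 3 to ≈ 0.32 at richness 7 — background-dependent (non-additive)
effects dominate as communities grow, and the FEE captures them.

## Command line

```bash
phylofee simulate collection --n-strains 60 --n-traits 43 --seed 1 --out-dir coll/
phylofee signal --tree coll/tree.nwk --traits coll/traits.tsv --n-perm 999 --seed 0 --out signal.tsv
phylofee impute --tree coll/tree.nwk --traits coll/traits.tsv \
    --metadata coll/metadata.tsv --loocv species --out-prefix imp
phylofee simulate communities --seed 4 --out-dir comm/
phylofee fee fit --measurements comm/measurements.csv --out fees.json
phylofee fee predict --fees fees.json --measurements comm/measurements.csv \
    --targets targets.csv --out pred.csv
phylofee design-counts
```

Exit codes: 0 success, 2 input error, 3 model/degenerate-data error. Every
run logs its configuration to stderr; identical inputs and seeds give
byte-identical outputs.

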