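# layerquant

Quantitative pipeline for 3-D tissue-imaging prognosis studies: per-layer
relative marker intensity from multi-channel confocal z-stacks, an exact
paired cluster permutation test comparing two subjects' layer profiles, a
Youden-index survival cutpoint scan, paired tumor/normal score comparison,
and a concordant differential-expression filter — with synthetic-data
generators that plant known ground truth for every stage.

The motivating application is the spatial distribution of a secreted
epithelial marker (elafin/PI3) in esophageal squamous cell carcinoma, where
web-like stromal infiltration versus confinement to tumor nests separates
poor from favorable prognosis. The package is data-agnostic: any
marker/membrane/nuclei stack, per-layer profile, survival table, or
fold-change table in the documented formats works.

## The statistics at the core

**Relative intensity.** For layer *z*,
`r_z = #marker pixels / #membrane pixels` after background subtraction and
2-D median filtering. Layers with `r > 0.01` form the selected tissue run;
thickness = layers × 0.7 µm.

**Exact paired permutation test.** Each subject's layers are grouped into
K = 20 contiguous clusters and dichotomized at 0.05; cluster score = the
proportion of supra-cutoff layers. For paired differences *d*, all 2^K sign
reallocations are enumerated (integer arithmetic, exact ties) and the
observed mean difference is ranked among them:

    p = 1 − (rank_smallest + tie_count/2) / 2^K   (midpoint of tied ranks)

**Cutpoint scan.** Candidate expression cutoffs (midpoints of sorted unique
values) are scored by Youden's `J = sensitivity + specificity − 1` against
vital status; the max-J cutoff is selected and a Cox model adjusted for age,
sex, smoking and alcohol gives the group log hazard ratio; Kaplan–Meier and
log-rank compare the groups.

**Concordance filter.** Genes with log2FC > 1 under marker overexpression
and < −1 under knockdown.

## Worked example

```python
from layerquant import (exact_paired_permutation, make_layer_profiles,
                        make_paired_series)

a, b = make_layer_profiles(200, frac_above=(0.55, 0.40), cutoff=0.05, seed=7)
series = make_paired_series(a, b, K=20, cutoff=0.05)
res = exact_paired_permutation(series)
```

Running `python examples/permutation_test.py` prints:

```
observed mean cluster-score difference: 0.120
smallest tied rank: 1,039,393 of 1,048,576 reallocations
tie block size:     5,312
upper-tail p:       0.00622463   two-sided: 0.0124493
Monte-Carlo check:  p = 0.00641494 +/- 0.00025 (100k draws)
```

Subject A's clusters score on average 0.120 higher than subject B's; only a
~0.6% upper tail of the 2^20 reallocations reaches the observed difference
(midpoint-tie convention), so the two layer profiles differ significantly.
The other examples cover stack quantification (`examples/quantify_stack.py`),
the survival cutpoint scan (`examples/survival_cutpoint.py` — recovers a
planted cutoff of 25 with an adjusted log-HR of 1.818 ± 0.136 against a
planted log 6 = 1.792), and score/fold-change comparison
(`examples/expression_comparison.py`).

A thin CLI mirrors the stages:

```sh
layerquant simulate profiles --out-a a.csv --out-b b.csv --frac-above-a 0.8 --frac-above-b 0.3
layerquant permtest --a a.csv --b b.csv --clusters 20 --dichotomize 0.05
layerquant run --seed 1 --out runs/demo        # full seeded pipeline + report
```

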