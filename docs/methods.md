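# Methods

`layerquant` implements the quantitative core of a 3-D tissue-imaging
prognosis workflow for a secreted epithelial marker (elafin/PI3 is the
motivating case) in esophageal squamous cell carcinoma: per-layer relative
marker intensity from confocal z-stacks, an exact paired cluster permutation
test comparing two subjects' layer profiles, a Youden-index cutpoint scan for
dichotomizing expression against survival, paired tumor/normal score
comparison, and a concordant differential-expression filter. Every stage is
exercised on synthetic data with known ground truth.

## Stack quantification

A stack is a `(3, n_layers, height, width)` array in the fixed channel order
marker / membrane / nuclei. Defaults encode the acquisition geometry: 0.7 µm
axial step and 317.95/512 µm lateral pixel size, so a run of *n* selected
layers corresponds to *n* × 0.7 µm of tissue.

Per layer and channel the pipeline applies:

1. **Background subtraction** — per-layer percentile (default 20th) or a
   constant. The exact background estimator of interactive imaging software
   is not reproducible; a percentile is deterministic and testable. For
   noise-free synthetic stacks it should be disabled (`background=None`),
   since subtracting the 20th percentile of a constant membrane channel
   annihilates it.
2. **2-D median filtering** (default 3×3, per layer, never 3-D; reflective
   boundaries; window 1 = identity).
3. **Pixel counting** — pixels strictly above a per-channel threshold
   (default 0 after preprocessing).
4. **Relative intensity** — `r_z = marker_count_z / membrane_count_z`.
   Layers with zero membrane pixels are flagged *undefined* (NaN) and
   excluded from selection and clustering; they are never silently treated
   as zero.

**Layer selection** returns the longest contiguous run of layers with
`r > 0.01` (earliest run on ties), because selected ranges are reported as
single contiguous spans ("13th–60th"); an `all` mode counts every
supra-cutoff layer instead. Indexing is 1-based inclusive and thickness is
`count × z_step`: 48 layers ⇒ 33.6 µm. One published table row
("1st–64th (45.5 µm)") is inconsistent with this arithmetic (64 × 0.7 =
44.8); it is a source-data inconsistency and is not emulated.

**Sum z-projection** accumulates in int64, so total intensity is conserved
exactly for integer stacks.

## Exact paired cluster permutation test

The defined layers of each subject are partitioned in z-order into K = 20
contiguous clusters with sizes as equal as possible (the first `N mod K`
clusters get the extra layer). Each layer is dichotomized at 0.05
(`r ≥ 0.05 → 1`), and a cluster's score is its *proportion* of supra-cutoff
layers — the only score definition under which published fractional mean
differences (e.g. 0.160 with K = 20) are attainable, since 0/1 cluster
scores would quantize the mean difference to multiples of 1/20.

With paired differences `d_i = a_i − b_i`, all `2^K` sign vectors
`s ∈ {±1}^K` are enumerated and `T_s = mean(s_i d_i)` computed. Exchanging
the two subjects within a cluster is exactly a sign flip, so under the null
hypothesis of no subject difference all reallocations are equally likely.
The observed value (`s = +1`) is ranked among all statistics sorted
ascending, and the upper-tail p-value uses the midpoint of tied ranks:

    p = 1 − (rank_smallest + tie_count/2) / 2^K

**Exact ties.** Every `d_i` is multiplied by the lcm of all cluster sizes,
turning the statistics into integers; ranks and tie counts never depend on
floating-point equality. `tie_count` is consequently always divisible by
`2^(#{i : d_i = 0})`.

**Numerical corner.** When the observed statistic strictly exceeds every
other reallocation (`rank = 2^K`, `tie = 1`) the midpoint formula yields
`−1/2^(K+1)`; `midpoint_tie_pvalue` returns the exact rational and the
result object floors the reported probability at 0. Two identities follow
from the formula and are tested exactly: identical subjects give
`p = 1/2 − 2^−K`, and the raw midpoint values of a series and its swap sum
to `1 − 2^−(K−1)`.

The printed formula is one-sided (upper tail); because the surrounding
analysis declares two-sided testing, a two-sided value (double the smaller
tail, capped at 1) is reported alongside without guessing intent.

Enumeration is capped at K = 24 (2^24 int64 sums ≈ 134 MB); beyond that
`monte_carlo_permutation` pools uniform random sign vectors with the observed
one and applies the same midpoint convention, reporting a binomial standard
error. Under exchangeable nulls the midpoint p is approximately uniform and
slightly liberal on lattice-valued statistics; the measured rate of
`p ≤ 0.05` over 2000 null series (K = 20, 200 layers) is ~0.053.

## Survival cutpoint scan

Candidates are midpoints between neighbouring sorted unique expression
values; cutoffs leaving either group below 10% of the cohort are
inadmissible. For each admissible cutoff, Youden's
`J = sensitivity + specificity − 1` is computed with the high/low split as
classifier and **vital status at last follow-up** as the binary outcome —
the most literal reading of maximizing J "from" a Cox fit on dichotomized
expression; a censoring-aware variant (death by a fixed horizon, subjects
censored earlier excluded) is available via `horizon`. The maximum-J cutoff
is selected (ties → smaller cutoff) and a Cox proportional-hazards model
(lifelines, Efron ties, Wald inference) adjusted for age, sex, smoking and
alcohol is fitted there; `fit_all=True` fits every admissible cutoff and
excludes non-converging rows from selection (the default fits only at the
optimum — selection depends only on J, and n fits per scan would be
quadratic work without influencing it).

The selected cutoff's naive p-value is anti-conservative under the null —
an unavoidable property of maximizing over cutoffs. The test suite measures
this instead of hiding it: with 7 candidate cutoffs the null rate of
`p ≤ 0.05` at the selected optimum is ~0.08.

Kaplan–Meier curves and the two-sample log-rank test (lifelines) compare the
resulting groups; with no censoring the KM estimate equals the empirical
survival function, which the suite checks, along with a hand-computed
log-rank chi-square on a small risk table.

## Expression comparison

Paired tumor/normal ordinal scores (0–3, stored as recorded; collapsing the
0–1 bin is a reporting option, not a data mutation) are summarized by the
mean ± SD (n−1) of tumor − normal differences with two-sided paired-t and
Wilcoxon signed-rank p-values; rows missing either side are excluded and
counted per side. A zero-variance difference vector supports neither test:
all-zero differences report p = 1, a constant nonzero shift p = 0, both with
an explicit flag. Group summaries report both Student's t and rank-sum
p-values, since either may be the one quoted in practice.

The concordance filter intersects two fold-change tables on genes with
log2FC strictly > 1 in the overexpression contrast and strictly < −1 in the
knockdown contrast (`strict=False` for inclusive bounds).

## Synthetic data: what it emulates and what it does not

**Stacks** (default 60 layers × 64 × 64; scaled down from the ~200-layer
512×512 acquisitions to keep full enumeration-based suites fast). Tumor
nests are random spheres (radius ~12 voxels ± 20%, 4 per stack, ≈10–15% of
the volume); stroma is the complement. The membrane channel covers the whole
field (tissue fills the view), nuclei are small scattered blobs.
`nest-confined` marks a Bernoulli subset of nest voxels at `marker_density`;
`stromal-web` grows random 3-D polyline filaments dilated to ~1 voxel,
restricted to stroma, until the stromal marker fraction reaches the density.
With *equal* densities the web pattern yields several-fold higher per-layer
relative intensity simply because the stroma is the larger compartment
(r ≈ 0.09 vs ≈ 0.01 at density 0.1) — reproducing the observed dichotomy of
stroma-infiltrating vs nest-confined expression and making the planted
difference detectable by the permutation test. Ground truth is the realized
mask, so noise-free quantification must match it exactly. Noise is additive
Gaussian clamped at zero and quantized to 16 bits; there is no
point-spread-function, attenuation-with-depth, or stitching artefact
modelling, so passing tests say nothing about those real-data effects.

**Layer profiles**: each layer independently exceeds the cutoff with
probability `frac_above` (above: `cutoff·(1+Exp(1))`, below: uniform on
`[0, cutoff)`). Layers are independent; real profiles are axially
autocorrelated, which the test does not model (the permutation test's
exchangeability assumption concerns subjects within clusters, not layers).

**Survival cohorts**: exponential baseline (0.05 /month — median ≈ 14 months
in the low group, matching a locoregional-disease cohort scale), hazard
multiplied by `hazard_ratio` above the planted cutoff, covariates age
~ N(58, 8), sex ~ Bernoulli(0.8) (majority-male cohort), smoking/alcohol
~ Bernoulli(0.5), with modest default log-hazards (0.02/yr, 0.3, 0.3, 0.2).
Censoring is an independent exponential whose rate is bisected so the
expected censored fraction equals `censor_rate`. Expression is drawn from a
**discrete grid** of 8 levels at ±1, ±3, ±5, ±7 around the cutoff. This is a
deliberate identifiability choice: a cutpoint is only estimable up to the
inter-subject gap containing it, and with continuous expression the max-J
argmax lands in the exact containing gap with probability ≈ 0.5 regardless
of n (the local behaviour of J is a random walk whose first step crosses a
single subject). With ~50 subjects per level, crossing one grid gap moves J
by a 50-subject aggregate with clearly negative drift, so the planted gap is
recovered reliably. Real expression is continuous; on real data the
recovered quantity is the gap, not a point.

**DE tables**: the concordant set gets `±(threshold + Exp(1))` fold changes;
every other gene has one side forced strictly inside `[−threshold,
threshold]`, making the planted count exact by construction.

## Reproducibility

All generators take explicit integer seeds; the pipeline derives named
per-stage substreams from one root seed via `SeedSequence.spawn`, so every
output file is byte-reproducible from (config, seed) — the run report
records parameters, which printed-constant defaults (0.7 µm, 0.01, 0.05,
K=20, log2FC 1) were overridden, and SHA-256 hashes of all outputs.

## Known limitations

- No 3-D surface/spot rendering, stitching, deconvolution or PSF modelling.
- The permutation test assumes within-cluster exchangeability between
  subjects; spatial autocorrelation between layers is not modelled.
- The Youden outcome ignores follow-up length by default (vital status at
  last follow-up); use `horizon` for the censoring-aware variant.
- Published cohort-specific values (e.g. a cutoff of 25 with J = 0.086 on an
  external registry cohort) depend on external data and are used here only
  as planted parameters for recovery tests.
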