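# Methods

## Experimental design modeled

One TMT 11-plex covering three arms of an EGF (10 nM) stimulation time
course in an EGFR-amplified cell background: a DMSO control arm and an
SHP099 (allosteric SHP2 inhibitor) arm sampled at 0, 5, 10, and 30 min
after EGF addition, and a washout arm in which the inhibitor is removed
10 min after stimulation and sampled 5, 10, and 30 min later. Washout
channels are indexed by minutes *post-washout*; they are compared
positionally with the SHP099 arm (5↔5, 10↔10, 30↔30). The absolute
post-EGF clock of the washout arm is therefore shifted by the 10 min of
stimulation preceding washout — deliberate, because the comparison asks
how a site evolves once inhibition is released, on the released arm's
own clock. The washout arm has no time-0 channel by construction.

Two biological replicates with partial site overlap are assumed. All
abundances are *relative*: each site-replicate vector is rescaled to
mean 1 across the 11 channels. Every downstream statistic is a ratio of
channels within one site, so the convention cancels and all results are
invariant to per-site multiplicative rescaling.

## Quantification filters

PSMs are kept when total reporter S/N > 200 (strict), isolation
specificity ≥ 0.5 (inclusive — "at 0.5" read as attainment), AScore > 13
(strict), and the site residue is whitelisted (default pY only).
Rejections are attributed to the *first* failing rule in the fixed order
S/N → specificity → AScore → residue, so reports are deterministic.
Multiple PSMs covering one (protein, position, replicate) are summed
before rescaling — reporter S/N is additive in the MS3 workflow; the
aggregation rule itself is this package's choice. A site whose summed
vector contains a zero channel is dropped (complete-case) with a logged
warning.

## Replicate merging

The merged table is the union of the replicates' site sets; sites found
in both get the channelwise arithmetic mean of their two mean-1 vectors
("averaging measurements" read literally — not a geometric mean), sites
found in one are carried unchanged, and provenance records contributors.
Merging is commutative in replicate order. Averaging operates on the
mean-1 relative vectors, not raw S/N.

## Dependence classification

Fold threshold θ = 1.5, applied symmetrically and inclusively on the
ratio scale (increase: ratio ≥ θ; decrease: ratio ≤ 1/θ). The same θ is
used for the SHP2 axis and exposed as a parameter.

* **EGF axis** (control arm only): fast/medium/slow increase assigned by
  the earliest of 5/10/30 min where `DMSO(t)/DMSO(0) ≥ θ`; otherwise
  decrease if any timepoint falls below 1/θ; otherwise neutral. When a
  time course crosses both bounds, the increase wins (the rule order
  evaluates increases first); such conflicts are counted and logged.
* **SHP2 axis**: pre-stimulation negative if `SHP099(0)/DMSO(0) ≥ θ`;
  pre-stimulation positive if ≤ 1/θ; otherwise post-stimulation
  negative/positive if any `SHP099(t)/DMSO(t)` crosses the respective
  bound; otherwise neutral. Pre-stimulation classes preempt
  post-stimulation ones: the post classes are defined as changes after
  EGF addition *but not before*.

Both classifiers are total functions on positive ratio bundles and are
invariant to global rescaling of a site's abundance vector. No per-site
significance test is attached to a class call.

## Synthetic data generator

The generator emulates the conditions above with six kinetic archetypes:

| archetype | DMSO (0,5,10,30) | SHP099 (0,5,10,30) | washout (5,10,30) |
|---|---|---|---|
| early substrate-like | 1, 2, 2, 2 | 1, 4, 4, 4 | 2, 2, 2 |
| late substrate-like | 1, 1.2, 1.3, 2 | 1, 1.2, 1.3, 4 | 1.2, 1.3, 2 |
| EGF-dependent protected | 1, 3, 3, 3 | 1, 1, 1, 1 | 3, 3, 3 |
| EGF-independent protected | 1, 1, 1, 1 | 0.4 ×4 | 1, 1, 1 |
| EGF-responsive, SHP2-neutral | 1, 2.5, 2, 1.5 | 1, 2.5, 2, 1.5 | 2.5, 2, 1.5 |
| flat neutral | 1 ×4 | 1 ×4 | 1 ×3 |

The numeric vectors are fixed package constants; only their qualitative
shapes mirror observed response signatures. Every decisive ratio sits
well past the θ = 1.5 boundary (smallest log-scale margin:
log(1.5/1.3) ≈ 0.14, versus a merged-ratio noise sd of ≈ 0.05 at
cv = 0.05), so classification at the default noise level is stable. Each
archetype's declared (EGF, SHP2) labels and cluster id are re-derived by
the classifier on the noise-free means at construction time; a mismatch
is a construction error, making ground truth correct by construction.

Noise is multiplicative log-normal — reporter intensities are positive
and approximately log-normal — with per-channel log-sd
`sqrt(log(1+cv²))`. Defaults: `cv = 0.05` (a plausible reporter-level
precision for MS3 TMT quantification; the generator's own choice, not a
measured value) and a per-(site, replicate) log-scale offset
`replicate_shift_sd = 0.1` emulating loading differences; the offset is
removed by mean-1 rescaling and thus only exercises the pipeline's scale
invariance. Sites appear in both replicates with probability
`overlap_fraction = 0.9`, otherwise in one chosen uniformly. PSM-level
simulation emits one filter-passing record per site profile plus a
`contamination` fraction of decoys each violating exactly one named
filter rule, with generator-side bookkeeping as ground truth for filter
reports.

What the generator does **not** emulate: peptide sequences and
missed-cleavage structure, channel-correlated (co-isolation) noise,
missing channels within a profile, ratio compression, batch effects
across plexes, or realistic class imbalance. Passing recovery tests
therefore demonstrate correctness of the pipeline's logic under the
stated noise model, not robustness to every artifact of real TMT data.

## Clustering

Agglomerative clustering under the Euclidean metric, average linkage by
default, on per-site z-scored profiles (shape, not amplitude). Sites are
processed in lexicographic key order and tree cuts use `maxclust`, so
results are deterministic.

**Flatness floor.** Z-scoring a kinetically flat profile amplifies pure
measurement noise to unit scale and scatters flat sites across the whole
profile space; their diffuse cloud then dominates the top of the
dendrogram and `maxclust` cuts spend the cluster budget on noise shards.
Profiles whose cross-channel coefficient of variation falls below
`flat_cv_floor = 0.1` are therefore mapped to the zero vector (one tight
"flat" group) before clustering. The floor sits well below the CV ≈ 0.14
produced by a single 1.5-fold excursion in an 11-channel profile — i.e.
below the smallest change the classifier calls meaningful — and the
standardized representation remains invariant to per-site multiplicative
rescaling. An affine *shift* of a profile changes its CV, so shift
invariance is deliberately given up for near-flat profiles.

`select_k` cuts one tree at each k in the candidate range and returns
the k maximizing mean silhouette width (ties → smallest k; degenerate
all-identical input → smallest k with a warning). The selection rule is
this package's addition; nothing in the modeled study describes how six
clusters were chosen.

## Volcano statistics

Computed on the unmerged per-replicate table so a p-value is available.
For one site at timepoint t, each replicate contributes the two fold
changes SHP099(t)/DMSO(t) and SHP099(t)/WASHOUT(t); the effect size is
their arithmetic mean across replicates (four ratios, or two for
single-replicate sites, which are flagged low-power). The p-value is a
two-sided one-sample t-test of the log₂ ratios against 0. Degenerate
samples: all ratios exactly 1 → p = 1 (no evidence); zero variance with
nonzero mean makes the t statistic infinite, and p is clamped to the
smallest positive normal float so −log₁₀ p stays finite.

## Paired-pY protection enrichment

A protein is *paired* when it carries ≥ 2 detected pY positions within
d = 50 residues — a span covering reported tandem-SH2 engagement motifs
(position gaps of ~20–35 residues) with headroom; d is a flag. The
observed statistic is the number of protection-class sites (pre- or
post-stimulation positive) on paired proteins. Significance comes from
permuting class labels across sites (respecting per-protein site
multiplicity, which a contingency-table test would not) with the add-one
estimator `p = (1 + #{null ≥ obs}) / (n_perm + 1)`, valid by
construction: p ∈ [1/(n_perm+1), 1]. Because the statistic is an
integer count, p-values are discrete and conservative in the presence of
ties by roughly the statistic's largest atom; calibration checks against
a continuous uniform use enough sites to make that atom ≈ 0.01.

## Substrate-candidate screen

Criteria in order, first failure recorded per site: (1) EGF class is an
increase class; (2) `max_t SHP099(t)/DMSO(t) > 2` strictly ("greater
than twofold"), evaluated on the merged profile at any post-stimulation
timepoint; (3) not annotated as a known substrate; (4) antibody
available. Criteria 3–4 are literature facts supplied as a user TSV;
unannotated sites default to (unknown substrate: no, antibody: no) with
a warning. The audit trail partitions the input, and the candidate count
is non-increasing in the fold threshold.

## Enzyme kinetics

Standard curve: ordinary least squares of A620 against µM phosphate,
requiring ≥ 2 distinct concentrations and a positive slope. Rate per
(peptide, concentration) from replicate wells:
`phosphate µM = (mean A620 − blank − intercept)/slope`, converted with
the reaction volume (40 µL default: µmol = µM × 4·10⁻⁵) and divided by
the reaction time (5 min default), giving µmol phosphate/min. The blank
defaults to the matching 0 mM substrate wells; calibrated phosphate
below zero clamps to 0 with a warning (below-detection convention).

Michaelis–Menten fitting (`v = Vmax·S/(Km+S)`, nonlinear least squares,
deterministic initialization Vmax₀ = max rate, Km₀ = concentration
nearest half-max) is an *extension* for substrate comparison beyond the
per-concentration rate definition and is labeled as such in outputs.
Rates are O(10⁻⁴) µmol/min, so the fit runs on rates normalized by their
maximum with tight tolerances (1e-12); this recovers noise-free
parameters to machine precision. An all-zero rate series short-circuits
to Vmax = 0, flagged non-substrate.

## Problem sizes and numerical conventions

Recovery and calibration suites run at: 100 sites/archetype (600 sites)
for label recovery and cluster-count selection; 20/archetype for exact
noise-free cluster recovery; 10,000 random ratio bundles for
classifier/oracle agreement; 500 repetitions × 199 permutations × 25,600
sites for permutation calibration; 50 seeds at 5% noise for
Michaelis–Menten recovery. Threshold boundaries are located by 80-step
bisection on the live decision rules. Site vectors are mean-1 within
1e-9; TSV round-trips preserve 6 significant digits.

## Known limitations

* The SHP2-axis fold threshold reuses θ = 1.5 (the only stated
  threshold); it is exposed as a parameter rather than asserted as the
  modeled study's value.
* Increase-vs-decrease conflicts on the EGF axis are resolved by rule
  order (increases first); the original resolution is not documented.
* Whether replicate averaging operated on raw S/N or relative abundance
  is not documented; this package averages mean-1 relative vectors.
* The screen cannot reproduce any specific published candidate list:
  criteria 3–4 depend on literature annotations outside computation.
* Clustering quality degrades gracefully but is not characterized beyond
  cv ≈ 0.05–0.2; the flatness floor assumes relative noise below ~10%
  per channel.
* No imputation: sites with missing channels are dropped, which biases
  against low-abundance sites in real data.
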