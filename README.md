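# phosphodyn

Analysis of phosphotyrosine (pY) time-course dynamics under allosteric
SHP2 inhibition, from TMT 11-plex quantification tables down to enzyme
kinetics.

SHP2 (PTPN11) is a non-receptor tyrosine phosphatase with two SH2 domains
and a catalytic PTP domain: it both **dephosphorylates** pY sites and
**scaffolds** them, shielding paired pY motifs (e.g. GAB1 pY627/pY659)
from other phosphatases. Inhibiting SHP2 with the allosteric inhibitor
SHP099 during an EGF stimulation time course therefore produces two
opposite signatures: substrate-like sites *gain* pY under the inhibitor
and revert on washout, while protected sites *lose* pY. `phosphodyn`
implements the complete computational pipeline that separates these
signatures, together with a ground-truth synthetic data generator so
every stage can be validated against known labels.

## Pipeline

1. **quant_io** — TMT 11-plex design (DMSO and SHP099 arms at 0/5/10/30
   min post-EGF; washout arm at 5/10/30 min post-washout); PSM-level
   quantification filters (total reporter S/N > 200, isolation
   specificity ≥ 0.5, AScore > 13, pY residues); collapse to mean-1
   relative-abundance site vectors.
2. **synthetic_data** — six kinetic archetypes (early/late substrate-like,
   EGF-dependent/-independent protected, EGF-responsive SHP2-neutral,
   flat) with multiplicative log-normal noise and two partially
   overlapping replicates; labels are correct by construction.
3. **preprocess** — union merge of replicates (intersection averaged) and
   the per-site fold-change bundle:
   `egf_fc(t) = DMSO(t)/DMSO(0)`, `shp2_pre = SHP099(0)/DMSO(0)`,
   `shp2_post(t) = SHP099(t)/DMSO(t)`, `wo(t) = SHP099(t)/WASHOUT(t)`.
4. **dependence_classify** — rule-based classification at θ = 1.5
   (increase: ratio ≥ θ; decrease: ratio ≤ 1/θ). EGF axis: fast/medium/
   slow increase by earliest responding timepoint, neutral, decrease.
   SHP2 axis: pre-/post-stimulation negative (substrate-like),
   neutral, pre-/post-stimulation positive (protected).
5. **profile_stats** — average-linkage Euclidean clustering of z-scored
   profiles with silhouette-based selection of k; volcano statistics
   (mean of SHP099/DMSO and SHP099/washout fold changes vs −log₁₀ p from
   a one-sample t-test of the log₂ ratios); permutation test for
   enrichment of protected sites on proteins with two pY residues within
   50 positions (tandem-SH2 pairing).
6. **substrate_screen** — four-criterion candidate screen: EGF increase,
   > 2-fold elevation under SHP099 at ≥ 1 timepoint, not a known
   substrate, antibody available.
7. **enzyme_kinetics** — malachite-green phosphatase assay: OLS standard
   curve (A620 vs µM phosphate), rates in µmol phosphate/min
   (`(A−blank−b)/m × 40 µL / 5 min` by default), optional
   Michaelis–Menten fits across the 0–0.5 mM titration, and the
   seven-phosphopeptide substrate panel.

## Worked example

```python
from collections import Counter
from phosphodyn import (NoiseModel, simulate_site_table, merge_replicates,
                        classify_table, select_k, cluster_profiles,
                        ClusterParams, volcano)

table, truth = simulate_site_table(25, NoiseModel(cv=0.05, seed=7))
merged = merge_replicates(table)
calls, grid = classify_table(merged)
print("SHP2 classes:", dict(Counter(c.shp2_class.value for c in calls)))
k = select_k(merged, range(2, 11))
res = cluster_profiles(merged, ClusterParams(k=k))
print("selected k:", k,
      "cluster sizes:", sorted(Counter(res.assignment.values()).values()))
```

prints

```
SHP2 classes: {'post_stim_negative': 50, 'post_stim_positive': 25,
               'pre_stim_positive': 25, 'neutral': 50}
selected k: 6 cluster sizes: [25, 25, 25, 25, 25, 25]
```

150 simulated sites (25 per archetype): the 50 substrate-like sites
(early + late) are called post-stimulation negative, the two protected
archetypes split into post- and pre-stimulation positive, and silhouette
selection recovers the six planted kinetic groups exactly. The volcano
view of the same table at 5 min puts an early-substrate site on top
(mean fold change 2.14, −log₁₀ p = 5.8).

The same stages are exposed as a CLI:
`phosphodyn simulate | filter | merge | classify | cluster | volcano |
enrich | screen | kinetics` (see `phosphodyn --help`).

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical conventions, and known limitations.
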