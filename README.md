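# gmsubtype

Data-driven MRI subtyping of dementia cohorts from regional
gray-matter volumes.

Heterogeneous neurodegenerative diseases — dementia with Lewy bodies
is the motivating case — plausibly contain distinct anatomical
subtypes: patients whose atrophy is diffusely cortical, patients with
focal fronto-occipital loss, patients with preserved cortex but
proportionally low basal-ganglia volume.  `gmsubtype` implements the
full unsupervised pipeline for finding and characterizing such
subtypes from a subjects × ROI table of gray-matter volumes (82
cortical, 12 subcortical, 2 brainstem ROIs), for researchers working
with multicenter structural-MRI cohorts.

The core algorithm:

1. residualize each ROI volume on center of origin and intracranial
   volume (OLS);
2. build an unsupervised **random-forest proximity** matrix — a
   two-class forest separates real subjects from a column-permuted
   synthetic contrast, and proximity(i,j) is the fraction of trees in
   which subjects i and j share a terminal node;
3. cluster the dissimilarity `d = sqrt(1 − proximity)` by
   **average-linkage** agglomeration;
4. choose the number of clusters K ∈ 2..10 by the
   **Calinski-Harabasz index**
   `CH(K) = [B/(K−1)] / [W/(n−K)]` in residual feature space;
5. rank ROIs by **mean decrease in Gini impurity** from a supervised
   forest on the cluster labels and refit the top 10 for out-of-bag
   discrimination;
6. assess **stability** by rebuilding the proximity matrix with fresh
   seeds and measuring the elementwise difference;
7. characterize subtypes: ANOVA/chi-squared battery, per-ROI
   age-adjusted ANCOVA with Benjamini-Hochberg FDR, z-score atrophy
   profiles against a reference subtype, the basal-ganglia/cortical
   volume ratio, and a linear mixed model for MMSE trajectories over
   0/12/24/36 months (random intercept, REML, estimated marginal
   means).

Because subject-level clinical MRI data are not distributable, the
package includes a first-class synthetic cohort generator
(`SimulationSpec`/`simulate_cohort`) with planted subtype structure,
calibrated to realistic multicenter marginals; every stage is tested
against it.  See `docs/methods.md` for the models and calibration.

## Worked example

```python
import gmsubtype as g

cohort = g.simulate_cohort(g.SimulationSpec(seed=7))   # 165 subjects
model = g.SubtypeModel(cohort)                          # center+ICV adjusted
results = model.fit(seed=7)
print(results.summary())
```

```
Gray-matter subtype clustering (RF proximity + average linkage)
  subjects: 165, ROIs: 96
  forest: 2000 trees x 5 repeats, seed 7
  chosen K = 3 (CH = 147.44)
  cluster sizes: C1=50, C2=75, C3=40
...
OOB accuracy of reduced supervised forest: 0.994
```

The Calinski-Harabasz curve peaks at K = 3 (147.44, against 115.21
for K = 2 and 99.36 for K = 4), recovering the three planted subtypes
almost exactly (the generator planted 49/76/40).  Characterization
hangs off the results object:

```python
print(results.bg_ratio().cluster_stats)
#  cluster  n    mean      sd
#        1 50  0.0372  0.0008     <- cortical predominant: smallest denominator
#        2 75  0.0342  0.0007
#        3 40  0.0311  0.0008     <- subcortical predominant: preserved cortex

lmm = results.longitudinal()      # MMSE ~ cluster*visit, random intercept
print(lmm.emm.tail(4))
#  cluster  month    emm    se
#        3      0  24.69  0.78
#        3     12  23.86  0.83
#        3     24  23.93  0.85
#        3     36  23.36  0.96
```

The basal-ganglia/cortical ratio orders the subtypes C1 > C2 > C3,
and the mixed model shows the cortical-predominant subtype declining
from an EMM of 21.3 at baseline to 14.2 at 36 months while the
subcortical-predominant subtype stays near 23–25 (cluster-3 × month-36
interaction +5.77 ± 0.92, p < 0.001).

A shell interface wraps the same pipeline:

```bash
subtype simulate --seed 7 --out cohort.csv --schema-out rois.json
subtype cluster --input cohort.csv --schema rois.json \
        --k-min 2 --k-max 10 --trees 2000 --seed 7 --out run/
subtype run-all --simulate --seed 7 --out full_run/   # all 7 stages + manifest
```

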