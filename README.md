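# hemiasym

Threshold-independent analysis of hemispheric asymmetry in surface-based
task fMRI.

Functional lateralization — the tendency of cortical activity to favor
one hemisphere — varies across cognitive domains and individuals, and
relates to task performance. `hemiasym` provides a tested pipeline for
quantifying that asymmetry from bilateral cortical contrast maps and for
relating it to behavior. It is aimed at neuroimaging researchers working
with HCP-style surface data (paired left/right cortical meshes, multiple
task contrasts per subject), and at anyone who needs a reproducible,
property-tested reference implementation of the method on synthetic
cohorts.

## The measures

For a left-hemisphere contrast estimate L and the estimate R at the
mirror-matched right-hemisphere vertex, the package computes the
vertex-wise asymmetry index

    Δ = (L − R) / (|L| + |R|)        ∈ [−1, 1]

and the bilateral amplitude

    A = (|L| + |R|) / 2.

Δ > 0 means leftward lateralization, Δ < 0 rightward; cells with
|L| + |R| = 0 are masked (0/0 carries no lateralization information).
No activation threshold is applied anywhere. Left–right vertex
correspondence is established geometrically: coordinates are centered on
the bounding box, the right hemisphere is mirrored across the
midsagittal plane, each left vertex is matched to its nearest right
vertex, and the match is accepted only if the correlation of matched
coordinates exceeds R = 0.995.

On top of the vertex maps the pipeline provides:

* **Network summaries and rankings** — Δ and A averaged within a
  12-network cortical partition (VIS1, VIS2, SMM, CON, DAN, LAN, FPN,
  AUD, DMN, PMM, VMM, ORA); networks ranked by the RMS of asymmetry
  across task epochs, epochs ranked by mean asymmetry across networks.
* **Vertex-wise group statistics** — age residualization, grand-mean
  scaling across sex × race cells, one-sample t-tests against zero,
  Benjamini–Hochberg FDR across vertices, Hedges-corrected Cohen's d.
* **Amplitude–asymmetry coupling** — vertex-wise correlation maps
  averaged over epochs, and rank-binned group analysis (subjects ranked
  by amplitude, groups of 10, group-mean amplitude vs group-mean Δ).
* **Accuracy associations** — Pearson correlations between network
  measures and task accuracy with Bonferroni control, plus
  linear-vs-polynomial AIC comparison.
* **PLS prediction** — partial least squares regression (statsmodels-style
  `PLSModel.fit() → PLSResults`) predicting asymmetry or task accuracy
  from 153 network × epoch predictors, with 10-fold cross-validation and
  two-cohort (Discovery/Replication) cross-sample validation on
  covariate-matched splits.
* **Synthetic cohorts** — a generator with planted lateralization,
  amplitude–asymmetry coupling, accuracy structure and covariate
  effects, exactly invertible by the asymmetry index at zero noise, used
  throughout the test suite for parameter-recovery checks.

## Worked example

```python
import numpy as np
from hemiasym import (SimulationConfig, generate_cohort, match_vertices,
                      compute_asymmetry, aggregate_by_network,
                      rank_networks, PLSModel, build_predictor_matrix)

config = SimulationConfig(n_subjects=200, n_vertices=2000, seed=1)
dataset, table, truth = generate_cohort(config)

corr = match_vertices(dataset.left_coords, dataset.right_coords)
result = compute_asymmetry(dataset, corr)
summary = aggregate_by_network(result, truth.partition())

ranking = rank_networks(summary)
print(ranking.network_order[:3],
      round(ranking.network_scores[ranking.network_order[0]], 3))

X = build_predictor_matrix(summary, "amplitude")
Y = build_predictor_matrix(summary, "delta").values
res = PLSModel(X, Y, n_components=12).fit(cv_folds=10, seed=1)
print(res.summary().splitlines()[6])
```

Output:

```
['SMM', 'LAN', 'DAN'] 0.162
Response variance explained (cumulative): 0.138
```

The somatomotor network ranks first (RMS asymmetry 0.162 across the 17
epochs — the planted contralateral motor pattern), followed by the
language network; 12 PLS components of network amplitude capture 13.8%
of the asymmetry variance in this 200-subject synthetic cohort (the
planted amplitude→asymmetry coupling is deliberately moderate).

The same pipeline is available from the shell:

```bash
hemiasym simulate --seed 1 --out-dir run/
hemiasym asymmetry --dataset run/dataset.h5 --out-dir run/
hemiasym summarize --dataset run/dataset.h5 --partition run/partition.tsv --out-dir run/
hemiasym vertex-stats --dataset run/dataset.h5 --subjects run/subjects.tsv --out-dir run/
hemiasym couple --summary run/summary.tsv --out-dir run/
hemiasym accuracy-corr --summary run/summary.tsv --subjects run/subjects.tsv --out-dir run/
hemiasym pls --summary run/summary.tsv --subjects run/subjects.tsv --measure amplitude --target accuracy --out-dir run/
hemiasym split --subjects run/subjects.tsv --out-dir run/
hemiasym report --out-dir run/
```

## Data formats

The canonical container is a single HDF5 file (`/left`, `/right`,
`/coords`, `/meta`; 0-based vertex indexing); CIFTI-2 dscalar pairs can
be read as an optional input path via nibabel. Subject tables, network
partitions and all result matrices are tab-separated text; run metadata
and rankings are JSON. The package never downloads or redistributes
restricted cohort data — the synthetic generator stands in for it.
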