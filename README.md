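# ossomech

Comparative musculoskeletal mechanics of archosaur forelimbs. `ossomech`
builds articulated 3D models of the pectoral girdle and forelimb (segments,
three-axis joints, multi-strand muscles, wrapping cylinders), computes
signed muscle moment arms by tendon excursion across standardized pose
sweeps, normalizes them by minimum humeral shaft circumference, and places
per-taxon summed leverages into phylogenetic PCA morphospaces with fossil
tree time-scaling. It is aimed at vertebrate palaeontologists and
biomechanists comparing muscle leverage across clades — particularly across
evolutionary transitions such as the repeated origins of quadrupedality in
ornithischian dinosaurs — without needing a closed-source multibody
dynamics stack.

## The models and statistics at the core

**Joint coordinate systems.** Each joint has three rotational axes through
a single fixed centre: one parented to the proximal segment, one to the
distal segment, and a floating axis kept mutually perpendicular
(Grood–Suntay convention). Rotations compose proximal → floating → distal.
At the shoulder the proximal axis is abduction–adduction, the distal axis
is mediolateral long-axis rotation, and the floating axis is
protraction–retraction; at the elbow the proximal axis (through both
distal humeral epicondyles) is extension–flexion.

**Tendon excursion.** The moment arm of a muscle strand about a joint
degree of freedom is

&nbsp;&nbsp;&nbsp;&nbsp;*r* = −d*L*/dθ

with *L* the origin-to-insertion path length (shortest route around any
wrapping cylinders: tangent line – helical geodesic – tangent line) and θ
the joint angle in radians. Sweeps follow standardized functional poses
(glenohumeral ±40° protraction at 5° with the humerus adducted 90°; elbow
10°–100° flexion at 5°), values are normalized as *r*/*C*<sub>min</sub> by
minimum humeral shaft circumference, and multi-strand muscles are pooled
over all strands × poses into mean/min/max.

**Morphospaces.** Per-taxon summed action magnitudes (12 actions across
shoulder and elbow) enter a phylogenetic PCA: with *C* the Brownian-motion
tree covariance from a time-scaled phylogeny ("basic" dating on first
appearance data with a 1.0 Myr minimum branch length),

&nbsp;&nbsp;&nbsp;&nbsp;**a** = (1ᵀC⁻¹1)⁻¹ 1ᵀC⁻¹X,&nbsp;&nbsp;
R = (X−1**a**)ᵀ C⁻¹ (X−1**a**)/(n−1),

and the eigenstructure of R (or its correlation standardization) gives
loadings, scores and variance proportions. Uniform-branch-length and
ordinary (non-phylogenetic) PCA variants are built in, as are the
sensitivity variants (75°/115° humeral adduction, 70° scapular slope,
elbow axis translated to 1/3 and 2/3 of condyle width) with Kendall-tau
rank-consistency reports, and osteometric regressions of mean moment arms
on landmark displacements.

## Worked example

```python
import numpy as np
from ossomech import (SyntheticLimbSpec, generate_limb, generate_action_table,
                      glenohumeral_protocol, sweep, aggregate, ppca)

# a synthetic limb whose strands have known closed-form moment arms
model, oracle = generate_limb(SyntheticLimbSpec(seed=3))
from ossomech.synthetic import shoulder_sweep_grid
grid = shoulder_sweep_grid(model)
ms = sweep(model, model.muscles[0], "shoulder", "protraction", grid)
print(aggregate(ms))

# a 17-taxon action table on a dated tree, and its morphospace
data = generate_action_table(seed=5)
res = ppca(data.table, tree=data.tree, mode="bm-correlation")
print(res.summary())
```

The summary prints the eigenvalue table; on this seed the first three
components carry 27.4%, 16.5% and 15.9% of the variance (cumulative
59.8%), followed by the 12 × 12 loading matrix — positive PC1 loadings mark
the actions whose summed leverages covary most strongly across taxa after
discounting shared ancestry. `aggregate` prints the pooled mean/min/max
normalized moment arm of the muscle across the 17 sweep poses.

The same operations are exposed as a CLI:

```bash
ossomech synth table --seed 5 --out demo/
ossomech ppca --traits demo/action_table.csv --tree demo/tree.nwk \
              --ages demo/ages.csv --mode bm-correlation
ossomech run --config run.yaml   # full pipeline with a hashed manifest
```

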