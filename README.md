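# polyclust

Validated clustering of molecular-simulation trajectories, using polymer
models with *known* answers.

Clustering is routinely applied to molecular dynamics (MD) ensembles to
extract meta-stable states (free-energy basins) and the transition states
between them — but on real biomolecules there is no ground truth to check
the clusters against. `polyclust` provides a benchmark suite of polymer
models whose meta-stable/transition structure is built in by construction,
together with a locally-scaled spectral clustering algorithm and the
cluster-level diagnostics that recognize those states. Run the pipeline on
the models, learn what the statistics of a "real" meta-stable cluster look
like, then apply the same pipeline and statistics to your own trajectories
(e.g. intrinsically disordered proteins such as the FG-nucleoporins, whose
sequences ship as fixtures).

## The models

| model | kind | built-in structure |
|---|---|---|
| linear | analytic matrix | none: `X_ij = \|i − j\|`, constant drift |
| sinusoid | analytic matrix | 3 meta-stable states, 4 transition regions |
| rotation | 3D chain, deterministic | none; probes RMSD nonlinearity |
| cyclical | 3D chain, deterministic | revisits the same states 3× |
| dynamic | 3D chain, simulated | folds to a helix at t≈500, then unfolds |

The sinusoid matrix accumulates positive increments
`cos(6π(u−1)/(n−2)) + z` (z = 1.01), so the trajectory alternately
compresses (dense, meta-stable) and dilates (sparse, transition). The
dynamic model is a coarse-grained 11-particle chain with rigid bonds
(SHAKE), WCA repulsion, a stiff bend restraint at `2π/5`, and a torsion
well at `θ0 = arcsin(1.1·r_cut/(h_p·l))`, integrated by leap-frog with a
velocity-scaling bath annealed geometrically (`T ← γT` every 4000 steps):
cooling from T0 = 6 with γ = 0.925 folds a random coil into a two-turn
helix; the reversed schedule unfolds it.

## The algorithm

Given the pairwise-RMSD (Kabsch, proper rotations only) dissimilarity
matrix **X**:

1. σᵢ = mean distance from frame *i* to its *q* = 10 nearest neighbors
   (the local density scale);
2. affinity `a_ij = exp(−x_ij² / 2σᵢσⱼ)`, zero diagonal;
3. normalized Laplacian `L = D^{−1/2} A D^{−1/2}`;
4. embed frames as the row-normalized top-*k* eigenvectors of L;
5. restarted k-means (10 inits from random data points, ≤30 Lloyd sweeps)
   keeping the smallest within-cluster sum of squares.

Per cluster, the diagnostics report size, intra-cluster RMSD, σ and radius
of gyration as notched boxplot summaries; a cluster whose median σ is a
local minimum along the temporal ordering (with non-overlapping notches) is
called **meta-stable**, a local maximum **transition**.

## Worked example

```python
import numpy as np
from polyclust import (AnalyticModelParams, sinusoid_dissimilarity,
                       sinusoid_state_centers, spectral_cluster,
                       compute_diagnostics)

X = sinusoid_dissimilarity(AnalyticModelParams(n=1000, z=1.01))
print("meta-stable centers:", sinusoid_state_centers(X))

result = spectral_cluster(X, k=15, q=10, seed=0)
for d in compute_diagnostics(X, result):
    print(f"cluster {d.cluster_id:2d}  size {d.size:3d}  "
          f"median sigma {d.intra_sigma.median:6.3f}  {d.state}")
```

```
meta-stable centers: [167, 500, 833]
cluster  1  size  54  median sigma  5.673  transition
cluster  2  size  71  median sigma  2.729  intermediate
cluster  3  size  67  median sigma  0.171  meta-stable
...
cluster  8  size  65  median sigma  0.166  meta-stable
...
cluster 13  size  68  median sigma  0.174  meta-stable
cluster 14  size  70  median sigma  2.757  intermediate
cluster 15  size  54  median sigma  5.673  transition
```

The three built-in meta-stable states land in their own clusters (3, 8,
13 — low σ: dense neighborhoods), every cluster is a temporally contiguous
block, and the sparse regions at the ends and between centers carry high σ.
The same pipeline runs from the shell:

```bash
polyclust protocol --model sinusoid --k 3,5,10,15 --seed 0 --out out/
polyclust generate dynamic --mode both --seed 1 --out traj.pdb
polyclust cluster --traj traj.pdb --k 10,15 --seed 1 --out out/
```

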