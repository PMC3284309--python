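# Methods

## Purpose and scope

`polyclust` tests whether a clustering algorithm can recover meta-stable and
transition states from conformational ensembles, by applying it to polymer
models whose state structure is known by construction. The package contains
the models, the clustering algorithm, and the cluster-level statistics; it
does not run all-atom MD (the FG-nucleoporin sequences are shipped only as
fixtures for users who have their own trajectories).

## Analytic models

Frame indices are 1-based everywhere a formula or a reported center is
concerned; array storage is 0-based.

**Linear.** `X_ij = |i − j|` with n = 1000 frames by default. A trajectory
drifting at constant speed through structure space: no meta-stable or
transition states. Useful as a null model and for the start/end edge
effects of clustering.

**Sinusoid.** Frame *t* sits at cumulative position
`p(t) = Σ_{u=1..t−1} [cos(6π(u−1)/(n−2)) + z]` and `X_ij = |p(i) − p(j)|`.
The constraint z > 1 keeps every increment positive, so each row of X is
strictly monotone away from the diagonal (the trajectory never revisits a
state); z defaults to 1.01. Successive-frame increments oscillate through
three minima — dense regions that act as meta-stable states — separated and
flanked by sparse, transition-like regions. `sinusoid_state_centers`
locates the strict local minima of the increment series `d(t) = X(1,t+1) −
X(1,t)`; for n = 1000, z = 1.01 these are frames **167, 500, 833** (the
cosine argument passes π, 3π, 5π at t ≈ 167.3, 500, 832.7). As z → ∞ the
model converges (entrywise, after dividing by z) to the linear model.

## Geometric chain models

Chains have 10 rigid links of 3.88 Å (the Cα–Cα spacing; no steric
exclusion). A frame is built from a single pair of joint angles shared by
all joints: deflection θ between consecutive bond directions, and azimuth φ
measured in a parallel-transported (Bishop) normal frame. θ = 0 gives the
fully extended chain for any φ.

A consequence worth knowing: because the transported frame carries no
intrinsic twist, deflecting every joint toward the same transported azimuth
produces *planar* conformations — the rotation model's collapse is a planar
spiral winding from a straight line to a tight coil, not a 3D helix. This
does not change what the models are for: the walk through angle space is
exactly linear, so all nonlinearity in the resulting RMSD landscape is
attributable to the RMSD metric, which is the property under study. It also
makes the cyclical model's chirality constraint (no handedness flip, checked
via the sign of bond triple products) hold trivially.

**Rotation.** φ = 2ε(t−1), θ = ε(t−1) with ε = 7π/(n−1), applied directly
(no range clamping). The chain contracts monotonically in radius of
gyration from extended (frame 1) to tightly wound (frame 1000).

**Cyclical.** θ follows a triangle wave 0 → π → 0 with step magnitude
ε = 2π·cycles/(n−1) (the stated 6π/(n−1) for the default three cycles) and
φ = 2θ. Collapse and re-extension visit identical structures in reverse
order: frame t and frame 2 + P − t (P = (n−1)/cycles the cycle length, 333
for defaults) coincide to machine precision, and frames one full cycle
apart are identical.

## Dynamic model

Reduced units throughout; Boltzmann constant = 1; unit particle masses.

* 11 particles, rigid bonds l = 1.3 (SHAKE, relative tolerance 1e-8,
  ≤500 iterations per step).
* WCA repulsion `V(r) = 4[(1/r)¹² − (1/r)⁶] + 1` for r < r_cut = 2^(1/6),
  between all pairs except bonded neighbors; cubic periodic box of side 12
  with minimum image.
* Stiff harmonic bend restraint `V = 100·(φ − 2π/5)²` on each deflection
  angle (a restraint approximates the "fixed" bend; a holonomic angle
  constraint on top of SHAKE bonds would buy little here).
* Torsion well `V = 5·(1 − cos(τ − θ0))` per dihedral,
  `θ0 = arcsin(1.1·r_cut/(h_p·l)) ≈ 0.1911` with helix period h_p = 5.
* Leap-frog integration, Δt = 0.004; velocity scaling to the bath target
  every step (kinetic temperature uses DOF = 3N − n_bonds = 23; a zero
  instantaneous temperature skips the scale). Initial velocities are
  Maxwell at T0 with net momentum removed and rescaled to exactly T0.
* Annealing: T = T0 through a 10 000-step burn-in, then ×γ every 4000
  steps through step 210 000 (50 events). Freezing: T0 = 6, γ = 0.925;
  melting: T0 = 0.1217, γ = 1.0811. The schedules are mutually inverse:
  6·0.925⁵⁰ = 0.1217 (4 s.f.) and 0.1217·1.0811⁵⁰ ≈ 6.0 (within 1%).
* Frames are saved every 400 steps after burn-in: 500 per phase, 1000
  after concatenating freeze + melt (frame times renumbered 1..1000).

The freezing run starts from a random coil (equilibrium bends, torsions
i.i.d. uniform on [0, 2π)); the melting run starts from the ideal helix
(all torsions at θ0). Coil draws that place a non-bonded pair closer than
0.8 reduced units are rejected and redrawn (~13% of draws): such overlaps
sit so deep in the r⁻¹² core that the first force evaluation exceeds the
integrator's stable range, and they are not representative coil states.

With the torsion minimum at θ0, the geometric ideal helix has a turn-turn
separation of 0.85 < r_cut, so the WCA term holds the *dynamical* folded
state slightly expanded: the minimum RMSD to the ideal helix over a folded
trajectory plateaus around 0.19–0.22 rather than 0. The folded state still
sits at the concatenation midpoint (argmin frame within ~10% of t = 500
across seeds), which is the model's defining feature.

The integrator core is a numba-compiled kernel (~1.5 s per 210 000-step
phase); analytic forces are verified against finite differences of the
potential in the test suite. Identical seeds give bitwise-identical
trajectories; the driver derives independent sub-seeds for coil generation
and the two phases by seed-sequence spawning.

## Spectral clustering

Pairwise dissimilarity is superposed RMSD (Kabsch/SVD with the determinant
correction; reflections excluded, equal weights, Cα only for protein
input). The pipeline then follows the nine-step locally-scaled scheme
described in the README. Numerical choices:

* σ flooring: `σᵢ = max(σᵢ, 1e-12·max(X))` so duplicated frames cannot
  zero a scale.
* Dense symmetric eigensolver on L (top-k eigenpairs); eigenvalue ties are
  left to the solver — the k-means objective is invariant under orthogonal
  transformations of tied subspaces. Embedding rows that are numerically
  zero stay zero (with a warning) instead of being normalized.
* k-means: squared Euclidean objective; initial centroids are k distinct
  data points drawn uniformly; an empty cluster during a Lloyd sweep is
  refilled with the point currently farthest from its centroid; 10
  restarts, ≤30 sweeps, stop when labels stabilize. One seeded generator
  drives all restarts, so a run is reproducible end to end.
* Final labels are renumbered 1..k by ascending median member frame time,
  so cluster indices read in temporal order.

## Diagnostics and state classification

Distributions are summarized as notched boxplots: quartiles by linear
interpolation of order statistics, notch half-width `1.58·R_IQ/√n` (an
approximate 95% CI on the median). Whiskers reach 1.5× the
median-to-quartile distance beyond each quartile, truncated to the most
extreme data point inside that limit; points beyond are outliers. The
conventional Tukey rule (1.5×IQR) is available via `whisker_style="tukey"`.
Intra-cluster RMSD summaries need at least three members (three pairwise
values); smaller clusters are flagged undefined.

Classification uses only the per-cluster σ medians and notches, compared
between temporally adjacent clusters: strict local minimum with disjoint
notches → meta-stable; strict local maximum with disjoint notches →
transition; otherwise intermediate (endpoints compare against their single
neighbor; fewer than three clusters are all intermediate). This is one
defensible formalization of "low/high σ relative to temporal neighbors";
medians-plus-notches was chosen because σ distributions are narrow within
well-formed clusters while RMSD distributions are not. Alternative rules
(distribution widths, radius-of-gyration shifts) are possible and the
thresholding is deliberately confined to one configurable function.

A cluster's representative structure is its medoid: the member minimizing
the summed intra-cluster distances, ties to the smallest frame index.

## What the models do and do not emulate

The models provide known state structure, deterministic or seeded
dynamics, and (for the dynamic model) thermal noise with rigid-bond
kinematics. They do not include solvent, side chains, attractive
interactions, steric exclusion (geometric models), or the rugged
high-dimensional landscapes of real proteins. Passing the suite shows the
pipeline recovers planted structure under these idealized conditions —
a necessary check, not a guarantee on any particular MD system.

## Problem sizes

Defaults match the study conditions throughout: n = 1000 frames per model,
q = 10, k ∈ {3, 5, 10, 15}, full 210 000-step dynamic phases. The test
suite runs the dynamic model at three seeds and reuses those trajectories
across tests; the n ≤ 12 k-means oracle comparisons enumerate all 3ⁿ
assignments directly.

## Known limitations

* The sinusoid model's first increment minimum is at frame 167; the middle
  and last (500, 833) are exact half-period points of the formula.
* The geometric chain models are planar (see above); handedness-sensitive
  statistics on them are degenerate.
* The velocity-scaling bath fixes kinetic temperature exactly each step;
  it does not sample a canonical ensemble (no thermostat fluctuations).
  That is intentional — the model needs reliable annealed folding, not
  equilibrium thermodynamics.
* State classification depends on k: a state split across two clusters
  (or merged with a neighbor) may be called intermediate; scanning several
  k values is part of the protocol by design.
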