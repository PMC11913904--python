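# Methods

This note documents the models and numerical choices behind `tunnelstates`,
what the synthetic-data generator does and does not emulate, and the known
limitations of each stage.

## Tunnel detection on a Voronoi clearance graph

A structure snapshot is a set of spheres: atom centers plus per-atom radii
(Bondi table by default, user-overridable; synthetic fixtures carry explicit
radii). The engine builds an *ordinary* Voronoi diagram over the atom centers
and corrects for radii afterwards: the clearance of a point is
min over atoms of (distance to center − radius). For equal radii — the
representation the detector is designed around, and the one the synthetic
fixtures use — the Voronoi diagram contains the exact max-min-clearance path,
so no additively weighted (Apollonius) diagram is needed. With heterogeneous
radii the graph is an approximation whose error is bounded by the radius
spread; this is the standard trade-off and the radii in question (heavy atoms,
1.5–1.8 Å) keep it small.

Implementation details that matter:

- **Far-field sentinels.** Fourteen sentinel sites (6 face + 8 corner
  directions, at twice the system span plus 20 Å) surround the atoms before
  the Voronoi construction. Escape routes are then carried by *finite* edges
  whose clearance is actually sampled. Without sentinels, a finite vertex of
  an unbounded ridge acts as an exit even when the escape ray beyond it
  pinches below the probe — a false tunnel through a sealed hull.
- **Edge clearances** are the minimum over samples at ≤ 0.5 Å spacing along
  each edge (configurable). Edges below the probe radius are impassable.
- **Pathways** are Dijkstra minimum-cost paths, cost = length / clearance^ε
  with ε = 2 by default (the conventional choice; exposed in config). The
  centerline starts at the start *point* (the heme centroid), runs through the
  path's Voronoi vertices, is densified at the edge-sampling spacing, and the
  clearance is recomputed at every sample — the reported bottleneck is the
  true minimum clearance along the polyline up to that sampling, not an
  interpolation between vertex values. A pathway whose start prefix pinches
  below the probe is treated as closed.
- **Bulk detection (shell rule).** Pass 1 reaches the diagram boundary
  (sentinel faces, plus any vertex with clearance above a fixed 8 Å
  threshold); the definitive bulk threshold is `shell_multiplier` (default 3)
  times the widest *bottleneck* any pass-1 path sustains, and pathways are
  truncated at the first bulk vertex. Interpreting "largest radius" as the
  largest sustainable bottleneck rather than the largest sphere anywhere on a
  path keeps the rule well-defined under truncation and non-degenerate for
  structures with large internal cavities.
- **Duplicate suppression.** Exits whose node sets overlap a kept pathway by
  more than 80% are suppressed, cheapest path first. Distinct exits that share
  a trunk (the solvent-tunnel bifurcation pattern) survive because their
  endpoint regions differ.
- Ties at the bottleneck go to the first minimum along the path from the
  start. Bottleneck residues are those whose atom surfaces lie within a 3 Å
  gap of the bottleneck sphere surface (configurable).

### The grid oracle and its resolution limit

`grid_oracle_bottleneck` is the independent check: clearance evaluated on a
cubic lattice (0.5 Å default), binary search over the clearance threshold,
26-connected flood fill from the start cell to the box boundary; values below
the probe report 0. 26-connectivity is deliberate — 6-connected chains cannot
follow a diagonal corridor and understate the max-min value by up to one grid
diagonal. The start cell inherits the exact clearance of the start position so
the search is not voided by the offset between the start and the nearest
lattice node.

A threshold flood fill has an intrinsic blind band: a corridor whose true
max-min clearance exceeds the probe by less than the sampling bias need not
contain any lattice node above the probe, so the oracle reports 0 for a
passage that genuinely exists (we observed a 0.906 Å corridor invisible to
grids down to 0.1 Å against the 0.9 Å probe — the margin was 0.006 Å).
Engine/oracle equivalence checks therefore draw systems from
`resolvable_sphere_systems`, which skips geometries whose widest exit falls in
(probe, probe + grid step]. The guard uses only the engine value and the
declared resolution limit — never the oracle outcome — and is the grid
analogue of not validating a measurement inside the reference instrument's
noise floor. On guarded random systems the two methods agree within ~0.35 Å
at a 0.5 Å grid (tolerance: one grid step).

## Pathway clustering and tunnel types

Pathways from all frames are resampled to a fixed sample count by arc length
and compared by the mean Euclidean distance over corresponding samples beyond
the first third of the arc (the region near the start point is shared by all
tunnels and carries no identity). Average-linkage hierarchical clustering cut
at 5 Å (the distance matrix and threshold are the only inputs) yields the
tunnel types; each cluster is labelled by the user-supplied reference exit
direction of maximal cosine similarity, with a 0.7 floor below which clusters
stay "unassigned". Several clusters may share a label; the per-frame,
per-type bottleneck is the maximum over that type's pathways in the frame
(near-duplicates and bifurcating variants then count once, through their wider
branch), and 0 when the type is absent.

On discretely gated ensembles the engine runs once per distinct gate
configuration and the result is broadcast over the frame sequence
(`gated_bottleneck_series`): frames carrying equal `geometry_key` values are
coordinate-identical by construction, so this is pure memoisation.

## State model

- **Features**: (cos θ, sin θ) per torsion channel — periodicity-safe;
  zero-variance channels are dropped with a warning. Synthetic ensembles emit
  angle channels directly; for PDB ensembles φ/ψ are computed from N/CA/C
  positions.
- **tICA**: C₀ and the symmetrised C_τ are estimated from pairs that never
  straddle trajectory boundaries; C₀ gets a relative ridge of 10⁻⁶·tr(C₀)/d
  before the generalized symmetric eigensolve. Components come out
  C₀-orthonormal, eigenvalues descending.
- **Microstates**: seeded k-means++ (single initialisation, fixed
  `random_state`) on the leading tICA components.
- **MSM**: sliding-window counts at the lag; the largest strongly connected
  set is retained (discards are warned about, and frames in discarded
  microstates are forward-filled in the state trajectory). The default
  estimator is plain row normalisation with the stationary distribution from
  the leading left eigenvector; the reversible option symmetrises counts,
  which enforces detailed balance exactly. The pipeline runs PCCA+ on the
  reversible estimate because PCCA+ needs a real dominant spectrum and
  finite-sampling non-reversible estimates of large matrices can have complex
  leading eigenvalues.
- **Implied timescales**: tᵢ(τ) = −τ/ln|λᵢ| for i ≥ 2, tabulated per lag;
  non-positive or unit eigenvalues are reported as undefined.
- **PCCA+**: inner-simplex algorithm on the dominant right eigenvectors
  (vertex search by repeated orthogonalisation, memberships χ = X·A with A
  from the vertex rows, clipped to [0, 1] and row-renormalised). Crisp
  assignment is the row argmax, ties to the lower index. A weak spectral gap
  after the requested number of macrostates triggers a warning, complex
  dominant eigenvalues an error.
- Lag times are always in frames; `TrajectoryEnsemble.lag_from_ns` converts
  (70 ns at 50 frames/ns → 3500 frames, 40 ns → 2000 frames).

## Per-state characterisation

Openness uses two thresholds: *open* means the bottleneck exceeds the probe
floor (0.9 Å), *wide* means it exceeds the 1.7 Å van-der-Waals radius of
water. A tunnel is labelled **closed** in a state when its `closed_quantile`
(default 95th percentile) bottleneck stays at or below the water radius — a
quantile rather than the maximum so that isolated numerical spikes cannot
flip a label; **open** requires an open fraction of at least one half;
anything else is **intermediate**.

Co-opening fractions (both open / both closed / exactly one open) are counts
divided by the state's frame total, so the four fractions per tunnel pair sum
to 1. Contacts are distance-based: any heavy-atom pair across two selections
within 4.5 Å (default); the membrane variant first restricts lipid atoms to a
10 Å neighborhood of the selection. Relative membrane interaction time is
100 × contact frames / state frames, stackable to 300% over three states.

Dihedral entropy is the differential entropy of the circular angle density in
nats (ln 2π ≈ 1.8379 for a uniform angle): histogram with 360 bins by
default, von Mises kernel optional. Angles are phase-aligned to their
circular mean before binning, which makes the estimate exactly invariant
under rotating all angles by a constant. A constant series reports −∞ with a
warning.

Crystal-structure PCA flattens the heavy-atom coordinates of a residue region
(pre-aligned structures required, mismatched atom counts are listed), and the
greedy max-min selection picks structures spanning the projected space,
starting from the one farthest from the centroid.

## Membrane metrics

Plane fits are total least squares (smallest-eigenvector normal of the
centered covariance), hence rotation-invariant; collinear selections raise.
Tilt = 90° − the angle between the membrane-plane and heme-plane normals,
folded to [0°, 90°] via |dot|, so 90° means the heme lies parallel to the
membrane. Area per lipid is box XY area / lipids per leaflet. Insertion
depth is the signed distance from the bottleneck-residue heavy-atom center of
mass (standard atomic masses) to the upper-leaflet nitrogen plane, the normal
oriented away from the tail carbons: negative values lie inside the bilayer.
The tail-carbon plane position is reported alongside as the apolar reference.

## The synthetic world

The generator is the package's ground-truth instrument, not a physical model:

- **Protein**: a sealed ball of equal-radius (1.5 Å) atoms on a 2.2 Å cubic
  lattice with ±0.1 Å jitter (ball radius 16 Å) — interstitial clearances
  stay below the 0.9 Å probe, so the undrilled ball is sealed. An 8 Å
  active-site cavity is carved around the origin and holds a planar ring of
  four nitrogen-labelled "heme" atoms (ring radius 4 Å, 0.7 Å atom radius, at
  z = −2.5 so the start region clears 3 Å in every direction). Each planted
  tunnel is a cylindrical channel: a carve of the lattice plus wall rings of
  atoms exactly at `wall_radius` from the axis, so the axial clearance is
  analytically `wall_radius − atom_radius` (3.0 Å by default) at every ring
  plane.
- **Gates**: one pseudo-residue per tunnel whose atoms teleport between two
  ring layouts with axial clearance exactly `gate_open_radius` (3.0 Å) or
  `gate_closed_radius` (0.5 Å, below the probe); ring spacing is chosen so no
  passage wider than the gate clearance survives around the rings. Discrete
  gate motion keeps the planted bottleneck analytic and the state boundaries
  sharp — and makes per-frame tunnel analysis memoisable.
- **Hidden dynamics**: a 3-state Markov chain (0.98 self-transition by
  default, uniform stationary distribution, relaxation time ≈ 33 frames)
  drives which gates are open (state s closes tunnel j iff (j − s) mod
  n_states = 0; every state has a distinct openness row) and the means of two
  torsion-like von Mises angle channels per gate residue (means 120° apart
  across states, κ = 4 — clearly separable but far from noise-free).
- **Membrane**: two planar leaflets of pseudo-lipids on a jittered grid at
  z = ±24 Å, each lipid carrying one phosphate, one nitrogen (outward) and
  three tail carbons (inward); 50 lipids per leaflet in a 100 × 100 Å box
  (200 Å² per lipid).
- **Study conditions**: 3 trajectories × 20 000 frames at 50 frames/ns for
  the full-scale validation; tICA lag 50 frames and MSM lag 20 frames, chosen
  from the hidden chain's analytic relaxation time (a lag far past the
  correlation time would estimate pure noise); 200 microstates at full scale.
  The bundled demo uses 2 × 3000 frames and 50 microstates and finishes in
  seconds.

Everything is deterministic given the spec seed (separate `default_rng`
streams for geometry, chain, angles, membrane).

What the generator does **not** emulate — and what passing tests therefore do
not show about real data: continuous gate motion and intermediate openness,
conformational coupling between backbone and gates (angles are emitted, not
derived from geometry), solvent, lipid chemistry and membrane deformation,
overlapping/merging tunnels, and tunnel-geometry noise within a state. The
pipeline's recovery rates on the gated world are upper bounds: they establish
that the machinery is correct, not that any real ensemble is this separable.

## Known limitations

- Ordinary Voronoi with clearance correction is exact only for equal radii.
- The minimum-cost (ε = 2) pathway to an exit is not guaranteed to be that
  exit's max-min path; in practice the best bottleneck over all exits tracks
  the true max-min within the verification tolerance.
- Contacts are distance-only; no hydrogen-bond or interaction typing.
- Rectangular boxes only; no periodic imaging beyond whole-molecule lipids.
- The MSM stage validates Markovianity only through implied timescales (no
  Chapman–Kolmogorov testing), and mean first-passage times and state
  populations are deliberately out of scope.
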