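# Methods

## What the package computes

`vczone` implements a zone-coupled enhanced-sampling scheme for
ligand–receptor binding on a few reaction coordinates (RCs), together with
the weighted-ensemble analyses used to characterize binding modes.  The
target application is the situation where a small compound can approach a
receptor cleft from many directions and a plain simulation would spend
nearly all of its time either unbound or stuck in one pose: the sampler
forces broad coverage of the RC space and the estimator restores correct
canonical (Boltzmann) statistics afterwards.

Because all-atom explicit-solvent systems are far beyond a desk-scale test
budget, the package ships its own synthetic coarse-grained systems with
analytic references.  The machinery (zones, transitions, stitching,
reweighting, analyses) is the artifact; the bead systems exist so that
every step of that machinery can be validated against an independent
oracle.

## The toy Hamiltonian

A `ToySystem` is a bead model with energy

    U = Σ_bonds k_b (r − r0)² + Σ_angles k_a (θ − θ0)²
      + Σ_pairs 4ε[(σ/r)¹² − (σ/r)⁶] + Σ_restraints k_r |x − x_ref|²

in Å, kcal/mol, K, fs and amu.  Harmonic terms carry no ½ factor (so a
restrained coordinate has variance k_BT/2k_r).  There is no nonbonded
cutoff: systems are tens of beads, and the analytic comparisons require
the exact Hamiltonian.  Receptor-internal LJ pairs are excluded from the
pair list — the receptor frame is held by stiff position restraints
(10 kcal/mol/Å² by default), so internal receptor interactions would only
add cost without changing the sampled physics.  A short "C-terminal tail"
bead chain is restrained weakly (0.5 kcal/mol/Å²), emulating a flexible
terminal segment that fluctuates around its reference conformation; the
harmonic form is a choice, not a claim about any particular real system.

The shipped receptor is a cup: three "cleft" beads lining the pocket
bottom, an under-ring and a base bead shielding the lining from below,
pocket-wall and rim rings, and jittered decorative surface beads.  The
under-ring matters: without it the deep head–cleft well is reachable from
underneath the receptor, creating a spurious second binding site.  Two
ligands are shipped:

* **binder** — 4-bead chain, moderately flexible (k_a = 6 kcal/mol/rad²),
  whose head bead has a 10× deeper LJ well with the cleft beads
  (ε = 2.0 vs 0.2 kcal/mol).  Its head group doubles as the "ring A"
  analog: the moiety that sinks into the pocket.
* **rod** — 7-bead stiff chain (k_a = 50), uniform affinity everywhere.
  A long rigid compound that can lie across the cleft but has no reason
  to insert anything into it.

These parameters were chosen once so that, at 300 K, the binder's bound
state is thermodynamically significant (head–cleft well depth ≈ 10 k_BT
against an unbound volume of order 10³ Å³) while the rod's is not; they
are the study conditions of the demo, not tuning knobs.

## Dynamics

Propagation is BAOAB-discretized Langevin dynamics (default dt = 8–10 fs
for the bead masses of 40 amu, friction 1 ps⁻¹, 300 K).  BAOAB was chosen
because it samples the configurational canonical distribution exactly in
the harmonic limit — the property every downstream estimate rests on.  A
deterministic splitting rule derives per-(iteration, run) RNG streams from
one root seed (`numpy` `SeedSequence(root, spawn_key=(iteration, run))`),
so campaigns are reproducible and runs are order-independent.

Zone confinement and seeding windows use half-harmonic RC walls
(k = 10 kcal/mol/Å² per RC): zero inside the window, k(λ−bound)² outside.
Inside a zone the wall contributes nothing, so within-zone statistics are
canonical — the stitching estimator requires exactly this.  The soft wall
lets λ leak ~0.2–0.5 Å past a boundary; a 0.5 Å bookkeeping tolerance
treats such frames as in-zone for state membership, and frames whose RC
bin falls outside their zone's bins are stored but flagged and excluded
from histograms and reweighting (a fraction of a percent in practice).

## Reaction coordinates and the virtual system

An RC is the distance between the centers of two bead groups; receptor
groups default to mass-weighted centers, ligand groups to geometric
centers (the same convention as the density analyses).  Each RC range is
tiled with uniformly sized, half-overlapping zones whose boundaries
coincide with histogram bin edges (default: 4 bins per zone, 2 of them
shared with each neighbor).  A virtual state is one zone index per RC; a
point in an overlap region belongs to up to 2^d states.  Zone intervals
are closed on the left and open on the right (the last zone closed on both
ends), which removes boundary double-counting; note that with exactly
half-overlapping zones an interior zone's center lies on its neighbors'
boundaries, so "the zone containing a zone center" is unique only for
overlap fractions below one half.

## The sampling loop

Each iteration runs `n_runs` wall-confined Langevin stretches.  Every
`transition_interval` steps a replica may hop among the states whose zones
contain its current λ, drawn with probability ∝ 1/Ẑ_v where Ẑ_v is the
current estimate of zone v's canonical mass (floored at 10⁻⁶ of the total
for unvisited zones, which makes them strongly attractive).  This
independence-sampling rule flattens the virtual-state marginal; since the
final estimate depends only on within-zone canonical sampling, the scheme
is robust to the precise transition rule, and the rule used here is a
declared design choice rather than a reproduction of any published one.
Iteration 1, having no estimate, hops uniformly.

Snapshots are stored every `snapshot_interval` steps with their current
state and accumulated into that state's RC histogram; histograms persist
over all iterations.  Seeds for the next iteration are split 50/50:

* an **evenness** half cycling round-robin through visited zones in
  ascending visit count;
* a **GA** half: two parents drawn ∝ 1/visit-count, the child zone taking
  each RC index from either parent with a ±1 mutation at probability 0.1,
  clipped to the grid; each target is realized by the stored snapshot
  whose zone-normalized λ is nearest the target zone center (earliest
  snapshot wins ties).

The 50/50 split and mutation rate are package choices; coverage of the
visited-zone set is monotone non-decreasing by construction.

## Stitching

Per-state histograms are combined into one global distribution Q_cano over
the RC bins.  With h_v(b) = c_v(b)/(N_v·vol) the within-zone densities,
log scale factors g_v solve the weighted least-squares system
g_v + ln h_v(b) = g_w + ln h_w(b) over all bins shared by two states with
counts on both sides (gauge g_ref = 0; connectivity of the overlap graph
is required and a disconnected graph is an error, except inside the
campaign driver, which falls back to the component holding the most counts
during early iterations).  The final estimate is the per-bin
normalized-count-weighted average of the matched densities.  Both the
equation weights (harmonic means) and the final average use per-state
*normalized* counts c_v(b)/N_v rather than raw counts: this makes the
whole estimate exactly invariant under rescaling any one zone's counts —
an invariance the raw-count weighting cannot provide when the overlap
equations are statistically inconsistent — at a negligible efficiency cost
when per-zone totals are comparable, as they are under the
evenness-seeking scheduler.

Q grids are kept sum-normalized internally; reported and exported grids
are max-normalized (peak = 1), with the convergence metric

    d = Σ|Q_M − Q_{M−1}| / ΣQ_M   over bins where either grid > 0.001

evaluated between consecutive iterations; convergence is declared after
two consecutive iterations with d < 0.1 (the threshold is configurable;
the full iteration budget always runs).

## Reweighting

A stored snapshot in RC bin b receives weight w ∝ Q(b)/c(b), where c(b)
is the total recorded count of bin b.  Snapshots in bins whose Q falls
below 10⁻⁸ of the peak get zero weight and are flagged.  The weighted
snapshot set is then a canonical ensemble at the simulation temperature:
weighted averages estimate equilibrium expectations, and the weighted RC
marginal reproduces Q by construction.

## Analyses

All real-space analyses run after Kabsch superposition of the
receptor-core beads onto the reference structure (SVD-based least-squares
rigid fit; collinear selections are rejected).

* **Spatial density** ρ(r): each snapshot's selection geometric center is
  binned into 1.0 Å voxels with its weight; the grid is a probability
  (sums to 1).  Contour levels are quoted as multiples of ρ0 = 0.001.
  Both the whole-ligand center and the ring-A (head) center density are
  computed; the head density is the pocket-localization marker because
  the whole-body center of a flexible chain sits above the cleft even
  when the head is fully inserted.
* **Clusters**: 26-connected voxel components above `level × ρ0`
  (default 0.5ρ0), ranked by probability mass.
* **Minimum-distance distributions** ("RDF" in this analysis): the
  weighted distribution of the minimum bead distance between the ligand
  and a named pocket residue, normalized to unit integral — no 4πr²
  correction, since the variable is a minimum distance rather than a pair
  separation.
* **Contacts**: strict rule r < 4.0 Å on the minimum distance; fractions
  are weight sums.
* **DDF / flexibility**: weighted distribution of one intramolecular
  distance; mean and SD are computed from the unbinned per-snapshot values
  (so they are bin-width independent) and sd = SD/⟨r⟩, reported to three
  significant figures, is the length-normalized flexibility.
* **Orientation field** ⟨e(r)⟩: per snapshot a unit vector from the
  tail-group to the head-group geometric center; per 2.0 Å voxel (assigned
  by ligand center of mass) the weighted mean vector.  |⟨e⟩| ≥ 0.5 marks a
  voxel as orientationally aligned.  |⟨e⟩| ≤ 1 always (convexity).

Voxel sizes (1.0 Å density, 2.0 Å orientation) are package defaults,
recorded in every output and configurable.

## Validation oracles and problem sizes

`vczone.validation` quantifies correctness end to end:

* **Canonical recovery** — on a two-bead system (one frozen bead, one
  harmonically tethered, U(r) = k(r−6)², k = 1 kcal/mol/Å²) the RC
  Boltzmann density p(r) ∝ r² e^{−U/k_BT} is evaluated by Simpson
  quadrature.  The full loop (3 zones on one RC, 4 iterations × 16 runs ×
  12,500 steps = 8×10⁵ steps) recovers it with L1 ≈ 0.02–0.03, and an
  unconfined Langevin run of half that length provides a second,
  independent route with similar error.  Both distances are asserted
  < 0.1 in the acceptance suite.
* **Stitching recovery** — multinomial draws of 10⁴ counts per zone from
  a known 3-D Gaussian-blob density on a 2×2×2-zone grid stitch back to
  it with a maximum deviation of the max-normalized grids ≈ 0.02
  (asserted < 0.05), and multiplying any one zone's counts by 10 changes
  the estimate by exactly zero.  The deviation is measured relative to
  the grid peak: a per-bin relative error on near-empty corner bins is
  not a statistically meaningful quantity at this sample size.
* **Demo contrast** — the shipped binder/rod pipelines (5 iterations ×
  16 runs × 6,000 steps each) must show the binder's largest ring-A
  density cluster inside the pocket with a predominantly aligned
  orientation field there, and the rod must not show both signatures.
  This is a qualitative smoke-level regression of the full pipeline, not
  a numeric claim.

These problem sizes keep the whole validation under a few CPU-minutes
while leaving comfortable statistical margins.

## What the synthetic systems do and do not show

The generator emulates: a rigid receptor frame with a concave hydrophobic
pocket, a selectively attractive pocket lining, a restrained flexible
tail, ligand flexibility differences, and the entropy imbalance between
bound and unbound states.  It does not emulate solvent, electrostatics,
conformational change of the receptor, multiple competing binding sites,
or realistic kinetics.  Passing tests therefore demonstrate that the
sampling, stitching, reweighting and analysis machinery is correct — they
say nothing about the force-field realism of any particular molecular
system.

## Numerical notes

* Energies in kcal/mol; the single conversion 1 kcal/mol =
  4.184×10⁻⁴ amu·Å²/fs² enters the integrator once.
* LJ pairs below 10⁻⁶ Å raise an overlap error; angle forces floor sin θ
  at 10⁻⁶ to avoid the collinear singularity.
* The stitched least-squares system is solved densely
  (`numpy.linalg.lstsq`); state counts are at most a few dozen here.
* Ties in the GA snapshot matcher break toward the earliest stored
  snapshot (stable argmin).
* Degenerate seed stores fall back to sampling with replacement.

## Known limitations

* The transition rule and GA operators are faithful-intent package
  choices, not reproductions of any published scheme.
* Reweighting variance: with few snapshots, rarely visited bins can
  carry large weights; analyses on very short campaigns are noisy (the
  demo mitigates this with evenness-seeded iterations).
* The analysis path assumes the package's own store format plus a
  reference structure; external all-atom trajectory ingestion is an
  extension point, not shipped.
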