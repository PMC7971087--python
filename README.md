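# vczone

Zone-coupled enhanced sampling and binding-mode analysis for
ligand–receptor systems on a few reaction coordinates, with synthetic
coarse-grained test systems and analytic oracles.

## The problem

When a small compound binds a receptor cleft, a plain molecular-dynamics
run at equilibrium spends almost all of its time either far from the
receptor or frozen in one pose; the binding-relevant part of configuration
space is barely sampled.  `vczone` implements the standard cure: pick a
few reaction coordinates λ^(h) (distances between centers of two atom
groups, h = α, β, γ), tile their joint range with overlapping zones, and
couple the dynamics to a discrete *virtual state* — one zone per RC — that
confines each replica softly to its zone while allowing hops between
overlapping zones.  Iterating short runs with adaptive re-seeding (an
evenness pass plus genetic-algorithm-style crossover of zone indices
toward poorly covered regions) spreads sampling over the whole RC space.

Afterwards the per-zone RC histograms h_v(b) are *stitched*: log scale
factors g_v solve the weighted least-squares system
g_v + ln h_v(b) = g_w + ln h_w(b) over shared bins, yielding one global
canonical distribution estimate Q_cano(λ^(α), λ^(β), λ^(γ)).  Each stored
snapshot then receives the thermodynamic weight

    w_i ∝ Q_cano(b(λ_i)) / c(b(λ_i)),

c(b) the total count of its bin, turning the biased store into a canonical
ensemble at the simulation temperature.  On that weighted ensemble the
package computes the binding-mode observables: spatial probability
densities ρ(r) of a selection center on a voxel grid (contours as
multiples of ρ0 = 0.001), high-density clusters, minimum-distance
distributions to named pocket residues, a strict r < 4.0 Å contact rule,
intramolecular distance distributions with the length-normalized
flexibility sd = SD(r)/⟨r⟩, and the per-voxel mean tail→head unit vector
⟨e(r)⟩ with |⟨e⟩| ≥ 0.5 marking an orientationally ordered pose.

All-atom systems are out of scope; the package ships coarse-grained bead
systems (a cup-shaped receptor with a selectively attractive pocket
lining, plus "binder" and stiff "rod" ligands) whose BAOAB Langevin
dynamics can be validated against closed-form Boltzmann densities.  See
`docs/methods.md` for the model and every numerical choice.

## Worked example

```python
import numpy as np
from vczone import (build_reduced_pair_system, build_zone_grid, RCDefinition,
                    DynamicsParams, IterationSchedule, run_ga_vcmd,
                    snapshot_weights, analytic_bin_probabilities)

# a two-bead system whose RC density is known in closed form
system = build_reduced_pair_system(r0=6.0, k_tether=1.0)   # U(r) = (r-6)^2
rc     = [RCDefinition("r", [0], [1], range=(3.5, 8.5))]
grid   = build_zone_grid((3.5, 8.5), n_vs=3)               # 3 half-overlapping zones
sched  = IterationSchedule(n_iterations=4, n_runs_per_iteration=16,
                           steps_per_run=12_500, dt=10.0,
                           snapshot_interval_steps=125,
                           transition_interval_steps=500)
params = DynamicsParams(temperature=300.0, dt=10.0, friction=1.0, rng_seed=3)

result = run_ga_vcmd(system, rc, grid, windows=[(7.0, 8.2)],
                     schedule=sched, params=params, root_seed=3)
print([round(d, 3) for d in result.convergence])

counted = [s for s in result.snapshots if s.counted]
ens = snapshot_weights(counted, result.qgrids[-1], result.stack.total_per_bin())
edges = grid.axes[0].bin_edges
marg = np.zeros(8)
for s, w in zip(ens.snapshots, ens.weights):
    marg[min(int((s.rc[0] - edges[0]) / grid.axes[0].bin_width), 7)] += w
truth = analytic_bin_probabilities(system, 300.0, edges)
print("L1 distance from analytic Boltzmann density:",
      round(float(np.abs(marg - truth).sum()), 4))
```

prints

```
[0.026, 0.018, 0.012]
L1 distance from analytic Boltzmann density: 0.0207
```

— the iteration-to-iteration change of Q_cano settles near 1–2% and the
reweighted RC marginal agrees with the exact Boltzmann density to an L1
distance of about 0.02 (distributions sum to 1, so 0.02 means ~2% of
probability mass misplaced).

The full demonstration pipeline, including densities, clusters, RDFs,
orientation fields and contact fractions on both shipped ligands:

```bash
vczone demo --out vczone_demo --seed 1
```

```
binder: top cluster in pocket = True, aligned fraction = 0.85
rod: top cluster in pocket = False, aligned fraction = 0.35
```

The head-attractive binder concentrates its largest ring-A density
cluster inside the pocket with a consistently oriented (head-in) vector
field; the uniform stiff rod lies across the cleft instead.  Artifacts
(HDF5 store, weight tables, OpenDX grids, TSV tables, PDB reference,
run log) land under `vczone_demo/binder/` and `vczone_demo/rod/`.
Other CLI verbs: `make-system`, `init-config`, `sample`, `converge`,
`reweight`, `analyze density|clusters|rdf|ddf|orient|contacts`.

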