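# Methods

## Model

A molecular constraint network is a multigraph over rigid bodies, each
carrying 6 degrees of freedom (DOF).  Constraints are typed bars:

| kind           | bars | present      | meaning                                   |
|----------------|------|--------------|-------------------------------------------|
| intra_residue  | 5    | always       | covalent bond; one dihedral DOF survives   |
| linker         | 6    | always       | peptide bond; amide planarity locks it     |
| disulfide      | 5    | always       | S–S bridge                                 |
| hbond          | 3    | probability p| hydrogen bond / salt bridge                |

The integer pebble game (PG) plays one on/off realization of the hydrogen
bonds; the virtual pebble game (VPG) aggregates every vertex pair into a
single edge of capacity `sum(bars x prob)` (so `3p` per hydrogen bond) and
plays the same game with real-valued pebbles.  The dilution parameter `p`
is global: during sweeps it overrides the per-constraint occupancy, i.e.
all hydrogen bonds are treated as equivalent.  Per-constraint probabilities
remain in the file format for future energy-dependent protocols.

## Engine mechanics

Every body starts with 6 free pebbles.  Inserting an edge `(u, v)` of
capacity `c` gathers and holds 6 pebbles on `u`, then gathers up to `c` on
`v` and lays them on the edge; the shortfall, if any, is recorded as
redundant capacity and the vertices visited by the failed search are
condensed into one supervertex that keeps exactly 6 trivial DOF.  Pebble
searches are repeated breadth-first passes over a directed view of the
covers: a search may step from `x` to `y` when `x` has its own pebbles on
the edge `(x, y)`; pulling pebbles back along the discovered path lets each
intermediate vertex re-cover with pebbles freed from the next edge, so
per-edge cover totals and per-vertex pebble ownership (free + own covers =
6) are conserved.  The pinned vertex of a search is flagged visited up
front: its pebbles are immobile and the search does not expand through it,
but it belongs to the condensed region of a failed search.

Numerical conventions:

* all comparisons use an absolute tolerance `tol` (default `1e-9`); a
  search pass that gains `<= tol` pebbles counts as failed, which guards
  against float-dust loops;
* BFS expands neighbors in ascending supervertex id, so runs are
  bit-reproducible;
* integer mode is the same code path with integer-capacity validation — on
  integer inputs the two modes produce identical covers and labels;
* a scalar ledger `consumed` tracks covers plus condensation charges;
  `6N = free_total + consumed` holds after every operation and is asserted
  throughout the tests;
* if the initial 6-pebble gather on an endpoint ever fails the engine
  raises rather than continuing, since that can only indicate internal
  corruption;
* edges whose endpoints already share a supervertex are wholly redundant;
  zero-capacity edges are registered but absorb nothing;
* multiple connected components each keep their own 6 trivial DOF:
  `excess = free - 6 x n_components`, with components counted on the
  support of inserted edges.

Rigidity queries never mutate the converged state observably: rigid
cluster decomposition (RCD) and shared-DOF probes snapshot the covers and
restore them.  RCD pins 6 pebbles on an unlabeled vertex and probes
candidates in id order; one failed search labels every visited supervertex
into the cluster at once, which keeps the decomposition near-linear on
protein-like networks.  The shared excess DOF of a pair pins the reference
and gathers on the query; it is symmetric and equals the rank increment a
hypothetical 6-bar edge between the pair would achieve, which is how the
independent LP oracle validates it.

## Validation oracle

The body-bar rank of a small weighted network is computed independently by
linear programming: maximize `sum(x_e)` subject to `0 <= x_e <= c_e` and
`sum_{e in S} x_e <= 6|S| - 6` for every vertex subset `S`, `|S| >= 2`
(scipy HiGHS; limited to 7 vertices).  The engine must reproduce
`free = 6|V| - rank` on random networks, must be invariant to edge
insertion order, and its integer and fractional modes must coincide on
integer capacities.  These properties are exercised on hundreds of seeded
random networks in the test suite.

## Ensembles

`mc_ensemble` draws n independent hydrogen-bond patterns (each bond kept
with probability p) and runs the integer game on each; per-realization
random streams are spawned by counter from one root seed, so results do not
depend on execution order.  `exact_ensemble` enumerates all `2^m` patterns
with weights `p^k (1-p)^(m-k)` and is the reference the sampler must
converge to (feasible for m <= 20).  Accumulated statistics: pairwise
co-rigidity frequency, mean shared DOF (normalized by 6), per-torsion
rigid/flexible votes, cluster-size lists and optional labels.  Consensus
maps use a >= 50% majority; a frequency exactly at one half counts rigid.
In applications 200 realizations are typically adequate; reference
comparisons in the tests use more (up to 10^4) where the check demands it.

## Metrics

* **Rand Measure (RM)** — fraction of vertex pairs whose same/different
  cluster status agrees between two partitions (delegated to
  scikit-learn's `rand_score`, cross-checked against hand enumeration).
  During sweeps each realization's RCD is compared with the single
  mean-field RCD and the scores are averaged.
* **Agreement Measure (AM)** — per torsion,
  `AM = sigma x max(0, n_disagree - n_agree) / n_total` with `sigma = +1`
  if the mean-field call is rigid, `-1` if flexible.  It is 0 whenever the
  mean-field call matches the ensemble majority, +1 when the mean-field
  game calls rigid against a unanimous flexible vote, and small in
  magnitude for near-tied votes.  The bounded `max(0, .)` form is this
  package's reconstruction, chosen to satisfy those boundary behaviors.
* **RCM / MCM** — binary co-rigidity and continuous shared-DOF/6 matrices
  over the alpha carbons; the composite export places the mean-field
  result in the lower triangle and the ensemble in the upper.
* **RCS** — reduced second moment of cluster sizes,
  `sum(s^2 n_s) / sum(s n_s)` excluding the single largest cluster (the
  percolation susceptibility convention; the fully rigid limit gives 0 and
  an all-singleton network gives 1).  **ACS** is the unweighted mean
  cluster size.  Both conventions are choices of this package — the
  quantities are named but not written out in the rigidity literature this
  follows — and are stated here prominently for that reason.
* **Transition locators** — `p_worst` is the occupancy of minimum mean RM;
  `p_t` the occupancy of the RCS peak, with ties broken toward smaller p
  and a boundary argmax reported as "no transition" (networks that never
  cross the rigidity transition).

## Synthetic generators

`triangle_network` (the worked 0.6/5/5 example), `fully_rigid_network`
(6-bar chain, exactly the 6 trivial DOF left), `toy_two_hbond_network`
(8-body backbone, two fluctuating bonds, ensemble of four networks) and
`chain_protein` are deterministic under a seed.

`chain_protein` emulates a protein chain at 3 bodies per residue (N, CA,
C) with 5-bar rotatable phi/psi bonds and 6-bar peptide linkers.  Two
design choices matter:

* the two chain-terminal bonds are modeled as 6-bar locked edges, standing
  in for the terminal atoms a real chain would have; this makes the
  uncrosslinked chain's excess DOF equal its torsion count `2n - 2`
  exactly (oracle-verified at small n);
* cross-links (3-bar hydrogen bonds between alpha carbons >= 3 residues
  apart) draw their sequence separation from `3 + Geometric(0.35) - 1`,
  mimicking the short-range-dominated contact maps of real proteins.
  Local contacts rigidify the chain progressively through growing
  segments, which is what produces an interior susceptibility peak at
  desk scale; uniformly random long-range contacts instead give an abrupt,
  first-order-like transition with no usable peak.

What the generator does **not** emulate: side chains, hydrogen positions,
heterogeneous bond strengths, realistic contact geometry, or chain
topology beyond a single linear chain.  Tests passing on these fixtures
show the algorithms and their mean-field limit behave correctly — not that
any particular real protein's rigidity profile is reproduced.

The synthetic PDB writers produce text fixtures for the structure reader:
a two-residue glycine peptide with no polar contacts, and a dilated
helical glycine coil whose carbonyl oxygens are placed exactly 2.9 A from
the backbone N four residues ahead so that geometric detection finds the
i -> i+4 bonds and nothing else.  Both are labelled synthetic; neither is
a real structure.

## Structure reader

Covalent connectivity comes from residue template tables (20 standard
amino acids) with a 1.9 A heavy-atom distance fallback for nonstandard
residues; peptide linkers require C–N <= 1.9 A (otherwise a chain break is
warned); disulfides use SG–SG <= 2.5 A.  Hydrogen bonds are geometric:
donor–acceptor <= 3.5 A, plus a D–H···A angle >= 120 degrees when the
donor carries a hydrogen; salt bridges (carboxylate O to basic N <= 4.0 A)
are encoded as hydrogen bonds.  Donor/acceptor pairs within the same or
adjacent residues are skipped as covalently close.  Waters are excluded;
other heteroatoms only enter with `include_ligands`.  Phi is not flagged
for prolines (ring closure) or chain-initial residues; psi is not flagged
for chain-final residues.  These thresholds are conventional geometric
values; real-protein analyses that used energy-screened hydrogen-bond
lists will not match edge-for-edge.

## Problem sizes

The test suite and examples run at desk scale by design: oracle
comparisons use networks of up to 7 bodies (the LP is exponential in
vertex count), ensemble convergence uses the 8-body toy at 10^4
realizations, mean-field fidelity uses 8-residue chains against exact
64-subset enumerations, and dilution sweeps use a 40-residue chain with 60
realizations per grid point on an 11-point grid.  All statements the
documentation makes about outputs are produced by the shipped tests,
examples and acceptance script at these sizes.

## Known limitations

* The mean-field game suppresses fluctuations by construction; near the
  rigidity transition its cluster decomposition can differ noticeably from
  individual realizations (that disagreement, and its location, is itself
  one of the quantities computed here).
* The RCS/ACS and AM formula conventions are this package's explicit
  choices, as noted above.
* Fractional arithmetic relies on an absolute tolerance; capacities are
  sums of few small terms, so accumulated error stays far below `tol`, but
  adversarial capacities at the `1e-9` scale are not meaningful inputs.
* The LP oracle, exact enumeration, and all-pairs coupling maps are
  exponential or quadratic and intended for validation at small size, not
  production runs on large structures.
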