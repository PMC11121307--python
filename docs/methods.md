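# Methods

This note documents the models, conventions, and numerical choices behind
the package, what the synthetic generator does and does not emulate, and
the known limitations.

## Hydrogen-bond criterion and atom roles

Throughout the package a hydrogen bond is a *heavy-atom* contact: a
donor-capable and an acceptor-capable atom within `max_heavy_distance`
(default 3.0 Å, the approximate hydrogen-bond length). No explicit
hydrogens are required and no angle term is applied by default (an optional
angle parameter exists in the criteria object but the distance-only
criterion is the primary definition, since the analyses target heavy-atom
trajectories). Roles are assigned purely from `(residue name, atom name)`:

* carboxylate oxygens (Asp/Glu) and imidazole nitrogens (His): **both**
  donor and acceptor — at the half-channel's working pH these groups are
  protonatable and act as proton relay sites; treating them as
  acceptor-only would make a link between two acidic side chains
  unrepresentable, contradicting the observed aE219–aD119 adjacency;
* hydroxyl oxygens (Ser/Thr/Tyr): both;
* amide oxygens (Asn/Gln): acceptor; amide nitrogens: donor;
* Arg/Lys/Trp side-chain nitrogens: donor;
* water oxygen (`O`/`OH2`/`OW` in residues HOH/TIP3/WAT/SOL, configurable):
  a dedicated `water_oxygen` role that counts as both.

Backbone N/O carry no role: the transfer-chain analyses and the
intramolecular H-bond count deliberately cover side-chain polar atoms plus
water, which is the part of the network a proton can actually traverse.
Consequently the absolute H-bond counts here are *side-chain* counts and
are not comparable to whole-protein counts that include backbone pairs.

## Transfer-chain connectivity

Per frame, the chain graph's nodes are all polar (non-water) atoms plus the
water oxygens inside the *analysis zone*: the union of the cluster-region
spheres and a corridor of radius 6 Å (configurable) around the canonical
chain residues. Edges are H-bond contacts as above, excluding intra-residue
pairs. The frame is *connected* when any path joins a source atom to a sink
atom; the witness path is the hop-count-shortest path from a breadth-first
search with sorted neighbor order, so reports are deterministic.

A scenario's verdict aggregates per-frame connectivity to a percentage;
below 5% (configurable) the chain is called **interrupted**. The narrative
the threshold operationalizes is binary ("the chain was interrupted"), so
any small threshold works for the packaged fixtures, whose connectivity is
either 0% or far above 5%; 5% leaves headroom for rare accidental bridges
in noisier data. `broken_links` lists consecutive segments of the canonical
chain (aE219 → aD119 → aH245 → W2/W3 → aN214 → W1 → cD61) that are bridged
in *no* frame — for a region segment, "bridged" means a flanking atom is
H-bonded to a water currently inside that region. A segment whose endpoint
was substituted away (e.g. 245 → Gly) resolves to an empty atom set and is
reported broken, independent of the source→sink verdict.

The packaged scenarios use aD119 — the gate residue that is unmutated in
all nine substitutions — as the source, and the cD61 carboxylate as the
sink. Anchoring the source at aE219 would conflate "the mutated residue is
gone" with "the pathway from the aqueous cavity is gone": the studied
E219 substitutions preserve proton access via water, which the toy geometry
represents by starting the path at the invariant gate hub. Per-frame
path-existence is the primary criterion; segment-wise bridging over
different frames is reported via `broken_links` but never drives the
verdict.

## Water clusters

A cluster region is a sphere (default radius 3.5 Å) centered at the
midpoint of two anchor-group centroids, re-resolved every frame so the
region follows residue motion. The region geometry is a modeling choice —
the cluster sites are defined only verbally in the source material ("near
cD61", "between aH245 and aN214") — hence both anchors and radius are
configurable per scenario. W2 and W3 are treated as one joint `W2/W3`
region in the packaged scenarios (they are reported jointly in the study's
figures and are not separable without explicit geometry); the scenario
loader's default region set offers separate W2/W3 spheres sharing the
aH245/aN214 midpoint for users who want to split them. Waters inside two
overlapping regions count in each.

*Occupancy* is the percentage of frames with at least one water oxygen in
the region, stored exactly and rounded to 0.1% only on serialization.
*Capacity* is the per-frame water count; its probability distribution is
taken over **all** frames (zeros included), which makes
`occupancy = 100 × (1 − pdf[0])` an exact identity and keeps
histogram-style capacity plots and occupancy mutually consistent. The
`cluster_absent` flag fires below 5% occupancy — the operationalization of
a cluster "disappearing", which the narrative never quantifies.

## Stability battery

* **Superposition**: Kabsch via SVD with reflection correction (determinant
  forced to +1). Selections must contain ≥ 3 non-collinear atoms (rank
  check, tolerance 1e-8). An independent quaternion (Horn) solver is used
  as the test oracle, never in the analysis path.
* **RMSD series**: reference is the first frame (configurable by slicing
  the trajectory); the frame-0 value is 0 by definition.
* **RMSF**: every frame is superposed to a mean structure that is seeded
  from frame 0 and refined twice (three alignment passes total), making the
  profile numerically independent of frame order; per-atom mean-square
  fluctuations are averaged within each residue before the square root.
* **Radius of gyration**: mass-weighted RMS distance from the center of
  mass; masses from a standard element table.
* **SASA**: Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points/atom, minimum 96), probe radius 1.4 Å, van der Waals
  radii by element (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å).
  A surface point is buried when strictly inside a neighbor's extended
  sphere; exact boundary contact (measure-zero except for degenerate
  coincident atoms) is attributed to the lower-index atom so that two
  fully overlapping identical atoms yield exactly one sphere's area.
* **Stability-table summarization**: means/min/max per metric, overall and
  mutants-only (the wild-type row excluded); means can be rounded half-up
  to the printed precision (2 decimals) for comparison against published
  tables. The packaged 10-system table ships with the package as CSV.

Absolute Table-style metrics from the original 150 ns simulations are not
reproducible here — they require those trajectories — so the tests
establish the estimators' correctness on constructed inputs and synthetic
systems instead.

## Side-chain spatial states

The tracked side chain's terminal-atom centroid is expressed in a local
frame by superposing the backbone of the residue's own helix segment
(± 4 residues) onto the first frame, isolating side-chain motion from
helix drift (which some substitutions make large). The per-frame positions
are clustered with k-means for k = 1…k_max (default 3, matching the up to
three observed stable positions); k is chosen by silhouette score, with a
minimum silhouette of 0.5 required to prefer any split over a single state
(an unsplit Gaussian cloud scores well below this, well-separated modes
well above). States are numbered by first appearance. Frames farther than
2× the within-state RMS spread from every center are left unassigned, so
occupancies plus the unassigned fraction total 100%. Orientation labels
(toward aH245 vs toward cD61) are an interpretation layered on the cluster
centers, not part of the assignment.

Gate contacts use the strict inequality (min cross-pair distance < cutoff,
default 3 Å) per frame. Cα–Cα distance distributions are histogram
densities (default bin width 0.2 Å; the source figures state no binning)
normalized to integrate to 1.

## Membrane bookkeeping

Lipid class percentages use exact shares, floored, with leftover points
assigned by largest fractional remainder (ties by class name) — this
reconciles rounding so the classes total exactly 100 and reproduces the
conventional 73/27 printed split from exact shares 73.43/26.57 for the
five-species PE/CL composition (206 DYPE + 96 DPPE + 96 PMPE PE species;
108 PMCL + 36 TYCL dianionic cardiolipins). The charge check sums formal
charges (CL species −2 by default) with ion counts and a protein charge
input; zero means neutral. The module validates metadata only and builds
no coordinates.

## The synthetic generator

The generator emulates the *statistical* structure of the bottleneck, not
its physics:

* Polar sites sit on a line with 2.7 Å spacing between directly linked
  residues and 5.4 Å gaps where a cluster water must bridge; waters are
  placed uniformly in small spheres (radius 0.3 Å) at the W2/W3 and W1
  midpoints, so any present water bridges both flanks by construction and
  per-frame connectivity is exactly "all bridging regions occupied and all
  relay side chains present".
* Water presence is Bernoulli per frame (probability p per region); the
  count, conditional on presence, is drawn from the region's capacity
  distribution. Packaged fixtures use the printed occupancies where
  available (wild-type W1 0.92, H245G 0.44, N214L 0.36) and qualitative
  encodings otherwise (e.g. H245G W2/W3 p = 0 for cluster disappearance,
  Q252L capacity support up to 4 vs the wild type's 2, H245S "two or three
  waters" bridging). These parameters define the study conditions for all
  tests and are fixed.
* A tracked side chain hops among mode centers ≥ 2 Å apart (a Markov
  resampling with per-frame switch probability and stationary weights) with
  isotropic Gaussian noise (σ 0.25 Å); the gate arginine has a two-mode
  contact/away model with 0.9/0.1 weights, putting it on the gate aspartate
  for ~90% of frames.
* Backbone atoms get per-residue Gaussian jitter (default σ 0.15 Å);
  side-chain relay atoms are deliberately noise-free so chain-link
  geometry stays exact.
* Absent waters are parked far outside the analysis zone so every frame
  has a constant atom count (a requirement of the multi-model format).
* Ground truth (per-frame counts, mode labels, connectivity) is recorded
  at generation time; connectivity is re-derived by an exhaustive
  depth-first path search implemented independently of the graph analyzer,
  sharing only the criterion definition.
* One RNG stream per trajectory, keyed by the system's `seed` field: identical specs
  generate bitwise-identical trajectories.

What passing tests on these systems shows: the estimators (occupancy,
capacity, connectivity, SP recovery, contact fractions) are unbiased and
correctly implemented at realistic noise levels, and the pipeline's
qualitative verdict logic reproduces the encoded per-mutant outcomes. What
it does not show: anything about real water dynamics, electrostatics,
membrane coupling, or the absolute hydration numbers of the original MD
ensembles — the fixture probabilities are qualitative encodings, not claims
of equivalence to those simulations.

## Problem sizes and runtime choices

The default fixture length is 600 frames at a 2 ps recording interval
(binomial standard error ~1–2 occupancy points, sharp enough to separate
every encoded contrast); property checks use 300–600 frames and 5 seeds
per condition. SASA inside the full pipeline is evaluated every 10th frame
(it is the only quadrature-heavy stage; hydration and connectivity use all
frames). All sizes are parameters and can be raised freely.

## I/O conventions and edge cases

Coordinates are Å throughout; residue numbers follow the authors'
numbering verbatim (no re-indexing). PDB parsing is strict: duplicate
serials and insertion codes are parse errors (residue keys must be
unambiguous), malformed records report their line number, and alternate
locations collapse to the highest-occupancy conformer with a warning.
Multi-model blocks must agree in atom count. DCD I/O goes through
MDAnalysis. The PDB round-trip is exact to the format's 3-decimal
precision. Result tables are CSV (RFC 4180) or JSON; only JSON round-trips
losslessly. Scenario YAML omitting regions gets the documented W1/W2/W3
defaults; omitting the canonical chain gets the full gate-to-cD61 chain.

## Known limitations

* Proton transport itself is not simulated anywhere — connectivity is a
  geometric proxy for transfer feasibility, as in the underlying analysis
  protocol.
* Occupancy counts frames with ≥ 1 water; no per-molecule residence or
  exchange-kinetics criterion is implemented.
* The H-bond criterion has no angular term by default and no
  donor-hydrogen bookkeeping.
* Water-model hydrogen atoms are ignored entirely; single-oxygen waters
  are sufficient for every analysis here.
* The SP classifier assumes roughly isotropic, well-separated modes;
  heavily overlapping rotamer baths will be merged by the silhouette
  criterion.
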