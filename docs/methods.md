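# Methods

This note documents the models, estimators, numerical choices and known
limitations of `dendristab`, in the order a user meets them.

## The reduced solution model

All structural analyses operate on `ParticleConfiguration` (coordinates in
Å, orthorhombic periodic box) plus a `TopologyMap` sidecar carrying the
semantics coordinates cannot: molecule membership, species roles
(protein / dendrimer / anion / water / other), hydrogen-bond donor and
acceptor flags, atomic radii, and the dendrimer arm groupings. Only
orthorhombic boxes are supported — the minimum-image convention is then a
per-axis nearest-image shift, which keeps every distance path verifiable
against a scalar loop. Triclinic input is rejected outright rather than
silently mishandled.

The synthetic generators reduce each species to the least structure the
analyses need:

- **Dendrimer**: a rigid 5-site star — a core (radius 2.0 Å) with four
  guanidinium-like arm sites (radius 1.6 Å) at 4 Å, tetrahedral in the
  free pose. Four distinguishable arms are the minimum for the arm-ranking
  analysis; the arm sites are hydrogen-bond donors without explicit
  hydrogens, so bond detection runs in distance-only mode on these systems.
- **Anion**: a single acceptor site (radius 1.3 Å). The arm and anion radii
  are chosen so a hydrogen-bond-distance contact (2.95 Å, below the 3.5 Å
  detection cutoff) does not violate the inter-molecular hard core
  (1.6 + 1.3 = 2.9 Å).
- **Water**: a featureless site (radius 1.4 Å); it exists to be counted as
  species 1 in the Γ₂₃ bulk-composition ratio and is never an occluder or
  hydrogen-bond partner.
- **Protein**: either a single sphere at the box center (default radius
  20 Å) or a user-supplied atom set. Γ₂₃, arm ranking and exclusion volumes
  only need a surface to measure distances to; note that a sphere-mode
  protein cannot itself appear in geometric hydrogen bonds, because its
  center is farther than any atom-atom cutoff — protein-anion /
  protein-dendrimer bond motifs require an atom-set protein.

Placement is single-shot rejection sampling under an inter-molecular
hard core (no two site centers closer than the sum of their radii); there
is no energy function and no propagation. Every generator is a pure
function of its `SolutionSpec`, including the seed. A spec whose hard-
sphere packing fraction exceeds 0.45 is rejected up front, and placement
failures after bounded retries raise an error suggesting a larger box.

### What the two solution generators emulate

`gen_mixture` emulates a chloride-like solution: every molecule uniform at
random (hard core aside), no ion pairing. `gen_bridged_solution` emulates
sulfate / dihydrogen-phosphate-like solutions: each anion independently
becomes a *bridge* with probability `bridge_propensity`, sitting at
hydrogen-bond distance from arm sites of one or two distinct dendrimers.
Two-dendrimer placements are bent (anion-tip vectors at 70–140°) — which is
also what puts the two bridged dendrimers close enough for their surfaces
to occlude each other, so the SASA dendrimer-overlap term responds to
bridging as it should. When dendrimers run out, further bridging anions
decorate already-placed dendrimers, growing hydrogen-bonded chains; mean
D-A-D counts therefore saturate near n_dendrimer/2 at high propensity and
compositions for monotonicity studies should keep
n_anion ≤ n_dendrimer/2.

With a protein present the generators also encode the two binding modes the
arm-ranking analysis is designed to resolve: in mixtures, a `bound_fraction`
(default 0.5) of dendrimers adopts a cooperative pose — core just off the
surface, all four arms tilted 35–55° toward it — while in bridged solutions
a `pad_fraction` (default 0.5) of bridges anchors a dendrimer to the
protein through a surface-adjacent anion, one arm bonded to the anion and
the other three facing the bulk. These poses are generator design choices:
they reproduce the *ordering* (cooperative binding ⇒ narrow rank-1→rank-4
gap; anion-mediated single-arm attachment ⇒ wide gap), not any measured
geometry.

An `ideal mixture` mode (`point_solutes=True`) samples anions and waters as
interaction-free point sites by the identical uniform law. This is the null
condition for Γ₂₃ calibration — both species are exchangeable, so the
long-run estimate must be statistically zero — and deliberately drops the
hard core for those sites.

What the generators do **not** emulate: real dendrimer flexibility and
atomistic detail, explicit hydrogens (and hence bond angles), water
structure, electrostatics, and any dynamics — frames are independent
samples, not a correlated trajectory. Passing tests therefore demonstrate
the correctness of the estimators and the qualitative orderings under the
stated geometric assumptions, not force-field-level agreement with real
solutions.

## Preferential interaction coefficient

Γ_inst = n₃ˡᵒᶜ − (n₃ᵇᵘˡᵏ/n₁ᵇᵘˡᵏ)·n₁ˡᵒᶜ, evaluated per frame on a two-domain
partition: a molecule is *local* when the minimum distance from any of its
atoms to the protein surface is ≤ the cutoff. Choices and rationale:

- **Counts, not concentrations**, in the bulk ratio: on a fixed partition
  the two differ only by the constant domain volumes, and counts keep the
  estimator exactly checkable against a brute-force classifier.
- **Molecule-level assignment** (nearest atom): Γ counts molecules;
  atom-level assignment would double-count.
- **Cutoff default 8 Å** from the protein surface, configurable. The
  surface distance subtracts each protein atom's radius; a bare
  center-distance mode (`distance_mode="atom"`) is available.
- **Burn-in as a fraction of frames** (default 0.2). Real trajectories
  discard an initial unequilibrated window stated in time units; mapping
  time to frames requires a frame interval the inputs may not carry, so the
  burn-in is expressed in frames. The sidecar's optional `frame_interval`
  is used only for axis labels.
- **Block-averaged standard error** (default 5 non-overlapping blocks),
  the standard stderr estimate for correlated series. For independent
  synthetic frames it is simply a valid (slightly conservative) stderr.
- Degenerate inputs: no water anywhere → Γ = n₃ˡᵒᶜ; local water with no
  bulk water → error (the composition ratio is undefined and enlarging the
  box is the only fix).

Salt-level values are weighted averages Σw·Γ/Σw of per-ion components
computed on identical partitions. The weighting is the caller's choice;
two presets are provided — per formula-unit ion counts (1 dendrimer :
n anions) and per guanidinium group (4 : 1) — because no single convention
is canonical for a polycation, and the two differ materially.

The exclusion-only reference Γ_excl = −c₃·N_A·V_shell evaluates the purely
steric limit: V_shell is the volume the solute *center* cannot enter around
the protein, minus the protein interior — analytic for a sphere,
Monte-Carlo integrated (default 2·10⁵ samples over the bounding box) for an
atom set. It is strictly decreasing in solute radius and linear in c₃.

## Hydrogen bonds, motifs, clusters

Detection is geometric: donor-heavy-atom⋯acceptor distance ≤ 3.5 Å and,
when an explicit hydrogen exists, D-H⋯A deviation from linearity ≤ 30° —
the de-facto community criteria; both are flags. Intra-molecular pairs are
excluded by default. All distances are minimum-image.

D-A-D and P-A-D are counted as *distinct unordered triplets*: an anion
bonded to d dendrimers yields C(d,2) D-A-D triplets, and to p proteins and
d dendrimers p·d P-A-D triplets. The triplet lists are returned, so the
alternative bookkeeping (number of bonds participating in bridges) is a
one-liner for users who prefer it. Clusters are connected components of
the molecule graph induced by the bond (or any contact) list, optionally
restricted to a species set; excluded species drop out as nodes, so paths
through them do not connect the remainder.

## Solvent-accessible surface area

Shrake-Rupley-style sampling with a *deterministic* generalized-spiral
(Fibonacci) point set — bit-stable outputs for a given `n_points`, at the
cost of a point set that is not exactly rotation-invariant (total SASA
varies < 0.1 % under rigid motion at 960 points; individual single-site
molecules up to ~1 %). Defaults: probe 1.4 Å, 960 points/atom, both flags;
a floor of 96 points is enforced. Radii live in the topology sidecar; the
generators write the reduced-model radii above, and a missing radius is an
error naming the atom.

The loss decomposition evaluates each dendrimer in three occluder contexts
— isolated, all dendrimers, dendrimers + anions — and reports
ΔSAA_total = SAA_iso − SAA_full, ΔSAA_dend = SAA_iso − SAA_dend_only,
ΔSAA_ion = SAA_dend_only − SAA_full. Additivity is exact by construction
for every input, so tests assert it with equality, not a tolerance. Water
never occludes; protein occlusion is opt-in (`include_protein=True`),
since the decomposition targets dendrimer-only solutions.

## Distributions

RDFs histogram minimum-image pair distances (default bin 0.1 Å; r_max
defaults to 0.45·min box edge and may never exceed half the smallest edge)
and normalize by ideal-gas shell counts at the mean partner density, with
self-pairs excluded for identical selections. No smoothing is applied. The
running coordination number is the cumulative mean partner count per
reference site.

Arm ranking uses one tagged site per arm (the first atom of each arm
group; the reduced model's arms are single sites), measures its distance
to the protein surface (nearest atom center minus that atom's radius,
clamped at 0), sorts the four distances per dendrimer per frame, and
assigns ranks 1–4. Ties break toward the lower atom id, which makes the
output permutation-invariant to input order except at exact ties. Rank
histograms are emitted in both normalizations (per-rank unit area, and
global density), since either can be wanted for per-arm profile plots.

## Aggregation kinetics and thermal shifts

The second-order model M(t) = M₀/(1 + k·M₀·t). The default fit is
nonlinear least squares on M(t) with k ≥ 0, seeded by the linearized
slope; the linearized 1/M-vs-t regression is exposed as an option but
distorts noise weighting at low M, which is why it is not the default.
Neither weighting variant is privileged in the outputs — both are labeled
by `method`. A series with no loss signal (non-positive linearized slope)
returns k = 0 with a warning and non-finite t50/t95; non-finite t95 is
serialized as an empty cell plus a status column, never a sentinel number.

Derived quantities: t50 = 1/(k·M₀); t95 uses the 5 %-loss threshold
(`loss_fraction` flag), t95 = (1/0.95 − 1)/(k·M₀). Against a reference fit
sharing M₀, the shelf-life extension factor t95/t95,₀ = k₀/k exactly;
with differing M₀ it falls back to the t95 ratio and is flagged.

Thermal-shift slopes dTm/d[c] are ordinary least squares on
(concentration, Tm) pairs, restricted to a declared linear range (default
≤ 0.2 mol/L, beyond which the Tm response is not linear); at least two
distinct concentrations are required.

The decay generator adds independent Gaussian noise (sd in mg/mL) to the
exact second-order curve, redrawing nonpositive readings so concentrations
stay positive — the simplest error model that supports recovery studies;
no claim is made that real HPLC noise is Gaussian.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence batteries run 50 seeded configurations of ≤ 200 atoms;
the Γ null calibration uses 2000 independent 550-site frames; trend
contrasts use 20 seed pairs of 8-dendrimer / 16-anion / 40-water systems
(70 Å box, 20 Å protein) with SASA at 240 points per atom; kinetics
recovery uses 500 seeds at 20 points per curve. These sizes give stable
statistics for the orderings and calibrations being checked while keeping
the whole suite fast on one CPU.

## Known limitations

- Single protein per configuration; no protein-protein statistics.
- Sphere-mode proteins cannot participate in geometric hydrogen bonds
  (see above); use atom-set proteins for P-A / P-D / P-A-D studies.
- SASA is sampled, not analytic; stated tolerances (1 % vs the analytic
  sphere at 960 points) bound the error for the contrasts of interest.
- The exclusion-only model is hard-sphere steric only — no soft
  interactions, no solvation structure.
- Binary trajectory formats (DCD/XTC) are out of scope; the reader seam is
  `read_xyz_frames` / `read_pdb_frames`, and a new format only needs to
  produce `ParticleConfiguration` frames in file order.
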