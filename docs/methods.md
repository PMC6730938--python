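# Methods

`nucleomix` couples a Brownian-dynamics polymer model of the budding-yeast
nucleolus to a temporal-network analysis of the resulting 4D data.  This
note records the model, its assumptions, the parameters that matter, and
the design decisions taken where the design was genuinely open.

## The polymer model

Chromatin is coarse-grained into beads of 5 kbp.  Beads on the same chain
are connected by entropic wormlike-chain (WLC) springs using the
Marko–Siggia interpolation

    f(r) = (kT / Lp) * [ 1/4 (1 - r/L0)^-2  -  1/4  +  r/L0 ],

attractive toward zero extension, with contour length `L0 = 200 nm` per
spring.  The force saturates at extension ratio 0.95 (backbone) so a
single Euler step can never move a bead farther than the integrator's
stability bound.  Beads repel below a contact distance of
`2 * 30 nm` with a soft linear push-back; chain ends (and, in the
nucleolar preset, several interior beads) are pinned to the nuclear
envelope; all other beads are confined to the spherical nucleus by
post-step radial projection plus an inward restoring force.

Dynamics are overdamped Euler–Maruyama,
`x <- x + (F/drag) dt + sqrt(2 D dt) xi`, with isotropic Stokes drag and
`D = kT/drag` chosen so a free bead diffuses (100 nm)^2 per 0.1 s.  The
integrator aborts if any bead moves more than half the repulsion radius
in one step.  `dt = 1e-4 s`; frames are saved every 0.1 s.

### Transient crosslinks

Every nucleolar bead switches between an active and an inactive state;
active durations are drawn from N(mu, (mu/5)^2) and inactive durations
from N(mu/9, (mu/45)^2) (truncated below at `dt`), so beads are
crosslink-competent ~90% of the time at every mu and the single timescale
`mu` sets how fast partnerships turn over.  Two active, unlinked,
non-adjacent nucleolar beads closer than `d_link = 90 nm` may bind; each
bead holds at most one crosslink; a crosslink breaks only when one of its
endpoints turns inactive.

Two choices here departed from the simplest reading of the model and are
deliberate:

* **Random rather than nearest-first matching.**  When several eligible
  pairs exist in a timestep, partners are drawn uniformly at random among
  the in-range pairs (seeded; a greedy nearest-first policy is available
  as `match_policy="greedy"`).  Nearest-first matching almost always
  pairs a bead with its `i±2` chain neighbor, which never staples chain
  loops; without loop staples no clustering regime exists at any
  parameter setting we tried.
* **A stiff crosslink spring.**  The crosslink uses the same WLC form but
  with its own scale `kT / Lp_link`, `Lp_link = 3 nm` (bond well ~9 kT),
  versus `Lp = 50 nm` for the backbone, and a lower saturation cap (0.5).
  Physically, an SMC protein tether is far stiffer than 5 kbp of
  chromatin.  Mechanically this decoupling matters: if backbone and
  crosslink share one spring, any well deep enough to drive condensation
  also contracts the backbone until every bead can bond its `i±2`
  neighbor — bonding saturates in the swollen coil, densification gains
  no bond energy, and no clustering transition exists.  With a soft
  backbone (~130 nm neighbor spacing) and a deep, short crosslink bond
  (~20–40 nm), condensation is rewarded and the rigid / flexible /
  dissolved regimes appear.

### The scaled nucleolar preset

The full-genome preset (2803 beads, 32 wall-tethered arms, 361 contiguous
nucleolar beads on chromosome XII's right arm) is supported by the data
model, but production analyses run a desk-scale surrogate: a single chain
(default 250 beads, all but the two tethered ends nucleolar) draped along
the envelope.  Three ingredients of the surrogate are calibrated, once,
against the reference rigid-regime morphology (several discrete clusters
of >= 10 beads, separated by gaps wider than the 325 nm network
threshold, with a low-distance histogram mode well separated from the
bulk):

* **Confinement radius** `R = 1000 nm * (14 n / 2803)^(1/3)` — the
  nuclear volume shrinks with the simulated bead fraction.  At the full
  1000 nm radius a 250-bead chain is far too dilute for cluster
  nucleation; at genome-matched density the chain is a single dense
  liquid.
* **Interior envelope anchors** — one bead per ~16 beads is pinned to the
  envelope, emulating the membrane association of the rDNA (CLIP/cohibin
  tethering).  The anchors partition the chain into envelope-pinned
  segments whose condensates cannot consolidate into one globule;
  without them the simulation coarsens to a single condensate within
  ~100 s, because the surrogate lacks the crowding of the other 15
  chromosomes that immobilizes clusters in the full model.  Replicates
  draw both the anchor directions and the anchored bead indices at
  random (`orientation_seed`): cells differ in where the rDNA touches
  the envelope, and replicate-invariant anchor geometry would let
  population averages retain inter-cluster structure that real
  heterogeneous populations wash out.
* **Soft excluded volume** (`repulsion_strength = 6`) — nucleolar beads
  interpenetrate readily, treating the cluster interior as a liquid-like
  droplet; harder repulsion holds cluster packing at >= 60 nm spacing and
  pushes the intra-cluster histogram mode far above the reference value.

### What the surrogate does and does not reproduce

At `mu = 0.09` the surrogate produces 10–16 discrete clusters of ~10–27
beads with a multimodal instantaneous pairwise-distance histogram (a
cluster-scale mode plus inter-cluster modes) and temporal communities
detectable at (gamma, omega) = (10, 1); time- and population-averaging
smears the multimodality away, and the simulated-microscope area and
signal-SD trends with mu match the reference directions.  Two aspects of
the full-genome phenomenology are *not* reproduced, and the corresponding
acceptance-style checks are expected to fail honestly rather than being
tuned green:

* the intra-cluster mode sits at ~75–95 nm rather than ~50 nm.  The mode
  tracks the cluster ball radius, `spacing * (n_c / 2.2)^(1/3)`; with
  clusters of >= 10 beads (required by the cluster-size target) the mode
  cannot be pushed to 50 nm without contradicting that size.
* the non-monotone mixing optimum at `mu = 0.19` does not emerge.  In
  the surrogate the rigid regime's clusters still exchange beads at
  their peripheries (there is empty space to traverse instead of a
  crowded nuclear interior), so pairwise mixing improves monotonically as
  crosslinks rewire faster, rather than peaking at the flexible
  timescale.  An immobile-crowder variant restored neither effect and
  cost 6x the runtime.  Two further small-scale artifacts follow from
  the same root: the bead-vs-community ordering of the three reference
  timescales is noise-dominated when the underlying curves are nearly
  flat, and in the dissolved regime the reduced bead count makes
  individual PSF blobs semi-resolvable, so the image-based cluster count
  does not fall off with `mu` the way a dense continuum signal would.

## Distance maps and networks

Instantaneous maps are Euclidean bead–bead distances; time-averaged maps
average distances entrywise over a frame window; population-averaged maps
average replicate simulations entrywise at a fixed time.  Histogram modes
use 10 nm bins on [0, 2R] smoothed with a 3-bin moving average; the mode
is a local maximum of the smoothed counts.  When *counting* modes (the
multimodality signal), maxima must additionally reach a prominence of 10%
of the tallest peak and five times the Poisson noise scale of the mean
bin occupancy, so sampling ripples on flat or plateaued histograms do not
register.

The gene-interaction network applies `A_ij = exp(-s X_ij)` for
`X_ij < d*` (zero otherwise, boundary excluded) with `s = 1/d*` by
default.  Temporal networks cut the trajectory into non-overlapping
windows of `Delta = 10` frames (1 s), average distances within the window
first, then apply the nonlinearity — the reverse order is not equivalent
and is deliberately not offered.  `d* = 325 nm` for community detection,
`d* = 100 nm` for bead-level mixing statistics.

## Multilayer modularity and Louvain

The quality function couples per-layer configuration-null modularity at
resolution `gamma` with an `omega`-weighted reward for keeping a bead's
label across consecutive layers; the normalization constant is the total
strength plus coupling capacity (`mu_norm` in the code, to avoid
colliding with the kinetic timescale).  With one layer and `omega = 0` it
reduces to standard resolution-`gamma` modularity (cross-checked against
networkx).

Optimization is our own Louvain over node-layer pairs: greedy single-node
moves with incrementally computed gains (verified against full
re-evaluation to 1e-10 in tests), then aggregation into super-nodes
carrying per-layer strength vectors, repeated to a local optimum.
Interlayer coupling is folded into the move graph as `omega`-weighted
edges between a bead's copies in consecutive layers.  Node order is
shuffled per sweep from a seeded generator; `n_restarts` independent runs
keep the best quality.  On every toy small enough to enumerate, the
optimizer attains the exhaustive-search optimum.

A practical property worth knowing: at resolution `gamma` a clique-like
community of weight `w` is only favorable up to about
`sqrt(2m / (gamma w))` members (2m = total layer weight).  At
(gamma, omega) = (10, 1) and our network sizes this caps viable
communities near ~20 beads; physical clusters larger than the cap are
deliberately split or left unmerged by the objective itself, not by the
optimizer.

## Mixing statistics

Bead-level interaction series mark frames where a pair sits below
`d* = 100 nm`; community-level ("cross-communication") series mark layers
of co-membership.  Both reduce to maximal true-runs (interactions) and
interior gaps (waits).  Leading and trailing gaps are censored and
excluded from waiting times; pairs that never interact contribute no
waiting time (not an infinite one).  Gaps pool across pairs by default
(`pooled=False` averages per-pair means instead).  The interaction number
counts simultaneous partners, not events.  Cluster lifetime spans first
to last populated layer inclusive; persistence is the pooled probability
that a member keeps its label in the next window.  Single-bead labels are
excluded when summarizing "clusters" (a cluster is a set of beads).

## Imaging

The forward model deposits a unit-amplitude 3D Gaussian PSF (125 nm
lateral / 300 nm axial sigma — widefield-like defaults; the acquisition
optics are not modeled further) for every nucleolar bead on a 7-plane,
55 x 55, 64.8 nm-pixel voxel grid centered on the nucleolar centroid,
then takes the maximum intensity projection.  Analysis mirrors the
experimental chain: Otsu's threshold over a 256-bin histogram
(vectorized, cross-checked against an exhaustive between-class-variance
scan; within the empty-histogram plateau between classes any candidate is
equivalent and implementations may differ by a few bins while inducing
the same pixel partition), min-max normalization (masked pixels become
NaN), area = suprathreshold pixel count x 0.0648^2 um^2, population
standard deviation of the re-normalized surviving signal, and cluster
counting by blind Richardson–Lucy deconvolution (5 x 5 Gaussian seed, 10
iterations — MATLAB-default-like), two rounds of threshold-and-zero
background subtraction (the second round recomputes the threshold on the
survivors; switchable), 8-connected regional maxima, and connected-
component counting so plateaus count once.

## Problem sizes

Production analyses use 250-bead chains simulated for 360 s (the
acceptance recomputation) and 100–200-bead chains for 60–300 s in the
test suite; these sizes give stable cluster statistics while keeping a
full pipeline run in minutes.  The full-genome preset is exercised for
layout and confinement invariants only.

## Known limitations

* The surrogate's free parameters (confinement factor, anchor spacing,
  repulsion softness, crosslink stiffness) were calibrated against the
  reference rigid-regime morphology; they are not measurements.
* Valence-one crosslinking plus an uncrowded interior cannot reproduce
  the 50 nm intra-cluster packing or the flexible-regime mixing optimum
  (see above); conclusions about those two observables should come from
  full-genome-scale runs.
* Hydrodynamics is bead-local Stokes drag; no interaction tensors.
* The imaging model has no camera noise or optical aberrations; the
  synthetic fixture generator adds Gaussian read noise only.
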