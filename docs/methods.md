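# Methods

This note documents the models, numerical choices, and limitations behind
`fret3d`. It is written for a user who wants to know exactly what the
package computes and what its synthetic benchmarks do and do not show.

## Binding kinetics model

Each docking site is an independent two-state continuous-time Markov chain:
an empty site binds imager species *s* at rate k_on·c_s (k_on in nM⁻¹s⁻¹,
c_s the solution concentration in nM) and a bound imager dissociates at
rate 1/τ_s, where τ_s is the mean dwell time. Exact event times are drawn
(Gillespie), then discretized to camera frames by majority occupancy: the
per-frame state is whichever occupant held the site for most of the frame,
so events shorter than half a frame are not resolved. Sites are kinetically
independent — no steric exclusion or cooperativity between neighboring
docking strands is modeled.

The stationary occupancy of species *s* on a site is the competitive-binding
closed form

    p_s = k_on c_s τ_s / (1 + Σ_s' k_on c_s' τ_s'),

which the simulator is tested against (within Monte Carlo standard errors).
The **single FRET-pair fraction** — frames with exactly one donor and one
acceptor bound anywhere on the molecule — is the assay's usable yield, and
the simulator exists largely to explore it across concentrations and dwell
times. Holding donor concentration fixed, a severalfold acceptor excess with
a longer acceptor dwell raises the yield, because donor binding events are
the scarce resource and each becomes more likely to have an acceptor
partner. (Note that sweeping the acceptor:donor ratio at fixed *total*
concentration does not generally help: donor occupancy is sacrificed
one-for-one.)

Defaults: k_on = 10⁻³ nM⁻¹s⁻¹ (typical short-oligo hybridization scale),
frame time 0.1 s so a 1 s dwell spans ~10 frames.

## Trace synthesis

Synthetic traces are rendered from a ground-truth geometry through the
Förster model E_ij = 1/(1 + (r_ij/R₀)⁶), with dye positions given by the
site coordinates pushed radially outward from their centroid by the linker
length. Emission is gated on donor binding: a frame with at least one bound
donor emits a total intensity of I₀ per bound donor (default 1000 a.u.),
split between channels by the donor's transfer efficiency; acceptor-only
frames stay at baseline because the acceptor is not directly excited. For a
donor facing several bound acceptors the standard multi-acceptor sum is
used, E = K/(1+K) with K = Σ_j (R₀/r_ij)⁶. Noise is additive Gaussian per
channel (default SD 40 a.u. while emitting, 20 a.u. dark — a
shot-noise-limited camera at SNR ≈ 25). No photobleaching, blinking,
spectral crosstalk, or dye-orientation (κ²) effects are modeled, so the
synthetic "apparent" efficiency is exactly the modeled quantity; real data
additionally carry those distortions, and passing the synthetic benchmarks
does not demonstrate robustness to them.

## Event detection and the averaged FRET per event

Events are contiguous runs of frames whose total intensity I_D + I_A exceeds
baseline + k·SD (default k = 3, minimum 3 frames — 5 in the bundled example
configuration). The dark baseline and its SD are estimated by iterative
median/MAD sigma-clipping of the total-intensity distribution; the robust
statistics ignore the bound population entirely, which a mean/SD clip cannot
do when the bound fraction is large. If clipping would discard almost all
frames, the lowest-quantile frames are used as a fallback.

The per-event efficiency is the **mean of the per-frame** ratio
I_A/(I_A+I_D) over the event's frames (frames with non-positive total are
excluded), clipped to [0, 1]. Under noise this differs from the
ratio-of-means estimator; the per-frame mean is used throughout because the
histogram is built from "averaged FRET value per event". The per-frame
scatter within each event is also recorded: a pure single-pair event
scatters at the channel-noise floor, while an event spanning a binding-state
change (acceptor exchange mid-event, donor-only → pair, …) mixes two FRET
levels and shows inflated scatter. The pipeline's **purity filter** keeps
events whose scatter is below 2.5× the median scatter; this is the
operational definition of a single FRET-pair event.

No gamma, leakage, or direct-excitation corrections are applied anywhere.

## Mixture model for the efficiency histogram

Event efficiencies are fitted by EM as a mixture of

* k free Gaussian peaks (k = 1..k_max, BIC-selected; the pipeline caps
  k_max at m = n(n−1)/2 when the site count is known),
* an optional **zero component** for donor-only events. Because event
  averages below zero clip to exactly 0, this component is a normal
  *censored* at zero: probability mass 1/2 on the atom at 0 plus the
  positive half-density. Exact zeros are assigned to it outright; a model
  without it is inadmissible whenever the data contain them.
* an optional **uniform background** on [0, 1] that absorbs residual blurred
  events.

Initialization uses data quantiles, an "upper" variant seeded above the
donor-only spill, and random data-point restarts; the best likelihood per
model size is kept and model sizes stop growing once BIC worsens twice in a
row. Component SDs are floored at 10⁻³. Two post-processing rules turn
components into *reported peaks*: components closer than 1× the narrower SD
are merged (they model one unresolvable peak), and components carrying less
than 10% of the non-zero peak mass are reported as background rather than
as distances — in simulation these minor populations are identifiable as
1-donor/2-acceptor binding states, whose efficiencies are combination sums,
not pair distances. Peak SEM is SD/√n with n the responsibility-weighted
event count.

## Degeneracy and the triangular-number rule

n sites imply m = n(n−1)/2 distances (1, 3, 6 for n = 2, 3, 4). If fewer
peaks are resolved than m, some peaks must be degenerate; all integer
compositions (μ₁..μ_p) with Σμ = m are enumerated (e.g. 10 expansions for 4
peaks on 4 sites) and every expansion is carried through reconstruction.
Several expansions can tie at zero violation — the method then genuinely
admits more than one best structure, and all tied shapes are returned with
the lexicographically smallest canonical form first.

## Distance conversion and reconstruction

Peaks convert to distances by r = R₀(1/E − 1)^(1/6); peak SEM propagates to
a distance uncertainty by the delta method (reported, not used as embedding
weights — no weighting scheme is assumed). Defaults R₀ = 5.4 nm (typical
Cy3–Cy5) and linker 1.8 nm, both configurable and calibratable.

For three distances the triangle is unique up to congruence and is placed in
closed form; if the triangle inequality fails, the least-violation collinear
layout is found exactly by non-negative least squares over the three vertex
orderings. For six distances, the multiset is assigned to the edges of K₄
in every dissimilar way — assignments related by one of the 24 vertex
permutations are collapsed via a canonical form, giving 30 classes for six
distinct lengths — and each assignment is embedded:

* exact sequential trilateration first (closed form; succeeds whenever the
  distances are realizable in 3D);
* otherwise Levenberg–Marquardt stress minimization with an analytic
  Jacobian over gauge-fixed coordinates (vertex 1 pinned, vertex 2 on x,
  vertex 3 in the xy-plane), started from the clamped trilateration and a
  classical-scaling (rank-3 Gram) solution, with up to 10 seeded random
  restarts used only when the two deterministic starts disagree (for four
  points they almost always find the same minimum).

The **violation residual** is the RMS difference between realized and target
edge lengths ("the edge lengths are required to change the least"); RMS was
chosen over per-edge max or L1 as it matches the least-squares embedding.
Assignments within 10⁻⁶ nm of the minimum residual are ties. All shapes are
reported in a canonical frame (vertex 1 at origin, vertex 2 on +x, vertex 3
at y ≥ 0, vertex 4 at z ≥ 0); canonicalization is idempotent. Distances
cannot determine chirality, so a shape and its mirror are equivalent
throughout.

## Averaging, bootstrap, reference fitting, calibration

Shapes from many molecules are aligned by generalized Procrustes analysis
(translation + rotation, reflection allowed, no scaling) iterated to a fixed
mean. Bootstrap uncertainty resamples molecules with replacement B times,
averages each replicate, aligns the replicate means, and reports the
per-vertex 3D positional SD. Fitting to a reference structure offsets each
reference point radially from the centroid by the dye linker length, then
searches vertex permutations (when unlabeled) for the best rigid ±
reflection superposition.

Helix calibration models a dye attached at base pair b as the B-DNA helix
point ((r+L)cosθ_b, (r+L)sinθ_b, rise·b), θ_b = 2πb/(bp per turn) + phase,
and fits (R₀, L) by least squares between helix-model distances and
FRET-derived distances over several 3-site constructs. Defaults: rise
0.34 nm/bp, 10.5 bp/turn, helix radius 1.0 nm. A common phase offset is a
rigid rotation about the helix axis and leaves all pairwise distances
unchanged — it is a gauge freedom, excluded from the fit by default. With
zero-noise synthetic data the fit recovers (R₀, L) to better than 1% and
positions to well under 0.1 nm.

## Classification

Shape features are the sorted pairwise distances plus their sum and, for
triangles, the Heron area — a complete congruence invariant for three
points, near-complete for four (two non-congruent tetrads can in principle
share a distance multiset; documented limitation). The classifier is a
histogram gradient-boosted tree ensemble (max depth 3) trained on a 70/30
molecule-level split, so reported accuracy is always on held-out molecules.
Absolute size is deliberately kept in the features — it is informative here.

## Problem sizes and determinism

The test suite runs the full synthetic pipeline at 80 molecules × 240 s ×
0.1 s frames per scenario and the distance-geometry self-consistency check
at 1,000 random 4-point configurations; the bundled example uses the same
sizes. Every stochastic stage receives a seed derived deterministically from
one global seed, and a fixed configuration reproduces byte-identical output
files.

## Known limitations

* Event calling assumes a stable dark baseline per trace; slow drift or a
  mostly-bound trace degrades the threshold (a quantile fallback guards the
  latter).
* The mixture model treats blur as uniform; strongly structured blur (few,
  long mixed events) can bias peak means by ~0.01 in E.
* Multiplicity expansions frequently tie at zero violation for degenerate
  peak sets; without external information (symmetry, reference structure)
  the choice among tied structures is a convention, not an inference.
* Sorted-distance features cannot separate the rare non-congruent tetrad
  pairs sharing a distance multiset.
* All results are for apparent efficiencies; instrument corrections must be
  applied upstream if absolute distances are required.
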