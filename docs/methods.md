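# Methods

## Problem and model

`nucalign` transfers cell identities between point-cloud representations of
the same developmental stage of an embryo.  The *labeled* side is an ensemble
of clouds of named nuclear centroids (e.g. lineage-traced fluorescence
recordings of n different embryos); the *unlabeled* side is an anonymous
centroid cloud from another modality (e.g. segmented electron microscopy).
Positions are real-valued micrometres in an arbitrary right-handed frame;
times are minutes post first cleavage.

The method rests on three observations:

1. **Cell contacts are more stereotyped than cell positions.**  Adjacency is
   approximated by the Gabriel graph — points u, v are adjacent iff the open
   ball with diameter uv contains no third point (a subgraph of the Delaunay
   graph).  Edges present in *every* ensemble member ("consistent
   adjacencies") are treated as structural constraints that a correct
   labeling of the unlabeled cloud should reproduce.
2. **Landmark sets disagree because development is asynchronous.**  Cells
   divide and die at slightly different times in different individuals
   (heterochrony), so clouds from the same nominal stage differ in which
   landmarks exist at all.  A division or death within the stage's temporal
   window (default 13 min) marks its cells as *inconsistent landmarks*.
3. **A single extra or missing landmark corrupts matching non-locally.**  A
   one-to-one matching must park the surplus landmark somewhere, displacing
   a correct match and cascading outward.  Hypothesis edits of the labeled
   cloud (remove a dead cell; merge two daughters into their parent at the
   midpoint; split a parent into two co-located daughters) are accepted when
   they reduce constraint violations, which repairs these cascades.

## Pipeline

For each labeled member the unlabeled cloud is first brought into the
member's frame: an affine least-squares fit (or a thin-plate spline, for
strongly bent stages) on a handful of manually identified correspondences,
followed by correspondence-free nonrigid refinement with coherent point
drift.  Matching is a rectangular linear assignment problem (LAP) minimizing
total Euclidean distance (scipy's `linear_sum_assignment`); the surplus side
stays unmatched.  An assignment is scored by counting consistent adjacencies
with no mirroring edge between the matched unlabeled points (computed on the
unlabeled cloud's Gabriel graph); a missing edge charges both endpoint
identities.  *Iterative error correction* repeatedly forbids (infinite cost)
the matched pair whose identity carries the most missing adjacencies and
re-solves; the assignment with the fewest total violations seen is kept
(ties by smaller total distance).  200 correction iterations are run when
judging each modification hypothesis and 1400 on the final cloud.  A
modification is accepted when it reduces the violation total by at least 3.
Division hypotheses are considered before deaths, in lexicographic subject
order; for one division the merge hypothesis is tried before the split and
they are mutually exclusive.  Constraint edges are remapped along with the
modification (daughter edges renamed to the parent after a merge; a split
parent's edges satisfiable by either co-located daughter; a removed cell's
edges dropped); an alternative mode drops all edges touching modified cells.

Identities are then decided by a vote across the per-member alignments
(abstentions excluded from the denominator; ties to the identity from the
least-violating assignment, then lexicographic).  A landmark is *confident*
when the winner holds at least a 75% supermajority.  Uniqueness across
landmarks is deliberately not enforced.  One reiteration round follows:
confident matches (deduplicated per identity) become control points of a
fresh thin-plate-spline warp whose smoothing is chosen by 5-fold
cross-validation on those control points, with outlying anchors trimmed at
3.5 robust standard deviations; the warp is refined by the same CPD step,
confident identities are frozen (removed from the LAP, reinserted when
scoring), and only uncertain landmarks are re-matched.  Modifications
settled in round 1 are carried over rather than re-derived — whether the
sample has divided or dead cells is a property of the data, not of the warp.
A member's round-2 alignment replaces its round-1 alignment only when it
strictly reduces violations.

## Numerical and design choices

- **Gabriel test** uses strict inequality (open ball): boundary witnesses do
  not delete an edge.  Candidate edges come from the Delaunay triangulation,
  with an all-pairs fallback for degenerate (collinear/coplanar) input.
- **TPS kernel** is the 3D biharmonic `U(r) = −r` (the conditionally
  positive definite sign convention); `lambda = 0` interpolates exactly,
  large `lambda` approaches the affine least-squares fit.
- **CPD** is the standard nonrigid Gaussian-mixture EM formulation with
  kernel width `beta = 2.0`, coherence weight `lambda = 3.0`, outlier weight
  0.1, at most 100 iterations and tolerance 1e-6, all in an internally
  normalized zero-mean unit-RMS frame.  Non-convergence returns the best
  iterate with a flag rather than raising.
- **Worst-match tie-break** in error correction: among identities with the
  maximal violation count, forbid the one with the largest matched distance,
  then lexicographic.  Forbidden pairs accumulate within one correction call
  and reset between calls; an infeasible forbid is dropped with a warning.
- **Cloud diameter** (the scale for all diameter-relative fractions) is the
  maximum pairwise distance.
- Costs are raw Euclidean distances; a squared-distance switch exists for
  sensitivity checks.  All randomness in the package flows from explicit
  seeds; the alignment pipeline itself is deterministic.

## Synthetic benchmark

The generator emulates a bean-stage embryo: `n` landmarks quasi-uniformly
fill a 2:1:1 ellipsoid (semi-axes 25 × 12.5 × 12.5 µm) with a minimum
separation of 0.3× the expected nearest-neighbour distance.  Each sample
(member or unlabeled) applies, in order: lineage events, a smooth random
warp (3–5 Gaussian bumps, length scale 0.3× diameter, total amplitude
`warp_amplitude` × diameter), and i.i.d. per-point Gaussian jitter with
per-coordinate σ = `jitter_sigma` × diameter.  Events are designated once
per benchmark (`frac_inconsistent` of cells, half divisions, times uniform
within a 13-min window) and realized per sample by drawing the sample's
developmental time offset from N(0, 3 min): an event is realized iff it
precedes the sample time.  This makes event realization consistent for
events far from the stage time and variable near it — heterochrony proper —
which is what gives the modification stage something detectable to correct.
Division daughters are offset ±0.5× the local nearest-neighbour distance
along a random axis.  The unlabeled sample additionally receives an
anisotropic scale (default (1, 1, 0.8), emulating section compression) and
a random rotation, is stripped of names and permuted, and ships with ground
truth plus a 6-landmark correspondence table of well-spread, event-free
cells (the "manual landmarks").

Defaults are n = 150 landmarks, 3 members, jitter 0.02, warp 0.03,
frac_inconsistent 0.05.  These sizes keep a full benchmark run (5 seeds,
three ablation variants each) in the minutes range on one CPU.

### What the benchmark does and does not emulate

It reproduces the pipeline-relevant structure — positional variability,
smooth cross-modality deformation, anisotropy, permutation, heterochronic
landmark-set mismatches — but no tissue substructure, no nucleus size/shape
information, and, importantly, **no spatial correlation in the per-point
jitter**.  Real inter-individual variability is largely coherent (neighbours
move together), which preserves adjacency; i.i.d. jitter at σ ≈ 0.33× the
nearest-neighbour spacing makes the Gabriel graph itself volatile between
samples.  Measured consequence at the default conditions: a ground-truth
labeling leaves ~20–27% of consistent adjacencies unmatched in the unlabeled
sample's graph, and a distance-optimal labeling sometimes violates *fewer*
edges than the truth.  The violation objective is therefore only weakly
informative here, and the violation-driven stages (iterative correction,
co-optimization, reiteration) measurably do not improve on plain LAP +
voting at this scale, unlike on real embryo data where adjacency is stable.
Passing tests on this benchmark consequently validate the mechanics and
contracts of every stage, not the real-data accuracy ranking of the
ablations; the corresponding accuracy-ordering checks in the acceptance
suite document this honestly by failing at the stated conditions.

## Known limitations

- Split daughters are co-located, so their two identities are assigned
  arbitrarily between the two matched points (~50% per daughter); a division
  axis prior was deliberately not used.
- Freezing confident-but-wrong round-1 votes (≈5% of confident calls on the
  benchmark) propagates anchor errors into round 2.
- The greedy modification sweep evaluates hypotheses through noisy
  correction trajectories; with weak constraints, delta estimates near the
  acceptance threshold produce occasional false accepts.
- No temporal-stage optimization: the stage time and window are inputs.
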