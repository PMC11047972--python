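# Methods

This note documents the model, the numerical and design choices behind it,
what the synthetic fixtures do and do not emulate, and the package's known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The connection model

A reconstruction is a rooted SWC tree.  It is decomposed breadth-first into
*branches* — maximal paths free of interior branching points, each sharing
its proximal anchor node with its parent branch — and every branch into
directed *branching segments*: `L` sample points at unit arc-length spacing
(so a segment spans `L − 1` voxels of arc).  A child's proximal segment is
anchored at the branching point and directed distally; a parent's distal
segment is anchored at the branching point and directed *into* it, so a
collinear continuation has angle θ = 0 between the two directions.

Treating each parent–child segment pair as one step of a simple Markov chain
(growth depends only on the immediate predecessor), connecting segment A to
segment B costs

    U(A, B) = α·|ΔI| + β·|Δσ|   if θ < 90°,   ∞ otherwise,

with ΔI and Δσ the differences of mean and population standard deviation of
the image sampled (trilinearly) under the two segments.  Absolute differences
are used so the energy is non-negative; intensities are normalized by the
image dtype maximum so the two terms are commensurate and α = β = 0.5 weights
them equally.  The θ boundary is harmonized to "≥ 90° is illegal" everywhere
(the angular prior: neurites do not grow backwards).

The probability that A connects to B is scored against the candidate set
S = {segments s with endpoint distance to A strictly inside (0, Td)} ∪ {B}:

    P(B | A) = 1 − U(A, B) / Z(A),   Z(A) = Σ_{s∈S, U finite} U(A, s).

Infinite-energy candidates are excluded from Z (otherwise every finite
candidate would be certain) and receive P = 0.  If every finite candidate has
exactly zero energy the mass is split uniformly (P = 1/n), the 0/0 limit
convention.  Two consequences of the formula are worth naming rather than
hiding: a sole candidate with finite non-zero energy is forced to P = 0, and
the candidate set must therefore be populated generously.  The pool for a
branch's own score includes the branch's *own downstream chunks* — they are
legitimate potential connections — and excludes only the parent branch's
pieces (the anchor's upstream structure is not a rival).  Without the own-
chunk members, one sibling of every two-candidate bifurcation would sit at
P < 0.5 by construction, which contradicts what a confidence score should say
about a clean bifurcation.

Per branch, `PG` is the probability of its proximal segment given the
parent's distal segment (soma-attached branches get PG = 1 — there is no pair
to score).  `PL` chains the branch's own consecutive segments, each given its
predecessor (the first uses the parent's distal segment), and aggregates by
the *mean* so PL stays in [0, 1]; the literal running sum is available as
`pl_sum` / `--pl-sum` but can exceed 1 and is off by default.  Branch
confidence is min(PG, PL); branches strictly below τ are low-confidence.

## Parameters

| name | default | units | role |
|---|---|---|---|
| α, β | 0.5, 0.5 | – | weights of intensity-mean and intensity-SD energy terms |
| L | 8 | sample points | segment length (7 voxels of arc) |
| Td | 20 | voxels | candidate search radius around a segment |
| D | 10 | voxels | maximum gap for incomplete-tracing continuation |
| τ | 0.5 | – | low-confidence threshold on min(PG, PL) |
| d_cover | 3 | voxels | skeleton points this close to reconstruction nodes count as reconstructed |
| d_match | 2 | voxels | node match distance in evaluation |
| energy_margin | 0.05 | normalized intensity | minimum energy advantage for a rival before a connection-error detector fires |
| min_skeleton_len | 2.5 | voxels | shortest skeleton chain usable as detector evidence |
| tubularity_fraction | 0.70 | – | fraction of branch nodes that must have vesselness (inclusive) |

The energy margin exists because the raw better-rival comparisons
(P(other|parent) > P(current|parent)) are hair-triggers under imaging noise:
at every clean bifurcation the two siblings' energies differ by the noise
floor, and the strict inequality would flag one of them.  With 8-bit
intensities, parent–child intensity SD ≈ 10 and background SD ≈ 5, typical
legitimate-pair energy differences are α·(≈10/255) ≈ 0.02; a rival must beat
the current child by more than 0.05 — about twice that floor — before a
connection error is declared.  `min_skeleton_len` is the matching evidence
floor on the image side: after background truncation a binarized tube
overhangs its final reconstruction node by roughly 2 voxels once the
`d_cover` erosion is taken out, so skeleton fragments shorter than 2.5 voxels
are indistinguishable from end-cap artifacts.

## Image pipeline

Working inside the union extended bounding box of the reconstruction
(margin 10 voxels) keeps the filters off empty background.

*Enhancement.*  A truncated gamma transform: intensities are clipped to a
window, rescaled to [0, 1], raised to γ = 0.6 (boosting weak signal) and
mapped back.  The lower window edge is chosen from the histogram derivative:
past the background peak's steepest falling flank, the first bin where the
derivative drops below 1% of that flank's magnitude marks the end of the
background tail.  A fixed low percentile would not work here: with a
background-dominated crop it leaves the noise floor inside the window, the
gamma lift amplifies it, and the downstream mean + k·σ binarization then
keeps ~18% of the voxels — the thinned skeleton drowns in noise fragments.
The derivative cut removes the background peak before the lift, and falls
back to the `pct_lo` percentile when the histogram has no dominant peak
(peak < 5× the median bin count).

*Binarization.*  Foreground = voxels strictly above mean + k·σ of the
enhanced crop, k = 0.5 (a global image-statistic threshold in the style of
the classic tracers).

*Thinning.*  Sequential six-subiteration border peeling: in each directional
pass, voxels open to that face are deleted one at a time if they are
(26, 6)-simple — by the Malandain–Bertrand characterization, exactly one
26-component of foreground neighbors and exactly one face-touching
6-component of background in the 18-neighborhood — and not curve endpoints
(≤ 1 foreground neighbor).  Because every deletion is individually
topology-preserving and re-tested against the current state, component and
cycle counts are preserved *by construction*, 1-voxel curves are fixed
points, and the result is idempotent.  The simple-point test is memoized on
the 26-bit neighborhood pattern.  (A borrowed thinning implementation was
rejected after it erased entire even-thickness bars, which violates component
preservation.)

*Vesselness.*  Multi-scale Frangi filtering at σ ∈ {1, 1.5, 2} voxels, with
Hessian eigenvalues obtained from Gaussian-smoothed finite differences via
the closed-form symmetric-3×3 eigenvalue solution (vectorized; an order of
magnitude faster than the reference implementation at these volume sizes,
which matters because detection sweeps hundreds of crops).  Bright-ridge
gating (λ2, λ3 < 0), standard sensitivity constants a = b = 0.5, structure
constant c = half the maximum Frobenius norm per scale.  The tubularity mask
thresholds the response at 5% of its maximum.  A point "has tubularity" if
the mask is set at the point or any of its 26 neighbors (the lenient OR
reading; the strict AND would reject every surface point of a 1-voxel tube),
and a branch has tubularity if ≥ 70% of its nodes do (boundary inclusive).

*Skeleton branches.*  Thinned voxels are filtered — tubular, 1–2 neighbors in
26-connectivity (dropping isolated and branching points), farther than
`d_cover` from every reconstruction node, outside 1.5× the soma radius — and
traced into simple chains.  Because the coverage erosion can cut one physical
unreconstructed branch into several fragments that would then compete with
each other in the branch-missing rules, near-collinear fragments whose
endpoints lie within 2·d_cover + 2 voxels (turn ≤ 60°) are re-bridged.

## Detection pass

Branches are visited breadth-first.  Global detectors run first: over-tracing
(θ ≥ 90° to the parent, or branch tubularity < 70%), then branch–skeleton
connection error (a legal, tubular skeleton segment within Td of the parent's
distal segment connects with energy lower by more than the margin).  Both are
transitive: descendants inherit the label and are not independently
classified.  Local detectors follow: branch–branch connection error (same
comparison against other reconstructed branches' segments; distance 0 is
allowed so the true continuation can compete), and incomplete tracing for
terminals (a tubular skeleton endpoint strictly within D of the tip, with a
legal bridge).  Connection legality checks θ (current direction vs gap),
φ (gap vs skeleton direction oriented away from the gap) and ω (the two
directions) all ≤ 90°, inclusive.  Branch-missing runs per skeleton branch:
its attachment segment on the nearest reconstructed branch (a distal-style
window ending at the nearest resampled point — the same geometry a parent has
at a true branching point) must be legal and lower-energy than the skeleton's
connection to every competing skeleton in range, and the chain must be longer
than those competitors; the host branch is labeled if not already claimed.
Remaining unlabeled branches below τ become low-confidence.  Precedence when
several detectors fire: over-tracing > branch–skeleton > branch–branch >
incomplete tracing; user-confirmed branches are skipped entirely.

## Synthetic fixtures

The generator emulates the two statistics the energy function relies on:
child directions drawn within 55° of the parent's end direction (polar angle
20–55°, azimuthal separation 70–150° between siblings), and child intensities
equal to the parent's plus zero-mean noise of SD 10 (8-bit scale).  Defaults:
128³ volume, depth-2 bifurcating tree (7 branches), branch arc lengths 16–24
voxels, nodes every 1.5 voxels, Gaussian-profile tubes of radius 1.5 at base
intensity 200, soma ball of radius 4, background 20 ± 5, plus two straight
interferer tubes placed ≥ 25 voxels from the tree.  One seeded generator
drives every stochastic choice, so a fixture is bit-reproducible from
(config, seed); that problem size keeps a full detection pass around a second
and the whole acceptance battery within a few minutes on one CPU.

Each injector corrupts the reconstruction the way the corresponding artifact
arises in practice: a spurious mid-branch child at a reverse angle or into
unsupported background (over-tracing); a child's subtree replaced by a chain
along a freshly painted dimmer decoy tube, its true continuation surviving
only in the image (branch–skeleton error); a terminal's tail grafted onto a
nearby sibling at a still-legal angle, so only the energy comparison — not
the angle rule — can catch it (branch–branch error); a deleted terminal
branch (branch missing); a terminal truncated by 30–60% (incomplete tracing).

What the fixtures do *not* emulate: optical point-spread anisotropy, Poisson
shot noise (a config option, off by default), depth-dependent attenuation,
densely interwoven neighboring neurons, varying radii, and soma-proximal
halos beyond a simple bright ball.  Passing the acceptance battery therefore
demonstrates internal correctness of the model and detectors under controlled
tube-plus-noise conditions, not field performance on whole-brain microscopy.

## Evaluation

Precision = matched(R)/|R|, recall = matched(G)/|G| (a node matches if its
nearest node of the other tree is within d_match = 2 voxels), F1 their
harmonic mean.  ESA is the mean of *bidirectional* nearest-node distances,
DSA the mean over nodes farther than the threshold (0 when there are none,
not NaN), PDS their fraction.  Distances are node-to-node, not node-to-edge;
empty inputs yield zero metrics with a warning.

## Degenerate inputs and tie-breaks

Single-node trees produce no branches and an empty report.  Branches shorter
than the segment span use the whole branch with a `short` flag.  A node with
more than two children starts one branch per child, ids assigned in node-id
order; traversal, candidate iteration and skeleton linking all use fixed
deterministic orders, so identical inputs give byte-identical outputs (the
determinism acceptance test enforces this end to end).  Zero-length gap
vectors in legality checks fall back to the current segment's direction.

## Known limitations

- The sole-candidate P = 0 artifact of the probability normalization is
  implemented as specified, not patched; isolated but correct branches in
  sparse scenes are under-scored (mitigated, not removed, by the candidate
  pool conventions above).
- Branch–branch misconnections whose energy advantage is inside the noise
  margin are deliberately not flagged; the margin trades those for not
  flagging one sibling of clean bifurcations.
- Radii are ignored everywhere except soma removal (inputs from tracers
  commonly carry radius 1).
- The image pipeline assumes the reconstruction's bounding box (plus margin)
  contains the relevant signal; structure entirely outside it is invisible.
- Volumes are processed in memory; the tool targets single-neuron crops
  (≈ 256³), not whole-brain stacks.
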