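# neuroconf

Branch-confidence artifact detection for neuron reconstruction proofreading.

Automatic tracers (APP2 and friends) turn 3D fluorescence microscopy stacks of
single neurons into SWC morphologies quickly, but their output is riddled with
artifacts: spurious branches traced into noise, children attached to the wrong
parent, sub-branches that were never traced, and branches that stop early.
Manual proofreading fixes this but is slow, because a human has to inspect
every branch.  `neuroconf` is for people building or running proofreading
pipelines: given the image volume and the reconstruction, it scores every
branch's connection confidence, classifies suspicious branches into five
artifact categories, and emits an annotated SWC plus machine-readable hints so
a proofreader only has to look where the tool points — supporting an iterative
detect–modify loop until every branch is clean or confirmed.

## The model

The reconstruction is decomposed into branches (maximal paths between
bifurcations) and each branch into fixed-length directed *branching segments*
resampled at unit arc-length.  Because a child branch's growth depends only on
its parent branch, each parent–child segment pair is treated as a step of a
simple Markov chain.  Connecting segment *A* to segment *B* costs energy

```
U(A, B) = α·|I(S_A) − I(S_B)| + β·|σ(S_A) − σ(S_B)|    if θ < 90°
        = ∞                                             if θ ≥ 90°
```

where `I` and `σ` are the mean and standard deviation of the image intensity
sampled under the segments (normalized to [0, 1]), and θ is the angle between
the segment directions — real parent–child pairs have similar intensities and
never grow backwards.  The probability that *A* connects to *B* is scored
against every rival segment within a distance `Td` of *A* (other branches and
unreconstructed *skeleton branches* extracted from the image):

```
P(B | A) = 1 − U(A, B) / Z(A),      Z(A) = Σ_{s ∈ S} U(A, s)
```

A branch's confidence is `min(PG, PL)`: `PG` scores its attachment to the
parent (global artifacts), `PL` aggregates the per-segment probabilities along
its own chain (local artifacts).  Branches below a threshold τ are flagged,
and five rule-based detectors name the artifact: **over-tracing** (θ ≥ 90° or
< 70% of the branch supported by Frangi tubularity), **branch–skeleton
connection error** (an unreconstructed skeleton branch connects to the parent
with lower energy), **branch–branch connection error** (another reconstructed
branch does), **branch missing** (an isolated, legally attachable skeleton
branch), and **incomplete tracing** (a skeleton branch continues a terminal
within distance `D`).  The image side — background-truncated gamma
enhancement, fixed-threshold binarization, topology-preserving 3D thinning,
multi-scale Frangi vesselness, soma removal and chain linking — produces the
skeleton branches that drive the local detectors.

An evaluation module scores reconstructions against ground truth with
distance-matched precision / recall / F1 and the structural distances
ESA / DSA / PDS; a deterministic synthetic-fixture generator renders tubular
neuron phantoms with ground truth and can inject each artifact kind on demand.

## Worked example

Simulate a fixture with a deleted sub-branch, then detect it:

```
$ neuroconf simulate --seed 3 --artifact branch_missing --out /tmp/fx
fixture written to /tmp/fx_*
$ neuroconf detect --image /tmp/fx_volume.tif --swc /tmp/fx_recon.swc \
    --soma-marker /tmp/fx_soma.marker --out /tmp/run
5 branches, 1 flagged -> /tmp/run_report.json
```

The corrupted reconstruction has 5 branches (the deletion merged the host
with the deleted terminal's sibling) and exactly one is flagged.  In
`/tmp/run_report.json` the flagged record reads (abridged):

```json
{"branch_id": 2, "label": "branch_missing",
 "PG": 0.932, "PL": 0.863, "confidence": 0.863,
 "evidence": {"host_branch_id": 2, "distance": 3.03, "U_host": 0.011,
              "skeleton_id": 0}}
```

meaning: skeleton branch 0 — image structure absent from the reconstruction —
attaches legally to branch 2 at 3.0 voxels with connection energy 0.011, so a
sub-branch is missing there.  The annotated SWC colors branch 2's nodes with
type code 263 (green, branch-missing host), and `/tmp/run_skeleton.swc` holds
the skeleton chain showing the proofreader what to re-trace.  Scoring the
corrupted reconstruction against the saved ground truth:

```
$ neuroconf evaluate --test /tmp/fx_recon.swc --ref /tmp/fx_truth.swc --out /tmp/m.json
precision=1.000 recall=0.884 f1=0.939 esa=0.498 dsa=7.931 pds=0.062
```

recall 0.884 reflects the deleted nodes (12 of 95 missing, all farther than
the 2-voxel match distance), while precision stays 1.000 because everything
that *was* traced is correct.

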