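"""Markov-chain connection confidence for parent-child branch pairs.

The reconstruction is modeled as a set of simple Markov chains over directed
branching segments: the state of a child segment depends only on its parent
segment.  Connecting two segments costs energy

    U(A, B) = alpha * |I_A - I_B| + beta * |sigma_A - sigma_B|   if theta < 90
            = +inf                                               if theta >= 90

where I and sigma are the mean/SD of image intensity under the segments
(normalized by the image dtype maximum) and theta is the angle between the
segment directions.  The probability that A connects to B is

    P(B | A) = 1 - U(A, B) / Z(A),      Z(A) = sum over candidates s of U(A, s)

with the candidate set S = {s : 0 < dist(A, s) < Td} plus the current segment
B itself; dist is the nearest distance between segment endpoints.  A branch's
confidence is min(PG, PL): PG scores its attachment to the parent under global
artifacts, PL scores the chain of its own consecutive segments under local
artifacts.  Branches with confidence below tau are flagged as low confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_features import ImageVolume, SegmentFeatures, TubularityMask, segment_intensity_stats
from .neuron_model import (
    Branch,
    BranchSegment,
    NeuronTree,
    angle_between,
    chain_segments,
    extract_segment,
    resample_polyline,
)

__all__ = [
    "ConfidenceParams",
    "EnergyBreakdown",
    "CandidateSet",
    "ConfidenceResult",
    "connection_energy",
    "build_candidate_set",
    "connection_probability",
    "ConfidenceContext",
]


@dataclass
class ConfidenceParams:
    """Tunable parameters of the confidence and detection engine.

    All distances are in voxels.  ``alpha``/``beta`` weight the intensity-mean
    and intensity-SD terms of the energy (intensities are normalized to [0, 1]
    so the two are commensurate).  ``Td`` bounds the candidate search, ``D``
    the incomplete-tracing gap, ``L`` the segment length in sample points,
    ``tau`` the low-confidence threshold, ``d_cover`` the distance within
    which image skeleton points count as already reconstructed, ``d_match``
    the evaluation match distance.  ``energy_margin`` is the minimum energy
    advantage a competing segment needs before a connection-error detector
    fires (differences below the imaging-noise floor should not drive
    rewiring suggestions).
    """

    alpha: float = 0.5
    beta: float = 0.5
    Td: float = 20.0
    D: float = 10.0
    L: int = 8
    tau: float = 0.5
    d_cover: float = 3.0
    d_match: float = 2.0
    energy_margin: float = 0.05
    pl_sum: bool = False  # literal Eq.-4 sum instead of the mean
    tubularity_fraction: float = 0.70
    # shortest skeleton chain usable as artifact evidence: after background
    # truncation a binarized tube overhangs its last reconstruction node by
    # ~2 voxels once the d_cover erosion is taken out, so shorter fragments
    # are indistinguishable from end-cap artifacts
    min_skeleton_len: float = 2.5

    def __post_init__(self):
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must lie in [0, 1]")
        for name in ("alpha", "beta", "Td", "D", "d_cover", "d_match"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class EnergyBreakdown:
    """Components of one connection energy evaluation."""

    delta_I: float
    delta_sigma: float
    theta: float
    U: float


@dataclass
class CandidateSet:
    """Candidate segments competing for connection to an anchor segment.

    ``candidates`` holds ``(segment, kind, distance)`` triples; the current
    segment is always a member (distance 0 allowed for it only).  ``Z`` is the
    partition energy, filled in by :func:`connection_probability`.
    """

    anchor_segment: BranchSegment
    candidates: list
    includes_current: bool = True
    Z: float | None = None


@dataclass
class ConfidenceResult:
    branch_id: int
    PG: float
    PL: float
    confidence: float
    low_confidence: bool


def connection_energy(
    featA: SegmentFeatures, featB: SegmentFeatures, theta: float, params: ConfidenceParams
) -> EnergyBreakdown:
    """Energy required to connect two segments (absolute-difference convention).

    The angular boundary is harmonized to "theta >= 90 degrees is illegal"
    (infinite energy): reverse growth never connects.
    """
    dI = abs(featA.mean_intensity - featB.mean_intensity)
    ds = abs(featA.intensity_sd - featB.intensity_sd)
    if theta >= 90.0:
        U = math.inf
    else:
        U = params.alpha * dI + params.beta * ds
    return EnergyBreakdown(dI, ds, theta, U)


def endpoint_distance(segA: BranchSegment, segB: BranchSegment) -> float:
    """Nearest Euclidean distance between the two segments' endpoints."""
    ea = segA.endpoints
    eb = segB.endpoints
    d = np.linalg.norm(ea[:, None, :] - eb[None, :, :], axis=-1)
    return float(d.min())


def build_candidate_set(
    segA: BranchSegment,
    segB: BranchSegment,
    other_segments,
    params: ConfidenceParams,
) -> CandidateSet:
    """Collect the segments competing with ``segB`` for connection to ``segA``.

    Membership: every segment whose nearest endpoint distance to ``segA`` lies
    strictly within (0, Td), plus the current segment ``segB`` itself.
    """
    cands = []
    for item in other_segments:
        seg, kind = (item if isinstance(item, tuple) else (item, item.kind))
        if seg is segB or seg is segA:
            continue
        d = endpoint_distance(segA, seg)
        if 0.0 < d < params.Td:
            cands.append((seg, kind, d))
    cands.append((segB, segB.kind, endpoint_distance(segA, segB)))
    return CandidateSet(anchor_segment=segA, candidates=cands, includes_current=True)


def connection_probability(
    segA: BranchSegment,
    segB: BranchSegment,
    cand: CandidateSet,
    vol: ImageVolume,
    params: ConfidenceParams,
    feature_fn=None,
) -> float:
    """P(segB | segA) = 1 - U(A, B) / Z(A) over the candidate set.

    Infinite-energy candidates (theta >= 90) are excluded from Z and receive
    probability 0.  If every finite candidate has exactly zero energy, the
    probability mass is split uniformly among them (the 0/0 limit convention);
    note that with a sole candidate the formula itself forces P = 0 whenever
    its energy is finite and non-zero.
    """
    feats = feature_fn or (lambda s: segment_intensity_stats(vol, s, normalize=True))
    featA = feats(segA)
    U_cur = None
    finite = []
    for seg, _kind, _d in cand.candidates:
        e = connection_energy(featA, feats(seg), angle_between(segA.direction, seg.direction), params)
        if seg is segB:
            U_cur = e.U
        if math.isfinite(e.U):
            finite.append(e.U)
    if U_cur is None:
        raise ValueError("candidate set does not contain the current segment")
    if not math.isfinite(U_cur):
        return 0.0
    Z = float(sum(finite))
    cand.Z = Z
    if Z <= 0.0:
        # all finite candidates cost nothing: uniform split among them
        return 1.0 / len(finite) if U_cur == 0.0 else 0.0
    return float(np.clip(1.0 - U_cur / Z, 0.0, 1.0))


class ConfidenceContext:
    """Precomputed state shared by the confidence and detection passes.

    Holds the tree, its branch decomposition, directed segments (proximal,
    distal and per-branch chains), image features and the skeleton segments
    extracted from the image, and caches intensity features per segment.
    """

    def __init__(
        self,
        tree: NeuronTree,
        branches: list[Branch],
        vol: ImageVolume,
        mask: TubularityMask | None,
        params: ConfidenceParams,
        skeleton_segments: list[BranchSegment] | None = None,
    ):
        self.tree = tree
        self.branches = branches
        self.by_id = {b.branch_id: b for b in branches}
        self.vol = vol
        self.mask = mask
        self.params = params
        self.skeleton_segments = list(skeleton_segments or [])
        self._feat_cache: dict[int, SegmentFeatures] = {}
        self.proximal: dict[int, BranchSegment] = {}
        self.distal: dict[int, BranchSegment] = {}
        self.chains: dict[int, list[BranchSegment]] = {}
        self.samples: dict[int, np.ndarray] = {}
        for b in branches:
            self.proximal[b.branch_id] = extract_segment(tree, b, "proximal", params.L)
            self.distal[b.branch_id] = extract_segment(tree, b, "distal", params.L)
            self.chains[b.branch_id] = chain_segments(tree, b, params.L)
            self.samples[b.branch_id], _ = resample_polyline(tree.coords(b.node_path), 1.0)
        self._results: dict[int, ConfidenceResult] = {}

    # -- feature cache ----------------------------------------------------
    def features(self, seg: BranchSegment) -> SegmentFeatures:
        key = id(seg)
        f = self._feat_cache.get(key)
        if f is None:
            f = segment_intensity_stats(self.vol, seg, normalize=True)
            self._feat_cache[key] = f
        return f

    # -- candidate pools --------------------------------------------------
    def pool(self, exclude_branches=(), include_skeleton: bool = True) -> list[BranchSegment]:
        """All chain segments of branches outside ``exclude_branches``, plus
        skeleton segments.  Distance filtering happens in build_candidate_set."""
        out: list[BranchSegment] = []
        excl = set(exclude_branches)
        for b in self.branches:
            if b.branch_id in excl:
                continue
            out.extend(self.chains[b.branch_id])
        if include_skeleton:
            out.extend(self.skeleton_segments)
        return out

    def probability(self, segA: BranchSegment, segB: BranchSegment, pool) -> float:
        cand = build_candidate_set(segA, segB, pool, self.params)
        return connection_probability(segA, segB, cand, self.vol, self.params, feature_fn=self.features)

    # -- per-branch confidences -------------------------------------------
    def global_confidence(self, branch: Branch) -> float:
        """PG: probability that the parent's distal segment connects to this
        branch's proximal segment, against nearby branch and skeleton segments."""
        if branch.parent_branch_id is None:
            return 1.0  # soma-attached branch: no parent pair to score
        parent = self.by_id[branch.parent_branch_id]
        segA = self.distal[parent.branch_id]
        segB = self.proximal[branch.branch_id]
        # candidate set = every segment within Td of the anchor, including the
        # child's own later chunks (they are potential connections too); only
        # the parent's own pieces are excluded — they are the anchor's
        # upstream structure, not rivals for the connection
        pool = self.pool(exclude_branches={parent.branch_id})
        return self.probability(segA, segB, pool)

    def local_confidence(self, branch: Branch) -> float:
        """PL: aggregate of per-segment connection probabilities along the
        branch's own chain, each conditioned on its predecessor segment."""
        chain = self.chains[branch.branch_id]
        if not chain:
            return 1.0
        # the parent's pieces are the anchor's upstream structure and are
        # excluded; everything else within Td competes, including the
        # branch's own downstream chunks
        excl = set()
        if branch.parent_branch_id is not None:
            excl.add(branch.parent_branch_id)
        pool = self.pool(exclude_branches=excl)
        probs = []
        for i, seg in enumerate(chain):
            if i == 0:
                if branch.parent_branch_id is None:
                    probs.append(1.0)  # root chain start: nothing to condition on
                    continue
                pred = self.distal[self.by_id[branch.parent_branch_id].branch_id]
            else:
                pred = chain[i - 1]
            # own other chain pieces are parts of this same branch, not rivals
            step_pool = [s for s in pool if s is not pred]
            probs.append(self.probability(pred, seg, step_pool))
        if self.params.pl_sum:
            return float(sum(probs))
        return float(np.mean(probs))

    def branch_confidence(self, branch: Branch) -> ConfidenceResult:
        res = self._results.get(branch.branch_id)
        if res is None:
            pg = self.global_confidence(branch)
            pl = self.local_confidence(branch)
            conf = min(pg, pl)
            res = ConfidenceResult(branch.branch_id, pg, pl, conf, conf < self.params.tau)
            self._results[branch.branch_id] = res
        return res
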