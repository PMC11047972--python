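"""The five artifact detectors and the per-branch classification pass.

Artifact taxonomy: over-tracing (spurious branch; reverse angle or no image
support), branch-skeleton connection error (branch rerouted onto interference
while its true continuation remains in the image), branch-branch connection
error (child attached to the wrong reconstructed branch), branch missing
(image structure absent from the reconstruction) and incomplete tracing
(premature termination of a terminal branch).  Over-tracing and
branch-skeleton errors are *global* and transitive: descendants of an
affected branch inherit the artifact and are not labeled independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .confidence import (
    ConfidenceContext,
    ConfidenceParams,
    ConfidenceResult,
    connection_energy,
    endpoint_distance,
)
from .image_features import ImageVolume, branch_has_tubularity
from .neuron_model import Branch, BranchSegment, NeuronTree, angle_between, decompose_branches
from .skeleton import SkeletonBranch, extract_skeleton_branches, skeleton_end_segments

__all__ = [
    "ArtifactLabel",
    "LegalityAngles",
    "BranchRecord",
    "SkeletonRecord",
    "ArtifactReport",
    "connection_legality",
    "detect_over_tracing",
    "detect_conn_err_branch_skeleton",
    "detect_conn_err_branch_branch",
    "detect_incomplete_tracing",
    "detect_branch_missing",
    "classify_branches",
]


class ArtifactLabel(Enum):
    NONE = "none"
    OVER_TRACING = "over_tracing"
    CONN_ERR_BRANCH_SKELETON = "conn_err_branch_skeleton"
    CONN_ERR_BRANCH_BRANCH = "conn_err_branch_branch"
    BRANCH_MISSING = "branch_missing"
    INCOMPLETE_TRACING = "incomplete_tracing"
    LOW_CONFIDENCE = "low_confidence"
    CONFIRMED = "confirmed"


#: artifacts inherited by all descendants of an affected branch
TRANSITIVE = {ArtifactLabel.OVER_TRACING, ArtifactLabel.CONN_ERR_BRANCH_SKELETON}


@dataclass
class LegalityAngles:
    theta: float
    phi: float
    omega: float


@dataclass
class BranchRecord:
    branch_id: int
    label: ArtifactLabel
    confidence: ConfidenceResult | None
    evidence: dict | None = None
    inherited: bool = False


@dataclass
class SkeletonRecord:
    skeleton_id: int
    role: str = "unused"  # missing-branch hint | reroute hint | gap hint | unused


@dataclass
class ArtifactReport:
    branch_records: list[BranchRecord] = field(default_factory=list)
    skeleton_records: list[SkeletonRecord] = field(default_factory=list)
    skeletons: list[SkeletonBranch] = field(default_factory=list)
    confidences: dict = field(default_factory=dict)

    def record(self, branch_id: int) -> BranchRecord:
        for r in self.branch_records:
            if r.branch_id == branch_id:
                return r
        raise KeyError(branch_id)

    def labels(self) -> dict[int, ArtifactLabel]:
        return {r.branch_id: r.label for r in self.branch_records}


def _oriented_away(seg: BranchSegment, near_idx: int) -> np.ndarray:
    """Segment direction oriented to point away from the given endpoint."""
    d = seg.direction
    # endpoints[0] is points[0]; direction points toward free_end
    points_toward_0 = np.allclose(seg.free_end, seg.points[0])
    if near_idx == 0:
        return d if not points_toward_0 else -d
    return -d if not points_toward_0 else d


def connection_legality(seg_cur: BranchSegment, seg_skel: BranchSegment):
    """Geometric legality of bridging seg_cur's free end to a skeleton segment.

    g runs from the current segment's free endpoint to the skeleton's nearest
    endpoint; theta = angle(cur direction, g), phi = angle(g, skeleton
    direction oriented away from the gap), omega = angle between the two
    directions.  Legal iff all three are <= 90 degrees (inclusive).
    """
    free = seg_cur.free_end
    ends = seg_skel.endpoints
    dists = np.linalg.norm(ends - free, axis=1)
    near = int(np.argmin(dists))
    g = ends[near] - free
    if np.linalg.norm(g) < 1e-9:
        g = seg_cur.direction
    away = _oriented_away(seg_skel, near)
    theta = angle_between(seg_cur.direction, g)
    phi = angle_between(g, away)
    omega = angle_between(seg_cur.direction, away)
    angles = LegalityAngles(theta, phi, omega)
    legal = theta <= 90.0 + 1e-9 and phi <= 90.0 + 1e-9 and omega <= 90.0 + 1e-9
    return legal, angles


def _parent_child_angle(ctx: ConfidenceContext, branch: Branch) -> float:
    parent = ctx.by_id[branch.parent_branch_id]
    return angle_between(ctx.distal[parent.branch_id].direction, ctx.proximal[branch.branch_id].direction)


def detect_over_tracing(ctx: ConfidenceContext, branch: Branch) -> bool:
    """Reverse-angle attachment (theta >= 90) or absent image support."""
    if branch.parent_branch_id is None:
        return False
    if _parent_child_angle(ctx, branch) >= 90.0:
        return True
    pts = ctx.tree.coords(branch.node_path)
    return not branch_has_tubularity(ctx.mask, pts, ctx.params.tubularity_fraction)


def _energy(ctx: ConfidenceContext, segA: BranchSegment, segB: BranchSegment) -> float:
    e = connection_energy(
        ctx.features(segA), ctx.features(segB), angle_between(segA.direction, segB.direction), ctx.params
    )
    return e.U


def detect_conn_err_branch_skeleton(ctx: ConfidenceContext, branch: Branch):
    """A legal, tubular skeleton segment near the parent connects better than
    the current child (by more than the energy margin)."""
    if branch.parent_branch_id is None:
        return False, None
    parent = ctx.by_id[branch.parent_branch_id]
    segA = ctx.distal[parent.branch_id]
    cur = ctx.proximal[branch.branch_id]
    U_cur = _energy(ctx, segA, cur)
    best = None
    for seg in ctx.skeleton_segments:
        d = endpoint_distance(segA, seg)
        if not (0.0 < d < ctx.params.Td):
            continue
        legal, _ = connection_legality(segA, seg)
        if not legal:
            continue
        U = _energy(ctx, segA, seg)
        if not math.isfinite(U):
            continue
        if U + ctx.params.energy_margin < U_cur and (best is None or U < best[0]):
            best = (U, seg)
    if best is None:
        return False, None
    U, seg = best
    return True, {
        "skeleton_id": seg.owner,
        "U_current": U_cur,
        "U_skeleton": U,
    }


def detect_conn_err_branch_branch(ctx: ConfidenceContext, branch: Branch):
    """A segment of another reconstructed branch connects to the parent better
    than the current child (by more than the energy margin)."""
    if branch.parent_branch_id is None:
        return False, None
    parent = ctx.by_id[branch.parent_branch_id]
    segA = ctx.distal[parent.branch_id]
    cur = ctx.proximal[branch.branch_id]
    U_cur = _energy(ctx, segA, cur)
    best = None
    for b in ctx.branches:
        if b.branch_id in (branch.branch_id, parent.branch_id):
            continue
        for seg in ctx.chains[b.branch_id]:
            # Td bounds the search; distance 0 (sharing the junction point)
            # is allowed here — the true continuation is a valid rival
            d = endpoint_distance(segA, seg)
            if d >= ctx.params.Td:
                continue
            U = _energy(ctx, segA, seg)
            if not math.isfinite(U):
                continue
            if U + ctx.params.energy_margin < U_cur and (best is None or U < best[0]):
                best = (U, b.branch_id)
    if best is None:
        return False, None
    U, bid = best
    return True, {"other_branch_id": bid, "U_current": U_cur, "U_other": U}


def detect_incomplete_tracing(ctx: ConfidenceContext, branch: Branch, skeleton_branches):
    """A tubular skeleton branch continues legally within D of a terminal tip."""
    if not branch.is_terminal:
        return False, None
    seg = ctx.distal[branch.branch_id]
    tip = seg.anchor
    for sk in skeleton_branches:
        if not sk.tubular or sk.length < ctx.params.min_skeleton_len:
            continue
        d = float(np.linalg.norm(sk.endpoints - tip, axis=1).min())
        if d >= ctx.params.D:
            continue
        for s in skeleton_end_segments(sk, ctx.params.L):
            legal, _ = connection_legality(seg, s)
            if legal:
                return True, {"skeleton_id": sk.skeleton_id, "gap": d}
    return False, None


def _attachment_segment(ctx: ConfidenceContext, point: np.ndarray):
    """Host-side branching segment for a putative mid-branch attachment.

    Finds the reconstruction sample nearest ``point`` over all branches and
    builds a distal-style segment ending there: anchored at the attachment
    sample, directed along the branch's growth *into* it — the same geometry
    a parent's distal segment has at a true branching point.
    """
    best = None
    for b in ctx.branches:
        s = ctx.samples[b.branch_id]
        d = np.linalg.norm(s - point, axis=1)
        i = int(np.argmin(d))
        if best is None or d[i] < best[0]:
            best = (float(d[i]), b.branch_id, i)
    if best is None:
        return None
    d, bid, i = best
    s = ctx.samples[bid]
    lo = max(i - (ctx.params.L - 1), 0)
    window = s[lo : i + 1][::-1]  # anchor (attachment sample) first
    if len(window) < 2:
        window = s[i : i + 2][::-1] if i + 2 <= len(s) else s[max(i - 1, 0) : i + 1][::-1]
    if len(window) < 2:
        return None
    chord = window[0] - window[-1]
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        return None
    seg = BranchSegment(
        branch_id=bid,
        anchor=window[0].copy(),
        points=window.copy(),
        direction=chord / norm,  # growth direction into the attachment point
        end="distal",
    )
    return d, bid, seg


def detect_branch_missing(ctx: ConfidenceContext, sk: SkeletonBranch, other_skeletons):
    """Is this tubular skeleton chain an isolated, unreconstructed branch?

    It must (a) connect to its nearest reconstructed branch segment with
    lower energy than to every competing skeleton segment in range, (b) be
    longer than those competitors, and (c) connect legally.  The host is the
    nearest reconstructed branch.
    """
    if not sk.tubular or sk.length < ctx.params.min_skeleton_len:
        return False, None
    segs = skeleton_end_segments(sk, ctx.params.L)
    if not segs:
        return False, None
    best_host = None
    for sk_seg in segs:
        host = _attachment_segment(ctx, sk_seg.anchor)
        if host is None:
            continue
        d, bid, host_seg = host
        if d >= ctx.params.Td:
            continue
        legal, _ = connection_legality(host_seg, sk_seg)
        if not legal:
            continue
        # energy of attaching this skeleton to the host: the skeleton plays
        # the child role, the host attachment segment the parent role
        U_host = _energy(ctx, host_seg, sk_seg)
        if not math.isfinite(U_host):
            continue
        out_seg = BranchSegment(
            branch_id=-1,
            anchor=sk_seg.anchor.copy(),
            points=sk_seg.points.copy(),
            direction=-sk_seg.direction,  # pointing out of the chain
            end="distal",
            kind="skeleton",
            owner=sk.skeleton_id,
        )
        ok = True
        for other in other_skeletons:
            if other.skeleton_id == sk.skeleton_id:
                continue
            if not other.tubular or other.length < ctx.params.min_skeleton_len:
                continue  # below the evidence floor; not a real competitor
            osegs = skeleton_end_segments(other, ctx.params.L)
            if not osegs:
                continue
            od = min(endpoint_distance(sk_seg, s) for s in osegs)
            if od >= ctx.params.Td:
                continue
            U_other = min(_energy(ctx, out_seg, s) for s in osegs)
            if U_other <= U_host or other.length >= sk.length:
                ok = False
                break
        if ok and (best_host is None or U_host < best_host[0]):
            best_host = (U_host, bid, d)
    if best_host is None:
        return False, None
    U_host, bid, d = best_host
    return True, {"host_branch_id": bid, "distance": d, "U_host": U_host}


def classify_branches(
    tree: NeuronTree,
    vol: ImageVolume,
    params: ConfidenceParams | None = None,
    *,
    soma_center=None,
    soma_radius: float | None = None,
    confirmed=(),
    skeleton_kwargs: dict | None = None,
) -> ArtifactReport:
    """Run the full detect pass: one label per branch, plus skeleton roles.

    Branches are visited breadth-first; global detectors (over-tracing,
    branch-skeleton error) run before local ones (branch-branch error,
    incomplete tracing); descendants of a branch carrying a transitive
    artifact inherit it.  Branch-missing detection runs per skeleton branch
    and attaches to otherwise unlabeled host branches.  Remaining branches
    below the confidence threshold are marked low-confidence.
    """
    params = params or ConfidenceParams()
    branches = decompose_branches(tree)
    report = ArtifactReport()
    if not branches:
        return report
    if soma_center is None:
        soma_center = tree.root.pos
    if soma_radius is None:
        soma_radius = max(float(tree.root.radius), 1.0)
    skeleton_kwargs = dict(skeleton_kwargs or {})
    skeleton_kwargs.setdefault("d_cover", params.d_cover)
    skeleton_kwargs.setdefault("tubularity_fraction", params.tubularity_fraction)
    skeletons, mask, _box = extract_skeleton_branches(
        vol, tree, soma_center, soma_radius, **skeleton_kwargs
    )
    sk_segs = []
    for sk in skeletons:
        if sk.tubular and sk.length >= params.min_skeleton_len:
            sk_segs.extend(skeleton_end_segments(sk, params.L))
    ctx = ConfidenceContext(tree, branches, vol, mask, params, skeleton_segments=sk_segs)
    confirmed = set(confirmed)

    records: dict[int, BranchRecord] = {}
    transitive_carrier: dict[int, ArtifactLabel] = {}
    used_skeletons: dict[int, str] = {}

    for branch in branches:  # decompose_branches yields BFS order
        conf = ctx.branch_confidence(branch)
        if branch.branch_id in confirmed:
            records[branch.branch_id] = BranchRecord(branch.branch_id, ArtifactLabel.CONFIRMED, conf)
            continue
        # inherit transitive artifacts from the nearest affected ancestor
        pid = branch.parent_branch_id
        if pid is not None and pid in transitive_carrier:
            label = transitive_carrier[pid]
            records[branch.branch_id] = BranchRecord(
                branch.branch_id, label, conf, evidence={"inherited_from": pid}, inherited=True
            )
            transitive_carrier[branch.branch_id] = label
            continue
        label = ArtifactLabel.NONE
        evidence = None
        if detect_over_tracing(ctx, branch):
            label = ArtifactLabel.OVER_TRACING
            evidence = {"theta": _parent_child_angle(ctx, branch)}
        else:
            hit, ev = detect_conn_err_branch_skeleton(ctx, branch)
            if hit:
                label = ArtifactLabel.CONN_ERR_BRANCH_SKELETON
                evidence = ev
                used_skeletons[ev["skeleton_id"]] = "reroute hint"
            else:
                hit, ev = detect_conn_err_branch_branch(ctx, branch)
                if hit:
                    label = ArtifactLabel.CONN_ERR_BRANCH_BRANCH
                    evidence = ev
                else:
                    hit, ev = detect_incomplete_tracing(ctx, branch, skeletons)
                    if hit:
                        label = ArtifactLabel.INCOMPLETE_TRACING
                        evidence = ev
                        used_skeletons[ev["skeleton_id"]] = "gap hint"
        records[branch.branch_id] = BranchRecord(branch.branch_id, label, conf, evidence=evidence)
        if label in TRANSITIVE:
            transitive_carrier[branch.branch_id] = label

    # branch-missing pass: attach to unlabeled hosts
    for sk in sorted(skeletons, key=lambda s: -s.length):
        if sk.skeleton_id in used_skeletons:
            continue
        hit, ev = detect_branch_missing(ctx, sk, skeletons)
        if not hit:
            continue
        host = records[ev["host_branch_id"]]
        if host.label in (ArtifactLabel.NONE, ArtifactLabel.LOW_CONFIDENCE):
            host.label = ArtifactLabel.BRANCH_MISSING
            host.evidence = dict(ev, skeleton_id=sk.skeleton_id)
            used_skeletons[sk.skeleton_id] = "missing-branch hint"

    # remaining clean branches below the confidence threshold
    for rec in records.values():
        if rec.label is ArtifactLabel.NONE and rec.confidence is not None and rec.confidence.low_confidence:
            rec.label = ArtifactLabel.LOW_CONFIDENCE

    report.branch_records = [records[b.branch_id] for b in branches]
    report.skeleton_records = [
        SkeletonRecord(sk.skeleton_id, used_skeletons.get(sk.skeleton_id, "unused")) for sk in skeletons
    ]
    report.skeletons = skeletons
    report.confidences = {b.branch_id: records[b.branch_id].confidence for b in branches}
    return report
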