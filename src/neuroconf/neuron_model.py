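"""SWC tree representation and decomposition into branches and branching segments.

A reconstruction is a rooted tree of :class:`NeuronNode`.  For confidence
calculation it is decomposed into *branches* — maximal paths free of interior
branching points — and each branch yields fixed-length, directed *branching
segments* resampled at unit arc-length spacing.  Segments are the units of the
Markov-chain connection model: the growth of a child branch is assumed to
depend only on the state of its parent's distal segment.

Coordinate convention: all point coordinates in this package are ``(x, y, z)``
floating-point voxel positions (0-based); image grids are indexed ``[z, y, x]``
(see :mod:`neuroconf.io`).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSegmentError, InvalidDirectionError, StructuralError

__all__ = [
    "NeuronNode",
    "NeuronTree",
    "Branch",
    "BranchSegment",
    "decompose_branches",
    "extract_segment",
    "resample_polyline",
    "angle_between",
]


@dataclass
class NeuronNode:
    """One SWC sample: position, radius and parent link."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class NeuronTree:
    """A rooted, acyclic SWC reconstruction.

    Parameters
    ----------
    nodes:
        Iterable of :class:`NeuronNode`.  Ids must be unique, exactly one node
        must have ``parent_id == -1``, and every other ``parent_id`` must refer
        to an existing node without creating a cycle.
    """

    def __init__(self, nodes):
        self.nodes: list[NeuronNode] = list(nodes)
        self._index: dict[int, NeuronNode] = {}
        for n in self.nodes:
            if n.id in self._index:
                raise StructuralError(f"duplicate node id {n.id}")
            if n.id == n.parent_id:
                raise StructuralError(f"node {n.id} is its own parent")
            if not np.isfinite([n.x, n.y, n.z]).all():
                raise StructuralError(f"node {n.id} has non-finite coordinates")
            self._index[n.id] = n
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root, found {len(roots)}")
        self.soma_id: int = roots[0].id
        self._children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                if n.parent_id not in self._index:
                    raise StructuralError(f"node {n.id} has missing parent {n.parent_id}")
                self._children[n.parent_id].append(n.id)
        for kids in self._children.values():
            kids.sort()
        # reachability from root == acyclic + connected
        seen = set()
        stack = [self.soma_id]
        while stack:
            nid = stack.pop()
            seen.add(nid)
            stack.extend(self._children[nid])
        if len(seen) != len(self.nodes):
            raise StructuralError("tree is not connected from the root (cycle or orphan)")

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, nid: int) -> NeuronNode:
        return self._index[nid]

    def children(self, nid: int) -> list[int]:
        return self._children[nid]

    @property
    def root(self) -> NeuronNode:
        return self._index[self.soma_id]

    def coords(self, ids=None) -> np.ndarray:
        """(N, 3) array of (x, y, z) positions, in node order or for ``ids``."""
        if ids is None:
            return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)
        return np.array([[self._index[i].x, self._index[i].y, self._index[i].z] for i in ids], dtype=float)

    def copy(self) -> "NeuronTree":
        return NeuronTree(
            NeuronNode(n.id, n.type_code, n.x, n.y, n.z, n.radius, n.parent_id) for n in self.nodes
        )


@dataclass
class Branch:
    """A maximal branching-point-free path of the reconstruction.

    ``node_path`` runs from the proximal anchor (a branching point, or the
    soma for level-0 branches) to the distal end (the next branching point or
    a terminal).  The anchor node is shared with the parent branch.
    """

    branch_id: int
    node_path: list[int]
    parent_branch_id: int | None
    level: int
    is_terminal: bool

    def __len__(self) -> int:
        return len(self.node_path)


@dataclass
class BranchSegment:
    """A fixed-length directed branching segment.

    ``points`` are resampled at unit arc-length spacing; ``points[0]`` is the
    anchor (the branching point the segment emanates from).  ``direction`` is
    the unit chord: for a child/proximal segment it points from the anchor into
    the branch (growth direction); for a parent/distal segment it points from
    the interior toward the anchor, i.e. the growth direction *into* the
    branching point.
    """

    branch_id: int
    anchor: np.ndarray
    points: np.ndarray  # (n, 3), points[0] == anchor
    direction: np.ndarray  # unit vector
    end: str  # "proximal" | "distal" | "chain"
    short: bool = False
    kind: str = "branch"  # "branch" | "skeleton"
    owner: int | None = None  # skeleton id when kind == "skeleton"

    @property
    def endpoints(self) -> np.ndarray:
        return np.array([self.points[0], self.points[-1]])

    @property
    def free_end(self) -> np.ndarray:
        """The endpoint the direction vector points toward."""
        return self.points[0] if self.end == "distal" else self.points[-1]


def decompose_branches(tree: NeuronTree) -> list[Branch]:
    """Split a tree into hierarchical branches, breadth-first from the soma.

    Every non-root node belongs to exactly one branch; branching points are
    shared as the anchor of each child branch.  Levels count bifurcations from
    the soma (soma branch = 0).  Branch ids are assigned in BFS order, children
    in node-id order.
    """
    branches: list[Branch] = []
    # queue of (anchor node id, first child id on the branch, parent branch id, level)
    queue: deque = deque()
    for cid in tree.children(tree.soma_id):
        queue.append((tree.soma_id, cid, None, 0))
    if not queue and len(tree) == 1:
        return []
    while queue:
        anchor, first, parent_bid, level = queue.popleft()
        path = [anchor, first]
        cur = first
        while True:
            kids = tree.children(cur)
            if len(kids) == 1:
                cur = kids[0]
                path.append(cur)
            else:
                break
        bid = len(branches)
        kids = tree.children(cur)
        branches.append(Branch(bid, path, parent_bid, level, is_terminal=not kids))
        for cid in kids:
            queue.append((cur, cid, bid, level + 1))
    return branches


def resample_polyline(points: np.ndarray, spacing: float = 1.0, max_points: int | None = None):
    """Resample a polyline at fixed arc-length spacing.

    Returns ``(samples, total_arc_length)``.  The first sample coincides with
    ``points[0]``; samples are placed every ``spacing`` units of arc length,
    optionally capped at ``max_points``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 1:
        raise DegenerateSegmentError("polyline needs at least one point")
    if len(pts) == 1:
        return pts.copy(), 0.0
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = float(cum[-1])
    n = int(np.floor(total / spacing + 1e-9)) + 1
    if max_points is not None:
        n = min(n, max_points)
    targets = np.arange(n) * spacing
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, cum, pts[:, k])
    return out, total


def extract_segment(tree: NeuronTree, branch: Branch, end: str, L: int) -> BranchSegment:
    """Extract the fixed-length directed branching segment at one end of a branch.

    The segment holds ``L`` points at unit arc-length spacing (so it spans
    ``L - 1`` voxels of arc).  If the branch is shorter, the whole branch is
    used and ``short`` is set.

    ``end="proximal"``: anchored at the branching point, directed distally
    (a child segment).  ``end="distal"``: anchored at the distal end, points
    walking back proximally, direction = growth *into* the distal point (a
    parent segment).
    """
    if L < 2:
        raise ValueError("segment length L must be >= 2")
    if len(branch.node_path) < 2:
        raise DegenerateSegmentError(f"branch {branch.branch_id} has fewer than 2 nodes")
    coords = tree.coords(branch.node_path)
    if end == "proximal":
        poly = coords
    elif end == "distal":
        poly = coords[::-1]
    else:
        raise ValueError(f"unknown segment end {end!r}")
    samples, total = resample_polyline(poly, 1.0, max_points=L)
    if len(samples) < 2:
        raise DegenerateSegmentError(f"branch {branch.branch_id} is degenerate (arc length ~0)")
    short = total < (L - 1) - 1e-9
    chord = samples[-1] - samples[0]
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        raise DegenerateSegmentError(f"branch {branch.branch_id} segment has zero chord")
    if end == "proximal":
        direction = chord / norm
    else:
        direction = -chord / norm  # toward the anchor = into the branching point
    return BranchSegment(
        branch_id=branch.branch_id,
        anchor=samples[0].copy(),
        points=samples,
        direction=direction,
        end=end,
        short=short,
    )


def chain_segments(tree: NeuronTree, branch: Branch, L: int) -> list[BranchSegment]:
    """Chop a branch into consecutive directed segments of ``L`` points each.

    These are the per-branch Markov-chain states used by the local confidence:
    every segment is anchored at its proximal sample and directed distally; the
    last chunk may be shorter (but keeps >= 2 points, merging into the previous
    chunk if necessary).
    """
    coords = tree.coords(branch.node_path)
    samples, _total = resample_polyline(coords, 1.0)
    if len(samples) < 2:
        raise DegenerateSegmentError(f"branch {branch.branch_id} is degenerate")
    out: list[BranchSegment] = []
    start = 0
    n = len(samples)
    while start < n - 1:
        stop = min(start + L, n)
        if n - stop == 1:  # avoid leaving a single orphan sample
            stop = n
        pts = samples[start:stop]
        chord = pts[-1] - pts[0]
        norm = np.linalg.norm(chord)
        if norm < 1e-12:
            break
        out.append(
            BranchSegment(
                branch_id=branch.branch_id,
                anchor=pts[0].copy(),
                points=pts,
                direction=chord / norm,
                end="chain",
                short=len(pts) < L,
            )
        )
        start = stop - 1  # consecutive chunks share their junction sample
    return out


def angle_between(d1, d2) -> float:
    """Angle between two direction vectors, in degrees within [0, 180]."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n1 = np.linalg.norm(d1)
    n2 = np.linalg.norm(d2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise InvalidDirectionError("zero-length direction vector")
    c = float(np.dot(d1, d2) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
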