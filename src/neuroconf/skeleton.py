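"""Extraction of candidate unreconstructed skeleton branches from the image.

Pipeline: weak-signal enhancement -> extended bounding box -> fixed-threshold
binarization -> topology-preserving 3D thinning -> Frangi vesselness gating ->
soma removal -> branching/isolated point removal -> coverage filtering against
the reconstruction -> linking of the survivors into undirected skeleton
branches.  A skeleton branch is image evidence of structure the reconstruction
does not explain, and feeds the artifact detectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .image_features import ImageVolume, TubularityMask
from .neuron_model import BranchSegment, NeuronTree, resample_polyline

__all__ = [
    "BoundingBoxExt",
    "SkeletonPointSet",
    "SkeletonBranch",
    "enhance",
    "extended_bbox",
    "binarize",
    "thin3d",
    "frangi_response",
    "vesselness",
    "remove_soma_region",
    "filter_skeleton_points",
    "link_skeleton_branches",
    "extract_skeleton_branches",
    "skeleton_end_segments",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BoundingBoxExt:
    """Axis-aligned box in voxel indices, (z, y, x) order, lo inclusive / hi exclusive."""

    lo: np.ndarray
    hi: np.ndarray
    margin: int

    def slices(self):
        return tuple(slice(int(a), int(b)) for a, b in zip(self.lo, self.hi))


@dataclass
class SkeletonPointSet:
    """Integer skeleton voxels, stored as an (N, 3) array in (x, y, z) order."""

    points: np.ndarray
    source_box: BoundingBoxExt | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=int).reshape(-1, 3)

    def __len__(self):
        return len(self.points)

    def as_set(self):
        return {tuple(p) for p in self.points}


@dataclass
class SkeletonBranch:
    """An undirected simple chain of 26-adjacent skeleton voxels."""

    skeleton_id: int
    chain: np.ndarray  # (N, 3) int, (x, y, z), ordered endpoint to endpoint
    length: float
    endpoints: np.ndarray
    tubular: bool = True

    def __post_init__(self):
        self.chain = np.asarray(self.chain, dtype=int).reshape(-1, 3)


def _derivative_truncation_point(data: np.ndarray, pct_lo: float, pct_hi: float) -> float:
    """Lower truncation intensity: where the histogram's derivative flattens
    just past the background mode.

    Microscopy stacks are background-dominated; clipping at the point where
    the (smoothed) intensity histogram stops falling steeply removes the
    background peak and its noise tail, so the subsequent gamma lift boosts
    weak *signal* rather than noise.  Falls back to the ``pct_lo`` percentile
    when no flattening point is found below the median.
    """
    lo_floor = float(np.percentile(data, pct_lo))
    hist, edges = np.histogram(data, bins=256)
    smooth = ndi.gaussian_filter1d(hist.astype(np.float64), 2.0)
    mode = int(np.argmax(smooth))
    # a background cut only makes sense when the histogram has a dominant
    # peak; otherwise (flat/uniform images) fall back to the percentile floor
    if smooth[mode] < 5.0 * max(float(np.median(smooth)), 1.0):
        return lo_floor
    d = np.diff(smooth)
    tail = d[mode:]
    if len(tail) == 0:
        return float(lo_floor)
    # walk past the steepest part of the background peak's falling flank,
    # then stop where the histogram flattens out (background tail exhausted)
    steep = int(np.argmin(tail))
    mag = abs(tail[steep])
    if mag <= 0:
        return float(lo_floor)
    flat = np.nonzero(np.abs(tail[steep:]) < 0.01 * mag)[0]
    if len(flat) == 0:
        return float(lo_floor)
    lo = float(edges[mode + steep + flat[0] + 1])
    return max(lo, lo_floor)


def enhance(vol: ImageVolume, gamma: float = 0.6, pct_lo: float = 1.0, pct_hi: float = 99.5) -> ImageVolume:
    """Derivative-truncated gamma enhancement of weak tube signal.

    Intensities are clipped to a window whose lower edge is the histogram-
    derivative truncation point (bounded below by the ``pct_lo`` percentile)
    and whose upper edge is the ``pct_hi`` percentile, rescaled to [0, 1],
    raised to ``gamma`` (< 1 boosts weak signal) and mapped back to the
    window — a monotone transform.  A constant image is returned unchanged.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    data = vol.data.astype(np.float32)
    hi = float(np.percentile(data, pct_hi))
    lo = _derivative_truncation_point(data, pct_lo, pct_hi)
    if hi <= lo:
        return ImageVolume(data.copy(), vol.dtype_max)
    out = np.clip(data, lo, hi)
    out = (out - lo) / (hi - lo)
    np.power(out, gamma, out=out)
    out = out * (hi - lo) + lo
    return ImageVolume(out, vol.dtype_max)


def extended_bbox(points, margin: int, vol_shape) -> BoundingBoxExt:
    """Extended bounding box of a set of (x, y, z) points, clipped to the volume.

    The dilation by ``margin`` retains the image context of the current branch
    and its neighbors.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if margin < 0:
        raise ValueError("margin must be >= 0")
    zyx = pts[:, ::-1]
    lo = np.maximum(np.floor(zyx.min(axis=0)).astype(int) - margin, 0)
    hi = np.minimum(np.ceil(zyx.max(axis=0)).astype(int) + margin + 1, np.asarray(vol_shape, dtype=int))
    return BoundingBoxExt(lo=lo, hi=hi, margin=margin)


def binarize(vol: ImageVolume, k: float = 0.5) -> np.ndarray:
    """Foreground = voxels strictly above mean + k * SD of the (sub)volume."""
    data = vol.data
    thr = float(data.mean()) + k * float(data.std())
    return data > thr


# --- simple-point machinery for topology-preserving thinning ---------------

# fixed enumeration of the 3x3x3 neighborhood (center last, excluded from code)
_NB_OFF = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)],
    dtype=int,
)
_POW2 = (1 << np.arange(26)).astype(np.int64)
_N18_IDX = [i for i, o in enumerate(_NB_OFF) if np.abs(o).sum() <= 2]
_N6_IDX = [i for i, o in enumerate(_NB_OFF) if np.abs(o).sum() == 1]


def _components(idx_list, adjacency, active):
    """Connected components over a tiny fixed graph; returns component count."""
    seen = set()
    ncomp = 0
    for i in idx_list:
        if i not in active or i in seen:
            continue
        ncomp += 1
        stack = [i]
        seen.add(i)
        while stack:
            j = stack.pop()
            for k in adjacency[j]:
                if k in active and k not in seen:
                    seen.add(k)
                    stack.append(k)
    return ncomp


def _build_adjacency():
    off = _NB_OFF
    adj26 = {i: [] for i in range(26)}
    adj6_18 = {i: [] for i in _N18_IDX}
    for i in range(26):
        for j in range(26):
            if i == j:
                continue
            d = np.abs(off[i] - off[j])
            if d.max() <= 1:
                adj26[i].append(j)
    for i in _N18_IDX:
        for j in _N18_IDX:
            if i == j:
                continue
            if np.abs(off[i] - off[j]).sum() == 1:
                adj6_18[i].append(j)
    return adj26, adj6_18


_ADJ26, _ADJ6_18 = _build_adjacency()
_SIMPLE_LUT: dict = {}


def _is_simple(code: int) -> bool:
    """Malandain-Bertrand characterization of a (26, 6)-simple point.

    Deleting the center preserves topology iff its foreground 26-neighbors
    form exactly one 26-component and its background 6-neighbors form
    exactly one 6-component within the 18-neighborhood that touches a face.
    Memoized on the 26-bit neighborhood pattern.
    """
    cached = _SIMPLE_LUT.get(code)
    if cached is not None:
        return cached
    fg = {i for i in range(26) if code >> i & 1}
    ok = False
    if fg:
        c26 = _components(range(26), _ADJ26, fg)
        if c26 == 1:
            bg18 = {i for i in _N18_IDX if i not in fg}
            # count only background 6-components touching a face neighbor
            seen = set()
            ncomp = 0
            for i in _N6_IDX:
                if i not in bg18 or i in seen:
                    continue
                ncomp += 1
                stack = [i]
                seen.add(i)
                while stack:
                    j = stack.pop()
                    for k in _ADJ6_18[j]:
                        if k in bg18 and k not in seen:
                            seen.add(k)
                            stack.append(k)
            ok = ncomp == 1
    _SIMPLE_LUT[code] = ok
    return ok


def thin3d(mask: np.ndarray) -> SkeletonPointSet:
    """Topology-preserving 3D thinning of a binary mask to a voxel skeleton.

    Six-subiteration border peeling: in each pass, border voxels open to one
    face direction are deleted one at a time if they are (26, 6)-simple and
    not curve endpoints, re-testing against the current state so every
    deletion provably preserves topology.  One-voxel curves are fixed points,
    cycles survive, and no connected component ever vanishes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return SkeletonPointSet(np.empty((0, 3), int))
    pad = np.pad(mask, 1).astype(np.uint8)
    dirs = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    changed = True
    while changed:
        changed = False
        for dz, dy, dx in dirs:
            fz, fy, fx = np.nonzero(pad)
            if len(fz) == 0:
                break
            open_face = pad[fz + dz, fy + dy, fx + dx] == 0
            cz, cy, cx = fz[open_face], fy[open_face], fx[open_face]
            for z, y, x in zip(cz, cy, cx):
                if not pad[z, y, x]:
                    continue
                nb = pad[z - 1 : z + 2, y - 1 : y + 2, x - 1 : x + 2].ravel()
                nb = np.delete(nb, 13)
                if nb.sum() <= 1:
                    continue  # curve endpoint (or isolated): keep
                code = int(nb.astype(np.int64) @ _POW2)
                if _is_simple(code):
                    pad[z, y, x] = 0
                    changed = True
    zyx = np.argwhere(pad.astype(bool)) - 1
    return SkeletonPointSet(points=zyx[:, ::-1])


def _eig3_sym(a11, a12, a13, a22, a23, a33):
    """Eigenvalues of symmetric 3x3 matrix fields, descending (trigonometric form)."""
    p1 = a12 * a12 + a13 * a13 + a23 * a23
    q = (a11 + a22 + a33) / 3.0
    p2 = (a11 - q) ** 2 + (a22 - q) ** 2 + (a33 - q) ** 2 + 2.0 * p1
    p = np.sqrt(np.maximum(p2 / 6.0, 1e-30))
    b11, b22, b33 = (a11 - q) / p, (a22 - q) / p, (a33 - q) / p
    b12, b13, b23 = a12 / p, a13 / p, a23 / p
    detB = (
        b11 * (b22 * b33 - b23 * b23)
        - b12 * (b12 * b33 - b23 * b13)
        + b13 * (b12 * b23 - b22 * b13)
    )
    r = np.clip(detB / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    return e1, e2, e3


def frangi_response(
    data: np.ndarray,
    scales=(1.0, 1.5, 2.0),
    alpha: float = 0.5,
    beta: float = 0.5,
    c: float | None = None,
) -> np.ndarray:
    """Multi-scale Frangi vesselness for bright tubes on dark background.

    For each scale, the scale-normalized Gaussian Hessian's eigenvalues
    (|l1| <= |l2| <= |l3|) give the plate/blob/structure ratios
    RA = |l2|/|l3|, RB = |l1|/sqrt(|l2 l3|), S = sqrt(sum l_i^2); the response

        V = (1 - exp(-RA^2/2a^2)) * exp(-RB^2/2b^2) * (1 - exp(-S^2/2c^2))

    is zeroed where l2 > 0 or l3 > 0 and maximized over scales.  ``c``
    defaults to half the maximum S per scale (the usual heuristic).
    """
    if not len(scales):
        raise ValueError("need at least one scale")
    vol = np.asarray(data, dtype=np.float32)
    out = np.zeros(vol.shape, np.float32)
    for s in scales:
        sm = ndi.gaussian_filter(vol, s, mode="nearest")
        gz = np.gradient(sm, axis=0)
        gy = np.gradient(sm, axis=1)
        gx = np.gradient(sm, axis=2)
        hzz = np.gradient(gz, axis=0)
        hzy = np.gradient(gz, axis=1)
        hzx = np.gradient(gz, axis=2)
        hyy = np.gradient(gy, axis=1)
        hyx = np.gradient(gy, axis=2)
        hxx = np.gradient(gx, axis=2)
        s2 = s * s
        e1, e2, e3 = _eig3_sym(hzz * s2, hzy * s2, hzx * s2, hyy * s2, hyx * s2, hxx * s2)
        lam = np.stack([e1, e2, e3])
        order = np.argsort(np.abs(lam), axis=0)
        lam = np.take_along_axis(lam, order, axis=0)
        l1, l2, l3 = lam[0], lam[1], lam[2]
        l2a = np.abs(l2)
        l3a = np.abs(l3)
        ra2 = (l2a / np.maximum(l3a, 1e-10)) ** 2
        rb2 = (np.abs(l1) ** 2) / np.maximum(l2a * l3a, 1e-10)
        s2sum = l1 * l1 + l2 * l2 + l3 * l3
        if c is None:
            cc = float(np.sqrt(s2sum.max())) / 2.0 or 1.0
        else:
            cc = c
        v = (
            (1.0 - np.exp(-ra2 / (2.0 * alpha * alpha)))
            * np.exp(-rb2 / (2.0 * beta * beta))
            * (1.0 - np.exp(-s2sum / (2.0 * cc * cc)))
        )
        v[(l2 > 0) | (l3 > 0)] = 0.0  # bright ridges need l2, l3 << 0
        np.maximum(out, v.astype(np.float32), out=out)
    return out


def vesselness(vol: ImageVolume, scales=(1.0, 1.5, 2.0), threshold: float = 0.05) -> TubularityMask:
    """Boolean tubularity mask: response >= threshold * max response."""
    resp = frangi_response(vol.data, scales=scales)
    mx = float(resp.max())
    if mx <= 0:
        return TubularityMask(np.zeros(vol.data.shape, bool), response=resp)
    return TubularityMask(resp >= threshold * mx, response=resp)


def remove_soma_region(pts: SkeletonPointSet, soma_center, soma_radius: float, inflation: float = 1.5) -> SkeletonPointSet:
    """Drop skeleton points within ``inflation * soma_radius`` of the soma (inclusive).

    Vesselness is unreliable in the soma halo, so its skeleton points are noise.
    """
    if soma_radius <= 0:
        raise ValueError("soma_radius must be positive")
    if len(pts) == 0:
        return SkeletonPointSet(np.empty((0, 3), int), pts.source_box)
    d = np.linalg.norm(pts.points - np.asarray(soma_center, dtype=float), axis=1)
    keep = d > inflation * soma_radius + 1e-9
    return SkeletonPointSet(pts.points[keep], pts.source_box)


def _degree26(points: np.ndarray) -> np.ndarray:
    """Number of 26-neighbors each point has within the point set."""
    if len(points) == 0:
        return np.zeros(0, int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=np.sqrt(3.0) + 1e-6, output_type="ndarray")
    deg = np.zeros(len(points), int)
    for a, b in pairs:
        if np.abs(points[a] - points[b]).max() <= 1:
            deg[a] += 1
            deg[b] += 1
    return deg


def filter_skeleton_points(
    pts: SkeletonPointSet,
    mask: TubularityMask,
    recon_coords: np.ndarray,
    d_cover: float = 3.0,
) -> SkeletonPointSet:
    """Keep tubular, chain-interior skeleton points unexplained by the reconstruction.

    (a) the point or one of its 26 neighbors has vesselness; (b) it has 1-2
    skeleton neighbors among the tubular survivors (isolated and branching
    points are dropped, so the remainder links into simple chains); (c) it
    lies farther than ``d_cover`` from every reconstruction node.
    """
    from .image_features import point_has_tubularity

    if len(pts) == 0:
        return SkeletonPointSet(np.empty((0, 3), int), pts.source_box)
    keep = np.array([point_has_tubularity(mask, p) for p in pts.points], bool)
    pp = pts.points[keep]
    deg = _degree26(pp)
    pp = pp[(deg >= 1) & (deg <= 2)]
    recon = np.asarray(recon_coords, dtype=float).reshape(-1, 3)
    if len(recon) and len(pp):
        d, _ = cKDTree(recon).query(pp.astype(float))
        pp = pp[d > d_cover]
    return SkeletonPointSet(pp, pts.source_box)


def link_skeleton_branches(pts: SkeletonPointSet) -> list[SkeletonBranch]:
    """Trace 26-connected skeleton points into ordered simple chains.

    Components are split at residual high-degree voxels; traversal starts at
    the lexicographically smallest endpoint so output order is deterministic.
    """
    points = pts.points
    if len(points) == 0:
        return []
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0]))
    points = points[order]
    index = {tuple(p): i for i, p in enumerate(points)}
    neigh: list[list[int]] = [[] for _ in points]
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for i, p in enumerate(points):
        for off in offsets:
            j = index.get((p[0] + off[0], p[1] + off[1], p[2] + off[2]))
            if j is not None:
                neigh[i].append(j)
    # split at residual high-degree voxels
    good = [i for i in range(len(points)) if len(neigh[i]) <= 2]
    goodset = set(good)
    visited = set()
    branches: list[SkeletonBranch] = []

    def trace(start: int) -> list[int]:
        chain = [start]
        visited.add(start)
        prev = None
        cur = start
        while True:
            nxt = [j for j in neigh[cur] if j in goodset and j != prev and j not in visited]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            chain.append(cur)
            visited.add(cur)
        return chain

    # endpoints first (degree <= 1 within the good set), then leftovers (cycles)
    for i in good:
        if i in visited:
            continue
        gn = [j for j in neigh[i] if j in goodset]
        if len(gn) <= 1:
            chain = trace(i)
            branches.append(_make_branch(len(branches), points[chain]))
    for i in good:
        if i not in visited:
            chain = trace(i)
            branches.append(_make_branch(len(branches), points[chain]))
    return branches


def merge_skeleton_fragments(branches: list[SkeletonBranch], bridge: float = 8.0, max_turn: float = 60.0):
    """Bridge near-collinear chain fragments separated by small gaps.

    Coverage erosion around the reconstruction (and local signal dropouts)
    can cut one physical skeleton branch into several fragments.  Two chains
    are merged when a pair of their endpoints lies within ``bridge`` voxels
    and continuing from one into the other turns by at most ``max_turn``
    degrees.  Greedy, deterministic, repeated to a fixed point.
    """

    def _end_tangent(chain: np.ndarray, at_start: bool) -> np.ndarray | None:
        if len(chain) < 2:
            return None
        k = min(3, len(chain) - 1)
        v = (chain[0] - chain[k]) if at_start else (chain[-1] - chain[-1 - k])
        n = np.linalg.norm(v.astype(float))
        return v / n if n > 0 else None

    chains = [b.chain.copy() for b in branches]
    merged = True
    while merged:
        merged = False
        for i in range(len(chains)):
            if merged:
                break
            for j in range(i + 1, len(chains)):
                ci, cj = chains[i], chains[j]
                best = None
                for ei, at_i in ((ci[0], True), (ci[-1], False)):
                    for ej, at_j in ((cj[0], True), (cj[-1], False)):
                        gap = float(np.linalg.norm((ei - ej).astype(float)))
                        if gap <= bridge and (best is None or gap < best[0]):
                            best = (gap, at_i, at_j)
                if best is None:
                    continue
                _gap, at_i, at_j = best
                ti = _end_tangent(ci, at_i)
                tj = _end_tangent(cj, at_j)
                if ti is None or tj is None:
                    continue
                # outgoing tangents at the two facing ends must be ~opposite
                cosang = float(np.dot(ti, tj))
                if cosang > -np.cos(np.radians(max_turn)):
                    continue
                a = ci if not at_i else ci[::-1]  # oriented to end at the gap
                b = cj if at_j else cj[::-1]  # oriented to start at the gap
                chains[i] = np.concatenate([a, b])
                del chains[j]
                merged = True
                break
    return [_make_branch(i, c) for i, c in enumerate(chains)]


def _make_branch(sid: int, chain: np.ndarray) -> SkeletonBranch:
    chain = np.asarray(chain, dtype=int)
    if len(chain) > 1:
        length = float(np.linalg.norm(np.diff(chain.astype(float), axis=0), axis=1).sum())
    else:
        length = 1.0
    return SkeletonBranch(
        skeleton_id=sid,
        chain=chain,
        length=length,
        endpoints=np.array([chain[0], chain[-1]]),
    )


def skeleton_end_segments(sk: SkeletonBranch, L: int) -> list[BranchSegment]:
    """Directed branching segments anchored at each end of a skeleton chain.

    The direction points from the endpoint into the chain (the growth
    direction if the chain were connected at that endpoint).
    """
    if len(sk.chain) < 2:
        return []
    segs = []
    for rev in (False, True):
        poly = sk.chain[::-1] if rev else sk.chain
        samples, _ = resample_polyline(poly.astype(float), 1.0, max_points=L)
        if len(samples) < 2:
            continue
        chord = samples[-1] - samples[0]
        norm = np.linalg.norm(chord)
        if norm < 1e-12:
            continue
        segs.append(
            BranchSegment(
                branch_id=-1,
                anchor=samples[0].copy(),
                points=samples,
                direction=chord / norm,
                end="proximal",
                short=len(samples) < L,
                kind="skeleton",
                owner=sk.skeleton_id,
            )
        )
    return segs


def extract_skeleton_branches(
    vol: ImageVolume,
    tree: NeuronTree,
    soma_center=None,
    soma_radius: float | None = None,
    *,
    gamma: float = 0.6,
    pct_lo: float = 1.0,
    pct_hi: float = 99.5,
    binarize_k: float = 0.5,
    scales=(1.0, 1.5, 2.0),
    vessel_threshold: float = 0.05,
    soma_inflation: float = 1.5,
    bbox_margin: int = 10,
    d_cover: float = 3.0,
    tubularity_fraction: float = 0.70,
):
    """Full image-side pipeline; returns (skeleton branches, tubularity mask, box).

    Works inside the union extended bounding box of the reconstruction, which
    keeps the heavy filters off empty background.  Returned chains and the
    mask are in global volume coordinates (mask as a full-size boolean grid).
    """
    from .image_features import branch_has_tubularity

    coords = tree.coords()
    box = extended_bbox(coords, bbox_margin, vol.shape)
    sub = ImageVolume(vol.data[box.slices()], vol.dtype_max)
    enh = enhance(sub, gamma=gamma, pct_lo=pct_lo, pct_hi=pct_hi)
    fg = binarize(enh, k=binarize_k)
    pts = thin3d(fg)
    pts.source_box = box
    mask_local = vesselness(enh, scales=scales, threshold=vessel_threshold)
    if soma_center is not None and soma_radius:
        offset = box.lo[::-1].astype(float)  # (x, y, z)
        pts = remove_soma_region(pts, np.asarray(soma_center, float) - offset, soma_radius, soma_inflation)
    local_coords = coords - box.lo[::-1]
    pts = filter_skeleton_points(pts, mask_local, local_coords, d_cover=d_cover)
    branches = link_skeleton_branches(pts)
    # lift to global coordinates and embed the mask in the full grid
    full_mask = np.zeros(vol.shape, bool)
    full_mask[box.slices()] = mask_local.data
    full = TubularityMask(full_mask)
    shift = box.lo[::-1]
    shifted = [_make_branch(b.skeleton_id, b.chain + shift) for b in branches]
    out = merge_skeleton_fragments(shifted, bridge=2.0 * d_cover + 2.0)
    for sk in out:
        sk.tubular = branch_has_tubularity(full, sk.chain, tubularity_fraction)
    return out, full, box
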