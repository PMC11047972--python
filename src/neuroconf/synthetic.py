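"""Deterministic synthetic neuron fixtures: volumes, trees and injected artifacts.

The generator emulates the statistics real parent-child branch pairs show:
child directions stay within ``branch_angle_max`` (< 90 degrees) of the parent
direction, and child intensities differ from the parent's by zero-mean noise
of SD ``intensity_child_sd`` — the intensity-similarity feature the energy
function exploits.  Branches are rendered as Gaussian-profile tubes over
Gaussian background noise, with optional interfering tubes that belong to no
tree.  Every stochastic choice draws from a single seeded generator so a
fixture is fully reproducible from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GenerationError, InjectionError
from .image_features import ImageVolume
from .neuron_model import Branch, NeuronNode, NeuronTree, angle_between, decompose_branches

__all__ = ["SynthConfig", "Fixture", "generate_tree", "render_volume", "inject_artifact", "make_fixture"]

ARTIFACT_KINDS = (
    "over_tracing",
    "conn_err_branch_skeleton",
    "conn_err_branch_branch",
    "branch_missing",
    "incomplete_tracing",
)


@dataclass
class SynthConfig:
    """Study conditions for synthetic fixtures.

    ``depth`` bifurcation levels below the stem; branch arc lengths drawn
    uniformly from ``branch_len`` voxels; bifurcation polar angles bounded by
    ``branch_angle_max`` (< 90).  Intensities are 8-bit: tubes at
    ``intensity_base`` with parent-child differences of SD
    ``intensity_child_sd`` over ``bg_mean`` +/- ``bg_sd`` background noise.
    """

    shape: tuple = (128, 128, 128)  # (nz, ny, nx)
    depth: int = 2
    branch_len: tuple = (16.0, 24.0)
    branch_angle_max: float = 55.0
    tube_radius: float = 1.5
    soma_radius: float = 4.0
    intensity_base: float = 200.0
    intensity_child_sd: float = 10.0
    bg_mean: float = 20.0
    bg_sd: float = 5.0
    n_interferers: int = 2
    node_spacing: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.branch_angle_max < 90):
            raise ValueError("branch_angle_max must lie in (0, 90)")
        for s in (self.intensity_child_sd, self.bg_sd):
            if s < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass
class Fixture:
    volume: ImageVolume
    truth: NeuronTree
    recon: NeuronTree
    injected: list = field(default_factory=list)  # (kind, marker node id) pairs
    config: SynthConfig | None = None
    node_intensity: dict = field(default_factory=dict)
    interferers: list = field(default_factory=list)  # polylines, (N, 3) (x, y, z)


def _unit(v):
    return v / np.linalg.norm(v)


def _perturb(rng, d, sd_deg):
    """Small random rotation of a unit vector (direction jitter along a branch)."""
    d = _unit(np.asarray(d, float))
    j = rng.normal(0.0, math.radians(sd_deg), 3)
    return _unit(d + np.cross(j, d))


def _rotate_towards(d, polar_deg, azimuth_deg):
    """Unit vector at ``polar_deg`` from d, around azimuth in d's normal plane."""
    d = _unit(np.asarray(d, float))
    # orthonormal frame around d
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, a))
    v = np.cross(d, u)
    t = math.radians(polar_deg)
    p = math.radians(azimuth_deg)
    return _unit(math.cos(t) * d + math.sin(t) * (math.cos(p) * u + math.sin(p) * v))


def _grow_polyline(rng, start, direction, length, spacing, bounds, margin):
    """March a gently curving polyline, bending inward near the volume faces."""
    pts = [np.asarray(start, float)]
    d = _unit(np.asarray(direction, float))
    traveled = 0.0
    lo = np.full(3, margin)
    hi = np.asarray(bounds, float)[::-1] - margin  # (x, y, z)
    while traveled < length:
        d = _perturb(rng, d, 3.0)
        nxt = pts[-1] + d * spacing
        for k in range(3):  # steer back inside
            if nxt[k] < lo[k] or nxt[k] > hi[k]:
                d[k] = -d[k]
                nxt = pts[-1] + _unit(d) * spacing
        if np.any(nxt < 0) or np.any(nxt > np.asarray(bounds, float)[::-1] - 1):
            raise GenerationError("polyline left the volume")
        pts.append(nxt)
        traveled += spacing
    return np.array(pts)


def generate_tree(cfg: SynthConfig, rng=None) -> NeuronTree:
    """Recursive bifurcating tree rooted at a soma in the volume center.

    Children leave the bifurcation at polar angles within
    ``branch_angle_max`` of the parent's end direction, separated in azimuth,
    so every realized parent-child angle respects the < 90 degree growth
    pattern.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    shape = np.asarray(cfg.shape)
    center = (shape[::-1] - 1) / 2.0  # (x, y, z)
    margin = 2.0 * cfg.tube_radius + 2.0
    nodes = [NeuronNode(1, 1, *center, cfg.soma_radius, -1)]
    next_id = 2

    def add_chain(poly, parent_id, radius):
        nonlocal next_id
        pid = parent_id
        for p in poly[1:]:
            nodes.append(NeuronNode(next_id, 3, p[0], p[1], p[2], radius, pid))
            pid = next_id
            next_id += 1
        return pid

    def grow(start, direction, parent_id, level):
        length = rng.uniform(*cfg.branch_len)
        poly = _grow_polyline(rng, start, direction, length, cfg.node_spacing, shape, margin)
        end_id = add_chain(poly, parent_id, cfg.tube_radius)
        if level < cfg.depth:
            end_dir = _unit(poly[-1] - poly[-2])
            az0 = rng.uniform(0.0, 360.0)
            az_sep = rng.uniform(70.0, 150.0)
            for i in range(2):
                polar = rng.uniform(20.0, cfg.branch_angle_max)
                child_dir = _rotate_towards(end_dir, polar, az0 + i * az_sep)
                grow(poly[-1], child_dir, end_id, level + 1)

    stem_dir = _unit(rng.normal(size=3))
    for attempt in range(20):
        try:
            nodes_backup = list(nodes)
            grow(center, stem_dir, 1, 0)
            break
        except GenerationError:
            nodes.clear()
            nodes.extend(nodes_backup[:1])
            next_id = 2
            stem_dir = _unit(rng.normal(size=3))
    else:
        raise GenerationError("could not fit a tree inside the volume")
    return NeuronTree(nodes)


def assign_intensities(tree: NeuronTree, cfg: SynthConfig, rng) -> dict:
    """Per-node tube intensity with parent-child similarity (branch-wise walk)."""
    branches = decompose_branches(tree)
    by_id = {b.branch_id: b for b in branches}
    intensity = {tree.soma_id: cfg.intensity_base}
    branch_I: dict[int, float] = {}
    for b in branches:
        base = cfg.intensity_base if b.parent_branch_id is None else branch_I[b.parent_branch_id]
        I = float(np.clip(base + rng.normal(0.0, cfg.intensity_child_sd), 40.0, 250.0))
        branch_I[b.branch_id] = I
        for nid in b.node_path[1:]:
            intensity[nid] = I
    return intensity


def _paint_tube(canvas, poly, radius, intensity):
    """Max-composite a Gaussian-profile tube along a polyline into the canvas."""
    shape = canvas.shape  # (z, y, x)
    r3 = int(math.ceil(3.0 * radius))
    # dense samples along the polyline
    seg = np.diff(poly, axis=0)
    for p0, d in zip(poly[:-1], seg):
        n = max(int(math.ceil(np.linalg.norm(d) / 0.5)), 1)
        for t in np.linspace(0.0, 1.0, n, endpoint=False):
            c = p0 + t * d  # (x, y, z)
            xi, yi, zi = (int(round(v)) for v in c)
            zs = slice(max(zi - r3, 0), min(zi + r3 + 1, shape[0]))
            ys = slice(max(yi - r3, 0), min(yi + r3 + 1, shape[1]))
            xs = slice(max(xi - r3, 0), min(xi + r3 + 1, shape[2]))
            zz, yy, xx = np.mgrid[zs, ys, xs]
            d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
            prof = intensity * np.exp(-d2 / (2.0 * radius * radius))
            np.maximum(canvas[zs, ys, xs], prof, out=canvas[zs, ys, xs])


def _paint_ball(canvas, center, radius, intensity):
    shape = canvas.shape
    xi, yi, zi = (int(round(v)) for v in center)
    r3 = int(math.ceil(radius + 2))
    zs = slice(max(zi - r3, 0), min(zi + r3 + 1, shape[0]))
    ys = slice(max(yi - r3, 0), min(yi + r3 + 1, shape[1]))
    xs = slice(max(xi - r3, 0), min(xi + r3 + 1, shape[2]))
    zz, yy, xx = np.mgrid[zs, ys, xs]
    d = np.sqrt((xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2)
    prof = np.where(d <= radius, intensity, intensity * np.exp(-((d - radius) ** 2) / 2.0))
    np.maximum(canvas[zs, ys, xs], prof, out=canvas[zs, ys, xs])


def render_volume(tree: NeuronTree, cfg: SynthConfig, rng=None, node_intensity=None, interferers=None):
    """Render a tree (plus optional interferer polylines) into an 8-bit volume."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    if node_intensity is None:
        node_intensity = assign_intensities(tree, cfg, rng)
    canvas = np.zeros(cfg.shape, np.float32)
    for n in tree.nodes:
        if n.parent_id == -1:
            continue
        p = tree.node(n.parent_id)
        I = node_intensity.get(n.id, cfg.intensity_base)
        _paint_tube(canvas, np.array([p.pos, n.pos]), cfg.tube_radius, I)
    _paint_ball(canvas, tree.root.pos, cfg.soma_radius, cfg.intensity_base)
    for poly, inten in interferers or []:
        _paint_tube(canvas, np.asarray(poly, float), cfg.tube_radius, inten)
    noise = rng.normal(cfg.bg_mean, cfg.bg_sd, cfg.shape)
    data = np.clip(canvas + noise, 0.0, 255.0).astype(np.uint8)
    return ImageVolume(data, 255.0)


def _sample_interferers(tree: NeuronTree, cfg: SynthConfig, rng):
    """Straight-ish tubes placed well away from the tree (>= 30 voxels)."""
    out = []
    coords = tree.coords()
    shape = np.asarray(cfg.shape, float)[::-1]
    for _ in range(cfg.n_interferers):
        for _attempt in range(50):
            start = rng.uniform(8.0, shape - 8.0)
            if np.linalg.norm(coords - start, axis=1).min() < 30.0:
                continue
            d = _unit(rng.normal(size=3))
            length = rng.uniform(20.0, 35.0)
            end = start + d * length
            if np.any(end < 4) or np.any(end > shape - 4):
                continue
            mids = start + np.outer(np.linspace(0, 1, 8), end - start)
            if min(np.linalg.norm(coords - m, axis=1).min() for m in mids) < 25.0:
                continue
            inten = cfg.intensity_base * rng.uniform(0.6, 1.0)
            out.append((np.array([start, end]), inten))
            break
    return out


def make_fixture(cfg: SynthConfig | None = None, seed: int | None = None) -> Fixture:
    """Generate a clean fixture (volume + truth tree + recon == truth)."""
    cfg = cfg or SynthConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    tree = generate_tree(cfg, rng)
    node_intensity = assign_intensities(tree, cfg, rng)
    interferers = _sample_interferers(tree, cfg, rng)
    vol = render_volume(tree, cfg, rng, node_intensity, interferers)
    return Fixture(
        volume=vol,
        truth=tree,
        recon=tree.copy(),
        injected=[],
        config=cfg,
        node_intensity=node_intensity,
        interferers=interferers,
    )


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------


def _branch_dir(tree: NeuronTree, branch: Branch, at: str = "start"):
    coords = tree.coords(branch.node_path)
    if at == "start":
        return _unit(coords[min(3, len(coords) - 1)] - coords[0])
    return _unit(coords[-1] - coords[max(len(coords) - 4, 0)])


def _fresh_id(tree: NeuronTree) -> int:
    return max(n.id for n in tree.nodes) + 1


def _add_chain(tree_nodes, poly, parent_id, radius, start_id):
    nid = start_id
    pid = parent_id
    for p in poly[1:]:
        tree_nodes.append(NeuronNode(nid, 3, p[0], p[1], p[2], radius, pid))
        pid = nid
        nid += 1
    return pid, nid


def _subtree_ids(tree: NeuronTree, root_id: int):
    out = []
    stack = [root_id]
    while stack:
        nid = stack.pop()
        out.append(nid)
        stack.extend(tree.children(nid))
    return out


def _delete_nodes(tree: NeuronTree, ids) -> NeuronTree:
    drop = set(ids)
    return NeuronTree([n for n in tree.nodes if n.id not in drop])


def inject_artifact(fixture: Fixture, kind: str, seed: int = 0) -> Fixture:
    """Corrupt the reconstruction (and, where needed, the image) with one artifact.

    over_tracing          append a spurious branch (reverse angle or no image
                          support) at a mid-branch node.
    conn_err_branch_skeleton
                          reroute a child onto a freshly painted decoy tube of
                          different intensity; its true continuation stays
                          only in the image.
    conn_err_branch_branch
                          reattach a terminal's proximal end onto a nearby
                          sibling's path.
    branch_missing        delete a terminal branch from the reconstruction.
    incomplete_tracing    truncate a terminal branch by 30-60%.

    The returned fixture records ``(kind, marker_node_id)``; the marker node
    identifies the affected branch in the corrupted reconstruction (for
    branch_missing it is the surviving attachment node).
    """
    if kind not in ARTIFACT_KINDS:
        raise InjectionError(f"unknown artifact kind {kind!r}")
    rng = np.random.default_rng(seed)
    tree = fixture.truth
    branches = decompose_branches(tree)
    recon = tree.copy()
    volume = fixture.volume
    cfg = fixture.config or SynthConfig()
    terminals = [b for b in branches if b.is_terminal and b.level >= 1]

    if kind == "over_tracing":
        hosts = [b for b in branches if len(b.node_path) >= 8]
        if not hosts:
            raise InjectionError("no branch long enough to host a spurious child")
        host = hosts[rng.integers(len(hosts))]
        k = int(rng.integers(3, len(host.node_path) - 3))
        attach = host.node_path[k]
        local_dir = _unit(tree.coords([host.node_path[k + 1]])[0] - tree.coords([host.node_path[k - 1]])[0])
        variant = rng.integers(2)
        for _attempt in range(40):
            if variant == 0:  # reverse growth
                polar = rng.uniform(120.0, 160.0)
            else:  # forward but unsupported by the image
                polar = rng.uniform(35.0, 70.0)
            d = _rotate_towards(local_dir, polar, rng.uniform(0, 360))
            start = tree.node(attach).pos
            poly = start + np.outer(np.arange(0.0, 10.5, cfg.node_spacing), d)
            shape = np.asarray(cfg.shape, float)[::-1]
            if np.any(poly < 3) or np.any(poly > shape - 3):
                continue
            # the far part of the spurious branch must sit in background
            # (points near the attachment are unavoidably close to the host)
            far = poly[4:]
            allc = tree.coords()
            if np.min(np.linalg.norm(allc[None, :, :] - far[:, None, :], axis=2)) < 4.0:
                continue
            if fixture.interferers and min(
                np.linalg.norm(np.asarray(p, float)[:, None, :] - far[None, :, :], axis=2).min()
                for p, _i in fixture.interferers
            ) < 5.0:
                continue
            nodes = list(recon.nodes)
            _last, _nid = _add_chain(nodes, poly, attach, cfg.tube_radius, _fresh_id(recon))
            recon = NeuronTree(nodes)
            marker = _fresh_id(fixture.truth)
            return replace(fixture, recon=recon, injected=[(kind, marker)])
        raise InjectionError("could not place a spurious branch")

    if kind == "branch_missing":
        eligible = [b for b in terminals if _arc_len(tree, b) >= 12.0]
        if not eligible:
            raise InjectionError("no terminal branch long enough to delete")
        b = eligible[rng.integers(len(eligible))]
        recon = _delete_nodes(recon, b.node_path[1:])
        return replace(fixture, recon=recon, injected=[(kind, b.node_path[0])])

    if kind == "incomplete_tracing":
        eligible = [b for b in terminals if _arc_len(tree, b) >= 14.0]
        if not eligible:
            raise InjectionError("no terminal branch long enough to truncate")
        b = eligible[rng.integers(len(eligible))]
        frac = rng.uniform(0.3, 0.6)
        n_keep = max(int(round(len(b.node_path) * (1.0 - frac))), 3)
        drop = b.node_path[n_keep:]
        recon = _delete_nodes(recon, drop)
        return replace(fixture, recon=recon, injected=[(kind, b.node_path[n_keep - 1])])

    if kind == "conn_err_branch_skeleton":
        eligible = [b for b in branches if b.level == 1 and len(b.node_path) >= 6]
        if not eligible:
            raise InjectionError("no level-1 branch to reroute")
        by_id = {b.branch_id: b for b in branches}
        b = eligible[rng.integers(len(eligible))]
        parent = by_id[b.parent_branch_id]
        parent_dir = _branch_dir(tree, parent, at="end")
        true_dir = _branch_dir(tree, b, at="start")
        anchor = tree.node(b.node_path[0]).pos
        for _attempt in range(60):
            d = _rotate_towards(parent_dir, rng.uniform(35.0, 70.0), rng.uniform(0, 360))
            if angle_between(d, true_dir) < 30.0 or angle_between(d, parent_dir) >= 80.0:
                continue
            length = rng.uniform(12.0, 18.0)
            poly = anchor + np.outer(np.arange(0.0, length, cfg.node_spacing), d)
            shape = np.asarray(cfg.shape, float)[::-1]
            if np.any(poly < 3) or np.any(poly > shape - 3):
                continue
            # keep the decoy clear of the true child's tube beyond the shared anchor
            true_coords = tree.coords(b.node_path[2:]) if len(b.node_path) > 2 else None
            if true_coords is not None and len(true_coords):
                dmin = np.linalg.norm(true_coords[None, :, :] - poly[2:, None, :], axis=2).min()
                if dmin < 4.0:
                    continue
            decoy_intensity = cfg.intensity_base * 0.55
            data = fixture.volume.data.astype(np.float32)
            _paint_tube(data, poly, cfg.tube_radius, decoy_intensity)
            volume = ImageVolume(np.clip(data, 0, 255).astype(np.uint8), 255.0)
            recon = _delete_nodes(recon, [nid for nid in _subtree_ids(tree, b.node_path[1])])
            nodes = list(recon.nodes)
            marker = _fresh_id(recon)
            _last, _nid = _add_chain(nodes, poly, b.node_path[0], cfg.tube_radius, marker)
            recon = NeuronTree(nodes)
            return replace(fixture, volume=volume, recon=recon, injected=[(kind, marker)])
        raise InjectionError("could not place a decoy tube")

    # conn_err_branch_branch: graft a terminal's tail onto a sibling's path so
    # the grafted branch still leaves its new parent at a legal (< 90 degree)
    # angle — the detector, not the angle rule, must catch it
    from .neuron_model import extract_segment

    pairs = []
    for b in terminals:
        for s in branches:
            if (
                s.parent_branch_id == b.parent_branch_id
                and s.branch_id != b.branch_id
                and s.is_terminal
                and len(s.node_path) >= 7
                and len(b.node_path) >= 8
            ):
                pairs.append((b, s))
    order = rng.permutation(len(pairs)) if pairs else []
    for pi in order:
        b, s = pairs[pi]
        for idx_m in (5, 6, 7):
            for idx_a in (2, 3, 4):
                if idx_m >= len(b.node_path) or idx_a >= len(s.node_path) - 1:
                    continue
                moved = b.node_path[idx_m]
                attach = s.node_path[idx_a]
                gap = float(np.linalg.norm(tree.node(moved).pos - tree.node(attach).pos))
                if gap > 9.0:
                    continue
                cand_nodes = []
                drop = set(b.node_path[1:idx_m])
                for n in recon.nodes:
                    if n.id in drop:
                        continue
                    if n.id == moved:
                        cand_nodes.append(NeuronNode(n.id, n.type_code, n.x, n.y, n.z, n.radius, attach))
                    else:
                        cand_nodes.append(n)
                cand = NeuronTree(cand_nodes)
                cb = decompose_branches(cand)
                target = find_branch_containing(cb, moved)
                if target is None or target.parent_branch_id is None:
                    continue
                parent = next(x for x in cb if x.branch_id == target.parent_branch_id)
                seg_p = extract_segment(cand, parent, "distal", 8)
                seg_c = extract_segment(cand, target, "proximal", 8)
                if angle_between(seg_p.direction, seg_c.direction) < 80.0:
                    return replace(fixture, recon=cand, injected=[(kind, moved)])
    raise InjectionError("no sibling terminal pair admits a legal-angle misconnection")


def _arc_len(tree: NeuronTree, branch: Branch) -> float:
    c = tree.coords(branch.node_path)
    return float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())


def find_branch_containing(branches, node_id: int):
    """The branch whose non-anchor path contains ``node_id`` (anchor as fallback)."""
    for b in branches:
        if node_id in b.node_path[1:]:
            return b
    for b in branches:
        if node_id == b.node_path[0]:
            return b
    return None
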