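"""Readers and writers: SWC, 3D TIFF stacks, Vaa3D markers, reports, config.

Coordinate conventions: SWC x, y, z are 0-based voxel coordinates in
(x, y, z) order; TIFF volumes load as (z, y, x) grids.  All writers are
deterministic — identical inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .confidence import ConfidenceParams
from .detection import ArtifactLabel, ArtifactReport
from .errors import ConfigError, FormatError, StructuralError
from .image_features import ImageVolume
from .neuron_model import NeuronNode, NeuronTree, decompose_branches

__all__ = [
    "SomaMarker",
    "RunConfig",
    "read_swc",
    "write_swc",
    "read_volume",
    "write_volume",
    "read_marker",
    "write_marker",
    "write_outputs",
    "read_report",
    "LABEL_TYPE_CODES",
]

#: SWC type_code per artifact label (Vaa3D-style color conventions)
LABEL_TYPE_CODES = {
    ArtifactLabel.NONE: 255,  # white: high confidence
    ArtifactLabel.CONFIRMED: 256,  # fuchsine: user-confirmed
    ArtifactLabel.OVER_TRACING: 260,  # red
    ArtifactLabel.CONN_ERR_BRANCH_SKELETON: 261,  # yellow
    ArtifactLabel.CONN_ERR_BRANCH_BRANCH: 262,  # blue
    ArtifactLabel.BRANCH_MISSING: 263,  # green (host branch)
    ArtifactLabel.INCOMPLETE_TRACING: 255,  # conveyed via the marker file
    ArtifactLabel.LOW_CONFIDENCE: 264,
}


@dataclass
class SomaMarker:
    x: float
    y: float
    z: float
    radius: float = 5.0

    @property
    def pos(self):
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class RunConfig:
    """Flat, serializable bundle of all pipeline parameters."""

    confidence: ConfidenceParams = field(default_factory=ConfidenceParams)
    gamma: float = 0.6
    pct_lo: float = 1.0
    pct_hi: float = 99.5
    binarize_k: float = 0.5
    vessel_scales: tuple = (1.0, 1.5, 2.0)
    vessel_threshold: float = 0.05
    soma_inflation: float = 1.5
    bbox_margin: int = 10
    seed: int = 0

    def to_flat(self) -> dict:
        d = {}
        for k, v in dataclasses.asdict(self.confidence).items():
            d[k] = v
        for f in dataclasses.fields(self):
            if f.name == "confidence":
                continue
            d[f.name] = getattr(self, f.name)
        return d

    @classmethod
    def from_flat(cls, d: dict) -> "RunConfig":
        conf_fields = {f.name: f for f in dataclasses.fields(ConfidenceParams)}
        own_fields = {f.name: f for f in dataclasses.fields(cls) if f.name != "confidence"}
        ckw, okw = {}, {}
        for k, v in d.items():
            if k in conf_fields:
                ckw[k] = _coerce(v, conf_fields[k].type)
            elif k in own_fields:
                okw[k] = _coerce(v, own_fields[k].type)
            else:
                raise ConfigError(f"unknown config key {k!r}")
        try:
            return cls(confidence=ConfidenceParams(**ckw), **okw)
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from e

    def save(self, path):
        lines = []
        for k, v in sorted(self.to_flat().items()):
            if isinstance(v, (tuple, list)):
                v = ",".join(repr(float(x)) for x in v)
            lines.append(f"{k} = {v}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = {}
        with open(path) as fh:
            for ln, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"line {ln}: expected key = value")
                k, v = (part.strip() for part in line.split("=", 1))
                d[k] = v
        return cls.from_flat(d)


def _coerce(v, typ):
    if not isinstance(v, str):
        return tuple(v) if isinstance(v, list) else v
    t = str(typ)
    if "bool" in t:
        return v.lower() in ("1", "true", "yes")
    if "int" in t:
        return int(v)
    if "tuple" in t:
        return tuple(float(x) for x in v.split(","))
    if "float" in t:
        return float(v)
    return v


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------


def read_swc(path) -> NeuronTree:
    """Parse a 7-column SWC file; tolerates comments, blank lines, unsorted ids
    and forward parent references.  Structural problems raise FormatError with
    the offending line number where known."""
    nodes = []
    seen = set()
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 7:
                raise FormatError(f"expected 7 columns, got {len(parts)}", line=ln)
            try:
                nid = int(parts[0])
                tc = int(parts[1])
                x, y, z, r = (float(p) for p in parts[2:6])
                pid = int(parts[6])
            except ValueError as e:
                raise FormatError(str(e), line=ln) from e
            if nid in seen:
                raise FormatError(f"duplicate node id {nid}", line=ln)
            seen.add(nid)
            nodes.append(NeuronNode(nid, tc, x, y, z, r, pid))
    if not nodes:
        raise FormatError(f"{path}: no SWC records found")
    try:
        return NeuronTree(nodes)
    except StructuralError as e:
        raise FormatError(f"{path}: {e}") from e


def write_swc(tree: NeuronTree, path, header: str | None = None):
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for n in sorted(tree.nodes, key=lambda n: n.id):
            fh.write(f"{n.id} {n.type_code} {n.x:.3f} {n.y:.3f} {n.z:.3f} {n.radius:.3f} {n.parent_id}\n")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def read_volume(path) -> ImageVolume:
    """Load a 3D grayscale TIFF stack as a (z, y, x) grid."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise FormatError(f"{path}: expected a 3D stack, got a single 2D page")
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D grayscale data, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"{path}: expected 8- or 16-bit integer data, got {data.dtype}")
    return ImageVolume(data, float(np.iinfo(data.dtype).max))


def write_volume(vol: ImageVolume, path):
    tifffile.imwrite(path, np.asarray(vol.data), photometric="minisblack")


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


def read_marker(path) -> list[SomaMarker]:
    """Vaa3D .marker CSV dialect (x,y,z,radius,shape,name,comment), 0-based."""
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 3:
                raise FormatError("marker rows need at least x,y,z", line=ln)
            try:
                x, y, z = (float(p) for p in parts[:3])
                r = float(parts[3]) if len(parts) > 3 and parts[3] else 5.0
            except ValueError as e:
                raise FormatError(str(e), line=ln) from e
            out.append(SomaMarker(x, y, z, r))
    if not out:
        raise FormatError(f"{path}: no marker rows found")
    return out


def write_marker(markers, path, comment: str = ""):
    with open(path, "w") as fh:
        fh.write("#x,y,z,radius,shape,name,comment\n")
        for i, m in enumerate(markers, 1):
            fh.write(f"{m.x:.3f},{m.y:.3f},{m.z:.3f},{m.radius:.3f},1,{i},{comment}\n")


# ---------------------------------------------------------------------------
# annotated outputs
# ---------------------------------------------------------------------------


def write_outputs(report: ArtifactReport, tree: NeuronTree, skeletons, path_prefix) -> dict:
    """Write the annotated SWC, skeleton-hint SWC, incomplete-tracing marker
    file and the JSON report; returns the path map."""
    prefix = str(path_prefix)
    paths = {
        "annotated": prefix + "_annotated.swc",
        "skeleton": prefix + "_skeleton.swc",
        "marker": prefix + "_incomplete.marker",
        "report": prefix + "_report.json",
    }
    branches = decompose_branches(tree)
    label_by_branch = report.labels()
    code_by_node: dict[int, int] = {tree.soma_id: 1}
    for b in branches:
        code = LABEL_TYPE_CODES[label_by_branch.get(b.branch_id, ArtifactLabel.NONE)]
        for nid in b.node_path[1:]:
            code_by_node[nid] = code
    annotated = NeuronTree(
        NeuronNode(n.id, code_by_node.get(n.id, 255), n.x, n.y, n.z, n.radius, n.parent_id)
        for n in tree.nodes
    )
    write_swc(annotated, paths["annotated"], header="annotated by neuroconf")

    sk_nodes = []
    nid = 1
    for sk in skeletons:
        pid = -1
        for p in sk.chain:
            sk_nodes.append(NeuronNode(nid, 263, float(p[0]), float(p[1]), float(p[2]), 0.5, pid))
            pid = nid
            nid += 1
    with open(paths["skeleton"], "w") as fh:
        fh.write("# candidate skeleton branches (one root per chain)\n")
        for n in sk_nodes:
            fh.write(f"{n.id} {n.type_code} {n.x:.3f} {n.y:.3f} {n.z:.3f} {n.radius:.3f} {n.parent_id}\n")

    markers = []
    by_id = {b.branch_id: b for b in branches}
    for rec in report.branch_records:
        if rec.label is ArtifactLabel.INCOMPLETE_TRACING:
            tip = tree.node(by_id[rec.branch_id].node_path[-1])
            markers.append(SomaMarker(tip.x, tip.y, tip.z, 2.0))
    write_marker(markers, paths["marker"], comment="incomplete tracing")

    payload = {
        "branches": [
            {
                "branch_id": rec.branch_id,
                "label": rec.label.value,
                "PG": None if rec.confidence is None else rec.confidence.PG,
                "PL": None if rec.confidence is None else rec.confidence.PL,
                "confidence": None if rec.confidence is None else rec.confidence.confidence,
                "low_confidence": None if rec.confidence is None else rec.confidence.low_confidence,
                "evidence": rec.evidence,
                "inherited": rec.inherited,
            }
            for rec in report.branch_records
        ],
        "skeletons": [
            {"skeleton_id": s.skeleton_id, "role": s.role} for s in report.skeleton_records
        ],
    }
    with open(paths["report"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
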