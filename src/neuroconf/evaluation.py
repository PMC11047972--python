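"""Reconstruction-vs-ground-truth metrics.

Node-level precision/recall/F1 under distance matching, and the structural
distance triple ESA / DSA / PDS:

    Precision(R, G) = |R matched to G| / |R|
    Recall(R, G)    = |G matched to R| / |G|
    F1              = 2 P R / (P + R)

with a node matched iff its nearest node in the other tree lies within
``d_match``.  ESA is the mean of bidirectional nearest-node distances, DSA
the mean over the "different" nodes (distance > ``d_thresh``), PDS their
fraction.  Distances are node-to-node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .neuron_model import NeuronTree

__all__ = ["MetricSet", "match_nodes", "precision_recall_f1", "esa_dsa_pds", "evaluate_pair"]


@dataclass
class MetricSet:
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    esa: float = 0.0
    dsa: float = 0.0
    pds: float = 0.0
    n_R: int = 0
    n_G: int = 0

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "esa": self.esa,
            "dsa": self.dsa,
            "pds": self.pds,
            "n_R": self.n_R,
            "n_G": self.n_G,
        }


def _coords(t) -> np.ndarray:
    if isinstance(t, NeuronTree):
        return t.coords()
    return np.asarray(t, dtype=float).reshape(-1, 3)


def match_nodes(R, G, d_match: float = 2.0):
    """Counts of R-nodes within ``d_match`` of G and vice versa."""
    r = _coords(R)
    g = _coords(G)
    if len(r) == 0 or len(g) == 0:
        return 0, 0
    dr, _ = cKDTree(g).query(r)
    dg, _ = cKDTree(r).query(g)
    return int((dr <= d_match).sum()), int((dg <= d_match).sum())


def precision_recall_f1(R, G, d_match: float = 2.0) -> MetricSet:
    r = _coords(R)
    g = _coords(G)
    m = MetricSet(n_R=len(r), n_G=len(g))
    if len(r) == 0 or len(g) == 0:
        warnings.warn("empty reconstruction or ground truth; metrics set to 0")
        return m
    mr, mg = match_nodes(r, g, d_match)
    m.precision = mr / len(r)
    m.recall = mg / len(g)
    if m.precision + m.recall > 0:
        m.f1 = 2.0 * m.precision * m.recall / (m.precision + m.recall)
    return m


def esa_dsa_pds(R, G, d_thresh: float = 2.0) -> MetricSet:
    """Bidirectional nearest-node structural distances."""
    r = _coords(R)
    g = _coords(G)
    m = MetricSet(n_R=len(r), n_G=len(g))
    if len(r) == 0 or len(g) == 0:
        warnings.warn("empty reconstruction or ground truth; metrics set to 0")
        return m
    dr, _ = cKDTree(g).query(r)
    dg, _ = cKDTree(r).query(g)
    d = np.concatenate([dr, dg])
    m.esa = float(d.mean())
    diff = d > d_thresh
    m.pds = float(diff.mean())
    m.dsa = float(d[diff].mean()) if diff.any() else 0.0
    return m


def evaluate_pair(R, G, d_match: float = 2.0, d_thresh: float = 2.0) -> MetricSet:
    """All metrics for one (reconstruction, ground truth) pair."""
    a = precision_recall_f1(R, G, d_match)
    b = esa_dsa_pds(R, G, d_thresh)
    a.esa, a.dsa, a.pds = b.esa, b.dsa, b.pds
    return a
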