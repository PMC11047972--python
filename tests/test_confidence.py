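"""Energy function, candidate sets, connection probability, PG/PL/confidence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroconf import (
    ConfidenceContext,
    ConfidenceParams,
    ImageVolume,
    SegmentFeatures,
    TubularityMask,
    build_candidate_set,
    connection_energy,
    connection_probability,
    decompose_branches,
)
from neuroconf.neuron_model import BranchSegment

from conftest import path_tree, y_tree


def seg(anchor, direction, n=5, branch_id=0, kind="branch"):
    anchor = np.asarray(anchor, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    pts = anchor + np.outer(np.arange(n, dtype=float), d)
    return BranchSegment(branch_id=branch_id, anchor=pts[0], points=pts, direction=d, end="proximal", kind=kind)


PARAMS = ConfidenceParams(alpha=1.0, beta=1.0)


class TestEnergy:
    def test_identical_features_zero(self):
        f = SegmentFeatures(0.5, 0.1, 5)
        assert connection_energy(f, f, 0.0, PARAMS).U == 0.0

    def test_ninety_degrees_is_infinite(self):
        f = SegmentFeatures(0.5, 0.1, 5)
        assert connection_energy(f, f, 90.0, PARAMS).U == math.inf
        assert connection_energy(f, f, 120.0, PARAMS).U == math.inf

    def test_hand_evaluated_formula(self):
        """alpha=1, beta=1, dI=3, dsigma=2, theta=45 -> U=5 (abs differences)."""
        a = SegmentFeatures(10.0, 4.0, 5)
        b = SegmentFeatures(7.0, 6.0, 5)
        e = connection_energy(a, b, 45.0, PARAMS)
        assert e.delta_I == pytest.approx(3.0)
        assert e.delta_sigma == pytest.approx(2.0)
        assert e.U == pytest.approx(5.0)

    def test_weights_scale_terms(self):
        a = SegmentFeatures(1.0, 0.0, 3)
        b = SegmentFeatures(0.0, 1.0, 3)
        e = connection_energy(a, b, 10.0, ConfidenceParams(alpha=0.25, beta=0.75))
        assert e.U == pytest.approx(0.25 + 0.75)


class TestCandidateSet:
    def test_no_neighbors_only_current(self):
        a = seg((0, 0, 0), (1, 0, 0))
        b = seg((4, 0, 0), (1, 0, 0), branch_id=1)
        far = seg((500, 0, 0), (1, 0, 0), branch_id=2)
        cs = build_candidate_set(a, b, [far], ConfidenceParams())
        assert len(cs.candidates) == 1
        assert cs.candidates[0][0] is b

    def test_strict_distance_boundary(self):
        params = ConfidenceParams(Td=20.0)
        a = seg((0, 0, 0), (1, 0, 0))
        b = seg((4, 0, 0), (1, 0, 0), branch_id=1)
        inside = seg((4 + 20 - 1e-6, 0, 0), (1, 0, 0), branch_id=2)  # just short of Td from a's far end
        at = seg((4.0 + 20.0, 0, 0), (1, 0, 0), branch_id=3)  # exactly Td from a's far end
        cs = build_candidate_set(a, b, [inside, at], params)
        members = {id(c[0]) for c in cs.candidates}
        assert id(inside) in members
        assert id(at) not in members

    def test_membership_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        params = ConfidenceParams(Td=15.0)
        a = seg((0, 0, 0), (1, 0, 0))
        b = seg((3, 3, 0), (1, 0, 0), branch_id=99)
        others = [seg(rng.uniform(-30, 30, 3), rng.normal(size=3), branch_id=i) for i in range(20)]
        cs = build_candidate_set(a, b, others, params)
        got = {id(c[0]) for c in cs.candidates} - {id(b)}
        ea = np.array([a.points[0], a.points[-1]])
        expected = set()
        for o in others:
            eo = np.array([o.points[0], o.points[-1]])
            d = np.linalg.norm(ea[:, None] - eo[None, :], axis=-1).min()
            if 0 < d < params.Td:
                expected.add(id(o))
        assert got == expected


class TestConnectionProbability:
    def _vol(self):
        return ImageVolume(np.full((40, 40, 120), 100.0), 255.0)

    def _prob(self, energies, which=0):
        """Probability of candidate `which` in a scene with prescribed energies."""
        vol = self._vol()
        params = ConfidenceParams(alpha=1.0, beta=0.0, Td=1000.0)
        a = seg((5, 5, 5), (1, 0, 0))
        featA = SegmentFeatures(0.5, 0.0, 5)
        cands = [seg((10 + 3 * i, 5, 5), (1, 0, 0), branch_id=i) for i in range(len(energies))]
        feats = {id(c): SegmentFeatures(0.5 + e, 0.0, 5) for c, e in zip(cands, energies)}
        feats[id(a)] = featA
        fn = lambda s: feats[id(s)]
        target = cands[which]
        cs = build_candidate_set(a, target, [c for c in cands if c is not target], params)
        return connection_probability(a, target, cs, vol, params, feature_fn=fn)

    def test_sole_candidate_formula_forced_zero(self):
        assert self._prob([0.3]) == pytest.approx(0.0)

    def test_two_equal_energies_half(self):
        assert self._prob([0.2, 0.2]) == pytest.approx(0.5)

    def test_three_candidate_summation(self):
        """Energies {1,2,7} -> P(first) = 1 - 1/10 = 0.9."""
        assert self._prob([0.1, 0.2, 0.7]) == pytest.approx(0.9)

    def test_infinite_energy_gives_zero(self):
        vol = self._vol()
        params = ConfidenceParams(alpha=1.0, beta=0.0, Td=1000.0)
        a = seg((5, 5, 5), (1, 0, 0))
        b = seg((10, 5, 5), (-1, 0, 0), branch_id=1)  # antiparallel: theta=180
        other = seg((13, 5, 5), (1, 0, 0), branch_id=2)
        cs = build_candidate_set(a, b, [other], params)
        assert connection_probability(a, b, cs, vol, params) == 0.0

    def test_all_zero_energy_uniform_split(self):
        assert self._prob([0.0]) == pytest.approx(1.0)
        assert self._prob([0.0, 0.0, 0.0]) == pytest.approx(1.0 / 3.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 5.0), min_size=2, max_size=6))
    def test_partition_identity(self, energies):
        """Over a finite-energy candidate set, sum of (1 - P) equals 1."""
        probs = [self._prob(energies, which=i) for i in range(len(energies))]
        assert all(0.0 <= p <= 1.0 for p in probs)
        assert sum(1.0 - p for p in probs) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_decreasing_in_own_energy(self):
        p1 = self._prob([0.1, 0.3, 0.3])
        p2 = self._prob([0.2, 0.3, 0.3])
        assert p2 < p1


class TestBranchConfidence:
    def _ctx(self, tree, intensity=150.0, params=None):
        data = np.full((30, 30, 30), 20.0)
        vol = ImageVolume(data, 255.0)
        # paint tree nodes so intensities match along branches
        for n in tree.nodes:
            x, y, z = int(round(n.x)), int(round(n.y)), int(round(n.z))
            if 0 <= z < 30 and 0 <= y < 30 and 0 <= x < 30:
                vol.data[z, y, x] = intensity
        mask = TubularityMask(np.ones((30, 30, 30), bool))
        branches = decompose_branches(tree)
        return ConfidenceContext(tree, branches, vol, mask, params or ConfidenceParams(L=4), [])

    def test_root_branch_pg_is_one(self, simple_path):
        ctx = self._ctx(simple_path)
        b = ctx.branches[0]
        assert ctx.global_confidence(b) == 1.0

    def test_reverse_child_gets_zero_pg(self):
        # stem along +x, child doubling straight back
        from neuroconf import NeuronNode, NeuronTree

        nodes = [NeuronNode(1, 1, 0, 0, 0, 1, -1)]
        for i in range(1, 7):
            nodes.append(NeuronNode(i + 1, 3, float(i), 0, 0, 1, i))
        parent = 7
        for i in range(1, 6):
            nodes.append(NeuronNode(7 + i, 3, 6.0 - i, 0.01 * i, 0, 1, parent))
            parent = 7 + i
        # second (forward) child so the junction is a branch point
        parent = 7
        for i in range(1, 6):
            nodes.append(NeuronNode(12 + i, 3, 6.0 + i, -0.5 * i, 0, 1, parent))
            parent = 12 + i
        tree = NeuronTree(nodes)
        ctx = self._ctx(tree)
        reverse = next(b for b in ctx.branches if 8 in b.node_path)
        assert ctx.global_confidence(reverse) == 0.0

    def test_confidence_is_min_and_threshold(self, bifurcation):
        ctx = self._ctx(bifurcation)
        for b in ctx.branches:
            res = ctx.branch_confidence(b)
            assert res.confidence == pytest.approx(min(res.PG, res.PL))
            assert res.low_confidence == (res.confidence < ctx.params.tau)
            assert 0.0 <= res.confidence <= 1.0

    def test_single_segment_branch_pl_equals_probability(self):
        tree = path_tree(4)
        ctx = self._ctx(tree, params=ConfidenceParams(L=8))
        b = ctx.branches[0]
        # root branch with a single chain segment: convention P = 1
        assert ctx.local_confidence(b) == pytest.approx(1.0)

    def test_pl_sum_option(self, bifurcation):
        mean_ctx = self._ctx(bifurcation)
        sum_ctx = self._ctx(bifurcation, params=ConfidenceParams(L=4, pl_sum=True))
        b = mean_ctx.branches[1]
        n = len(mean_ctx.chains[b.branch_id])
        assert sum_ctx.local_confidence(b) == pytest.approx(mean_ctx.local_confidence(b) * n, rel=1e-9)
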