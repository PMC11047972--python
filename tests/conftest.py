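"""Shared fixtures: tiny trees, volumes and one rendered synthetic scene."""

import numpy as np
import pytest

from neuroconf import ImageVolume, NeuronNode, NeuronTree, SynthConfig, make_fixture


def path_tree(n=10, spacing=1.0, axis=(1.0, 0.0, 0.0)):
    """Unbranched chain of n nodes starting at the origin."""
    ax = np.asarray(axis, float)
    nodes = []
    for i in range(n):
        p = ax * spacing * i
        nodes.append(NeuronNode(i + 1, 1 if i == 0 else 3, p[0], p[1], p[2], 1.0, i if i else -1))
    return NeuronTree(nodes)


def y_tree():
    """Soma stem along +x, two children splitting in the xy plane."""
    nodes = [NeuronNode(1, 1, 0, 0, 0, 2.0, -1)]
    for i in range(1, 6):
        nodes.append(NeuronNode(i + 1, 3, float(i), 0, 0, 1.0, i))
    nid = 7
    for sign in (1, -1):
        parent = 6
        for i in range(1, 6):
            nodes.append(NeuronNode(nid, 3, 5.0 + i * 0.8, sign * i * 0.6, 0, 1.0, parent))
            parent = nid
            nid += 1
    return NeuronTree(nodes)


@pytest.fixture(scope="session")
def simple_path():
    return path_tree()

@pytest.fixture(scope="session")
def bifurcation():
    return y_tree()


@pytest.fixture(scope="session")
def uniform_volume():
    return ImageVolume(np.full((20, 20, 20), 100.0, dtype=np.float64), 255.0)


@pytest.fixture(scope="session")
def synth_fixture():
    """One rendered clean fixture shared by image-level tests."""
    return make_fixture(SynthConfig(seed=7))
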