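import pandas as pd
import pytest

import dendrokit as dk
from dendrokit import fixtures as fx


@pytest.fixture(scope="session")
def mods():
    return fx.make_channels()


@pytest.fixture(scope="session")
def chans(mods):
    return {name: dk.parse_mod(text) for name, text in mods.items()}


@pytest.fixture()
def ball_stick():
    m = fx.ball_and_stick()
    m.build_segments(3)
    return m


@pytest.fixture()
def binary2():
    m = fx.binary_tree(depth=2)
    m.build_segments(3)
    return m


def passive_table(morph, g_leak=1e-4, cm=1.0, Ra=100.0):
    n = len(morph.segments)
    return pd.DataFrame({"cm": [cm] * n, "Ra": [Ra] * n,
                         "gbar_leak": [g_leak] * n})


def single_compartment():
    from dendrokit.morphology import Morphology, PointNode
    m = Morphology([PointNode(1, 1, 0.0, 0.0, 0.0, 10.0, -1)])
    m.build_segments(1)
    return m


def dend_cable(length=500.0, diameter=2.0, nseg=51):
    """A lone sealed dendritic cable (no soma), for cable-theory checks."""
    from dendrokit.morphology import Morphology, PointNode
    m = Morphology([PointNode(1, 3, 0.0, 0.0, 0.0, diameter / 2.0, -1),
                    PointNode(2, 3, length, 0.0, 0.0, diameter / 2.0, 1)])
    m.build_segments(nseg)
    return m
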