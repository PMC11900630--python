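"""Shared fixtures: tiny hand-built networks and small generated ones."""

from __future__ import annotations

import numpy as np
import pytest

from glomflow.network import (
    BoundaryConditions,
    CapillarySegment,
    GlomerularNetwork,
    NetworkNode,
)
from glomflow.synthetic import GeneratorSpec, generate_network
from glomflow.units import PhysioConstants


def make_network(segs, aa="AA", ea="EA", r_a=0.0, r_e=0.0):
    """Build a network from (id, from, to, L, D, t) tuples."""
    segments = [CapillarySegment(*s) for s in segs]
    ids, seen = [], set()
    for s in segments:
        for nid in (s.from_node, s.to_node):
            if nid not in seen:
                seen.add(nid)
                ids.append(nid)
    kind = {aa: "aa_entry", ea: "ea_exit"}
    nodes = [NetworkNode(nid, kind.get(nid, "interior")) for nid in ids]
    net = GlomerularNetwork(nodes=nodes, segments=segments, r_a=r_a, r_e=r_e)
    net.validate()
    return net


@pytest.fixture
def physio() -> PhysioConstants:
    return PhysioConstants()


@pytest.fixture
def bc() -> BoundaryConditions:
    return BoundaryConditions(map_pressure=100.0)


@pytest.fixture
def chain_network() -> GlomerularNetwork:
    """AA -> n1 -> n2 -> EA, three capillaries in series."""
    return make_network(
        [
            ("c0", "AA", "n1", 60.0, 9.0, 0.2),
            ("c1", "n1", "n2", 50.0, 8.0, 0.2),
            ("c2", "n2", "EA", 55.0, 9.5, 0.2),
        ]
    )


@pytest.fixture
def diamond_network() -> GlomerularNetwork:
    """Two identical parallel paths: AA -> a -> {b1,b2} -> c -> EA."""
    return make_network(
        [
            ("d0", "AA", "a", 40.0, 10.0, 0.2),
            ("d1", "a", "b1", 55.0, 7.5, 0.2),
            ("d2", "a", "b2", 55.0, 7.5, 0.2),
            ("d3", "b1", "c", 45.0, 7.0, 0.2),
            ("d4", "b2", "c", 45.0, 7.0, 0.2),
            ("d5", "c", "EA", 40.0, 10.0, 0.2),
        ]
    )


@pytest.fixture(scope="session")
def small_network() -> GlomerularNetwork:
    """A generated 44-segment network for solver/fitting tests."""
    return generate_network(GeneratorSpec(seed=7, n_segments=44, n_nodes=30))


def small_spec(seed: int) -> GeneratorSpec:
    return GeneratorSpec(seed=seed, n_segments=44, n_nodes=30)
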