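"""Seeded generator of anatomically plausible glomerular capillary networks.

The real rat glomerular tuft used by the underlying reconstruction has 320
capillary segments joining 193 nodes, organised into three lobules that
branch off the afferent arteriole and coalesce into the efferent arteriole.
The generator emulates that architecture: each lobule is an
expand-then-coalesce ladder of bifurcations and anastomoses built off a
shared afferent entry node, merging into a shared efferent exit node, with
exact segment/node counts and capillary-scale lognormal diameters and
lengths.  It is a stand-in for the (optional, externally supplied)
reconstruction: counts and scales match; true lobule sizes and the degree
distribution of the real network do not.

Topology is a deterministic function of the counts; the seed drives the
geometry draws and the placement of the extra anastomoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    BoundaryConditions,
    CapillarySegment,
    GlomerularNetwork,
    NetworkNode,
    AA_ENTRY,
    EA_EXIT,
    INTERIOR,
)

__all__ = ["GeneratorSpec", "generate_network", "generate_observations"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic-network generator.

    Defaults reproduce the scale of the reconstructed rat glomerulus:
    320 segments, 193 nodes, 3 lobules.  Diameters and lengths are drawn
    lognormally (median in µm, sigma in log-space); ``lobule_bias``
    scales the diameters of successive lobules by (1, 1+b, 1+2b)/norm to
    deliberately favour flow through one lobule.
    """

    seed: int = 1
    n_lobules: int = 3
    n_segments: int = 320
    n_nodes: int = 193
    diameter_median: float = 7.0   # µm
    diameter_sigma: float = 0.25
    length_median: float = 50.0    # µm
    length_sigma: float = 0.4
    wall_thickness: float = 0.2    # µm
    lobule_bias: float = 0.0
    max_width: int = 8


def _split(total: int, parts: int) -> list[int]:
    base = total // parts
    rem = total - base * parts
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _widths(n: int, max_width: int) -> list[int]:
    """Level widths of one lobule: ramp 1,2,4,6,8..., middle, mirrored ramp."""
    ramp = [1]
    w = 1
    while True:
        w = min(w + (1 if w == 1 else 2), max_width)
        # keep room for the mirrored ramp
        if (sum(ramp) + w) * 2 > n:
            break
        ramp.append(w)
        if w == max_width:
            break
    middle_total = n - 2 * sum(ramp)
    widths = list(ramp)
    while middle_total > 0:
        take = min(max_width, middle_total)
        if take == 1 and widths[-1] > 2:
            take = 2 if middle_total >= 2 else 1
        widths.append(take)
        middle_total -= take
    widths.extend(reversed(ramp))
    assert sum(widths) == n
    return widths


def _lobule_edges(widths: list[int], n_edges: int,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    """Edges (by node index within the lobule) of one expand/coalesce ladder.

    Base edges guarantee every node has an inflow and an outflow; extra
    anastomoses between consecutive levels are added in seeded random
    order until the requested edge count is reached.
    """
    levels: list[list[int]] = []
    idx = 0
    for w in widths:
        levels.append(list(range(idx, idx + w)))
        idx += w

    edges: set[tuple[int, int]] = set()
    for la, lb in zip(levels[:-1], levels[1:]):
        for j in range(max(len(la), len(lb))):
            edges.add((la[j % len(la)], lb[j % len(lb)]))
    if len(edges) > n_edges:
        raise ValueError(
            f"lobule needs at least {len(edges)} edges for its node count, "
            f"got {n_edges}"
        )
    extra: list[tuple[int, int]] = []
    for la, lb in zip(levels[:-1], levels[1:]):
        for a in la:
            for b in lb:
                if (a, b) not in edges:
                    extra.append((a, b))
    order = rng.permutation(len(extra))
    out = sorted(edges)
    for i in order[: n_edges - len(edges)]:
        out.append(extra[i])
    # tiny lobules with a high edge/node ratio run out of distinct level
    # pairs: add parallel capillaries (the graph is a multigraph)
    all_pairs = sorted(edges) + [extra[i] for i in order]
    j = 0
    while len(out) < n_edges:
        out.append(all_pairs[j % len(all_pairs)])
        j += 1
    return sorted(out)


def generate_network(spec: GeneratorSpec | None = None) -> GlomerularNetwork:
    """Generate a valid synthetic glomerular network per the spec.

    Deterministic for a fixed spec (seed included); default spec yields
    exactly 320 segments and 193 nodes.
    """
    spec = spec or GeneratorSpec()
    if spec.n_segments <= spec.n_nodes - 1:
        raise ValueError("n_segments must exceed n_nodes - 1 (cycles required)")
    if spec.n_lobules < 1:
        raise ValueError("need at least one lobule")
    interior = spec.n_nodes - 2
    if interior < 3 * spec.n_lobules:
        raise ValueError("too few nodes for the requested lobule count")

    rng = np.random.default_rng(spec.seed)
    lob_nodes = _split(interior, spec.n_lobules)
    lob_edges = _split(spec.n_segments - 2 * spec.n_lobules, spec.n_lobules)

    nodes = [NetworkNode("AA", AA_ENTRY), NetworkNode("EA", EA_EXIT)]
    segments: list[CapillarySegment] = []
    seg_counter = 0

    bias = np.array([1.0 + spec.lobule_bias * i for i in range(spec.n_lobules)])
    bias /= bias.mean()

    for lob in range(spec.n_lobules):
        n, e = lob_nodes[lob], lob_edges[lob]
        widths = _widths(n, spec.max_width)
        local_edges = _lobule_edges(widths, e, rng)
        names = [f"L{lob + 1}n{i}" for i in range(n)]
        nodes.extend(NetworkNode(nm, INTERIOR) for nm in names)

        # level width per node, to grade diameters: edges near the lobule
        # root/outlet carry the whole lobule flow, so give them Murray-law
        # calibre (D ~ flow^(1/3), flow ~ 1/width) to keep the internal
        # pressure drop capillary-realistic
        node_width: dict[str, int] = {}
        i0 = 0
        for w in widths:
            for j in range(w):
                node_width[names[i0 + j]] = w
            i0 += w
        peak = max(widths)

        all_pairs = (
            [("AA", names[0])]
            + [(names[a], names[b]) for a, b in local_edges]
            + [(names[-1], "EA")]
        )
        wmean = np.array(
            [
                0.5 * (node_width.get(fr, 1) + node_width.get(to, 1))
                for fr, to in all_pairs
            ]
        )
        calibre = (peak / wmean) ** (1.0 / 3.0)
        d = (
            spec.diameter_median * bias[lob] * calibre
            * np.exp(spec.diameter_sigma * rng.standard_normal(len(all_pairs)))
        )
        ln = spec.length_median * np.exp(
            spec.length_sigma * rng.standard_normal(len(all_pairs))
        )
        for i, (fr, to) in enumerate(all_pairs):
            segments.append(
                CapillarySegment(
                    segment_id=f"s{seg_counter:04d}",
                    from_node=fr,
                    to_node=to,
                    length=float(ln[i]),
                    diameter=float(d[i]),
                    wall_thickness=spec.wall_thickness,
                )
            )
            seg_counter += 1

    net = GlomerularNetwork(nodes=nodes, segments=segments)
    net.validate()
    assert net.n_segments == spec.n_segments and net.n_nodes == spec.n_nodes
    return net


def generate_observations(
    network: GlomerularNetwork,
    true_params: tuple[float, float, float],
    bc: BoundaryConditions,
    noise_sd: float = 0.0,
    seed: int | None = None,
    condition: str = "synthetic",
):
    """Forward-simulate known parameters into noisy hemodynamic 'observations'.

    ``true_params`` is (R_A, R_E, k) in reported units.  Returns a
    :class:`~glomflow.fitting.HemodynamicTargets` whose (P_GC, Q_A, SNGFR)
    are the forward model outputs, optionally perturbed by multiplicative
    Gaussian noise of relative standard deviation ``noise_sd``.  With
    ``noise_sd = 0`` the targets equal the forward values exactly, so
    fitting them must recover the true parameters (the package's core
    inverse-problem check).
    """
    from .fitting import HemodynamicTargets
    from .solver import solve_network

    r_a, r_e, k = true_params
    sol = solve_network(network, bc, k, r_a, r_e)
    vals = np.array([sol.p_gc, sol.q_a_plasma, sol.sngfr])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals * (1.0 + noise_sd * rng.standard_normal(3))
    return HemodynamicTargets(
        condition=condition,
        map_pressure=bc.map_pressure,
        p_gc=float(vals[0]),
        q_a=float(vals[1]),
        sngfr=float(vals[2]),
    )
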