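"""Glomerular capillary network data model and I/O.

A :class:`GlomerularNetwork` is an undirected multigraph of capillary
segments between named nodes, with exactly one afferent entry node and one
efferent exit node; the afferent and efferent arterioles themselves are
lumped resistors ``r_a``/``r_e`` outside the graph.  Segments carry a
reference orientation (``from_node`` -> ``to_node``) that is purely a
bookkeeping convention — actual flow direction is a property of the solved
pressure field, not of the anatomy file.

Supported on-disk formats: edge-list CSV, a JSON mirror of it, and GraphML
export (for visualisation in generic graph tools).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "NetworkNode",
    "CapillarySegment",
    "GlomerularNetwork",
    "BoundaryConditions",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "validate_network",
]

AA_ENTRY = "aa_entry"
EA_EXIT = "ea_exit"
INTERIOR = "interior"

CSV_COLUMNS = ["segment_id", "from", "to", "length_um", "diameter_um", "wall_thickness_um"]


class NetworkValidationError(ValueError):
    """Raised when a network breaches a structural invariant."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    kind: str = INTERIOR  # interior | aa_entry | ea_exit


@dataclass(frozen=True)
class CapillarySegment:
    """One capillary: geometry only; rheology state lives in the solver."""

    segment_id: str
    from_node: str
    to_node: str
    length: float          # µm
    diameter: float        # µm
    wall_thickness: float  # µm


@dataclass
class GlomerularNetwork:
    """Capillary graph plus the two arteriolar boundary resistors.

    ``r_a`` and ``r_e`` are in reported units (mmHg·min/nL) and may be
    overridden per solve/fit; they default to 0 (no boundary resistance)
    until set.
    """

    nodes: list[NetworkNode]
    segments: list[CapillarySegment]
    r_a: float = 0.0
    r_e: float = 0.0

    # -- convenience accessors -------------------------------------------------
    @property
    def aa_entry(self) -> str:
        return next(n.node_id for n in self.nodes if n.kind == AA_ENTRY)

    @property
    def ea_exit(self) -> str:
        return next(n.node_id for n in self.nodes if n.kind == EA_EXIT)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": [s.segment_id for s in self.segments],
                "from": [s.from_node for s in self.segments],
                "to": [s.to_node for s in self.segments],
                "length_um": [s.length for s in self.segments],
                "diameter_um": [s.diameter for s in self.segments],
                "wall_thickness_um": [s.wall_thickness for s in self.segments],
            }
        )

    def to_multigraph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.node_id, kind=n.kind)
        for s in self.segments:
            g.add_edge(
                s.from_node,
                s.to_node,
                key=s.segment_id,
                segment_id=s.segment_id,
                length_um=s.length,
                diameter_um=s.diameter,
                wall_thickness_um=s.wall_thickness,
            )
        return g

    def validate(self) -> None:
        violations = validate_network(self)
        if violations:
            raise NetworkValidationError(violations)


def _infer_nodes(segments: list[CapillarySegment], aa: str, ea: str) -> list[NetworkNode]:
    ids: list[str] = []
    seen = set()
    for s in segments:
        for nid in (s.from_node, s.to_node):
            if nid not in seen:
                seen.add(nid)
                ids.append(nid)
    kind = {aa: AA_ENTRY, ea: EA_EXIT}
    return [NetworkNode(nid, kind.get(nid, INTERIOR)) for nid in ids]


def build_network(
    segments: list[CapillarySegment], aa_entry: str, ea_exit: str,
    r_a: float = 0.0, r_e: float = 0.0,
) -> GlomerularNetwork:
    """Assemble and validate a network from a segment list and boundary labels."""
    net = GlomerularNetwork(
        nodes=_infer_nodes(segments, aa_entry, ea_exit),
        segments=list(segments),
        r_a=r_a,
        r_e=r_e,
    )
    net.validate()
    return net


def validate_network(network: GlomerularNetwork) -> list[str]:
    """Return a list of invariant violations (empty when the network is valid)."""
    v: list[str] = []
    aa = [n for n in network.nodes if n.kind == AA_ENTRY]
    ea = [n for n in network.nodes if n.kind == EA_EXIT]
    if len(aa) != 1:
        v.append(f"expected exactly one {AA_ENTRY} node, found {len(aa)}")
    if len(ea) != 1:
        v.append(f"expected exactly one {EA_EXIT} node, found {len(ea)}")

    node_ids = [n.node_id for n in network.nodes]
    if len(set(node_ids)) != len(node_ids):
        v.append("duplicate node ids")

    seen_seg = set()
    for s in network.segments:
        if s.segment_id in seen_seg:
            v.append(f"duplicate segment id {s.segment_id!r}")
        seen_seg.add(s.segment_id)
        if s.from_node == s.to_node:
            v.append(f"segment {s.segment_id!r} is a self-loop at {s.from_node!r}")
        if s.length <= 0:
            v.append(f"segment {s.segment_id!r} has non-positive length {s.length}")
        if s.diameter <= 0:
            v.append(f"segment {s.segment_id!r} has non-positive diameter {s.diameter}")
        if s.wall_thickness <= 0:
            v.append(
                f"segment {s.segment_id!r} has non-positive wall thickness "
                f"{s.wall_thickness}"
            )
        for nid in (s.from_node, s.to_node):
            if nid not in set(node_ids):
                v.append(f"segment {s.segment_id!r} references unknown node {nid!r}")

    if network.r_a < 0 or network.r_e < 0:
        v.append("boundary resistances must be non-negative")

    if not network.segments:
        v.append("network has no segments")
        return v

    g = network.to_multigraph()
    if not nx.is_connected(g):
        comps = list(nx.connected_components(g))
        v.append(f"graph is disconnected ({len(comps)} components)")
    elif aa and ea and len(aa) == 1 and len(ea) == 1:
        if not nx.has_path(g, aa[0].node_id, ea[0].node_id):
            v.append("no path from aa_entry to ea_exit")

    boundary = {n.node_id for n in aa + ea}
    for n in network.nodes:
        if n.node_id in boundary:
            continue
        if g.degree(n.node_id) < 2:
            v.append(f"interior node {n.node_id!r} has degree {g.degree(n.node_id)} < 2")
    return v


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _segments_from_frame(df: pd.DataFrame, default_wall: float) -> list[CapillarySegment]:
    required = {"segment_id", "from", "to", "length_um", "diameter_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if "wall_thickness_um" not in df.columns:
        df = df.assign(wall_thickness_um=default_wall)
    df = df.copy()
    df["wall_thickness_um"] = df["wall_thickness_um"].fillna(default_wall)
    return [
        CapillarySegment(
            segment_id=str(r["segment_id"]),
            from_node=str(r["from"]),
            to_node=str(r["to"]),
            length=float(r["length_um"]),
            diameter=float(r["diameter_um"]),
            wall_thickness=float(r["wall_thickness_um"]),
        )
        for _, r in df.iterrows()
    ]


def read_network(
    path: str | Path,
    fmt: str | None = None,
    aa_entry: str | None = None,
    ea_exit: str | None = None,
    default_wall_thickness: float = 0.2,
) -> GlomerularNetwork:
    """Read a network from edge-list CSV or JSON.

    For CSV the boundary node labels must be given (or default to ``"AA"``
    and ``"EA"`` if present in the file); the JSON format stores them.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"

    if fmt == "csv":
        df = pd.read_csv(path)
        segments = _segments_from_frame(df, default_wall_thickness)
        node_ids = {s.from_node for s in segments} | {s.to_node for s in segments}
        aa = aa_entry if aa_entry is not None else ("AA" if "AA" in node_ids else None)
        ea = ea_exit if ea_exit is not None else ("EA" if "EA" in node_ids else None)
        if aa is None or ea is None:
            raise ValueError(
                "aa_entry/ea_exit labels required (no AA/EA nodes found in file)"
            )
        net = GlomerularNetwork(nodes=_infer_nodes(segments, aa, ea), segments=segments)
    elif fmt == "json":
        with open(path) as fh:
            obj = json.load(fh)
        df = pd.DataFrame(obj["segments"])
        segments = _segments_from_frame(df, default_wall_thickness)
        net = GlomerularNetwork(
            nodes=_infer_nodes(segments, obj["aa_entry"], obj["ea_exit"]),
            segments=segments,
            r_a=float(obj.get("r_a", 0.0)),
            r_e=float(obj.get("r_e", 0.0)),
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")

    net.validate()
    return net


def write_network(network: GlomerularNetwork, path: str | Path, fmt: str | None = None) -> Path:
    """Write a network as edge-list CSV, JSON, or GraphML.

    CSV/JSON round-trip losslessly; GraphML carries geometry as edge
    attributes and node kinds as node attributes.
    """
    if not network.segments:
        raise ValueError("refusing to write an empty network")
    path = Path(path)
    if fmt is None:
        fmt = {".json": "json", ".graphml": "graphml"}.get(path.suffix.lower(), "csv")

    if fmt == "csv":
        network.segment_table().to_csv(path, index=False, float_format="%.12g")
    elif fmt == "json":
        obj = {
            "aa_entry": network.aa_entry,
            "ea_exit": network.ea_exit,
            "r_a": network.r_a,
            "r_e": network.r_e,
            "segments": network.segment_table().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
    elif fmt == "graphml":
        nx.write_graphml(network.to_multigraph(), path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


@dataclass(frozen=True)
class BoundaryConditions:
    """Pressures and afferent blood composition driving one solve.

    Pressures in mmHg; ``map_pressure`` sits upstream of the afferent
    resistor, ``p_downstream`` downstream of the efferent resistor,
    ``p_bs`` in Bowman's space on the far side of every capillary wall.
    """

    map_pressure: float
    p_downstream: float = 15.0
    p_bs: float = 14.0
    hematocrit_in: float = 0.5
    protein_conc_in: float = 5.7

    def __post_init__(self) -> None:
        if self.map_pressure <= self.p_downstream:
            raise ValueError("MAP must exceed the downstream pressure")
        if self.map_pressure <= self.p_bs:
            raise ValueError("MAP must exceed Bowman's-space pressure")
        if not 0.0 <= self.hematocrit_in < 1.0:
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.protein_conc_in < 0:
            raise ValueError("protein concentration must be non-negative")
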