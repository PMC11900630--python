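"""Per-capillary mechanical stresses and condition-vs-condition comparisons.

Two wall stresses are computed for every capillary from a converged
solution:

* shear stress on the endothelium (Poiseuille):
  ``tau = 32 µ <|Q|> / (π D³)`` with <|Q|> the length-averaged magnitude
  of the axial blood flow, reported in dyn/cm²;
* circumferential hoop stress on the wall (Laplace law on the length-mean
  transmural pressure): ``sigma = D <p − p_BS> / (2 t)``, reported in kPa.

Hoop-stress magnitudes scale with the assumed wall thickness t (not
measured here), so only hoop *ratios* across conditions are robust; the
report header echoes the thickness used.  Population comparisons use
Welch's unequal-variance t-test across the segment population (no
multiple-testing correction); paired per-segment deltas are available when
two reports share a topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .mechanics import FlowProfile, SegmentProfile, excess_pressure_integral
from .network import GlomerularNetwork
from .solver import NetworkSolution
from .units import from_working, to_working

__all__ = [
    "StressReport",
    "segment_shear_stress",
    "segment_hoop_stress",
    "build_stress_report",
    "compare_conditions",
    "welch_t",
    "export_stress_map",
]


def segment_shear_stress(mu_cp: float, flowp: FlowProfile, diameter_um: float) -> float:
    """Wall shear stress of one segment, dyn/cm².

    32 µ <|Q|> / (π D³), evaluated in working units from the closed-form
    flow profile.  Sign is dropped: the stress magnitude on the wall is
    what matters, and the flow direction is already the solved one.
    """
    q_mean_w = to_working(flowp.mean_abs_flow(), "flow")
    mu_w = to_working(mu_cp, "viscosity")
    tau_w = 32.0 * mu_w * q_mean_w / (math.pi * diameter_um**3)
    return from_working(tau_w, "shear_stress")


def segment_hoop_stress(profile: SegmentProfile, diameter_um: float,
                        wall_um: float) -> float:
    """Laplace hoop stress of one segment, kPa.

    D·<p − p_BS>/(2t) on the length-mean transmural pressure (profile in
    mmHg).
    """
    if wall_um <= 0:
        raise ValueError("wall thickness must be positive")
    mean_excess_mmHg = excess_pressure_integral(profile) / profile.length
    sigma_w = diameter_um * to_working(mean_excess_mmHg, "pressure") / (2.0 * wall_um)
    return from_working(sigma_w, "hoop_stress")


@dataclass
class StressReport:
    """Per-segment stress table plus network summaries for one condition."""

    condition: str
    table: pd.DataFrame        # segment_id, csgfr, tau_dyn_cm2, sigma_kPa, ...
    wall_thickness_note: str
    sngfr: float

    def summary(self) -> pd.DataFrame:
        t = self.table
        rows = []
        for col, name in (("tau_dyn_cm2", "shear (dyn/cm^2)"),
                          ("sigma_kPa", "hoop (kPa)"),
                          ("csgfr", "CSGFR (nL/min)")):
            rows.append(
                {"quantity": name, "mean": t[col].mean(),
                 "sd": t[col].std(ddof=1), "n": len(t)}
            )
        return pd.DataFrame(rows)


def build_stress_report(
    solution: NetworkSolution,
    network: GlomerularNetwork,
    condition: str = "",
) -> StressReport:
    """Stress table for every segment of a converged solution.

    Segments are annotated with their (unweighted) graph distance to the
    afferent entry and efferent exit, supporting inspection of where in
    the network the stresses concentrate.
    """
    g = network.to_multigraph()
    d_aa = nx.single_source_shortest_path_length(g, network.aa_entry)
    d_ea = nx.single_source_shortest_path_length(g, network.ea_exit)

    rows = []
    for _, r in solution.segments.iterrows():
        prof, flowp = solution.segment_profile(r["segment_id"])
        tau = segment_shear_stress(r["mu_cp"], flowp, r["diameter_um"])
        sigma = segment_hoop_stress(prof, r["diameter_um"], r["wall_thickness_um"])
        rows.append(
            {
                "segment_id": r["segment_id"],
                "csgfr": r["csgfr"],
                "tau_dyn_cm2": tau,
                "sigma_kPa": sigma,
                "mean_pressure_mmHg": r["mean_pressure_mmHg"],
                "q_in": r["q_in"],
                "dist_to_aa": min(d_aa[r["upstream"]], d_aa[r["downstream"]]),
                "dist_to_ea": min(d_ea[r["upstream"]], d_ea[r["downstream"]]),
            }
        )
    table = pd.DataFrame(rows)
    wall = network.segments[0].wall_thickness
    return StressReport(
        condition=condition,
        table=table,
        wall_thickness_note=(
            f"hoop stress computed with assumed wall thickness "
            f"{wall:g} um; only cross-condition ratios are robust"
        ),
        sngfr=solution.sngfr,
    )


def welch_t(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df.

    Returns mean difference, t, df and the two-sided p.  Degenerate
    (zero-variance) inputs are flagged rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx_, ny_ = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    se2 = vx / nx_ + vy / ny_
    if se2 == 0.0:
        return {"mean_diff": float(diff), "t": 0.0 if diff == 0 else math.inf,
                "df": float(nx_ + ny_ - 2), "p": 1.0 if diff == 0 else 0.0,
                "degenerate": True}
    t = diff / math.sqrt(se2)
    df = se2**2 / ((vx / nx_) ** 2 / (nx_ - 1) + (vy / ny_) ** 2 / (ny_ - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"mean_diff": float(diff), "t": float(t), "df": float(df),
            "p": float(p), "degenerate": False}


def compare_conditions(
    report_a: StressReport,
    report_b: StressReport,
    paired_by_segment: bool = True,
) -> dict:
    """Compare two conditions' stress populations (a minus b).

    Always reports Welch's test across the segment populations for mean
    shear and mean hoop stress; when ``paired_by_segment`` the two
    reports must share a segment set and per-segment deltas are included.
    """
    out: dict = {"a": report_a.condition, "b": report_b.condition}
    for col, name in (("tau_dyn_cm2", "shear"), ("sigma_kPa", "hoop")):
        out[name] = welch_t(report_a.table[col].to_numpy(),
                            report_b.table[col].to_numpy())
    if paired_by_segment:
        ta = report_a.table.set_index("segment_id")
        tb = report_b.table.set_index("segment_id")
        if not ta.index.equals(tb.index):
            if set(ta.index) != set(tb.index):
                raise ValueError("paired comparison requires identical segment sets")
            tb = tb.loc[ta.index]
        deltas = pd.DataFrame(
            {
                "segment_id": ta.index,
                "d_tau_dyn_cm2": (ta["tau_dyn_cm2"] - tb["tau_dyn_cm2"]).to_numpy(),
                "d_sigma_kPa": (ta["sigma_kPa"] - tb["sigma_kPa"]).to_numpy(),
                "d_csgfr": (ta["csgfr"] - tb["csgfr"]).to_numpy(),
            }
        )
        out["deltas"] = deltas
        out["frac_tau_increased"] = float((deltas["d_tau_dyn_cm2"] > 0).mean())
    return out


def export_stress_map(
    report: StressReport,
    network: GlomerularNetwork,
    path,
    quantity: str = "tau_dyn_cm2",
    graphml_path=None,
):
    """Render the network coloured by a stress quantity; optionally export
    GraphML with the stress attributes attached to edges."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = network.to_multigraph()
    values = report.table.set_index("segment_id")[quantity]
    simple = nx.Graph(g)  # layout on the simple graph
    pos = nx.kamada_kawai_layout(simple)
    fig, ax = plt.subplots(figsize=(8, 8))
    vmin, vmax = float(values.min()), float(values.max())
    cmap = plt.get_cmap("viridis")
    for u, v, key in g.edges(keys=True):
        val = values[key]
        frac = 0.5 if vmax == vmin else (val - vmin) / (vmax - vmin)
        ax.plot(*zip(pos[u], pos[v]), color=cmap(frac), linewidth=2)
    nx.draw_networkx_nodes(simple, pos, ax=ax, node_size=8, node_color="k")
    sm = plt.cm.ScalarMappable(cmap=cmap,
                               norm=matplotlib.colors.Normalize(vmin, vmax))
    fig.colorbar(sm, ax=ax, label=quantity)
    ax.set_title(f"{report.condition}: {quantity}")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)

    if graphml_path is not None:
        for u, v, key in g.edges(keys=True):
            g.edges[u, v, key][quantity] = float(values[key])
        nx.write_graphml(g, graphml_path)
    return path
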