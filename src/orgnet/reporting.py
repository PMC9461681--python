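"""Network plots, per-case metric summaries, and perception tabulation.

Plot conventions: one node per roster organization (isolates are always
drawn), node color keyed to organization type with a legend, node area a
linear function of degree centrality (in-degree for directed networks)
with a floor so isolates stay visible, arrowheads only on directed
networks, and a force-directed layout that is deterministic for a given
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

from .cpat_scoring import CPATDomainMap, CPATResponseSet, score_provider, score_team
from .network_metrics import NetworkMetrics, compute_metrics
from .survey_io import OrgType, Roster
from .tie_construction import Sociomatrix

__all__ = ["CaseSummary", "plot_network", "summarize_case", "tabulate_perceptions"]

_TYPE_COLORS: dict[OrgType, str] = {
    OrgType.PRIMARY_CARE_LEAD: "#d62728",
    OrgType.PRIMARY_CARE: "#ff9896",
    OrgType.HOSPITAL: "#1f77b4",
    OrgType.HOME_COMMUNITY_CARE: "#2ca02c",
    OrgType.LONG_TERM_CARE: "#9467bd",
    OrgType.COMMUNITY_AGENCY: "#8c564b",
    OrgType.GOVERNMENT_AGENCY: "#e377c2",
    OrgType.OTHER: "#7f7f7f",
}

_SIZE_FLOOR = 120.0  # pt²; isolates must remain visible
_SIZE_SLOPE = 140.0


def _to_graph(m: Sociomatrix) -> Union[nx.Graph, nx.DiGraph]:
    g: Union[nx.Graph, nx.DiGraph] = nx.DiGraph() if m.directed else nx.Graph()
    ids = m.roster.org_ids
    g.add_nodes_from(ids)
    for i in range(m.n):
        for j in range(m.n):
            if m.values[i, j] and (m.directed or i < j):
                g.add_edge(ids[i], ids[j])
    return g


def plot_network(
    m: Sociomatrix,
    path: Union[str, Path],
    size_basis: Literal["degree", "in_degree"] | None = None,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Render one sociomatrix to an image file; returns the layout positions.

    ``size_basis`` defaults to total degree for undirected networks and
    in-degree for directed ones.  The returned ``{org_id: (x, y)}`` dict is
    byte-stable for a fixed matrix and seed.
    """
    if size_basis is None:
        size_basis = "in_degree" if m.directed else "degree"
    if size_basis == "in_degree" and not m.directed:
        raise ValueError("in_degree sizing is undefined on an undirected network")
    metrics = compute_metrics(m)
    cent = metrics.in_degree if size_basis == "in_degree" else metrics.degree

    g = _to_graph(m)
    pos = nx.spring_layout(g, seed=seed)
    sizes = [_SIZE_FLOOR + _SIZE_SLOPE * cent[org] for org in g.nodes]
    colors = [
        _TYPE_COLORS[m.roster.organizations[m.roster.index(org)].org_type]
        for org in g.nodes
    ]

    fig, ax = plt.subplots(figsize=(7, 6))
    nx.draw_networkx_edges(
        g, pos, ax=ax, arrows=m.directed, edge_color="#999999",
        connectionstyle="arc3,rad=0.05" if m.directed else "arc3",
    )
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=sizes, node_color=colors)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=7)
    present = {m.roster.organizations[m.roster.index(org)].org_type for org in g.nodes}
    handles = [
        plt.Line2D([], [], marker="o", linestyle="", color=_TYPE_COLORS[t],
                   label=t.value.replace("_", " "))
        for t in OrgType if t in present
    ]
    ax.legend(handles=handles, loc="lower left", fontsize=7, frameon=False)
    basis_label = "in-degree" if size_basis == "in_degree" else "degree"
    ax.set_title(
        f"{m.roster.case_label}: {m.relation.value.replace('_', ' ')} "
        f"({m.mode}, node size ∝ {basis_label})"
        if m.directed
        else f"{m.roster.case_label}: {m.relation.value.replace('_', ' ')} "
        f"(node size ∝ {basis_label})",
        fontsize=10,
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return {org: (float(x), float(y)) for org, (x, y) in pos.items()}


@dataclass
class CaseSummary:
    """Per-case summary: one row per (relation, mode) plus CPAT and perceptions."""

    case_label: str
    metrics: list[NetworkMetrics]
    cpat_team_score: float | None = None
    cpat_team_sd: float | None = None
    perception_percentages: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.metrics:
            rows.append(
                {
                    "case": self.case_label,
                    "relation": m.relation,
                    "mode": m.mode,
                    "n": m.n,
                    "ties": m.tie_count,
                    "density": round(m.density, 3),
                    "density_band": m.density_band,
                    "centralization": round(m.centralization, 3),
                    "centralization_basis": m.centralization_basis,
                    "centralization_band": m.centralization_band,
                    "isolates": len(m.isolates),
                    "response_rate": m.response_rate,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "case": self.case_label,
            "networks": [m.to_dict() for m in self.metrics],
            "cpat_team_score": self.cpat_team_score,
            "cpat_team_sd": self.cpat_team_sd,
            "perceptions": self.perception_percentages,
        }
        return json.dumps(payload, indent=2)


def summarize_case(
    networks: Iterable[Sociomatrix],
    roster: Roster,
    cpat: pd.DataFrame | None = None,
    domain_map: CPATDomainMap | None = None,
    perceptions: pd.DataFrame | None = None,
) -> CaseSummary:
    """Tabulate metrics for every built network of one case.

    Densities, centralizations and bands in the summary are recomputed
    directly from the matrices, so the table is recomputation-stable.
    """
    networks = list(networks)
    if not networks:
        raise ValueError("summarize_case needs at least one built network")
    for m in networks:
        if m.roster.case_label != roster.case_label:
            raise ValueError("all networks must belong to the summarized case")
    metrics = [compute_metrics(m) for m in networks]
    team_score = team_sd = None
    if cpat is not None and not cpat.empty:
        totals = [
            score_provider(r, domain_map) for r in CPATResponseSet.from_frame(cpat)
        ]
        team_score, team_sd = score_team(totals)
    percep = tabulate_perceptions(perceptions, roster) if perceptions is not None else None
    return CaseSummary(
        case_label=roster.case_label,
        metrics=metrics,
        cpat_team_score=team_score,
        cpat_team_sd=team_sd,
        perception_percentages=percep,
    )


def tabulate_perceptions(responses: pd.DataFrame, roster: Roster) -> dict[str, float]:
    """Per-item endorsement percentages among responding organizations.

    For each item: 100 × endorsers / respondents, to one decimal.  The
    denominator is the number of responding organizations on the roster.
    """
    n_resp = len(roster.respondents)
    if n_resp == 0:
        raise ValueError("no responding organizations: percentages undefined")
    out: dict[str, float] = {}
    for item, grp in responses.groupby("item", sort=True):
        endorsers = int(grp["endorsed"].astype(bool).sum())
        out[str(item)] = round(100.0 * endorsers / n_resp, 1)
    return out
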