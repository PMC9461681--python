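"""Network- and node-level measures with interpretive bands.

Implements the standard whole-network descriptives for binary
sociomatrices: density (realized ties over possible ties), Freeman degree
centralization (concentration of connectivity on a few actors), per-node
degree/in-degree/out-degree centrality, isolate detection, and the
organization-level survey response rate.  Density and centralization
scores are classified into interpretive bands: under 0.30 low, 0.30–0.50
moderate (inclusive at both ends), above 0.50 high.

Centralization follows Freeman's index: the sum of gaps between the
maximum observed centrality and each actor's centrality, normalized by the
maximum attainable gap sum — (n−1)(n−2) for undirected total degree, and
(n−1)² for directed in- or out-degree.  A star achieves 1.0 on the
relevant basis; any regular graph achieves 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .survey_io import Roster
from .tie_construction import Sociomatrix

__all__ = [
    "NetworkMetrics",
    "classify_band",
    "compute_metrics",
    "count_isolates",
    "degree_centrality",
    "density",
    "freeman_centralization",
    "response_rate",
]

Basis = Literal["total", "in", "out"]
Band = Literal["low", "moderate", "high"]


def density(m: Sociomatrix) -> float:
    """Proportion of actual ties relative to the maximum possible.

    Undirected: 2·edges / n(n−1).  Directed: arcs / n(n−1) (possible ties
    counted at the arc level).  0 means no connections; 1 means every pair
    of members is connected.
    """
    n = m.n
    if n < 2:
        raise ValueError(f"density undefined for n={n} < 2")
    total = int(m.values.sum())  # undirected matrices count each edge twice
    return total / (n * (n - 1))


def degree_centrality(m: Sociomatrix, basis: Basis = "total") -> np.ndarray:
    """Per-node tie counts on the requested basis.

    ``in``/``out`` are only defined for directed matrices.  ``total`` on a
    directed matrix counts distinct neighbors (union of in- and
    out-neighborhoods), so a reciprocated arc pair contributes one.
    """
    if basis not in ("total", "in", "out"):
        raise ValueError(f"unknown basis {basis!r}")
    if basis in ("in", "out") and not m.directed:
        raise ValueError(f"{basis}-degree is undefined on an undirected network")
    a = m.values
    if basis == "in":
        return a.sum(axis=0).astype(int)
    if basis == "out":
        return a.sum(axis=1).astype(int)
    if m.directed:
        return ((a + a.T) > 0).sum(axis=1).astype(int)
    return a.sum(axis=1).astype(int)


def freeman_centralization(m: Sociomatrix, basis: Basis | None = None) -> float:
    """Freeman degree centralization in [0, 1].

    Σᵢ(c_max − cᵢ) over the maximum attainable sum: (n−1)(n−2) for
    undirected total degree, (n−1)² for directed in/out degree.  All-zero
    networks score 0 by convention.  Defaults to in-degree for directed
    matrices and total degree for undirected ones.
    """
    n = m.n
    if n < 3:
        raise ValueError(f"centralization undefined for n={n} < 3")
    if basis is None:
        basis = "in" if m.directed else "total"
    c = degree_centrality(m, basis)
    if c.max() == 0:
        return 0.0
    gaps = (c.max() - c).sum()
    if basis == "total":
        denom = (n - 1) * (n - 2)
    else:
        denom = (n - 1) ** 2
    return float(gaps) / denom


def classify_band(score: float) -> Band:
    """Interpretive band for a density or centralization score.

    Under 0.30 → low; 0.30–0.50 (inclusive) → moderate; above 0.50 → high.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score < 0.30:
        return "low"
    if score <= 0.50:
        return "moderate"
    return "high"


def count_isolates(m: Sociomatrix) -> tuple[int, list[str]]:
    """Organizations with zero ties on the total-degree basis."""
    deg = degree_centrality(m, "total")
    ids = [org for org, d in zip(m.roster.org_ids, deg) if d == 0]
    return len(ids), ids


def response_rate(roster: Roster) -> float:
    """Survey response rate as a percentage, to one decimal place."""
    return round(100.0 * len(roster.respondents) / roster.n, 1)


@dataclass
class NetworkMetrics:
    """Metric bundle for one relation network in one mode."""

    case_label: str
    relation: str
    mode: str
    n: int
    tie_count: int
    density: float
    density_band: Band
    centralization: float
    centralization_basis: Basis
    centralization_band: Band
    response_rate: float
    isolates: list[str]
    degree: dict[str, int]
    in_degree: dict[str, int] = field(default_factory=dict)
    out_degree: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        per_node = {
            org: {
                "degree": self.degree[org],
                **({"in": self.in_degree[org]} if self.in_degree else {}),
                **({"out": self.out_degree[org]} if self.out_degree else {}),
            }
            for org in self.degree
        }
        return {
            "case": self.case_label,
            "relation": self.relation,
            "mode": self.mode,
            "n": self.n,
            "L": self.tie_count,
            "density": round(self.density, 3),
            "density_band": self.density_band,
            "centralization": round(self.centralization, 3),
            "centralization_basis": self.centralization_basis,
            "centralization_band": self.centralization_band,
            "response_rate": self.response_rate,
            "isolates": self.isolates,
            "per_node": per_node,
        }


def compute_metrics(m: Sociomatrix, basis: Basis | None = None) -> NetworkMetrics:
    """Compute the full metric bundle for one sociomatrix.

    ``basis`` selects the centralization degree basis; the default is
    in-degree for directed networks (matching the node-size convention for
    directed network plots) and total degree for undirected ones.
    """
    if basis is None:
        basis = "in" if m.directed else "total"
    ids = m.roster.org_ids
    deg = dict(zip(ids, map(int, degree_centrality(m, "total"))))
    in_deg = dict(zip(ids, map(int, degree_centrality(m, "in")))) if m.directed else {}
    out_deg = dict(zip(ids, map(int, degree_centrality(m, "out")))) if m.directed else {}
    d = density(m)
    c = freeman_centralization(m, basis)
    _, isolate_ids = count_isolates(m)
    return NetworkMetrics(
        case_label=m.roster.case_label,
        relation=m.relation.value,
        mode=m.mode,
        n=m.n,
        tie_count=m.tie_count,
        density=d,
        density_band=classify_band(d),
        centralization=c,
        centralization_basis=basis,
        centralization_band=classify_band(c),
        response_rate=response_rate(m.roster),
        isolates=isolate_ids,
        degree=deg,
        in_degree=in_deg,
        out_degree=out_deg,
    )
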