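"""From validated dyadic responses to per-relation binary sociomatrices.

The preprocessing rules, applied per relation kind:

* **Undirected relations** (contact, integration).  Each respondent's
  report is dichotomized at the relation's cut-off (contact: monthly or
  more often; integration: coordination or above).  When the two members
  of a dyad disagree, the mean of the two reports is taken and the dyad is
  linked when the mean reaches the discrepancy threshold (default 0.5,
  inclusive).  Dyads with exactly one responding endpoint are imputed by
  *reconstruction*: the single respondent's report is taken as the dyad
  value — defensible only while organization-level missingness stays under
  the configured limit (default 30 %).
* **Directed relations** (referral, information sharing, joint care
  planning, shared resources).  In *confirmed* mode an arc A→B exists only
  when A reports sending to B and B reports receiving from A; in
  *unconfirmed* mode either report suffices.  Dyads touching a
  nonrespondent cannot be confirmed; by default the single available
  report is used as a fallback (configurable to strict dropping).

A respondent who lists no tie with some partner is read as reporting the
absence of a tie (frequency ``none`` / level ``not_linked`` / no arc) for
that partner — the roster-based questionnaire enumerates all partners, so
silence from a respondent is an answer, unlike silence from a
nonrespondent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Union

import numpy as np
import pandas as pd

from .survey_io import (
    CONTACT_LEVELS,
    INTEGRATION_LEVELS,
    DyadicResponse,
    Relation,
    Roster,
    respondent_missingness,
)

__all__ = [
    "ImputationRefusedError",
    "Sociomatrix",
    "TieRuleConfig",
    "build_network",
    "confirm_ties",
    "dichotomize_contact",
    "dichotomize_integration",
    "read_adjacency",
    "reconstruct_impute",
    "resolve_discrepancy",
    "write_adjacency",
    "write_edgelist",
]

logger = logging.getLogger(__name__)

Mode = Literal["confirmed", "unconfirmed", "not_applicable"]


class ImputationRefusedError(RuntimeError):
    """Missingness is too high for reconstruction imputation to be defensible."""


@dataclass(frozen=True)
class TieRuleConfig:
    """Tunable preprocessing rules.

    contact_cutoff / integration_cutoff
        Ordinal codes at or above which a report counts as a tie.
        Defaults: monthly (contact code 3) and coordination (code 3).
    discrepancy_threshold
        Mean tie value at or above which a discrepant dyad is linked.
    missingness_limit
        Organization-level nonresponse fraction above which reconstruction
        imputation is refused.
    single_report_fallback
        For directed dyads with one nonrespondent endpoint, use the single
        available report (True) or leave the dyad missing (False).
    averaging
        ``"dichotomize_first"`` averages the two dichotomized reports;
        ``"ordinal_first"`` averages the raw ordinal codes and applies the
        cut-off to the mean.
    """

    contact_cutoff: int = CONTACT_LEVELS.index("monthly")
    integration_cutoff: int = INTEGRATION_LEVELS.index("coordination")
    discrepancy_threshold: float = 0.5
    missingness_limit: float = 0.30
    single_report_fallback: bool = True
    averaging: Literal["dichotomize_first", "ordinal_first"] = "dichotomize_first"

    def __post_init__(self) -> None:
        if not 0 <= self.contact_cutoff < len(CONTACT_LEVELS):
            raise ValueError(f"contact_cutoff {self.contact_cutoff} outside ordinal domain")
        if not 0 <= self.integration_cutoff < len(INTEGRATION_LEVELS):
            raise ValueError(
                f"integration_cutoff {self.integration_cutoff} outside ordinal domain"
            )
        if not 0 < self.discrepancy_threshold <= 1:
            raise ValueError("discrepancy_threshold must be in (0, 1]")
        if not 0 < self.missingness_limit <= 1:
            raise ValueError("missingness_limit must be in (0, 1]")
        if self.averaging not in ("dichotomize_first", "ordinal_first"):
            raise ValueError(f"unknown averaging rule {self.averaging!r}")


@dataclass
class Sociomatrix:
    """Binary tie structure for one relation over a roster.

    ``values`` is n×n in {0, 1}; the diagonal is structurally zero.  For
    undirected relations both ``values`` and ``missing_mask`` are
    symmetric.  ``missing_mask`` marks dyads with no usable report (both
    endpoints nonrespondents, or unconfirmable dyads in strict mode).
    """

    roster: Roster
    relation: Relation
    values: np.ndarray
    directed: bool
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    mode: Mode = "not_applicable"

    def __post_init__(self) -> None:
        n = self.roster.n
        self.values = np.asarray(self.values)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}×{n}, got {self.values.shape}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, n), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, n):
            raise ValueError("missing_mask shape mismatch")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero (no self-ties)")
        if not self.directed:
            if not np.array_equal(self.values, self.values.T):
                raise ValueError("undirected sociomatrix must be symmetric")
            if not np.array_equal(self.missing_mask, self.missing_mask.T):
                raise ValueError("undirected missing_mask must be symmetric")

    @property
    def n(self) -> int:
        return self.roster.n

    @property
    def tie_count(self) -> int:
        """Edges if undirected, arcs if directed."""
        total = int(self.values.sum())
        return total // 2 if not self.directed else total

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.roster.org_ids)
        return pd.DataFrame(self.values.astype(int), index=ids, columns=ids)


def dichotomize_contact(value: int, config: TieRuleConfig | None = None) -> int:
    """1 iff the contact frequency code is at or above the cut-off.

    With the default cut-off at monthly, organizations in contact more
    than twice per year are linked; biannual or rarer contact is not.
    """
    config = config or TieRuleConfig()
    if not 0 <= value < len(CONTACT_LEVELS):
        raise ValueError(f"contact code {value} outside ordinal domain")
    return int(value >= config.contact_cutoff)


def dichotomize_integration(value: int, config: TieRuleConfig | None = None) -> int:
    """1 iff the integration level is 'coordination' (3) or above by default."""
    config = config or TieRuleConfig()
    if not 0 <= value < len(INTEGRATION_LEVELS):
        raise ValueError(f"integration code {value} outside ordinal domain")
    return int(value >= config.integration_cutoff)


def resolve_discrepancy(report_a: float, report_b: float) -> float:
    """Mean tie value for a dyad reported by both endpoints."""
    return (float(report_a) + float(report_b)) / 2.0


def reconstruct_impute(
    single_report: int,
    *,
    missingness: float,
    config: TieRuleConfig | None = None,
) -> int:
    """Impute a dyad with exactly one responding endpoint.

    Reconstruction takes the single respondent's (dichotomized) answer as
    the dyad value — in both directions: a reported tie is imputed as
    present, a reported non-tie as absent.  Refused when organization-level
    missingness reaches the configured limit.
    """
    config = config or TieRuleConfig()
    if missingness >= config.missingness_limit:
        raise ImputationRefusedError(
            f"missingness {missingness:.3f} ≥ limit {config.missingness_limit:.2f}: "
            "reconstruction imputation is not defensible; collect more responses "
            "or analyze respondent-only subnetworks"
        )
    return int(bool(single_report))


def _dichotomize(relation: Relation, code: int, config: TieRuleConfig) -> int:
    if relation is Relation.CONTACT:
        return dichotomize_contact(code, config)
    if relation is Relation.INTEGRATION:
        return dichotomize_integration(code, config)
    return int(bool(code))


def _cutoff(relation: Relation, config: TieRuleConfig) -> int:
    return (
        config.contact_cutoff if relation is Relation.CONTACT else config.integration_cutoff
    )


def _build_undirected(
    responses: list[DyadicResponse],
    roster: Roster,
    relation: Relation,
    config: TieRuleConfig,
) -> Sociomatrix:
    n = roster.n
    ids = roster.org_ids
    values = np.zeros((n, n), dtype=float)
    missing = np.zeros((n, n), dtype=bool)

    # reporter -> dyad -> ordinal code; a respondent's unreported dyads are 0
    by_reporter: dict[str, dict[tuple[str, str], int]] = {}
    for r in responses:
        by_reporter.setdefault(r.reporter, {})[r.dyad] = r.value

    miss = respondent_missingness(roster)
    nonrespondents = [o for o in ids if not roster.responded_flag(o)]
    if nonrespondents and miss >= config.missingness_limit:
        raise ImputationRefusedError(
            f"missingness {miss:.3f} ≥ limit {config.missingness_limit:.2f}: "
            "reconstruction imputation is not defensible for "
            f"relation {relation.value!r}"
        )

    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            dyad = (a, b) if a < b else (b, a)
            resp_a, resp_b = roster.responded_flag(a), roster.responded_flag(b)
            code_a = by_reporter.get(a, {}).get(dyad, 0)
            code_b = by_reporter.get(b, {}).get(dyad, 0)
            if resp_a and resp_b:
                if config.averaging == "dichotomize_first":
                    mean = resolve_discrepancy(
                        _dichotomize(relation, code_a, config),
                        _dichotomize(relation, code_b, config),
                    )
                    tie = int(mean >= config.discrepancy_threshold)
                else:
                    mean_code = resolve_discrepancy(code_a, code_b)
                    tie = int(mean_code >= _cutoff(relation, config))
            elif resp_a or resp_b:
                code = code_a if resp_a else code_b
                tie = reconstruct_impute(
                    _dichotomize(relation, code, config), missingness=miss, config=config
                )
            else:
                logger.warning(
                    "dyad (%s, %s) has no responding endpoint for %s; left missing",
                    a, b, relation.value,
                )
                tie = 0
                missing[i, j] = missing[j, i] = True
            values[i, j] = values[j, i] = tie

    return Sociomatrix(
        roster=roster,
        relation=relation,
        values=values.astype(int),
        directed=False,
        missing_mask=missing,
        mode="not_applicable",
    )


def confirm_ties(
    responses: Iterable[DyadicResponse],
    roster: Roster,
    relation: Relation,
    mode: Literal["confirmed", "unconfirmed"] = "confirmed",
    config: TieRuleConfig | None = None,
) -> Sociomatrix:
    """Build a directed sociomatrix from sender and receiver reports.

    An arc A→B is reported twice on a fully-observed dyad: by A (reporter
    A, source A, target B: "I sent") and by B (reporter B, source A,
    target B: "I received").  Confirmed mode requires both; unconfirmed
    mode requires either.
    """
    config = config or TieRuleConfig()
    if not relation.directed:
        raise ValueError(f"relation {relation.value!r} is undirected; use build_network")
    if mode not in ("confirmed", "unconfirmed"):
        raise ValueError(f"unknown mode {mode!r}")
    n = roster.n
    ids = roster.org_ids
    values = np.zeros((n, n), dtype=int)
    missing = np.zeros((n, n), dtype=bool)

    # (source, target) -> {reporter: report}
    reports: dict[tuple[str, str], dict[str, int]] = {}
    for r in responses:
        if r.relation is not relation:
            continue
        reports.setdefault((r.source, r.target), {})[r.reporter] = int(bool(r.value))

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            src, dst = ids[i], ids[j]
            resp_src, resp_dst = roster.responded_flag(src), roster.responded_flag(dst)
            arc_reports = reports.get((src, dst), {})
            sent = arc_reports.get(src, 0)
            received = arc_reports.get(dst, 0)
            if resp_src and resp_dst:
                arc = (sent and received) if mode == "confirmed" else (sent or received)
            elif resp_src or resp_dst:
                single = sent if resp_src else received
                if config.single_report_fallback:
                    arc = single
                else:
                    arc = 0
                    missing[i, j] = True
            else:
                arc = 0
                missing[i, j] = True
            values[i, j] = int(bool(arc))

    return Sociomatrix(
        roster=roster,
        relation=relation,
        values=values,
        directed=True,
        missing_mask=missing,
        mode=mode,
    )


def build_network(
    responses: Iterable[DyadicResponse],
    roster: Roster,
    relation: Relation,
    config: TieRuleConfig | None = None,
    mode: Literal["confirmed", "unconfirmed"] = "confirmed",
) -> Sociomatrix:
    """Build the final binary sociomatrix for one relation.

    Contact and integration reports are dichotomized, dyadic discrepancies
    resolved by the mean, one-sided dyads imputed by reconstruction; the
    four directed relations go through confirmed/unconfirmed tie
    extraction.
    """
    config = config or TieRuleConfig()
    relevant = [r for r in responses if r.relation is relation]
    for r in relevant:
        if r.reporter not in roster or r.source not in roster or r.target not in roster:
            raise KeyError(f"response {r} references an org not on the roster")
        if not roster.responded_flag(r.reporter):
            raise ValueError(
                f"reporter {r.reporter!r} is flagged as a nonrespondent but has responses"
            )
    if relation.directed:
        return confirm_ties(relevant, roster, relation, mode=mode, config=config)
    return _build_undirected(relevant, roster, relation, config)


def write_adjacency(m: Sociomatrix, path: Union[str, Path]) -> None:
    """Write a square 0/1 adjacency CSV with roster-ordered headers."""
    m.to_frame().to_csv(path, index_label="org_id")


def read_adjacency(path: Union[str, Path], roster: Roster, relation: Relation,
                   mode: Mode = "not_applicable") -> Sociomatrix:
    df = pd.read_csv(path, index_col="org_id")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.loc[list(roster.org_ids), list(roster.org_ids)]
    return Sociomatrix(
        roster=roster,
        relation=relation,
        values=df.to_numpy(dtype=int),
        directed=relation.directed,
        mode=mode,
    )


def write_edgelist(m: Sociomatrix, path: Union[str, Path]) -> None:
    """Write an edge-list CSV (source,target,relation,mode), self-loops never emitted."""
    ids = m.roster.org_ids
    rows = []
    for i in range(m.n):
        js = range(m.n) if m.directed else range(i + 1, m.n)
        for j in js:
            if i != j and m.values[i, j]:
                rows.append((ids[i], ids[j], m.relation.value, m.mode))
    pd.DataFrame(rows, columns=["source", "target", "relation", "mode"]).to_csv(
        path, index=False
    )
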