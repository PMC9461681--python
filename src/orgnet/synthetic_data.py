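"""Seeded synthetic survey cases with known ground truth.

The study's raw sociomatrices were never published, so every pipeline
stage is exercised against generated cases instead: a roster with one
lead agency, six-relation dyadic survey responses with controllable true
density, hub structure, reporting noise and organizational nonresponse,
CPAT item responses realizing a target team score, and perception
endorsements.

The generative model, per relation:

1. **Ground truth.**  Each dyad (unordered for contact/integration,
   ordered for the four directed relations) is an independent Bernoulli
   draw.  The tie probability interpolates between a uniform random graph
   at rate ``true_density`` and a star through the lead agency:
   ``p_tie = (1 − α)·p + α·[lead ∈ dyad]`` with ``α = hub_weight``.  At
   α = 0 expected density is exactly ``p``; at α = 1 the network is a pure
   star (maximal degree centralization).
2. **Observation.**  Every respondent reports its own row of the truth,
   with each dichotomous view flipped independently at the
   false-negative/false-positive rates.  A surviving tie is voiced as an
   ordinal level drawn uniformly from the levels at or above the
   relation's cut-off (contact: monthly/weekly/daily; integration:
   coordination…fully_linked); a non-tie as a level below the cut-off,
   with the zero level (frequency ``none`` / ``not_linked``) emitting no
   row at all.  Directed relations are reported twice per arc — the
   sender's "I sent" and the receiver's "I received" — each with its own
   independent noise, which is what makes confirmed ties informative.
3. **Nonresponse.**  ``floor(nonresponse_fraction · n)`` organizations,
   drawn uniformly among the non-lead organizations, contribute no rows
   (the lead agency, which runs the survey, always responds).

A single integer seed fully determines every output; per-stage substreams
are spawned deterministically from it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .cpat_scoring import N_DOMAINS, N_ITEMS
from .survey_io import (
    CONTACT_LEVELS,
    INTEGRATION_LEVELS,
    DyadicResponse,
    Organization,
    OrgType,
    Relation,
    Roster,
    write_responses,
    write_roster,
)
from .tie_construction import Sociomatrix, TieRuleConfig, write_adjacency

__all__ = [
    "RelationSimConfig",
    "SimulationConfig",
    "SyntheticCase",
    "generate_case",
    "generate_cpat",
    "generate_perceptions",
    "generate_responses",
    "generate_roster",
    "generate_true_network",
    "high_cpat_case_config",
    "low_cpat_case_config",
]


@dataclass(frozen=True)
class RelationSimConfig:
    """Ground-truth parameters for one relation network."""

    true_density: float
    hub_weight: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_density <= 1.0:
            raise ValueError(f"true_density {self.true_density} outside [0, 1]")
        if not 0.0 <= self.hub_weight <= 1.0:
            raise ValueError(f"hub_weight {self.hub_weight} outside [0, 1]")


def _default_relations() -> dict[Relation, RelationSimConfig]:
    # Default true densities echo the printed per-relation densities of the
    # low-CPAT-led case (the larger of the two study networks).
    return {
        Relation.CONTACT: RelationSimConfig(0.648),
        Relation.INTEGRATION: RelationSimConfig(0.400),
        Relation.REFERRAL: RelationSimConfig(0.119),
        Relation.INFORMATION_SHARING: RelationSimConfig(0.229),
        Relation.JOINT_CARE_PLANNING: RelationSimConfig(0.110),
        Relation.SHARED_RESOURCES: RelationSimConfig(0.100),
    }


def _default_org_type_probs() -> dict[OrgType, float]:
    return {
        OrgType.PRIMARY_CARE: 0.15,
        OrgType.HOSPITAL: 0.15,
        OrgType.HOME_COMMUNITY_CARE: 0.10,
        OrgType.LONG_TERM_CARE: 0.10,
        OrgType.COMMUNITY_AGENCY: 0.35,
        OrgType.GOVERNMENT_AGENCY: 0.10,
        OrgType.OTHER: 0.05,
    }


def _default_perception_probs() -> dict[str, float]:
    return {
        "improved_capacity_to_serve_patients": 0.80,
        "better_use_of_organization_services": 0.70,
        "loss_of_control_autonomy": 0.18,
        "strained_relations_within_organization": 0.36,
        "too_much_time_and_resources": 0.45,
        "difficulty_dealing_with_members": 0.27,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of one synthetic case.

    The defaults mirror the low-CPAT-led study case: 15 organizations led
    by a primary care team, one nonrespondent, per-relation true densities
    at the printed values, and a CPAT target of 43.74.
    """

    seed: int = 0
    case_label: str = "synthetic_case"
    n_orgs: int = 15
    org_type_probs: dict[OrgType, float] = field(default_factory=_default_org_type_probs)
    relations: dict[Relation, RelationSimConfig] = field(default_factory=_default_relations)
    false_negative_rate: float = 0.10
    false_positive_rate: float = 0.02
    nonresponse_fraction: float = 1.0 / 15.0
    n_providers: int = 8
    target_team_mean: float = 43.74
    provider_sd: float = 2.47
    item_dispersion: float = 0.3
    perception_probs: dict[str, float] = field(default_factory=_default_perception_probs)

    def __post_init__(self) -> None:
        if self.n_orgs < 3:
            raise ValueError("n_orgs must be ≥ 3")
        for name in ("false_negative_rate", "false_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")
        if not 0.0 <= self.nonresponse_fraction < 1.0:
            raise ValueError("nonresponse_fraction must be in [0, 1)")
        if not 8.0 <= self.target_team_mean <= 56.0:
            raise ValueError(
                f"target_team_mean {self.target_team_mean} outside the CPAT range [8, 56]"
            )
        if self.provider_sd < 0:
            raise ValueError("provider_sd must be ≥ 0")
        if self.n_providers < 1:
            raise ValueError("n_providers must be ≥ 1")


def low_cpat_case_config(seed: int = 0) -> SimulationConfig:
    """Study conditions of the low-CPAT-led case (n = 15, CPAT 43.74)."""
    return SimulationConfig(seed=seed, case_label="low_cpat_case")


def high_cpat_case_config(seed: int = 0) -> SimulationConfig:
    """Study conditions of the high-CPAT-led case (n = 12, CPAT 50.01)."""
    return SimulationConfig(
        seed=seed,
        case_label="high_cpat_case",
        n_orgs=12,
        nonresponse_fraction=1.0 / 12.0,
        relations={
            Relation.CONTACT: RelationSimConfig(0.485),
            Relation.INTEGRATION: RelationSimConfig(0.242),
            Relation.REFERRAL: RelationSimConfig(0.379),
            Relation.INFORMATION_SHARING: RelationSimConfig(0.500),
            Relation.JOINT_CARE_PLANNING: RelationSimConfig(0.150),
            Relation.SHARED_RESOURCES: RelationSimConfig(0.023),
        },
        target_team_mean=50.01,
        perception_probs={
            "improved_capacity_to_serve_patients": 0.80,
            "better_use_of_organization_services": 0.70,
            "loss_of_control_autonomy": 0.18,
            "strained_relations_within_organization": 0.36,
            "too_much_time_and_resources": 0.45,
            "difficulty_dealing_with_members": 0.27,
        },
    )


def _rng(seed_or_rng: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_roster(
    config: SimulationConfig, rng: Union[int, np.random.Generator, None] = None
) -> Roster:
    """Draw a roster: one lead agency (always a respondent) plus typed partners.

    ``floor(nonresponse_fraction · n)`` non-lead organizations are flagged
    as nonrespondents.
    """
    rng = _rng(config.seed if rng is None else rng)
    types = list(config.org_type_probs)
    probs = np.array([config.org_type_probs[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    n = config.n_orgs
    drawn = rng.choice(len(types), size=n - 1, p=probs)
    n_nonresp = int(np.floor(config.nonresponse_fraction * n))
    nonresp_idx = set(rng.choice(np.arange(1, n), size=n_nonresp, replace=False).tolist())
    orgs = [
        Organization(
            org_id="org_01",
            name=f"{config.case_label} lead agency",
            org_type=OrgType.PRIMARY_CARE_LEAD,
            is_lead=True,
            responded=True,
        )
    ]
    for k in range(1, n):
        orgs.append(
            Organization(
                org_id=f"org_{k + 1:02d}",
                name=f"{config.case_label} partner {k + 1}",
                org_type=types[drawn[k - 1]],
                is_lead=False,
                responded=k not in nonresp_idx,
            )
        )
    return Roster(case_label=config.case_label, organizations=tuple(orgs))


def generate_true_network(
    config: SimulationConfig,
    relation: Relation,
    roster: Roster | None = None,
    rng: Union[int, np.random.Generator, None] = None,
) -> Sociomatrix:
    """Draw the ground-truth binary sociomatrix for one relation.

    Tie probability per dyad: ``(1 − α)·p + α·[lead agency ∈ dyad]``, so
    expected density is ``p`` at α = 0 and the α = 1 network is a star
    through the lead agency.
    """
    rng = _rng(config.seed if rng is None else rng)
    roster = roster if roster is not None else generate_roster(config, rng)
    rel_cfg = config.relations[relation]
    p, alpha = rel_cfg.true_density, rel_cfg.hub_weight
    n = roster.n
    lead = roster.index(roster.lead.org_id)
    values = np.zeros((n, n), dtype=int)
    if relation.directed:
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                p_tie = (1 - alpha) * p + alpha * (1.0 if lead in (i, j) else 0.0)
                values[i, j] = int(rng.random() < p_tie)
    else:
        for i in range(n):
            for j in range(i + 1, n):
                p_tie = (1 - alpha) * p + alpha * (1.0 if lead in (i, j) else 0.0)
                tie = int(rng.random() < p_tie)
                values[i, j] = values[j, i] = tie
    return Sociomatrix(
        roster=roster,
        relation=relation,
        values=values,
        directed=relation.directed,
        mode="not_applicable",
    )


_LINKED_CODES = {
    Relation.CONTACT: tuple(
        range(TieRuleConfig().contact_cutoff, len(CONTACT_LEVELS))
    ),
    Relation.INTEGRATION: tuple(
        range(TieRuleConfig().integration_cutoff, len(INTEGRATION_LEVELS))
    ),
}
_UNLINKED_CODES = {
    Relation.CONTACT: tuple(range(TieRuleConfig().contact_cutoff)),
    Relation.INTEGRATION: tuple(range(TieRuleConfig().integration_cutoff)),
}


def generate_responses(
    truth: Sociomatrix,
    config: SimulationConfig,
    rng: Union[int, np.random.Generator, None] = None,
) -> list[DyadicResponse]:
    """Survey the ground truth: each respondent reports its noisy view.

    Respondent status is read off ``truth.roster``.  Zero-valued reports
    (frequency ``none``, level ``not_linked``, no arc) emit no row, which
    is exactly the roster-questionnaire semantics the reader assumes.
    """
    rng = _rng(config.seed if rng is None else rng)
    roster = truth.roster
    relation = truth.relation
    fn, fp = config.false_negative_rate, config.false_positive_rate
    ids = roster.org_ids
    responses: list[DyadicResponse] = []

    def observe(true_tie: int) -> int:
        if true_tie:
            return int(rng.random() >= fn)
        return int(rng.random() < fp)

    for r_id in ids:
        if not roster.responded_flag(r_id):
            continue
        i = roster.index(r_id)
        for j, partner in enumerate(ids):
            if partner == r_id:
                continue
            if relation.directed:
                if observe(int(truth.values[i, j])):  # "I sent to partner"
                    responses.append(
                        DyadicResponse(r_id, r_id, partner, relation, 1)
                    )
                if observe(int(truth.values[j, i])):  # "I received from partner"
                    responses.append(
                        DyadicResponse(r_id, partner, r_id, relation, 1)
                    )
            else:
                observed = observe(int(truth.values[i, j]))
                pool = _LINKED_CODES[relation] if observed else _UNLINKED_CODES[relation]
                code = int(pool[rng.integers(len(pool))])
                if code > 0:
                    responses.append(
                        DyadicResponse(r_id, r_id, partner, relation, code)
                    )
    return responses


def generate_cpat(
    config: SimulationConfig, rng: Union[int, np.random.Generator, None] = None
) -> pd.DataFrame:
    """Draw CPAT item responses whose rescored team mean tracks the target.

    Provider totals are drawn Normal(target_team_mean, provider_sd) and
    clipped to [8, 56]; each total is realized as integer item values by
    splitting the implied item-point sum as evenly as possible over the 8
    uniform domains and 7 items per domain (largest-remainder rounding),
    so the rescored total differs from the drawn one by at most 1/14 per
    domain mean.  ``item_dispersion`` then applies sum-preserving ±1 swaps
    between items within each domain to roughen the profile.
    """
    rng = _rng(config.seed if rng is None else rng)
    rows: list[tuple[str, int, int]] = []
    items_per_domain = N_ITEMS // N_DOMAINS
    for p in range(config.n_providers):
        provider = f"provider_{p + 1:02d}"
        total = float(
            np.clip(rng.normal(config.target_team_mean, config.provider_sd), 8.0, 56.0)
        )
        point_sum = int(round(total * items_per_domain))  # total item points, 56..392
        base, rem = divmod(point_sum, N_DOMAINS)
        domain_sums = [base + (1 if d < rem else 0) for d in range(N_DOMAINS)]
        for d, s in enumerate(domain_sums):
            item_base, item_rem = divmod(s, items_per_domain)
            values = np.full(items_per_domain, item_base, dtype=int)
            bump = rng.choice(items_per_domain, size=item_rem, replace=False)
            values[bump] += 1
            n_swaps = int(round(config.item_dispersion * items_per_domain))
            for _ in range(n_swaps):
                a, b = rng.choice(items_per_domain, size=2, replace=False)
                if values[a] < 7 and values[b] > 1:
                    values[a] += 1
                    values[b] -= 1
            for k in range(items_per_domain):
                item_id = d * items_per_domain + k + 1
                rows.append((provider, item_id, int(values[k])))
    return pd.DataFrame(rows, columns=["provider_id", "item_id", "value"])


def generate_perceptions(
    config: SimulationConfig,
    roster: Roster,
    rng: Union[int, np.random.Generator, None] = None,
) -> pd.DataFrame:
    """Draw benefit/drawback endorsements from responding organizations."""
    rng = _rng(config.seed if rng is None else rng)
    rows = []
    for org_id in roster.respondents:
        for item, prob in config.perception_probs.items():
            rows.append((org_id, item, bool(rng.random() < prob)))
    return pd.DataFrame(rows, columns=["org_id", "item", "endorsed"])


@dataclass
class SyntheticCase:
    """One complete generated case: inputs for every pipeline stage."""

    config: SimulationConfig
    roster: Roster
    truths: dict[Relation, Sociomatrix]
    responses: list[DyadicResponse]
    cpat: pd.DataFrame
    perceptions: pd.DataFrame

    def write(self, outdir: Union[str, Path]) -> None:
        """Write roster/responses/cpat/perceptions CSVs, truth matrices and a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_roster(self.roster, outdir / "roster.csv")
        write_responses(self.responses, outdir / "responses.csv")
        self.cpat.to_csv(outdir / "cpat.csv", index=False)
        self.perceptions.to_csv(outdir / "perceptions.csv", index=False)
        for relation, truth in self.truths.items():
            write_adjacency(truth, outdir / f"truth_{relation.value}.csv")
        manifest = dataclasses.asdict(self.config)
        manifest["org_type_probs"] = {k.value: v for k, v in manifest["org_type_probs"].items()}
        manifest["relations"] = {
            k.value: dataclasses.asdict(v) for k, v in self.config.relations.items()
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def generate_case(config: SimulationConfig) -> SyntheticCase:
    """Generate a full case deterministically from ``config.seed``.

    Per-stage random substreams are spawned from a single seed sequence,
    so adding relations or providers never perturbs the other stages.
    """
    ss = np.random.SeedSequence(config.seed)
    n_streams = 2 + 2 * len(config.relations)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_streams + 1)]
    roster = generate_roster(config, streams[0])
    truths: dict[Relation, Sociomatrix] = {}
    responses: list[DyadicResponse] = []
    for k, relation in enumerate(config.relations):
        truth = generate_true_network(config, relation, roster, streams[1 + 2 * k])
        truths[relation] = truth
        responses.extend(generate_responses(truth, config, streams[2 + 2 * k]))
    cpat = generate_cpat(config, streams[n_streams - 1])
    perceptions = generate_perceptions(config, roster, streams[n_streams])
    return SyntheticCase(
        config=config,
        roster=roster,
        truths=truths,
        responses=responses,
        cpat=cpat,
        perceptions=perceptions,
    )
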