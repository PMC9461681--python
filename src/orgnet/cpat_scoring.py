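"""Scoring the Collaborative Practice Assessment Tool (CPAT).

The CPAT measures interprofessional collaboration within a team through 56
Likert items (7-point scale, 1–7) grouped into 8 domains.  Scoring is
hierarchical: each domain is the arithmetic mean of its items (range 1–7),
a provider's total is the sum of the 8 domain means (range 8–56), and the
team score is the unweighted mean of provider totals, with the standard
deviation reported as a dispersion measure when at least two providers
responded.

The true instrument has uneven domain sizes, so the domain map is a
required input; :func:`uniform_domain_map` (8 domains × 7 items) is
provided as a documented fallback for synthetic work.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "CPATDomainMap",
    "CPATResponseSet",
    "read_domain_map",
    "score_domains",
    "score_provider",
    "score_team",
    "uniform_domain_map",
]

N_ITEMS = 56
N_DOMAINS = 8
SCALE_MIN, SCALE_MAX = 1, 7


class CPATDomainMap:
    """Mapping of 8 domain labels to disjoint item-id sets covering 1–56."""

    def __init__(self, domains: Mapping[str, Iterable[int]]):
        self.domains: dict[str, frozenset[int]] = {
            str(k): frozenset(int(i) for i in v) for k, v in domains.items()
        }
        if len(self.domains) != N_DOMAINS:
            raise ValueError(f"expected {N_DOMAINS} domains, got {len(self.domains)}")
        all_items = [i for items in self.domains.values() for i in items]
        if len(all_items) != len(set(all_items)):
            raise ValueError("domains overlap: an item appears in more than one domain")
        if set(all_items) != set(range(1, N_ITEMS + 1)):
            missing = set(range(1, N_ITEMS + 1)) - set(all_items)
            extra = set(all_items) - set(range(1, N_ITEMS + 1))
            raise ValueError(
                f"domain map must cover items 1–{N_ITEMS} exactly "
                f"(missing {sorted(missing)}, extraneous {sorted(extra)})"
            )

    def __iter__(self):
        return iter(self.domains.items())

    def __len__(self) -> int:
        return len(self.domains)


def uniform_domain_map() -> CPATDomainMap:
    """Fallback map: 8 consecutive blocks of 7 items each."""
    return CPATDomainMap(
        {f"domain_{d + 1}": range(7 * d + 1, 7 * d + 8) for d in range(N_DOMAINS)}
    )


def read_domain_map(path: Union[str, Path]) -> CPATDomainMap:
    """Read a domain map from a two-column CSV (domain,item_id)."""
    df = pd.read_csv(path)
    if not {"domain", "item_id"}.issubset(df.columns):
        raise ValueError("domain map CSV needs columns 'domain' and 'item_id'")
    groups = df.groupby("domain")["item_id"].apply(list).to_dict()
    return CPATDomainMap(groups)


class CPATResponseSet:
    """One provider's item responses: item_id → Likert value in [1, 7]."""

    def __init__(self, provider_id: str, items: Mapping[int, int]):
        self.provider_id = str(provider_id)
        self.items: dict[int, int] = {}
        for item_id, value in items.items():
            item_id, value = int(item_id), int(value)
            if not 1 <= item_id <= N_ITEMS:
                raise ValueError(f"item_id {item_id} outside 1–{N_ITEMS}")
            if not SCALE_MIN <= value <= SCALE_MAX:
                raise ValueError(
                    f"item {item_id}: value {value} outside [{SCALE_MIN}, {SCALE_MAX}]"
                )
            self.items[item_id] = value

    @property
    def complete(self) -> bool:
        return len(self.items) == N_ITEMS

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["CPATResponseSet"]:
        """Split a validated long table (provider_id,item_id,value) by provider."""
        return [
            cls(pid, dict(zip(grp["item_id"], grp["value"])))
            for pid, grp in df.groupby("provider_id", sort=True)
        ]


def score_domains(
    r: CPATResponseSet,
    domain_map: CPATDomainMap | None = None,
    *,
    partial: bool = False,
) -> dict[str, float]:
    """Average the items within each domain.

    Each domain score is the arithmetic mean of its item values, in
    [1, 7].  A missing item raises by default; with ``partial=True`` the
    domain mean is taken over the answered items instead.
    """
    domain_map = domain_map or uniform_domain_map()
    scores: dict[str, float] = {}
    for domain, item_ids in domain_map:
        answered = [r.items[i] for i in item_ids if i in r.items]
        if len(answered) < len(item_ids) and not partial:
            missing = sorted(i for i in item_ids if i not in r.items)
            raise ValueError(
                f"provider {r.provider_id}: domain {domain!r} missing items {missing}"
            )
        if not answered:
            raise ValueError(
                f"provider {r.provider_id}: domain {domain!r} has no answered items"
            )
        scores[domain] = float(np.mean(answered))
    return scores


def score_provider(
    r: CPATResponseSet,
    domain_map: CPATDomainMap | None = None,
    *,
    partial: bool = False,
) -> float:
    """Provider total: the sum of the 8 domain means, in [8, 56]."""
    return float(sum(score_domains(r, domain_map, partial=partial).values()))


def score_team(provider_totals: Iterable[float]) -> tuple[float, float | None]:
    """Aggregate provider totals to a team score.

    Returns ``(mean, sd)`` where the sd (ddof=1) is ``None`` with a single
    provider.  Raises on an empty collection.
    """
    totals = np.asarray(list(provider_totals), dtype=float)
    if totals.size == 0:
        raise ValueError("cannot score a team with no provider totals")
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1)) if totals.size >= 2 else None
    return mean, sd
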