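"""Reading, validating and writing the survey tables.

Four CSV tables feed the pipeline, all UTF-8 with a header row:

* ``roster.csv`` — ``org_id,name,org_type,is_lead,responded``: the bounded
  set of organizations in one case.  Row order is meaningful; it fixes the
  sociomatrix row/column indexing.
* ``responses.csv`` — ``reporter,source,target,relation,value``: one
  reporter's claim about one dyad under one relation kind.
* ``cpat.csv`` — ``provider_id,item_id,value``: Likert item responses
  (items 1–56, values 1–7) from providers in the lead agency.
* ``perceptions.csv`` — ``org_id,item,endorsed``: benefit/drawback
  endorsements.

Everything is validated against the roster before any computation:
unknown organizations, out-of-domain values, reporters that are not an
endpoint of the dyad they report on, and duplicate rows are all rejected
with the offending row numbers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "CONTACT_LEVELS",
    "INTEGRATION_LEVELS",
    "DyadicResponse",
    "Organization",
    "OrgType",
    "Relation",
    "Roster",
    "ValidationError",
    "read_cpat",
    "read_perceptions",
    "read_responses",
    "read_roster",
    "respondent_missingness",
    "write_responses",
    "write_roster",
]


class ValidationError(ValueError):
    """An input table violates the schema or referential integrity."""


class OrgType(str, enum.Enum):
    PRIMARY_CARE_LEAD = "primary_care_lead"
    PRIMARY_CARE = "primary_care"
    HOSPITAL = "hospital"
    HOME_COMMUNITY_CARE = "home_community_care"
    LONG_TERM_CARE = "long_term_care"
    COMMUNITY_AGENCY = "community_agency"
    GOVERNMENT_AGENCY = "government_agency"
    OTHER = "other"


class Relation(str, enum.Enum):
    """The six relation kinds collected by the network questionnaire.

    Contact frequency and perceived integration are undirected; referrals,
    information sharing, joint care planning and shared resources are
    directed (a tie has a sender and a receiver).
    """

    CONTACT = "contact"
    INTEGRATION = "integration"
    REFERRAL = "referral"
    INFORMATION_SHARING = "information_sharing"
    JOINT_CARE_PLANNING = "joint_care_planning"
    SHARED_RESOURCES = "shared_resources"

    @property
    def directed(self) -> bool:
        return self not in (Relation.CONTACT, Relation.INTEGRATION)

    @property
    def value_domain(self) -> str:
        if self is Relation.CONTACT:
            return "contact_frequency"
        if self is Relation.INTEGRATION:
            return "integration_level"
        return "binary_report"


#: Ordinal contact-frequency scale, lowest to highest.  The code of a level
#: is its index.  Absence of a report for a pair maps to ``none``.
CONTACT_LEVELS: tuple[str, ...] = (
    "none",
    "annually",
    "biannually",
    "monthly",
    "weekly",
    "daily",
)

#: Ordinal perceived-integration scale, coded 0–6.
INTEGRATION_LEVELS: tuple[str, ...] = (
    "not_linked",
    "communication",
    "cooperation",
    "coordination",
    "collaboration",
    "partnership",
    "fully_linked",
)

_CONTACT_CODE = {name: i for i, name in enumerate(CONTACT_LEVELS)}
_INTEGRATION_CODE = {name: i for i, name in enumerate(INTEGRATION_LEVELS)}

_BOOL_STRINGS = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "yes": True,
    "no": False,
}


@dataclass(frozen=True)
class Organization:
    org_id: str
    name: str
    org_type: OrgType
    is_lead: bool
    responded: bool


@dataclass(frozen=True)
class Roster:
    """The organizations of one case, in fixed (matrix) order.

    Exactly one organization carries the lead-agency flag; org_ids are
    unique.  The roster order defines sociomatrix row/column indexing.
    """

    case_label: str
    organizations: tuple[Organization, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.organizations) < 2:
            raise ValidationError(
                f"roster {self.case_label!r} needs at least 2 organizations, "
                f"got {len(self.organizations)}"
            )
        ids = [o.org_id for o in self.organizations]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate org_id(s) in roster: {sorted(dupes)}")
        leads = [o.org_id for o in self.organizations if o.is_lead]
        if len(leads) != 1:
            raise ValidationError(
                f"roster must have exactly one lead agency, found {len(leads)}: {leads}"
            )
        object.__setattr__(self, "_index", {i: k for k, i in enumerate(ids)})

    @property
    def n(self) -> int:
        return len(self.organizations)

    @property
    def org_ids(self) -> tuple[str, ...]:
        return tuple(o.org_id for o in self.organizations)

    @property
    def lead(self) -> Organization:
        return next(o for o in self.organizations if o.is_lead)

    @property
    def respondents(self) -> tuple[str, ...]:
        return tuple(o.org_id for o in self.organizations if o.responded)

    def index(self, org_id: str) -> int:
        try:
            return self._index[org_id]
        except KeyError:
            raise KeyError(f"org_id {org_id!r} not in roster {self.case_label!r}") from None

    def __contains__(self, org_id: object) -> bool:
        return org_id in self._index

    def responded_flag(self, org_id: str) -> bool:
        return self.organizations[self.index(org_id)].responded


@dataclass(frozen=True)
class DyadicResponse:
    """One reporter's claim about one dyad under one relation.

    ``value`` is the ordinal code (contact: 0–5, integration: 0–6) or a
    0/1 binary report for directed relations.  The reporter must be one of
    the two endpoints; for undirected relations the (source, target) pair
    is stored in canonical (lexicographic) order.
    """

    reporter: str
    source: str
    target: str
    relation: Relation
    value: int

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValidationError(
                f"self-dyad ({self.source!r}, {self.target!r}) is not allowed"
            )
        if self.reporter not in (self.source, self.target):
            raise ValidationError(
                f"reporter {self.reporter!r} is not an endpoint of "
                f"({self.source!r}, {self.target!r})"
            )
        if not self.relation.directed and self.source > self.target:
            # canonicalize unordered pairs lexicographically
            s, t = self.source, self.target
            object.__setattr__(self, "source", t)
            object.__setattr__(self, "target", s)
        _check_value(self.relation, self.value)

    @property
    def dyad(self) -> tuple[str, str]:
        return (self.source, self.target)


def _check_value(relation: Relation, value: int) -> None:
    dom = relation.value_domain
    if dom == "contact_frequency":
        hi = len(CONTACT_LEVELS) - 1
    elif dom == "integration_level":
        hi = len(INTEGRATION_LEVELS) - 1
    else:
        hi = 1
    if not isinstance(value, (int,)) or isinstance(value, bool) or not 0 <= value <= hi:
        raise ValidationError(
            f"value {value!r} outside the {dom} domain [0, {hi}] for {relation.value}"
        )


def parse_value(relation: Relation, raw: object) -> int:
    """Parse a raw CSV cell into the ordinal/binary code for ``relation``.

    Contact accepts level names (``monthly``) or codes 0–5; integration
    accepts level names (``coordination``) or codes 0–6; binary relations
    accept 0/1/true/false.
    """
    s = str(raw).strip().lower()
    dom = relation.value_domain
    if dom == "contact_frequency" and s in _CONTACT_CODE:
        return _CONTACT_CODE[s]
    if dom == "integration_level" and s in _INTEGRATION_CODE:
        return _INTEGRATION_CODE[s]
    if dom == "binary_report" and s in _BOOL_STRINGS:
        return int(_BOOL_STRINGS[s])
    try:
        code = int(s)
    except ValueError:
        raise ValidationError(
            f"cannot parse value {raw!r} for relation {relation.value}"
        ) from None
    _check_value(relation, code)
    return code


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing required column(s) {missing}")


def _parse_bool(raw: object, row: int, col: str) -> bool:
    s = str(raw).strip().lower()
    if s not in _BOOL_STRINGS:
        raise ValidationError(f"row {row}: {col}={raw!r} is not a boolean")
    return _BOOL_STRINGS[s]


def read_roster(path: Union[str, Path], case_label: str | None = None) -> Roster:
    """Read and validate a roster CSV.

    Row order is preserved and becomes the sociomatrix index order.
    Raises :class:`ValidationError` on a missing column, duplicate org_id,
    or zero/multiple lead agencies.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["org_id", "name", "org_type", "is_lead", "responded"], str(path))
    orgs = []
    for row, rec in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            org_type = OrgType(str(rec.org_type).strip())
        except ValueError:
            raise ValidationError(
                f"row {row}: unknown org_type {rec.org_type!r}"
            ) from None
        orgs.append(
            Organization(
                org_id=str(rec.org_id).strip(),
                name=str(rec.name),
                org_type=org_type,
                is_lead=_parse_bool(rec.is_lead, row, "is_lead"),
                responded=_parse_bool(rec.responded, row, "responded"),
            )
        )
    label = case_label if case_label is not None else path.stem
    return Roster(case_label=label, organizations=tuple(orgs))


def write_roster(roster: Roster, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "org_id": [o.org_id for o in roster.organizations],
            "name": [o.name for o in roster.organizations],
            "org_type": [o.org_type.value for o in roster.organizations],
            "is_lead": [o.is_lead for o in roster.organizations],
            "responded": [o.responded for o in roster.organizations],
        }
    ).to_csv(path, index=False)


def read_responses(path: Union[str, Path], roster: Roster) -> list[DyadicResponse]:
    """Read and validate a dyadic response CSV against ``roster``.

    Every reporter/source/target must resolve to a roster org_id, values
    must parse into the relation's domain, the reporter must be an endpoint,
    and duplicate (reporter, dyad, relation) rows are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["reporter", "source", "target", "relation", "value"], str(path))
    out: list[DyadicResponse] = []
    seen: set[tuple[str, str, str, Relation]] = set()
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            relation = Relation(str(rec.relation).strip())
        except ValueError:
            raise ValidationError(f"row {row}: unknown relation {rec.relation!r}") from None
        reporter = str(rec.reporter).strip()
        source = str(rec.source).strip()
        target = str(rec.target).strip()
        for org in (reporter, source, target):
            if org not in roster:
                raise ValidationError(f"row {row}: unknown org_id {org!r}")
        try:
            resp = DyadicResponse(
                reporter=reporter,
                source=source,
                target=target,
                relation=relation,
                value=parse_value(relation, rec.value),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {row}: {exc}") from None
        key = (resp.reporter, resp.source, resp.target, resp.relation)
        if key in seen:
            raise ValidationError(f"row {row}: duplicate response {key}")
        seen.add(key)
        out.append(resp)
    return out


def write_responses(responses: Iterable[DyadicResponse], path: Union[str, Path]) -> None:
    rows = list(responses)
    pd.DataFrame(
        {
            "reporter": [r.reporter for r in rows],
            "source": [r.source for r in rows],
            "target": [r.target for r in rows],
            "relation": [r.relation.value for r in rows],
            "value": [r.value for r in rows],
        }
    ).to_csv(path, index=False)


def read_cpat(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CPAT item-response table.

    Returns a validated DataFrame with columns ``provider_id`` (str),
    ``item_id`` (int, 1–56) and ``value`` (int, 1–7); duplicate
    (provider, item) rows are rejected.
    """
    df = pd.read_csv(path, dtype={"provider_id": str})
    _require_columns(df, ["provider_id", "item_id", "value"], str(path))
    df = df.copy()
    df["item_id"] = pd.to_numeric(df["item_id"], errors="raise").astype(int)
    df["value"] = pd.to_numeric(df["value"], errors="raise").astype(int)
    bad_items = df.loc[~df["item_id"].between(1, 56)]
    if not bad_items.empty:
        raise ValidationError(f"item_id outside 1–56 at rows {list(bad_items.index + 2)}")
    bad_vals = df.loc[~df["value"].between(1, 7)]
    if not bad_vals.empty:
        raise ValidationError(f"Likert value outside 1–7 at rows {list(bad_vals.index + 2)}")
    if df.duplicated(["provider_id", "item_id"]).any():
        dup = df[df.duplicated(["provider_id", "item_id"], keep=False)]
        raise ValidationError(
            f"duplicate (provider_id, item_id) rows at {list(dup.index + 2)}"
        )
    return df


def read_perceptions(path: Union[str, Path], roster: Roster) -> pd.DataFrame:
    """Read a benefit/drawback endorsement table validated against ``roster``."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["org_id", "item", "endorsed"], str(path))
    df = df.copy()
    unknown = df.loc[~df["org_id"].isin(roster.org_ids)]
    if not unknown.empty:
        raise ValidationError(
            f"unknown org_id(s) {sorted(unknown['org_id'].unique())} in perceptions"
        )
    if df.duplicated(["org_id", "item"]).any():
        dup = df[df.duplicated(["org_id", "item"], keep=False)]
        raise ValidationError(f"duplicate (org_id, item) rows at {list(dup.index + 2)}")
    df["endorsed"] = [
        _parse_bool(v, i + 2, "endorsed") for i, v in enumerate(df["endorsed"])
    ]
    return df


def respondent_missingness(roster: Roster) -> float:
    """Fraction of roster organizations that did not respond at all.

    This organization-level definition (rather than a fraction of
    unobserved dyads) is what the 30 % imputation-defensibility limit is
    compared against.
    """
    return 1.0 - len(roster.respondents) / roster.n
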