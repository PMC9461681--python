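import numpy as np
import pytest
from hypothesis import settings

from orgnet import Organization, OrgType, Relation, Roster, Sociomatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_roster(n, case_label="case", nonrespondents=(), lead_idx=0):
    """Roster of n orgs org_01..org_n; nonrespondents given by 0-based index."""
    orgs = []
    for k in range(n):
        orgs.append(
            Organization(
                org_id=f"org_{k + 1:02d}",
                name=f"Org {k + 1}",
                org_type=OrgType.PRIMARY_CARE_LEAD if k == lead_idx else OrgType.HOSPITAL,
                is_lead=k == lead_idx,
                responded=k not in nonrespondents,
            )
        )
    return Roster(case_label=case_label, organizations=tuple(orgs))


def make_matrix(values, relation=Relation.CONTACT, roster=None, mode="not_applicable"):
    values = np.asarray(values, dtype=int)
    roster = roster or make_roster(values.shape[0])
    return Sociomatrix(
        roster=roster,
        relation=relation,
        values=values,
        directed=relation.directed,
        mode=mode,
    )


@pytest.fixture
def roster5():
    return make_roster(5)


@pytest.fixture
def star5(roster5):
    """Undirected star on 5 nodes, hub org_01."""
    a = np.zeros((5, 5), dtype=int)
    a[0, 1:] = a[1:, 0] = 1
    return make_matrix(a, Relation.CONTACT, roster5)
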