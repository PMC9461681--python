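"""Preprocessing rules: dichotomization, mean-tie resolution, imputation, confirmation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgnet import (
    DyadicResponse,
    ImputationRefusedError,
    Relation,
    TieRuleConfig,
    build_network,
    confirm_ties,
    dichotomize_contact,
    dichotomize_integration,
    reconstruct_impute,
    resolve_discrepancy,
)
from orgnet.survey_io import CONTACT_LEVELS
from orgnet.tie_construction import read_adjacency, write_adjacency, write_edgelist

from conftest import make_roster


def contact_response(reporter, other, level_name):
    return DyadicResponse(
        reporter, reporter, other, Relation.CONTACT, CONTACT_LEVELS.index(level_name)
    )


class TestDichotomization:
    @pytest.mark.parametrize(
        "level, linked",
        [("none", 0), ("annually", 0), ("biannually", 0),
         ("monthly", 1), ("weekly", 1), ("daily", 1)],
    )
    def test_contact_cutoff_at_more_than_twice_a_year(self, level, linked):
        assert dichotomize_contact(CONTACT_LEVELS.index(level)) == linked

    @pytest.mark.parametrize(
        "code, linked", [(0, 0), (1, 0), (2, 0), (3, 1), (4, 1), (5, 1), (6, 1)]
    )
    def test_integration_cutoff_coordination_or_above(self, code, linked):
        assert dichotomize_integration(code) == linked

    def test_cutoffs_configurable(self):
        config = TieRuleConfig(contact_cutoff=2, integration_cutoff=5)
        assert dichotomize_contact(2, config) == 1
        assert dichotomize_integration(4, config) == 0


class TestDiscrepancyAndImputation:
    @pytest.mark.parametrize("pair, mean", [((1, 0), 0.5), ((1, 1), 1.0), ((0, 0), 0.0)])
    def test_mean_tie_value(self, pair, mean):
        assert resolve_discrepancy(*pair) == mean

    @pytest.mark.parametrize("report, imputed", [(1, 1), (0, 0)])
    def test_reconstruction_uses_single_report(self, report, imputed):
        assert reconstruct_impute(report, missingness=0.07) == imputed

    def test_refused_when_missingness_at_limit(self):
        with pytest.raises(ImputationRefusedError, match="not defensible"):
            reconstruct_impute(1, missingness=0.30)


class TestBuildUndirected:
    def test_saturated_consistent_input_is_complete(self):
        roster = make_roster(3)
        responses = [
            contact_response(a, b, "monthly")
            for a in roster.org_ids
            for b in roster.org_ids
            if a != b
        ]
        m = build_network(responses, roster, Relation.CONTACT)
        assert m.values.sum() == 6  # all 3 edges, counted twice
        assert not m.missing_mask.any()

    def test_discrepant_dyad_linked_at_default_threshold(self):
        # reports (monthly, annually) dichotomize to (1, 0); mean 0.5 is linked
        roster = make_roster(2)
        responses = [
            contact_response("org_01", "org_02", "monthly"),
            contact_response("org_02", "org_01", "annually"),
        ]
        m = build_network(responses, roster, Relation.CONTACT)
        assert m.values[0, 1] == 1

    def test_discrepant_dyad_unlinked_at_strict_threshold(self):
        roster = make_roster(2)
        responses = [
            contact_response("org_01", "org_02", "monthly"),
            contact_response("org_02", "org_01", "annually"),
        ]
        config = TieRuleConfig(discrepancy_threshold=0.75)
        m = build_network(responses, roster, Relation.CONTACT, config)
        assert m.values[0, 1] == 0

    def test_ordinal_first_averaging_differs_on_skewed_dyad(self):
        # (daily=5, annually=1): mean code 3 ≥ monthly cut → linked;
        # dichotomize-first gives mean 0.5 → linked too, so use (weekly=4, none=0):
        # ordinal mean 2 < 3 unlinked, dichotomized mean 0.5 linked.
        roster = make_roster(2)
        responses = [contact_response("org_01", "org_02", "weekly")]
        ordinal = build_network(
            responses, roster, Relation.CONTACT, TieRuleConfig(averaging="ordinal_first")
        )
        dichot = build_network(responses, roster, Relation.CONTACT)
        assert dichot.values[0, 1] == 1
        assert ordinal.values[0, 1] == 0

    def test_one_sided_dyads_imputed_by_reconstruction(self):
        roster = make_roster(15, nonrespondents={14})
        responses = [contact_response("org_01", "org_15", "weekly")]
        m = build_network(responses, roster, Relation.CONTACT)
        assert m.values[0, 14] == 1
        assert not m.missing_mask[0, 14]
        # the single respondent's silence about org_15 imputes absence
        assert m.values[1, 14] == 0 and not m.missing_mask[1, 14]

    def test_both_nonrespondents_left_missing(self):
        roster = make_roster(15, nonrespondents={13, 14})
        m = build_network([], roster, Relation.CONTACT)
        assert m.values[13, 14] == 0
        assert m.missing_mask[13, 14] and m.missing_mask[14, 13]

    def test_refuses_imputation_above_missingness_limit(self):
        roster = make_roster(10, nonrespondents={6, 7, 8, 9})  # 40% missing
        with pytest.raises(ImputationRefusedError):
            build_network([], roster, Relation.CONTACT)

    def test_nonrespondent_with_rows_rejected(self):
        roster = make_roster(3, nonrespondents={0})
        responses = [contact_response("org_01", "org_02", "daily")]
        with pytest.raises(ValueError, match="nonrespondent"):
            build_network(responses, roster, Relation.CONTACT)


def referral(reporter, source, target):
    return DyadicResponse(reporter, source, target, Relation.REFERRAL, 1)


class TestConfirmTies:
    def test_reciprocally_reported_arc_confirmed(self):
        roster = make_roster(12)
        responses = [
            referral("org_01", "org_01", "org_02"),  # A: I sent to B
            referral("org_02", "org_01", "org_02"),  # B: I received from A
        ]
        m = build_network(responses, roster, Relation.REFERRAL, mode="confirmed")
        assert m.values.sum() == 1 and m.values[0, 1] == 1

    def test_unconfirmed_report_dropped_in_confirmed_mode_only(self):
        roster = make_roster(3)
        responses = [referral("org_01", "org_01", "org_02")]
        confirmed = build_network(responses, roster, Relation.REFERRAL, mode="confirmed")
        unconfirmed = build_network(responses, roster, Relation.REFERRAL, mode="unconfirmed")
        assert confirmed.values[0, 1] == 0
        assert unconfirmed.values[0, 1] == 1

    def test_empty_reports_give_empty_arc_set(self):
        roster = make_roster(4)
        m = build_network([], roster, Relation.REFERRAL, mode="confirmed")
        assert m.values.sum() == 0

    def test_single_report_fallback_for_nonrespondent_endpoint(self):
        roster = make_roster(3, nonrespondents={2})
        responses = [referral("org_01", "org_01", "org_03")]
        m = build_network(responses, roster, Relation.REFERRAL, mode="confirmed")
        assert m.values[0, 2] == 1
        strict = build_network(
            responses, roster, Relation.REFERRAL,
            TieRuleConfig(single_report_fallback=False), mode="confirmed",
        )
        assert strict.values[0, 2] == 0 and strict.missing_mask[0, 2]

    def test_undirected_relation_rejected(self):
        roster = make_roster(3)
        with pytest.raises(ValueError, match="undirected"):
            confirm_ties([], roster, Relation.CONTACT)


class TestInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_confirmed_subset_of_unconfirmed(self, seed):
        rng = np.random.default_rng(seed)
        roster = make_roster(6, nonrespondents=set(rng.choice(6, rng.integers(0, 2))))
        responses = []
        for r_idx in range(6):
            r = f"org_{r_idx + 1:02d}"
            if not roster.responded_flag(r):
                continue
            for o_idx in range(6):
                o = f"org_{o_idx + 1:02d}"
                if o == r:
                    continue
                if rng.random() < 0.4:
                    responses.append(referral(r, r, o))
                if rng.random() < 0.4:
                    responses.append(referral(r, o, r))
        conf = build_network(responses, roster, Relation.REFERRAL, mode="confirmed")
        unconf = build_network(responses, roster, Relation.REFERRAL, mode="unconfirmed")
        assert np.all(conf.values <= unconf.values)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_undirected_output_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        roster = make_roster(6, nonrespondents={5} if rng.random() < 0.5 else set())
        responses = []
        for r_idx in range(6):
            r = f"org_{r_idx + 1:02d}"
            if not roster.responded_flag(r):
                continue
            for o_idx in range(6):
                o = f"org_{o_idx + 1:02d}"
                if o != r and rng.random() < 0.5:
                    responses.append(
                        contact_response(r, o, CONTACT_LEVELS[rng.integers(1, 6)])
                    )
        m = build_network(responses, roster, Relation.CONTACT)
        assert np.array_equal(m.values, m.values.T)
        assert np.array_equal(m.missing_mask, m.missing_mask.T)

    @given(st.integers(1, 5), st.integers(1, 5))
    @settings(max_examples=25, deadline=None)
    def test_monotonicity_raising_a_report_never_deletes_ties(self, low, high):
        # same dyad reported at two levels; the higher report can only add ties
        roster = make_roster(2)
        base = build_network(
            [contact_response("org_01", "org_02", CONTACT_LEVELS[min(low, high)])],
            roster, Relation.CONTACT,
        )
        raised = build_network(
            [contact_response("org_01", "org_02", CONTACT_LEVELS[max(low, high)])],
            roster, Relation.CONTACT,
        )
        assert np.all(base.values <= raised.values)

    def test_imputation_never_alters_fully_reported_dyads(self):
        roster_full = make_roster(4)
        roster_missing = make_roster(4, nonrespondents={3})
        responses = [
            contact_response("org_01", "org_02", "daily"),
            contact_response("org_02", "org_01", "daily"),
            contact_response("org_03", "org_01", "annually"),
        ]
        full = build_network(responses, roster_full, Relation.CONTACT)
        imputed = build_network(responses, roster_missing, Relation.CONTACT)
        assert np.array_equal(full.values[:3, :3], imputed.values[:3, :3])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_reconstruction_recovers_ground_truth(self, seed):
        # fully-observed symmetric truth, one org's responses deleted:
        # consistent remaining reports restore the truth exactly
        rng = np.random.default_rng(seed)
        n = 8
        truth = np.triu(rng.random((n, n)) < 0.4, k=1).astype(int)
        truth = truth + truth.T
        roster = make_roster(n, nonrespondents={int(rng.integers(n))})
        responses = []
        for i in range(n):
            r = f"org_{i + 1:02d}"
            if not roster.responded_flag(r):
                continue
            for j in range(n):
                if i != j and truth[i, j]:
                    responses.append(contact_response(r, f"org_{j + 1:02d}", "weekly"))
        m = build_network(responses, roster, Relation.CONTACT)
        assert np.array_equal(m.values, truth)


class TestExports:
    def test_adjacency_roundtrip(self, tmp_path):
        roster = make_roster(4)
        responses = [
            contact_response("org_01", "org_02", "daily"),
            contact_response("org_02", "org_01", "daily"),
        ]
        m = build_network(responses, roster, Relation.CONTACT)
        write_adjacency(m, tmp_path / "adj.csv")
        back = read_adjacency(tmp_path / "adj.csv", roster, Relation.CONTACT)
        assert np.array_equal(back.values, m.values)

    def test_edgelist_has_no_self_loops_and_matches_tie_count(self, tmp_path):
        import pandas as pd

        roster = make_roster(4)
        responses = [
            referral("org_01", "org_01", "org_02"),
            referral("org_02", "org_01", "org_02"),
            referral("org_03", "org_03", "org_04"),
            referral("org_04", "org_03", "org_04"),
        ]
        m = build_network(responses, roster, Relation.REFERRAL, mode="confirmed")
        write_edgelist(m, tmp_path / "edges.csv")
        df = pd.read_csv(tmp_path / "edges.csv")
        assert len(df) == m.tie_count == 2
        assert (df["source"] != df["target"]).all()
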