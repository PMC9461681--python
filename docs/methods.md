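# Methods

## Measurement model

The pipeline assumes a *bounded* (whole-network) design: a fixed roster of
`n` organizations is established in advance and every organization is
asked about its relationship with every other roster member under six
relation kinds.  Two kinds are undirected — frequency of contact (ordinal:
none < annually < biannually < monthly < weekly < daily) and perceived
level of integration (seven ordered levels, coded 0–6: not linked,
communication, cooperation, coordination, collaboration, partnership,
fully linked) — and four are directed with sender/receiver roles:
referrals, information sharing, joint care planning, shared resources.

A respondent that does not list a partner under a relation is read as
reporting *no tie* (frequency `none`, level `not_linked`, no arc) with
that partner.  This is the key semantic distinction the roster design
buys: silence from a **respondent** is an answer; silence from a
**nonrespondent** is missing data.  Without it, reconstruction imputation
could not tell "reported absent" from "unobserved".

## Tie construction

1. **Dichotomization.**  Contact is cut at *monthly or more often*
   (ordinal code ≥ 3): contact more than twice per year is a link, and
   since no level of the instrument lies strictly between biannual and
   monthly, "more than twice per year" and "monthly or more often" encode
   the same rule.  Integration is cut at *coordination or above*
   (code ≥ 3), inclusive.  Both cut-offs are configurable
   (`TieRuleConfig`).
2. **Discrepancy resolution.**  When both members of a dyad responded and
   disagree, the mean of the two reports is taken.  By default the
   *dichotomized* reports are averaged and the dyad is linked when the
   mean reaches 0.5 (so a (1, 0) split counts as linked — inclusive
   rounding favors reported connectivity).  Both choices are genuinely
   open at the instrument level, so both are configurable: the threshold
   (`discrepancy_threshold`) and the order of operations (`averaging =
   "ordinal_first"` averages raw ordinal codes and applies the cut-off to
   the mean — stricter on skewed dyads such as (weekly, none)).
3. **Reconstruction imputation** (undirected relations).  A dyad with
   exactly one responding endpoint takes that endpoint's dichotomized
   answer, in both directions (reported ties are imputed present,
   reported non-ties absent).  Imputation is refused outright when
   organization-level nonresponse reaches `missingness_limit`
   (default 0.30): above that, a single report per dyad is no longer a
   defensible stand-in, and the error says so rather than silently
   degrading.  Missingness is defined at the organization level
   (fraction of roster members with no response at all), matching how
   response rates are reported for such surveys, not as a fraction of
   unobserved dyads.  Dyads between two nonrespondents stay 0 with the
   missing mask set and a logged warning.
4. **Confirmed ties** (directed relations).  Every arc A→B is potentially
   reported twice: A says "I sent", B says "I received".  Confirmed mode
   requires both; unconfirmed mode accepts either.  Confirmation is
   undefined on dyads touching a nonrespondent; the default
   (`single_report_fallback=True`) falls back to the single available
   report so that nonrespondents still appear in the directed networks,
   with a strict mode that instead leaves such dyads masked as missing.
   Reconstruction-style imputation is deliberately *not* applied to
   directed relations; the fallback rule covers the same gap.

Invariants maintained (and property-tested): undirected outputs are
symmetric; the confirmed arc set is a subset of the unconfirmed arc set
on identical inputs; imputation never alters dyads where both endpoints
responded; raising a report's ordinal value never deletes a tie.

## Network metrics

Density is ties over possible ties — `2L/(n(n−1))` undirected,
`L/(n(n−1))` directed.  Possible ties for directed relations are counted
at the arc level (each ordered pair), the convention of the standard
whole-network tools; a dyad-level alternative would halve the
denominator and is easy to derive from the reported `L` and `n`.

Freeman degree centralization is `Σᵢ(c_max − cᵢ)` over its theoretical
maximum: `(n−1)(n−2)` for undirected total degree and `(n−1)²` for
directed in- or out-degree (the standard directed extension; a star of
arcs all pointing at one node attains exactly `(n−1)²`).  All-zero
networks score 0 by convention.  For directed networks the default basis
is in-degree, matching the node-sizing convention used in directed
network plots; total-degree on a directed matrix counts distinct
neighbors (union of in- and out-neighborhoods).

Interpretive bands for density and centralization: under 0.30 low,
0.30–0.50 moderate (inclusive at both boundaries), above 0.50 high.
Metrics are carried at full precision; reports round densities and
centralizations to 3 decimals and percentages to 1 decimal.

## CPAT scoring

Items are on a 1–7 Likert scale — implied by the instrument's stated
bounds (a minimum total of 8 and maximum of 56 under sum-of-domain-mean
scoring with 8 domains).  Domain score = mean of the domain's items;
provider total = sum of the 8 domain means ∈ [8, 56]; team score =
unweighted mean of provider totals, with the sample standard deviation
(ddof = 1) reported for ≥ 2 providers.  The real instrument's domain
sizes are uneven and not public here, so the domain map is an input;
`uniform_domain_map()` (8 × 7 consecutive items) is the documented
fallback and any exact 8-part partition of items 1–56 is accepted.
Missing items raise by default; `partial=True` averages over answered
items per domain instead.  Reverse-scored items, if the instrument
defines any, must be recoded before scoring — the package does not guess.

## Synthetic-data generator

The generator emulates the two-case study design the pipeline was built
around and is the test bed for every stage.

Ground truth per relation: each dyad (ordered for directed relations) is
an independent Bernoulli draw with
`p_tie = (1 − α)·p + α·[lead ∈ dyad]`, where `p = true_density` and
`α = hub_weight`.  At `α = 0` the expected density is exactly `p` (the
regime all recovery checks use); at `α = 1` the network is a pure star
through the lead agency with centralization 1.  At intermediate `α` the
expected density is a mix of `p` and the star's density, so `p` is a
lower-level dial, not a guaranteed realized density.

Observation: each respondent reports its own row of the truth, with each
dichotomous view flipped independently at the false-negative rate
(default 0.10) and false-positive rate (default 0.02) — modest,
asymmetric reporting noise chosen as typical of informant accuracy in
organizational surveys; no published estimate exists for this
instrument.  Surviving ties are voiced as an ordinal level drawn
uniformly from the levels at or above the relation's cut-off, non-ties
uniformly below it; the zero level emits no row.  Noise acting on each
reporter's dichotomized view independently is the simplest mechanism
that produces dyadic discrepancies (exercising the mean-tie rule) and
confirmed-tie attenuation.  Directed arcs are voiced twice (sender and
receiver views) with independent noise.

Nonresponse: `floor(nonresponse_fraction · n)` organizations drawn
uniformly among non-lead members contribute nothing.  The lead agency
always responds — in the emulated design the lead runs the survey.

CPAT block: provider totals are drawn Normal(`target_team_mean`,
`provider_sd`) clipped to [8, 56], then realized as integer item values
by largest-remainder rounding of the implied item-point sum across the 8
uniform domains, so each rescored total is within 1/14 per domain mean
(< 0.08 in total) of its drawn value; `item_dispersion` applies
sum-preserving ±1 swaps within domains to roughen item profiles.
Defaults `provider_sd = 2.47` and `n_providers = 8` echo the dispersion
of the antecedent multi-team survey and a typical interprofessional
primary-care team size.

Presets `low_cpat_case_config()` / `high_cpat_case_config()` fix the
study conditions: n = 15 / 12 organizations, one nonrespondent each
(response rates 93.3 % / 91.7 %), per-relation true densities set to the
published per-case density estimates, CPAT targets 43.74 / 50.01.
Default `hub_weight = 0.25` gives the lead agency a visible but not
dominant hub role, consistent with moderate published centralization
scores.

What the generator does **not** model: valued (non-binary) tie
strengths, correlation between the six relations within a dyad,
systematic (non-random) nonresponse, reporter-specific bias, or temporal
dynamics.  Passing recovery tests therefore show the pipeline's rules
are implemented correctly, not that real survey data meet these
assumptions.

## Reporting

Plots draw one node per roster organization (isolates always included),
colored by organization type with a legend, sized linearly in degree
(undirected) or in-degree (directed) with a floor of 120 pt² so isolates
stay visible, arrowheads only for directed relations, and a
force-directed (Fruchterman–Reingold) layout seeded for determinism.
Case summaries emit one row per (relation, mode) — 10 rows for the full
design: 2 undirected relations plus 4 directed × {confirmed,
unconfirmed} — and are pure functions of the input matrices.  Perception
percentages are 100 × endorsers / responding organizations, one decimal.

## Numerical and edge-case choices

Density requires n ≥ 2; centralization requires n ≥ 3 (its normalizer
vanishes at n = 2).  Degenerate all-zero networks: density 0,
centralization 0, everyone an isolate.  Undirected dyad keys are
canonicalized lexicographically.  A single integer seed determines every
synthetic output; per-stage substreams are spawned from one seed
sequence so adding a relation or provider never perturbs other stages.

## Problem sizes used in the checks

The acceptance script and test suite run at the scale the method is
designed for: networks of 3–15 organizations, 100–500 Monte-Carlo
replicates for recovery checks, 200 random graphs for oracle agreement —
the whole battery completes in seconds.
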