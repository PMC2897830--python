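"""Grouping, reliability scoring, structure classes and the weight rules."""

from __future__ import annotations

import itertools
import random

import pytest

from domcons import (
    Parameters,
    SecondaryStructureAnnotation,
    StructureClass,
    apply_weight_rules,
    assignments_agree,
    canonical_order,
    classify_structure,
    generate_method_set,
    generate_true_partition,
    group_methods,
    simple_consensus,
    weighted_consensus,
    PerturbationSpec,
)
from conftest import METHODS7, distinct_partitions, make_set

IRREGULAR_SS = SecondaryStructureAnnotation.from_codes("-" * 300)


def partition_shape(a):
    a = canonical_order(a)
    return [[(f.start, f.end) for f in d.fragments] for d in a.domains]


class TestGrouping:
    def test_identical_methods_form_one_group(self, seven_identical):
        groups = group_methods(seven_identical)
        assert len(groups) == 1
        assert set(groups[0].members) == set(METHODS7)
        assert groups[0].representative == "PDP"

    def test_4_2_1_split(self, split_4_2_1):
        groups = group_methods(split_4_2_1)
        assert [g.size for g in groups] == [4, 2, 1]
        assert groups[0].representative == "PDP"
        assert set(groups[1].members) == {"NCBI", "DHcL"}

    def test_two_disagreeing_methods_two_singletons(self):
        S = make_set({"M1": [[(1, 300)]], "M2": [[(1, 150)], [(151, 300)]]})
        assert [g.size for g in group_methods(S)] == [1, 1]

    def test_empty_set_rejected(self):
        from domcons import AssignmentSet

        with pytest.raises(ValueError):
            group_methods(AssignmentSet("1abc", "A", {}))

    def test_members_agree_with_representative(self, split_4_2_1):
        p = Parameters()
        for g in group_methods(split_4_2_1, p):
            rep = split_4_2_1[g.representative]
            for m in g.members:
                assert assignments_agree(split_4_2_1[m], rep, p)


class TestSimpleConsensus:
    def test_unanimous_reliability_is_100(self, seven_identical):
        r = simple_consensus(seven_identical)
        assert r.status == "consensus"
        assert r.groups[0].reliability == 100.0
        assert r.consensus == [0]

    def test_4_2_1_reliabilities(self, split_4_2_1):
        r = simple_consensus(split_4_2_1)
        rel = [round(g.reliability, 1) for g in r.groups]
        assert rel == [57.1, 28.6, 14.3]
        # 57.1 - 28.6 >= 10, so only the top group is the consensus
        assert r.status == "consensus"
        assert r.consensus == [0]

    def test_3_3_1_is_a_tie(self):
        a = [[(1, 150)], [(151, 300)]]
        b = [[(1, 100)], [(101, 200)], [(201, 300)]]
        c = [[(1, 300)]]
        S = make_set(
            {"PDP": a, "DomainParser2": a, "PUU": a,
             "DDomain": b, "NCBI": b, "DHcL": b,
             "Dodis": c}
        )
        r = simple_consensus(S)
        rel = [round(g.reliability, 1) for g in r.groups]
        assert rel == [42.9, 42.9, 14.3]
        assert r.status == "tied_consensus"
        assert len(r.consensus) == 2

    def test_2_2_2_1_no_consensus(self):
        a = [[(1, 150)], [(151, 300)]]
        b = [[(1, 100)], [(101, 200)], [(201, 300)]]
        c = [[(1, 300)]]
        d = [[(1, 70)], [(71, 140)], [(141, 210)], [(211, 300)]]
        S = make_set(
            {"PDP": a, "DomainParser2": a,
             "PUU": b, "DDomain": b,
             "NCBI": c, "DHcL": c,
             "Dodis": d}
        )
        r = simple_consensus(S)
        assert max(g.reliability for g in r.groups) == pytest.approx(200 / 7)
        assert r.status == "no_consensus"
        assert r.consensus == []

    def test_reliabilities_sum_to_100(self, split_4_2_1):
        r = simple_consensus(split_4_2_1)
        assert sum(g.reliability for g in r.groups) == pytest.approx(100.0, abs=1e-9)

    def test_smallest_consensus_group_of_seven_is_three(self):
        # with 7 equal votes and a 40% floor, ceil(0.4 * 7) = 3 methods
        parts = distinct_partitions(7)
        for k in range(1, 8):
            shared = parts[0]
            layouts = {}
            for i, m in enumerate(METHODS7):
                layouts[m] = shared if i < k else parts[i]
            r = simple_consensus(make_set(layouts))
            assert (r.status != "no_consensus") == (k >= 3)


class TestStructureClass:
    def test_pure_helix_is_all_alpha(self):
        ss = SecondaryStructureAnnotation.from_codes("-" * 10 + "H" * 60 + "-" * 30)
        assert classify_structure(ss) is StructureClass.ALL_ALPHA

    def test_trace_helix_still_all_beta(self):
        # 1 helix residue of 41 element residues: 0.024 <= 0.05
        codes = "E" * 20 + "---" + "E" * 20 + "---" + "G" + "-" * 10
        ss = SecondaryStructureAnnotation.from_codes(codes)
        n_h = sum(s.length for s in ss.elements_of("helix"))
        n_e = sum(s.length for s in ss.elements_of("strand"))
        assert (n_h, n_e) == (1, 40)
        assert classify_structure(ss) is StructureClass.ALL_BETA

    def test_balanced_mix_is_alpha_beta(self):
        ss = SecondaryStructureAnnotation.from_codes("H" * 30 + "-" * 10 + "E" * 30)
        assert classify_structure(ss) is StructureClass.ALPHA_BETA

    def test_no_elements_is_irregular(self):
        assert classify_structure(IRREGULAR_SS) is StructureClass.IRREGULAR

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            classify_structure(SecondaryStructureAnnotation.from_codes(""))


# -- weight rule engine ----------------------------------------------------

# layouts by domain count, tiling 1..300
P1 = [[(1, 300)]]
P2 = [[(1, 150)], [(151, 300)]]
P3 = [[(1, 100)], [(101, 200)], [(201, 300)]]
P4 = [[(1, 75)], [(76, 150)], [(151, 225)], [(226, 300)]]
P5 = [[(1, 60)], [(61, 120)], [(121, 180)], [(181, 240)], [(241, 300)]]
# fragmented variants (first domain in two pieces)
F2 = [[(1, 80), (221, 300)], [(81, 220)]]
F3 = [[(1, 50), (251, 300)], [(51, 150)], [(151, 250)]]

BASE = Parameters().base_weights


def _wv(layouts, cls=StructureClass.IRREGULAR, p=None):
    p = p or Parameters()
    S = make_set(layouts)
    return apply_weight_rules(S, cls, group_methods(S, p), p)


class TestWeightRules:
    def test_no_rule_is_identity(self):
        wv = _wv({"PDP": P2, "NCBI": P2, "DomainParser2": P2})
        assert wv.weights == {m: BASE[m] for m in ("PDP", "NCBI", "DomainParser2")}
        assert all(not rules for rules in wv.provenance.values())

    def test_r1_many_domains_downgrades_domainparser2(self):
        wv = _wv({"PDP": P4, "NCBI": P4, "DomainParser2": P2})
        assert wv.weights["DomainParser2"] == pytest.approx(78.1 * 0.9)
        assert wv.provenance["DomainParser2"] == ["R1"]
        assert wv.weights["PDP"] == BASE["PDP"]

    def test_r2_puu_overcut_downgraded(self):
        wv = _wv({"PDP": P2, "NCBI": P2, "PUU": P3})
        assert wv.weights["PUU"] == pytest.approx(74.0 * 0.9)
        assert wv.provenance["PUU"] == ["R2"]

    def test_r3_pdp_five_domains_downgrades_ncbi(self):
        wv = _wv({"PDP": P5, "NCBI": P2})
        assert wv.weights["NCBI"] == pytest.approx(81.9 * 0.9)
        assert wv.provenance["NCBI"] == ["R3"]

    def test_r4_nonfragmenting_methods_downgraded(self):
        # three fragmenting methods, PDP among them so the R5 gate is closed
        wv = _wv({"PDP": F2, "PUU": F2, "DDomain": F3,
                  "NCBI": P2, "DomainParser2": P2})
        for m in ("NCBI", "DomainParser2"):
            assert wv.weights[m] == pytest.approx(BASE[m] * 0.9)
            assert wv.provenance[m] == ["R4"]
        assert wv.weights["PDP"] == BASE["PDP"]

    def test_r5_fragmenting_methods_downgraded(self):
        wv = _wv({"PDP": P2, "NCBI": P2, "PUU": F2})
        assert wv.weights["PUU"] == pytest.approx(74.0 * 0.9)
        assert wv.provenance["PUU"] == ["R5"]

    def test_r6_all_alpha_count_disagreement_boosts_pdp(self):
        wv = _wv({"PDP": P1, "NCBI": P2}, cls=StructureClass.ALL_ALPHA)
        assert wv.weights["PDP"] == pytest.approx(84.4 * 1.1)
        assert wv.provenance["PDP"] == ["R6"]

    def test_r7_all_beta_count_disagreement_boosts_pdp(self):
        wv = _wv({"PDP": P1, "NCBI": P2}, cls=StructureClass.ALL_BETA)
        assert wv.weights["PDP"] == pytest.approx(84.4 * 1.1)
        assert wv.provenance["PDP"] == ["R7"]

    def test_r8_all_beta_count_agreement_boosts_both(self):
        wv = _wv({"PDP": P2, "NCBI": P2}, cls=StructureClass.ALL_BETA)
        assert wv.weights["PDP"] == pytest.approx(84.4 * 1.1)
        assert wv.weights["NCBI"] == pytest.approx(81.9 * 1.1)
        assert wv.provenance["PDP"] == ["R8"]

    def test_r9_alpha_beta_dissenters_downgraded(self):
        wv = _wv({"PDP": P2, "NCBI": P2, "Dodis": P3},
                 cls=StructureClass.ALPHA_BETA)
        assert wv.weights["Dodis"] == pytest.approx(40.0 * 0.9)
        assert wv.provenance["Dodis"] == ["R9"]
        assert wv.weights["PDP"] == BASE["PDP"]

    def test_r4_and_r5_stack_on_different_methods(self):
        # PUU, DDomain, DHcL fragment; PDP and NCBI do not: R4 hits the
        # non-fragmenting methods, R5 the fragmenting ones
        wv = _wv({"PDP": P2, "NCBI": P2, "PUU": F2, "DDomain": F2, "DHcL": F3})
        for m in ("PDP", "NCBI"):
            assert wv.weights[m] == pytest.approx(BASE[m] * 0.9)
            assert wv.provenance[m] == ["R4"]
        for m in ("PUU", "DDomain", "DHcL"):
            assert wv.weights[m] == pytest.approx(BASE[m] * 0.9)
            assert wv.provenance[m] == ["R5"]

    def test_unknown_method_gets_fallback_weight(self):
        wv = _wv({"PDP": P2, "Mystery": P2})
        assert wv.weights["Mystery"] == 50.0

    def test_rules_for_absent_methods_skipped(self):
        # PDP has 5 domains but NCBI is absent: R3 cannot fire
        wv = _wv({"PDP": P5, "PUU": P2})
        assert all(not rules for rules in wv.provenance.values())


class TestWeightedConsensus:
    def test_unanimous_is_100_regardless_of_weights(self, seven_identical):
        r = weighted_consensus(seven_identical, IRREGULAR_SS)
        assert r.groups[0].reliability == pytest.approx(100.0)
        assert r.status == "consensus"

    def test_three_heavyweights_reach_consensus(self):
        layouts = {
            "PDP": P2, "DomainParser2": P2, "NCBI": P2,
            "PUU": P1, "DDomain": P3, "DHcL": P4, "Dodis": P5,
        }
        r = weighted_consensus(make_set(layouts), IRREGULAR_SS)
        top = r.groups[r.consensus[0]]
        assert set(top.members) == {"PDP", "DomainParser2", "NCBI"}
        assert top.reliability == pytest.approx(100 * 244.4 / 503.2, abs=1e-9)
        assert round(top.reliability, 2) == 48.57
        assert r.status == "consensus"

    def test_absent_method_drops_from_denominator(self):
        layouts = {
            "PDP": P2, "DomainParser2": P2, "NCBI": P2,
            "PUU": P1, "DDomain": P3, "DHcL": P4,
        }
        r = weighted_consensus(make_set(layouts), IRREGULAR_SS)
        top = r.groups[r.consensus[0]]
        assert top.reliability == pytest.approx(100 * 244.4 / 463.2, abs=1e-9)
        assert round(top.reliability, 2) == 52.76

    def test_uniform_weights_reproduce_simple_consensus(self):
        rng = random.Random(7)
        uniform = Parameters(
            base_weights={m: 50.0 for m in METHODS7},
            rule_adjustment=0.0,  # no rule can perturb equality
        )
        for trial in range(20):
            truth = generate_true_partition(300, rng.randint(1, 4), seed=trial)
            specs = {
                m: PerturbationSpec(
                    boundary_jitter=rng.randint(0, 20),
                    merge_prob=rng.random() * 0.6,
                    split_prob=rng.random() * 0.6,
                    seed=trial,
                )
                for m in METHODS7
            }
            S = generate_method_set(truth, specs)
            simple = simple_consensus(S, uniform)
            weighted = weighted_consensus(S, IRREGULAR_SS, uniform)
            assert [g.members for g in weighted.groups] == [
                g.members for g in simple.groups
            ]
            for gw, gs in zip(weighted.groups, simple.groups):
                assert gw.reliability == pytest.approx(gs.reliability)
            assert weighted.status == simple.status
            assert weighted.consensus == simple.consensus

    def test_weighted_reliabilities_sum_to_100(self, split_4_2_1):
        r = weighted_consensus(split_4_2_1, IRREGULAR_SS)
        assert sum(g.reliability for g in r.groups) == pytest.approx(100.0, abs=1e-9)


# -- structural properties of the grouping --------------------------------

def _agreement_components(S, p):
    """Brute-force connected components of the pairwise agreement graph."""
    methods = list(S.methods)
    parent = {m: m for m in methods}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for a, b in itertools.combinations(methods, 2):
        if assignments_agree(S[a], S[b], p):
            parent[find(a)] = find(b)
    comps = {}
    for m in methods:
        comps.setdefault(find(m), set()).add(m)
    return sorted(map(frozenset, comps.values()), key=sorted)


def _is_transitive(S, p):
    ms = list(S.methods)
    agree = {
        (a, b): assignments_agree(S[a], S[b], p)
        for a, b in itertools.product(ms, ms)
    }
    return all(
        not (agree[(a, b)] and agree[(b, c)]) or agree[(a, c)]
        for a, b, c in itertools.product(ms, ms, ms)
    )


def test_grouping_matches_graph_components_when_transitive():
    p = Parameters()
    n_transitive = 0
    for seed in range(40):
        truth = generate_true_partition(300, 1 + seed % 4, seed=seed)
        specs = {
            m: PerturbationSpec(
                boundary_jitter=4 * (i % 3),
                merge_prob=0.3 if i % 2 else 0.0,
                split_prob=0.3 if i % 3 == 0 else 0.0,
                seed=seed,
            )
            for i, m in enumerate(METHODS7)
        }
        S = generate_method_set(truth, specs)
        if not _is_transitive(S, p):
            continue
        n_transitive += 1
        got = sorted((frozenset(g.members) for g in group_methods(S, p)), key=sorted)
        assert got == _agreement_components(S, p)
    assert n_transitive >= 10  # the check must actually exercise instances


def test_method_order_permutation_keeps_unanimity(seven_identical):
    rng = random.Random(0)
    order = list(METHODS7)
    for _ in range(10):
        rng.shuffle(order)
        p = Parameters(method_order=tuple(order))
        r = simple_consensus(seven_identical, p)
        assert r.groups[0].reliability == 100.0
        assert r.status == "consensus"


def test_order_dependence_on_nontransitive_instance_is_stable():
    """Regression fixture: grouping of a non-transitive chain of partitions.

    B agrees with both A and C, but A and C disagree; processed A-first the
    greedy pass yields {A, B}, {C}, processed C-first it yields {C, B}, {A}.
    """
    layouts = {
        "A": [[(1, 100)]],
        "B": [[(11, 100)]],
        "C": [[(26, 100)]],
    }
    S = make_set(layouts, extent=(1, 100))
    fwd = group_methods(S, Parameters(method_order=("A", "B", "C")))
    rev = group_methods(S, Parameters(method_order=("C", "B", "A")))
    assert [set(g.members) for g in fwd] == [{"A", "B"}, {"C"}]
    assert [set(g.members) for g in rev] == [{"C", "B"}, {"A"}]


def test_parameter_recovery_with_majority_of_faithful_methods():
    """With >=4 of 7 methods copying the truth, the consensus recovers it."""
    faithful = METHODS7[:4]
    noisy = METHODS7[4:]
    for seed in range(100):
        truth = generate_true_partition(300, 1 + seed % 4, seed=seed)
        specs = {}
        for m in faithful:
            specs[m] = PerturbationSpec(seed=seed)
        for m in noisy:
            specs[m] = PerturbationSpec(
                boundary_jitter=40, merge_prob=0.9, split_prob=0.9, seed=seed
            )
        S = generate_method_set(truth, specs)
        r = simple_consensus(S)
        assert r.status in ("consensus", "tied_consensus")
        rep = S[r.groups[r.consensus[0]].representative]
        assert partition_shape(rep) == partition_shape(truth)
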