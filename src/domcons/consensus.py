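"""Consensus of domain assignments across methods.

Grouping is greedy and deterministic: methods are processed in a fixed
order; the first method founds the first group and becomes its
representative; every subsequent method is compared against each existing
group's representative (in group-creation order) and joins the first group
it agrees with, otherwise founds its own group.

Reliability of a group is the percentage of methods it contains (simple
consensus) or the normalized sum of its members' adjusted weights
(weighted consensus). A consensus is declared when the best group reaches
the threshold (default 40%); if the runner-up is strictly closer than the
near-tie window (default 10 points), both groups are reported.

The weighted variant starts from prior per-method success rates and
adjusts them with context rules keyed to predicted domain counts, domain
fragmentation, and the chain's secondary-structure class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .agreement import assignments_agree
from .core import (
    AssignmentSet,
    ConsensusGroup,
    ConsensusResult,
    Parameters,
    SecondaryStructureAnnotation,
    StructureClass,
)

__all__ = [
    "WeightVector",
    "group_methods",
    "simple_consensus",
    "weighted_consensus",
    "classify_structure",
    "apply_weight_rules",
]

log = logging.getLogger(__name__)

#: weight given (with a warning) to methods missing from base_weights
FALLBACK_WEIGHT = 50.0


@dataclass
class WeightVector:
    """Adjusted per-method weights plus which rules touched each method."""

    weights: dict[str, float]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.weights.values())


def _ordered_methods(S: AssignmentSet, p: Parameters) -> list[str]:
    present = set(S.methods)
    ordered = [m for m in p.method_order if m in present]
    ordered += sorted(present - set(ordered))
    return ordered


def group_methods(S: AssignmentSet, p: Parameters | None = None) -> list[ConsensusGroup]:
    """Greedy grouping of methods by pairwise agreement.

    Returned groups carry the *simple* (equal-vote) reliability; the
    weighted variant rescores the same groups. Group order is creation
    order.
    """
    p = p or Parameters()
    if not S.assignments:
        raise ValueError("cannot group an empty assignment set")
    order = _ordered_methods(S, p)
    groups: list[list[str]] = []
    for m in order:
        for g in groups:
            if assignments_agree(S[m], S[g[0]], p):
                g.append(m)
                break
        else:
            groups.append([m])
    n = len(order)
    return [
        ConsensusGroup(
            members=tuple(g), representative=g[0], reliability=100.0 * len(g) / n
        )
        for g in groups
    ]


def _select(
    groups: list[ConsensusGroup], p: Parameters, mode: str
) -> ConsensusResult:
    """Apply the threshold / near-tie logic to scored groups."""
    # ties in reliability broken by earlier creation order (stable sort)
    ranked = sorted(range(len(groups)), key=lambda i: -groups[i].reliability)
    top = ranked[0]
    flags: list[str] = []
    if groups[top].reliability >= p.consensus_threshold:
        consensus = [top]
        status = "consensus"
        if len(ranked) > 1:
            runner = ranked[1]
            if groups[top].reliability - groups[runner].reliability < p.near_tie_window:
                consensus.append(runner)
                status = "tied_consensus"
                if groups[runner].reliability < p.consensus_threshold:
                    flags.append("tied_runner_up_below_threshold")
    else:
        consensus = []
        status = "no_consensus"
    return ConsensusResult(
        groups=groups, consensus=consensus, mode=mode, status=status,
        parameters=p, flags=flags,
    )


def simple_consensus(S: AssignmentSet, p: Parameters | None = None) -> ConsensusResult:
    """Equal-vote consensus: reliability = 100 x members / methods."""
    p = p or Parameters()
    return _select(group_methods(S, p), p, mode="simple")


def classify_structure(
    ss: SecondaryStructureAnnotation, p: Parameters | None = None
) -> StructureClass:
    """Coarse structure class from the helix/strand element content.

    Fractions are taken among residues covered by any element; an element
    kind contributing no more than ``ss_class_minor_fraction`` is ignored.
    A chain with no elements at all is irregular.
    """
    p = p or Parameters()
    if not ss.codes:
        raise ValueError("cannot classify an empty annotation")
    n_h = sum(seg.length for seg in ss.elements_of("helix"))
    n_e = sum(seg.length for seg in ss.elements_of("strand"))
    total = n_h + n_e
    if total == 0:
        return StructureClass.IRREGULAR
    h, e = n_h / total, n_e / total
    if e <= p.ss_class_minor_fraction:
        return StructureClass.ALL_ALPHA
    if h <= p.ss_class_minor_fraction:
        return StructureClass.ALL_BETA
    return StructureClass.ALPHA_BETA


def apply_weight_rules(
    S: AssignmentSet,
    cls: StructureClass,
    groups: list[ConsensusGroup],
    p: Parameters | None = None,
) -> WeightVector:
    """Adjust base weights with the nine context rules, in fixed order.

    Each applicable rule multiplies the affected methods' weights by
    (1 - rule_adjustment) for a reduction or (1 + rule_adjustment) for an
    increase; rules stack multiplicatively and each fires at most once.
    Rules that reference a method not present in the set are skipped.
    """
    p = p or Parameters()
    weights: dict[str, float] = {}
    prov: dict[str, list[str]] = {m: [] for m in S.methods}
    for m in S.methods:
        w = p.base_weights.get(m)
        if w is None:
            log.warning("method %r has no base weight; using %.1f", m, FALLBACK_WEIGHT)
            w = FALLBACK_WEIGHT
        weights[m] = w

    down = 1.0 - p.rule_adjustment
    up = 1.0 + p.rule_adjustment
    counts = {m: S[m].n_domains for m in S.methods}
    fragmented = {m: S[m].has_fragmented_domain for m in S.methods}

    def adjust(methods, factor: float, rule: str) -> None:
        for m in methods:
            if m in weights:
                weights[m] *= factor
                prov[m].append(rule)

    def have(*ms: str) -> bool:
        return all(m in weights for m in ms)

    # -- domain-count rules ------------------------------------------------
    if have("PDP", "NCBI", "DomainParser2") and counts["PDP"] >= 4 and counts["NCBI"] >= 4:
        adjust(["DomainParser2"], down, "R1")
    if have("PUU", "PDP", "NCBI") and counts["PUU"] > counts["PDP"] and counts["PUU"] > counts["NCBI"]:
        adjust(["PUU"], down, "R2")
    if have("PDP", "NCBI") and counts["PDP"] >= 5:
        adjust(["NCBI"], down, "R3")
    # -- fragmentation rules ----------------------------------------------
    if sum(fragmented.values()) >= 3:
        adjust([m for m in weights if not fragmented[m]], down, "R4")
    if have("PDP", "NCBI") and not fragmented["PDP"] and not fragmented["NCBI"]:
        adjust([m for m in weights if fragmented[m]], down, "R5")
    # -- structure-class rules --------------------------------------------
    counts_differ = have("PDP", "NCBI") and counts["PDP"] != counts["NCBI"]
    counts_equal = have("PDP", "NCBI") and counts["PDP"] == counts["NCBI"]
    if cls is StructureClass.ALL_ALPHA and counts_differ:
        adjust(["PDP"], up, "R6")
    if cls is StructureClass.ALL_BETA and counts_differ:
        adjust(["PDP"], up, "R7")
    if cls is StructureClass.ALL_BETA and counts_equal:
        adjust(["PDP", "NCBI"], up, "R8")
    if cls is StructureClass.ALPHA_BETA and counts_equal:
        pdp_group = next((g for g in groups if "PDP" in g.members), None)
        if pdp_group is not None:
            adjust([m for m in weights if m not in pdp_group.members], down, "R9")
    return WeightVector(weights=weights, provenance=prov)


def weighted_consensus(
    S: AssignmentSet,
    ss: SecondaryStructureAnnotation,
    p: Parameters | None = None,
) -> ConsensusResult:
    """Weight-adjusted consensus on the same groups as the simple mode.

    Group reliability = 100 x sum(member weights) / sum(all present
    methods' weights); with equal weights this reduces exactly to the
    simple consensus. Weights are renormalized over the methods present,
    so an absent method drops out of the denominator.
    """
    p = p or Parameters()
    groups = group_methods(S, p)
    cls = classify_structure(ss, p)
    wv = apply_weight_rules(S, cls, groups, p)
    total = wv.total
    scored = [
        ConsensusGroup(
            members=g.members,
            representative=g.representative,
            reliability=100.0 * sum(wv.weights[m] for m in g.members) / total,
        )
        for g in groups
    ]
    result = _select(scored, p, mode="weighted")
    result.structure_class = cls
    result.weights = wv
    return result
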