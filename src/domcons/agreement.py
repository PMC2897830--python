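"""Pairwise agreement between two methods' domain assignments of one chain.

Two assignments agree when (i) they partition the chain into the same
number of domains, (ii) after pairing domains along the sequence, each
matched pair has the same number of fragments, and (iii) the residue
overlap between each matched domain — and each positionally matched
fragment — covers at least ``overlap_threshold`` (default 80%) of *both*
partners. The bidirectional form is the strictest reading of "80% of the
residues should be the same" and keeps the relation symmetric.

The relation is reflexive and symmetric but *not* transitive: a boundary
can drift a little between A and B and a little more between B and C so
that A and C no longer overlap sufficiently. Consensus grouping therefore
depends on processing order for such instances (see :mod:`domcons.consensus`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    ChainAssignment,
    Parameters,
    canonical_order,
    residue_set,
)

__all__ = ["DomainMatch", "overlap_fractions", "match_domains", "assignments_agree"]


def overlap_fractions(a: set[int], b: set[int]) -> tuple[float, float]:
    """(|a∩b|/|a|, |a∩b|/|b|) for two non-empty residue sets."""
    if not a or not b:
        raise ValueError("overlap_fractions requires non-empty residue sets")
    inter = len(a & b)
    return inter / len(a), inter / len(b)


@dataclass(frozen=True)
class DomainMatch:
    """A pairing of A's domains with B's domains and their overlaps."""

    pairs: tuple[tuple[int, int], ...]
    per_pair_overlap: tuple[tuple[float, float], ...]


def _check_same_chain(A: ChainAssignment, B: ChainAssignment) -> None:
    if (A.pdb_id, A.chain_id) != (B.pdb_id, B.chain_id):
        raise ValueError(
            f"cannot compare assignments of different chains: "
            f"{A.pdb_id}{A.chain_id} vs {B.pdb_id}{B.chain_id}"
        )


def _optimal_pairs(
    sets_a: list[set[int]], sets_b: list[set[int]]
) -> list[tuple[int, int]]:
    """Max-total-overlap bijection (greedy on sorted overlaps; n <= ~20).

    Offered behind ``Parameters.optimal_domain_matching`` for robustness
    studies; the default positional pairing is the primary semantics.
    """
    n = len(sets_a)
    cand = sorted(
        ((len(sets_a[i] & sets_b[j]), -i, -j, i, j) for i in range(n) for j in range(n)),
        reverse=True,
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
        if len(pairs) == n:
            break
    return sorted(pairs)


def match_domains(
    A: ChainAssignment, B: ChainAssignment, parameters: Parameters | None = None
) -> DomainMatch | None:
    """Pair up domains of two assignments, or return None on a no-match.

    No-match when the domain counts differ, or when any matched pair has
    differing fragment counts. Pairing is positional after canonical
    (N-terminal start) ordering.
    """
    p = parameters or Parameters()
    _check_same_chain(A, B)
    A = canonical_order(A)
    B = canonical_order(B)
    if len(A.domains) != len(B.domains):
        return None
    sets_a = [residue_set(d) for d in A.domains]
    sets_b = [residue_set(d) for d in B.domains]
    if p.optimal_domain_matching:
        pairs = _optimal_pairs(sets_a, sets_b)
    else:
        pairs = [(i, i) for i in range(len(A.domains))]
    for i, j in pairs:
        if A.domains[i].n_fragments != B.domains[j].n_fragments:
            return None
    overlaps = tuple(overlap_fractions(sets_a[i], sets_b[j]) for i, j in pairs)
    return DomainMatch(pairs=tuple(pairs), per_pair_overlap=overlaps)


def assignments_agree(
    A: ChainAssignment, B: ChainAssignment, p: Parameters | None = None
) -> bool:
    """Do two assignments agree under the overlap criterion?

    True iff :func:`match_domains` succeeds and every matched domain pair —
    and, with ``fragment_level_check``, every positionally matched fragment
    pair — has both overlap fractions >= ``p.overlap_threshold``.
    """
    p = p or Parameters()
    m = match_domains(A, B, p)
    if m is None:
        return False
    t = p.overlap_threshold
    if any(fa < t or fb < t for fa, fb in m.per_pair_overlap):
        return False
    if p.fragment_level_check:
        Ac = canonical_order(A)
        Bc = canonical_order(B)
        for i, j in m.pairs:
            for fa, fb in zip(Ac.domains[i].fragments, Bc.domains[j].fragments):
                ra, rb = overlap_fractions(set(fa.residues()), set(fb.residues()))
                if ra < t or rb < t:
                    return False
    return True
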