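"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pytest

from domcons import (
    AssignmentSet,
    ChainAssignment,
    Domain,
    Parameters,
    Segment,
)

METHODS7 = ("PDP", "DomainParser2", "PUU", "DDomain", "NCBI", "DHcL", "Dodis")


def make_assignment(
    domains: "list[list[tuple[int, int]]]",
    method: str = "M",
    extent: "tuple[int, int] | None" = None,
    pdb_id: str = "1abc",
    chain_id: str = "A",
) -> ChainAssignment:
    """Build a ChainAssignment from [[(start, end), ...], ...] per domain."""
    doms = tuple(
        Domain(f"D{i + 1}", tuple(Segment(s, e) for s, e in frags))
        for i, frags in enumerate(domains)
    )
    if extent is None:
        lo = min(s for frags in domains for s, _ in frags)
        hi = max(e for frags in domains for _, e in frags)
    else:
        lo, hi = extent
    return ChainAssignment(pdb_id, chain_id, method, doms, Segment(lo, hi))


def make_set(
    per_method: "dict[str, list[list[tuple[int, int]]]]",
    extent: "tuple[int, int] | None" = None,
    pdb_id: str = "1abc",
    chain_id: str = "A",
) -> AssignmentSet:
    """Build an AssignmentSet from per-method domain layouts.

    All methods share the widest extent so that comparisons are sound.
    """
    if extent is None:
        lo = min(s for doms in per_method.values() for frags in doms for s, _ in frags)
        hi = max(e for doms in per_method.values() for frags in doms for _, e in frags)
        extent = (lo, hi)
    return AssignmentSet(
        pdb_id,
        chain_id,
        {
            m: make_assignment(doms, method=m, extent=extent,
                               pdb_id=pdb_id, chain_id=chain_id)
            for m, doms in per_method.items()
        },
    )


def distinct_partitions(n: int, length: int = 300) -> "list[list[list[tuple[int, int]]]]":
    """n mutually disagreeing partitions of 1..length (distinct domain counts)."""
    out = []
    for k in range(1, n + 1):
        size = length // k
        doms = []
        pos = 1
        for i in range(k):
            end = length if i == k - 1 else pos + size - 1
            doms.append([(pos, end)])
            pos = end + 1
        out.append(doms)
    return out


@pytest.fixture
def params() -> Parameters:
    return Parameters()


@pytest.fixture
def seven_identical() -> AssignmentSet:
    """All seven canonical methods reporting the same 2-domain partition."""
    layout = [[(1, 150)], [(151, 300)]]
    return make_set({m: layout for m in METHODS7})


@pytest.fixture
def split_4_2_1() -> AssignmentSet:
    """Four methods agree, two agree on another partition, one is alone."""
    a = [[(1, 150)], [(151, 300)]]
    b = [[(1, 100)], [(101, 200)], [(201, 300)]]
    c = [[(1, 300)]]
    return make_set(
        {
            "PDP": a, "DomainParser2": a, "PUU": a, "DDomain": a,
            "NCBI": b, "DHcL": b,
            "Dodis": c,
        }
    )
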