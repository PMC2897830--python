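"""Domain/fragment boundaries and whether they cut secondary structure.

A boundary is a residue at which a domain fragment starts or ends,
excluding the chain termini. A helix is cut by a boundary falling anywhere
inside it except the two residues at either end (first, second,
penultimate, ultimate); a strand is cut except at its first and last
residue. These trimmed rules drive the per-method statistics; the context
track rendering shows the untrimmed elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import (
    AssignmentSet,
    ChainAssignment,
    Parameters,
    SecondaryStructureAnnotation,
    Segment,
    canonical_order,
)

__all__ = [
    "Boundary",
    "CutRecord",
    "MethodBoundaryStats",
    "BoundaryStats",
    "extract_boundaries",
    "is_cut",
    "cut_records",
    "boundary_statistics",
    "boundary_context",
]


@dataclass(frozen=True)
class Boundary:
    """A residue where a domain or fragment starts/ends (termini excluded)."""

    residue: int
    kind: str  # "domain_start" | "domain_end" | "fragment_start" | "fragment_end"
    method: str
    domain_id: str


@dataclass(frozen=True)
class CutRecord:
    """One boundary examined against one secondary-structure element."""

    boundary: Boundary
    element_kind: str  # "helix" | "strand"
    element: Segment
    is_cut: bool


@dataclass(frozen=True)
class MethodBoundaryStats:
    method: str
    n_boundaries: int
    n_helix_cuts: int
    n_strand_cuts: int
    helix_cut_fraction: float
    strand_cut_fraction: float
    no_boundaries: bool = False


@dataclass
class BoundaryStats:
    """Per-method boundary/cut statistics for one chain."""

    per_method: dict[str, MethodBoundaryStats] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(s) for s in self.per_method.values()]
        cols = [
            "method",
            "n_boundaries",
            "n_helix_cuts",
            "n_strand_cuts",
            "helix_cut_fraction",
            "strand_cut_fraction",
            "no_boundaries",
        ]
        return pd.DataFrame(rows, columns=cols)


def extract_boundaries(
    a: ChainAssignment, dedupe: bool = True
) -> list[Boundary]:
    """Fragment start/end residues of an assignment, minus chain termini.

    The first fragment's start and last fragment's end of each domain are
    labelled domain_start/domain_end; interior fragment endpoints are
    fragment_start/fragment_end. With ``dedupe`` (the default), several
    endpoints of one method falling on the same residue are kept once.
    """
    a = canonical_order(a)
    ext = a.chain_extent
    out: list[Boundary] = []
    seen: set[int] = set()
    for d in a.domains:
        last = len(d.fragments) - 1
        for i, f in enumerate(d.fragments):
            for residue, kind in (
                (f.start, "domain_start" if i == 0 else "fragment_start"),
                (f.end, "domain_end" if i == last else "fragment_end"),
            ):
                if residue in (ext.start, ext.end):
                    continue
                if dedupe and residue in seen:
                    continue
                seen.add(residue)
                out.append(Boundary(residue, kind, a.method, d.domain_id))
    return sorted(out, key=lambda b: b.residue)


def is_cut(
    b: "Boundary | int", kind: str, el: Segment, p: Parameters | None = None
) -> bool:
    """Does a boundary cut an element, under the end-exclusion rule?

    Helix: cut iff start + helix_end_exclusion <= residue <= end -
    helix_end_exclusion (so a helix of length <= 4 can never be cut with
    the default exclusion of 2). Strand: analogous with the 1-residue
    exclusion.
    """
    p = p or Parameters()
    residue = b.residue if isinstance(b, Boundary) else b
    excl = p.helix_end_exclusion if kind == "helix" else p.strand_end_exclusion
    return el.start + excl <= residue <= el.end - excl


def cut_records(
    S: AssignmentSet,
    ss: SecondaryStructureAnnotation,
    p: Parameters | None = None,
) -> list[CutRecord]:
    """Every (boundary, element-it-falls-in) pair with its cut decision."""
    p = p or Parameters()
    records: list[CutRecord] = []
    for m in S.methods:
        for b in extract_boundaries(S[m], dedupe=p.dedupe_shared_boundaries):
            for kind, el in ss.elements:
                if b.residue in el:
                    records.append(CutRecord(b, kind, el, is_cut(b, kind, el, p)))
    return records


def boundary_statistics(
    S: AssignmentSet,
    ss: SecondaryStructureAnnotation,
    p: Parameters | None = None,
) -> BoundaryStats:
    """Per-method counts and fractions of boundaries cutting helices/strands.

    A boundary is counted at most once per element kind even if elements
    were (pathologically) adjacent; a method with zero boundaries reports
    fractions of 0 and is flagged.
    """
    p = p or Parameters()
    stats = BoundaryStats()
    for m in S.methods:
        bounds = extract_boundaries(S[m], dedupe=p.dedupe_shared_boundaries)
        n = len(bounds)
        h_cuts = e_cuts = 0
        for b in bounds:
            if any(is_cut(b, "helix", el, p) for el in ss.elements_of("helix")):
                h_cuts += 1
            if any(is_cut(b, "strand", el, p) for el in ss.elements_of("strand")):
                e_cuts += 1
        stats.per_method[m] = MethodBoundaryStats(
            method=m,
            n_boundaries=n,
            n_helix_cuts=h_cuts,
            n_strand_cuts=e_cuts,
            helix_cut_fraction=h_cuts / n if n else 0.0,
            strand_cut_fraction=e_cuts / n if n else 0.0,
            no_boundaries=(n == 0),
        )
    return stats


def boundary_context(
    S: AssignmentSet,
    ss: SecondaryStructureAnnotation,
    rng: Segment,
    methods: "list[str] | None" = None,
) -> str:
    """Plain-text track aligning elements and boundaries over a range.

    One ruler line, one secondary-structure line (H = helix, E = strand,
    untrimmed element spans), then one line per method with ``|`` at its
    boundary residues. Rendering deliberately uses the full element spans,
    not the end-trimmed spans of the statistics.
    """
    chain_lo = min((S[m].chain_extent.start for m in S.methods), default=1)
    chain_hi = max((S[m].chain_extent.end for m in S.methods), default=0)
    if rng.start < chain_lo or rng.end > chain_hi or rng.end < rng.start:
        raise ValueError(f"range {rng} outside chain extent {chain_lo}-{chain_hi}")
    cols = list(rng.residues())
    width = max(len(m) for m in (["SS", "ruler"] + S.methods)) + 2

    def ruler() -> str:
        marks = []
        for r in cols:
            marks.append("+" if r % 10 == 0 else ".")
        return f"{rng.start:>{width}} " + "".join(marks) + f" {rng.end}"

    ss_line = []
    for r in cols:
        char = "."
        for kind, el in ss.elements:
            if r in el:
                char = "H" if kind == "helix" else "E"
                break
        ss_line.append(char)
    lines = [ruler(), f"{'SS':>{width}} " + "".join(ss_line)]
    selected = methods if methods is not None else S.methods
    for m in selected:
        marks = {b.residue for b in extract_boundaries(S[m])}
        lines.append(
            f"{m:>{width}} " + "".join("|" if r in marks else "." for r in cols)
        )
    return "\n".join(lines)
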