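"""Core data model for multi-method protein domain assignments.

A protein chain is partitioned by each assignment method into *domains*;
a domain consists of one or more contiguous *fragments* (residue segments),
so discontinuous domains are representable. Residue coordinates are dense
1-based sequential indices within the chain — PDB author numbering with
insertion codes is mapped onto this coordinate at parse time (see
:mod:`domcons.formats`), because the agreement arithmetic downstream needs
an integer residue set.

Unassigned residues between domains are allowed (several methods leave
linkers unassigned); they belong to no domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Segment",
    "Domain",
    "ChainAssignment",
    "AssignmentSet",
    "SecondaryStructureAnnotation",
    "Parameters",
    "ConsensusGroup",
    "ConsensusResult",
    "StructureClass",
    "Violation",
    "ValidationError",
    "residue_set",
    "validate_assignment",
    "canonical_order",
    "HELIX_CODES",
    "STRAND_CODES",
    "DEFAULT_BASE_WEIGHTS",
    "DEFAULT_METHOD_ORDER",
]

log = logging.getLogger(__name__)

#: chains shorter than this trigger a warning (no hard minimum is enforced)
SHORT_CHAIN_WARNING_LENGTH = 40

#: DSSP codes counted as helix (alpha, 3-10, pi) and strand (extended sheet
#: only; the isolated bridge code B is not a sheet run).
HELIX_CODES = frozenset("HGI")
STRAND_CODES = frozenset("E")


@dataclass(frozen=True, order=True)
class Segment:
    """One contiguous residue range, inclusive at both ends (1-based)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def overlaps(self, other: "Segment") -> bool:
        return self.start <= other.end and other.start <= self.end

    def __contains__(self, residue: object) -> bool:
        return isinstance(residue, int) and self.start <= residue <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class Domain:
    """A domain: one or more ordered, non-overlapping fragments.

    Invariants are *checked* by :func:`validate_assignment`, not enforced at
    construction, so that malformed input files can be loaded, diagnosed and
    reported rather than crashing the loader.
    """

    domain_id: str
    fragments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragments", tuple(self.fragments))

    @property
    def start(self) -> int:
        """Start of the N-terminal fragment."""
        return min(f.start for f in self.fragments)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def is_fragmented(self) -> bool:
        return len(self.fragments) > 1

    @property
    def n_residues(self) -> int:
        return len(residue_set(self))


@dataclass(frozen=True)
class ChainAssignment:
    """One method's partition of one chain into domains."""

    pdb_id: str
    chain_id: str
    method: str
    domains: tuple[Domain, ...]
    chain_extent: Segment

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        if self.chain_extent.length < SHORT_CHAIN_WARNING_LENGTH:
            log.warning(
                "chain %s%s is only %d residues long",
                self.pdb_id,
                self.chain_id,
                self.chain_extent.length,
            )

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def has_fragmented_domain(self) -> bool:
        return any(d.is_fragmented for d in self.domains)

    def residue_set(self) -> set[int]:
        out: set[int] = set()
        for d in self.domains:
            out |= residue_set(d)
        return out


@dataclass
class AssignmentSet:
    """All methods' assignments of one chain, keyed by method name."""

    pdb_id: str
    chain_id: str
    assignments: dict[str, ChainAssignment]

    def __post_init__(self) -> None:
        for m, a in self.assignments.items():
            if (a.pdb_id, a.chain_id) != (self.pdb_id, self.chain_id):
                raise ValueError(
                    f"assignment for method {m!r} is for chain "
                    f"{a.pdb_id}{a.chain_id}, not {self.pdb_id}{self.chain_id}"
                )
            if a.method != m:
                raise ValueError(f"method key {m!r} != assignment.method {a.method!r}")

    @property
    def methods(self) -> list[str]:
        return list(self.assignments)

    @property
    def n_methods(self) -> int:
        return len(self.assignments)

    def __getitem__(self, method: str) -> ChainAssignment:
        return self.assignments[method]

    def __iter__(self) -> Iterator[str]:
        return iter(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class SecondaryStructureAnnotation:
    """Per-residue secondary-structure codes plus derived elements.

    ``codes`` maps sequential residue index -> one-letter DSSP code
    (H/G/I/E/B/T/S and ``-`` for loop). ``elements`` are the maximal helix
    (codes H/G/I) and strand (code E) runs, terminated at chain breaks.
    """

    codes: dict[int, str]
    elements: list[tuple[str, Segment]]
    #: sequential index -> original (author resseq, icode), when parsed from
    #: a DSSP file; retained for traceability of the renumbering.
    author_numbering: dict[int, tuple[int, str]] | None = None

    @classmethod
    def from_codes(
        cls,
        codes: "str | Mapping[int, str]",
        breaks: Iterable[int] = (),
        author_numbering: dict[int, tuple[int, str]] | None = None,
    ) -> "SecondaryStructureAnnotation":
        """Build an annotation from a code string or map.

        A string is interpreted as residues 1..len. ``breaks`` lists residue
        indices whose bond to the *preceding* residue is broken; elements do
        not span a break or a gap in the residue indices.
        """
        if isinstance(codes, str):
            code_map = {i + 1: (c if c != " " else "-") for i, c in enumerate(codes)}
        else:
            code_map = {int(i): (c if c != " " else "-") for i, c in dict(codes).items()}
        break_set = set(breaks)
        elements: list[tuple[str, Segment]] = []
        run_kind: str | None = None
        run_start = 0
        prev: int | None = None

        def close(end: int) -> None:
            nonlocal run_kind
            if run_kind is not None:
                elements.append((run_kind, Segment(run_start, end)))
                run_kind = None

        for idx in sorted(code_map):
            kind: str | None
            c = code_map[idx]
            if c in HELIX_CODES:
                kind = "helix"
            elif c in STRAND_CODES:
                kind = "strand"
            else:
                kind = None
            broken = prev is not None and (idx != prev + 1 or idx in break_set)
            if broken or kind != run_kind:
                if prev is not None:
                    close(prev)
                if kind is not None:
                    run_kind = kind
                    run_start = idx
            prev = idx
        if prev is not None:
            close(prev)
        return cls(codes=code_map, elements=elements, author_numbering=author_numbering)

    @property
    def n_residues(self) -> int:
        return len(self.codes)

    def elements_of(self, kind: str) -> list[Segment]:
        return [seg for k, seg in self.elements if k == kind]

    def code_string(self) -> str:
        """Codes as a string over the full residue range (gaps as ``!``)."""
        if not self.codes:
            return ""
        lo, hi = min(self.codes), max(self.codes)
        return "".join(self.codes.get(i, "!") for i in range(lo, hi + 1))


class StructureClass(Enum):
    """Coarse composition class of a chain's secondary structure."""

    ALL_ALPHA = "all_alpha"
    ALL_BETA = "all_beta"
    ALPHA_BETA = "alpha_beta"
    IRREGULAR = "irregular"


# Per-method prior success rates (percent correct domain counts on a balanced
# multi-domain benchmark); these seed the weighted consensus.
DEFAULT_BASE_WEIGHTS: dict[str, float] = {
    "PDP": 84.4,
    "NCBI": 81.9,
    "DomainParser2": 78.1,
    "DDomain": 76.5,
    "PUU": 74.0,
    "DHcL": 68.3,
    "Dodis": 40.0,
}

DEFAULT_METHOD_ORDER: tuple[str, ...] = (
    "PDP",
    "DomainParser2",
    "PUU",
    "DDomain",
    "NCBI",
    "DHcL",
    "Dodis",
)


@dataclass(frozen=True)
class Parameters:
    """All tunable thresholds and weights of the consensus procedure.

    overlap_threshold
        Fraction of residues of *each* partner that the intersection must
        cover for two compared domains/fragments to agree.
    consensus_threshold
        Minimum group reliability (percent) for a consensus to be declared.
    near_tie_window
        If the runner-up group's reliability is strictly closer than this to
        the top group's, both are reported as a tied consensus.
    helix_end_exclusion / strand_end_exclusion
        Number of residues at each element end where a boundary does not
        count as cutting the element.
    rule_adjustment
        Multiplicative step of the weighting rules: "reduced by 10%" means
        weight x (1 - rule_adjustment).
    base_weights
        Prior per-method weights (percent) for the weighted consensus.
    method_order
        Processing order for greedy grouping; methods absent from it are
        appended alphabetically.
    ss_class_minor_fraction
        Element-residue fraction below which a structure class ignores the
        minority element kind (e.g. a trace of helix in an all-beta chain).
    """

    overlap_threshold: float = 0.80
    consensus_threshold: float = 40.0
    near_tie_window: float = 10.0
    helix_end_exclusion: int = 2
    strand_end_exclusion: int = 1
    rule_adjustment: float = 0.10
    base_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_WEIGHTS)
    )
    method_order: tuple[str, ...] = DEFAULT_METHOD_ORDER
    ss_class_minor_fraction: float = 0.05
    #: use optimal (max-overlap) domain pairing instead of positional pairing
    optimal_domain_matching: bool = False
    #: also require the 80% rule per positionally matched fragment pair
    fragment_level_check: bool = True
    #: collapse boundaries of one method falling on the same residue
    dedupe_shared_boundaries: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.overlap_threshold <= 1):
            raise ValueError("overlap_threshold must be in (0, 1]")
        if not (0 <= self.consensus_threshold <= 100):
            raise ValueError("consensus_threshold must be in [0, 100]")
        if self.near_tie_window < 0:
            raise ValueError("near_tie_window must be >= 0")
        if self.helix_end_exclusion < 0 or self.strand_end_exclusion < 0:
            raise ValueError("end exclusions must be >= 0")
        for m, w in self.base_weights.items():
            if not (0 < w <= 100):
                raise ValueError(f"base weight for {m!r} must be in (0, 100]")
        object.__setattr__(self, "base_weights", dict(self.base_weights))
        object.__setattr__(self, "method_order", tuple(self.method_order))

    def replace(self, **kw) -> "Parameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            elif isinstance(v, Mapping):
                v = dict(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "Parameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path) -> "Parameters":
        """Load overrides from a YAML or JSON config file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a JSON superset
        if data is None:
            return cls()
        if not isinstance(data, Mapping):
            raise ValueError(f"config {path} must contain a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class ConsensusGroup:
    """A set of mutually agreeing methods with a reliability score.

    ``members`` are kept in join order; the first member founded the group
    and serves as its representative — the partition shown for the group is
    the representative's.
    """

    members: tuple[str, ...]
    representative: str
    reliability: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if self.representative not in self.members:
            raise ValueError("representative must be a member")
        if not (0 < self.reliability <= 100 + 1e-9):
            raise ValueError("reliability must be in (0, 100]")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusResult:
    """Outcome of a consensus run: groups, the reported consensus, status."""

    groups: list[ConsensusGroup]
    consensus: list[int]  # indices into groups; 0, 1 or 2 entries
    mode: str  # "simple" | "weighted"
    status: str  # "consensus" | "tied_consensus" | "no_consensus"
    parameters: Parameters = field(default_factory=Parameters)
    structure_class: StructureClass | None = None
    weights: "object | None" = None  # WeightVector for weighted mode
    flags: list[str] = field(default_factory=list)

    @property
    def consensus_groups(self) -> list[ConsensusGroup]:
        return [self.groups[i] for i in self.consensus]

    @property
    def top_reliability(self) -> float | None:
        return max((g.reliability for g in self.groups), default=None)


@dataclass(frozen=True)
class Violation:
    """One failed invariant found by :func:`validate_assignment`."""

    kind: str  # "empty" | "range" | "fragment_overlap" | "order" | "overlap" | "extent"
    message: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.message}"


class ValidationError(ValueError):
    """Raised by operations that require a valid assignment."""

    def __init__(self, assignment: ChainAssignment, violations: list[Violation]):
        self.violations = violations
        msg = "; ".join(str(v) for v in violations)
        super().__init__(
            f"invalid assignment ({assignment.method} on "
            f"{assignment.pdb_id}{assignment.chain_id}): {msg}"
        )


def residue_set(d: Domain) -> set[int]:
    """Union of a domain's fragment ranges, endpoints inclusive."""
    out: set[int] = set()
    for f in d.fragments:
        out.update(f.residues())
    return out


def validate_assignment(a: ChainAssignment) -> list[Violation]:
    """Check all invariants; return violations instead of raising.

    Checks, per domain: >=1 fragment, well-formed ranges (start >= 1,
    end >= start), fragments sorted and pairwise non-overlapping; across
    domains: pairwise residue-disjointness; globally: every residue within
    the chain extent, and >=1 domain.
    """
    v: list[Violation] = []
    if not a.domains:
        v.append(Violation("empty", "assignment has no domains"))
        return v
    ext = a.chain_extent
    if ext.end < ext.start or ext.start < 1:
        v.append(Violation("range", f"chain extent {ext} is malformed"))
    for d in a.domains:
        if not d.fragments:
            v.append(Violation("empty", f"domain {d.domain_id} has no fragments"))
            continue
        bad_range = False
        for f in d.fragments:
            if f.start < 1 or f.end < f.start:
                v.append(
                    Violation("range", f"domain {d.domain_id} fragment {f} is malformed")
                )
                bad_range = True
        if bad_range:
            continue
        starts = [f.start for f in d.fragments]
        if starts != sorted(starts):
            v.append(
                Violation("order", f"domain {d.domain_id} fragments not sorted by start")
            )
        by_start = sorted(d.fragments)
        for f1, f2 in zip(by_start, by_start[1:]):
            if f1.overlaps(f2):
                v.append(
                    Violation(
                        "fragment_overlap",
                        f"domain {d.domain_id} fragments {f1} and {f2} overlap",
                    )
                )
        for f in d.fragments:
            if f.start < ext.start or f.end > ext.end:
                v.append(
                    Violation(
                        "extent",
                        f"domain {d.domain_id} fragment {f} outside chain extent {ext}",
                    )
                )
    # cross-domain disjointness on residue sets
    seen: dict[int, str] = {}
    for d in a.domains:
        for f in d.fragments:
            if f.start < 1 or f.end < f.start:
                continue
            for r in f.residues():
                other = seen.get(r)
                if other is not None and other != d.domain_id:
                    v.append(
                        Violation(
                            "overlap",
                            f"domains {other} and {d.domain_id} share residue {r}",
                        )
                    )
                    break  # one violation per offending domain pair is enough
                seen.setdefault(r, d.domain_id)
    return v


def canonical_order(a: ChainAssignment) -> ChainAssignment:
    """Deterministic ordering: fragments by start within each domain, then
    domains by the start of their N-terminal fragment. Idempotent.

    Raises :class:`ValidationError` on an invalid assignment (downstream
    domain pairing relies on the invariants).
    """
    violations = [v for v in validate_assignment(a) if v.kind != "order"]
    if violations:  # ordering itself is what this function repairs
        raise ValidationError(a, violations)
    domains = tuple(
        sorted(
            (replace(d, fragments=tuple(sorted(d.fragments))) for d in a.domains),
            key=lambda d: d.fragments[0].start,
        )
    )
    starts = [d.fragments[0].start for d in domains]
    assert len(set(starts)) == len(starts), "disjoint domains cannot share a start"
    return replace(a, domains=domains)
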