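"""Synthetic multi-method assignment sets and secondary-structure strings.

Real inputs to the consensus are the outputs of several independent domain
assignment programs run on one chain. This module emulates that situation:
a planted "true" partition of a chain is perturbed independently per
method — boundary jitter, merging or splitting of adjacent domains, and
fragmentation — mimicking the over-cutting / under-cutting tendencies of
real methods. All randomness flows from explicit seeds; per-method streams
are derived by hashing (seed, method name) so results do not depend on
iteration order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    AssignmentSet,
    ChainAssignment,
    Domain,
    SecondaryStructureAnnotation,
    Segment,
    StructureClass,
    validate_assignment,
)

__all__ = [
    "PerturbationSpec",
    "generate_true_partition",
    "perturb",
    "generate_method_set",
    "generate_ss",
    "random_specs",
]

log = logging.getLogger(__name__)

MIN_DOMAIN_LENGTH = 20


def _substream(seed: int, *tokens: str) -> np.random.Generator:
    """Derive an independent RNG stream from a seed and string tokens."""
    h = hashlib.sha256(f"{seed}|{'|'.join(tokens)}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big") % (2**31))


@dataclass(frozen=True)
class PerturbationSpec:
    """How one simulated method deviates from the planted truth."""

    boundary_jitter: int = 0  # max shift of each inter-domain boundary, residues
    merge_prob: float = 0.0  # chance of merging one adjacent domain pair
    split_prob: float = 0.0  # chance of splitting one domain in two
    fragment_prob: float = 0.0  # chance of fragmenting one domain
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("merge_prob", "split_prob", "fragment_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be >= 0")


def generate_true_partition(
    length: int,
    n_domains: int,
    seed: int,
    pdb_id: str = "SYN1",
    chain_id: str = "A",
    method: str = "truth",
) -> ChainAssignment:
    """A contiguous, exhaustive random partition of residues 1..length.

    Domain lengths are 20 plus a random (multinomial) share of the excess,
    so every domain is at least 20 residues. Deterministic per seed.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    if length < MIN_DOMAIN_LENGTH * n_domains:
        raise ValueError(
            f"length {length} cannot hold {n_domains} domains of >= "
            f"{MIN_DOMAIN_LENGTH} residues"
        )
    rng = _substream(seed, "truth")
    extra = rng.multinomial(length - MIN_DOMAIN_LENGTH * n_domains,
                            [1.0 / n_domains] * n_domains)
    lengths = (MIN_DOMAIN_LENGTH + extra).tolist()
    domains = []
    pos = 1
    for i, ln in enumerate(lengths, start=1):
        domains.append(Domain(f"D{i}", (Segment(pos, pos + ln - 1),)))
        pos += ln
    return ChainAssignment(
        pdb_id=pdb_id,
        chain_id=chain_id,
        method=method,
        domains=tuple(domains),
        chain_extent=Segment(1, length),
    )


def _contiguous_spans(a: ChainAssignment) -> list[tuple[str, int, int]]:
    spans = []
    for d in a.domains:
        s = min(f.start for f in d.fragments)
        e = max(f.end for f in d.fragments)
        spans.append((d.domain_id, s, e))
    return sorted(spans, key=lambda t: t[1])


def _perturb_once(
    truth: ChainAssignment, spec: PerturbationSpec, rng: np.random.Generator
) -> ChainAssignment:
    spans = _contiguous_spans(truth)
    # jitter the internal boundaries of the contiguous tiling
    cuts = [e for _, _, e in spans[:-1]]
    if spec.boundary_jitter:
        cuts = [c + int(rng.integers(-spec.boundary_jitter, spec.boundary_jitter + 1))
                for c in cuts]
    lo = truth.chain_extent.start
    hi = truth.chain_extent.end
    edges = [lo - 1] + sorted(cuts) + [hi]
    segments = [Segment(a + 1, b) for a, b in zip(edges, edges[1:])]
    # each domain is one segment at this point
    domains: list[list[Segment]] = [[s] for s in segments]

    if len(domains) > 1 and rng.random() < spec.merge_prob:
        i = int(rng.integers(0, len(domains) - 1))
        domains[i] = domains[i] + domains.pop(i + 1)
        merged = Segment(domains[i][0].start, domains[i][-1].end)
        domains[i] = [merged]
    if rng.random() < spec.split_prob:
        i = int(rng.integers(0, len(domains)))
        seg = domains[i][0]
        if seg.length >= 2:
            at = int(rng.integers(seg.start, seg.end))  # split after `at`
            domains[i] = [Segment(seg.start, at)]
            domains.insert(i + 1, [Segment(at + 1, seg.end)])
    if rng.random() < spec.fragment_prob:
        i = int(rng.integers(0, len(domains)))
        seg = domains[i][0]
        if seg.length >= 9:
            third = seg.length // 3
            p1 = Segment(seg.start, seg.start + third - 1)
            p2 = Segment(seg.start + third, seg.end - third)
            p3 = Segment(seg.end - third + 1, seg.end)
            domains[i] = [p1, p3]  # the domain becomes two fragments
            # the carved-out middle goes to a neighbouring domain when one
            # exists, else those linker residues are left unassigned
            if len(domains) > 1:
                j = i - 1 if i > 0 else i + 1
                domains[j] = sorted(domains[j] + [p2])

    built = tuple(
        Domain(f"D{k}", tuple(sorted(frs))) for k, frs in enumerate(domains, start=1)
    )
    return ChainAssignment(
        pdb_id=truth.pdb_id,
        chain_id=truth.chain_id,
        method=truth.method,
        domains=built,
        chain_extent=truth.chain_extent,
    )


def perturb(
    truth: ChainAssignment, spec: PerturbationSpec, method_name: str
) -> ChainAssignment:
    """One method's view of the truth under a perturbation spec.

    Retries up to 100 times if a draw produces an invalid assignment
    (e.g. jitter collapsing a domain); falls back to the unperturbed truth
    with a warning if no valid draw is found.
    """
    from dataclasses import replace

    rng = _substream(spec.seed, "perturb", method_name)
    for _ in range(100):
        candidate = _perturb_once(truth, spec, rng)
        if not validate_assignment(candidate):
            return replace(candidate, method=method_name)
    log.warning(
        "no valid perturbation of %s%s found for %s in 100 attempts; "
        "returning the unperturbed truth",
        truth.pdb_id,
        truth.chain_id,
        method_name,
    )
    return replace(truth, method=method_name)


def generate_method_set(
    truth: ChainAssignment, specs: dict[str, PerturbationSpec]
) -> AssignmentSet:
    """One perturbed assignment per method; deterministic per (seed, method)."""
    if not specs:
        raise ValueError("specs must name at least one method")
    return AssignmentSet(
        pdb_id=truth.pdb_id,
        chain_id=truth.chain_id,
        assignments={m: perturb(truth, spec, m) for m, spec in specs.items()},
    )


def random_specs(
    methods: "list[str] | tuple[str, ...]",
    seed: int,
    max_jitter: int = 10,
    max_prob: float = 0.4,
) -> dict[str, PerturbationSpec]:
    """Randomized per-method perturbation specs for simulation studies."""
    out = {}
    for m in methods:
        rng = _substream(seed, "spec", m)
        out[m] = PerturbationSpec(
            boundary_jitter=int(rng.integers(0, max_jitter + 1)),
            merge_prob=float(rng.uniform(0, max_prob)),
            split_prob=float(rng.uniform(0, max_prob)),
            fragment_prob=float(rng.uniform(0, max_prob)),
            seed=seed,
        )
    return out


def generate_ss(
    length: int, cls: StructureClass, seed: int
) -> SecondaryStructureAnnotation:
    """A secondary-structure string whose classification round-trips to cls.

    Helix elements are 6-15 residues, strands 4-8, separated by 2-5 loop
    residues; element kinds alternate for the mixed class.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    rng = _substream(seed, "ss", cls.value)
    codes = ["-"] * length
    if cls is StructureClass.IRREGULAR:
        for i in range(length):
            codes[i] = str(rng.choice(["-", "T", "S"]))
        return SecondaryStructureAnnotation.from_codes("".join(codes))

    pos = 0
    toggle = 0
    while pos < length - 4:
        pos += int(rng.integers(2, 6))  # loop
        if cls is StructureClass.ALL_ALPHA:
            kind = "H"
        elif cls is StructureClass.ALL_BETA:
            kind = "E"
        else:
            kind = "H" if toggle % 2 == 0 else "E"
            toggle += 1
        ln = int(rng.integers(6, 16)) if kind == "H" else int(rng.integers(4, 9))
        end = min(pos + ln, length)
        for i in range(pos, end):
            codes[i] = kind
        pos = end
    ann = SecondaryStructureAnnotation.from_codes("".join(codes))
    # guarantee feasibility for very short chains: rebuild deterministically
    # if the random draw missed a required element kind
    n_h = sum(s.length for s in ann.elements_of("helix"))
    n_e = sum(s.length for s in ann.elements_of("strand"))
    needs_h = cls in (StructureClass.ALL_ALPHA, StructureClass.ALPHA_BETA)
    needs_e = cls in (StructureClass.ALL_BETA, StructureClass.ALPHA_BETA)
    if (needs_h and n_h == 0) or (needs_e and n_e == 0):
        codes = ["-"] * length
        half = length // 2
        if needs_h:
            for i in range(min(4, half)):
                codes[i] = "H"
        if needs_e:
            for i in range(half, min(half + 4, length)):
                codes[i] = "E"
        ann = SecondaryStructureAnnotation.from_codes("".join(codes))
    return ann
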