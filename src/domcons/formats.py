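"""File formats: native assignment TSV/JSON, CATH Domall, DSSP, reports.

Native assignment TSV dialect: tab-separated, UTF-8, ``#`` comment lines,
required header ``pdb_id  chain_id  method  domain_id  start  end``, one
domain fragment per row. The JSON flavour carries the same rows under an
``assignments`` key. Rows sharing (pdb_id, chain_id, method, domain_id)
form one domain; rows sharing (pdb_id, chain_id) form one chain.

CATH Domall (CDDF v3.x) is read-only: each record lists a chain's domain
count, unassigned-fragment count, and per-domain segments with author
numbering and insertion-code columns. DSSP classic text output is parsed
through Biopython; residues are renumbered to dense sequential indices in
file order (the author-numbering map is retained on the annotation).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    AssignmentSet,
    ChainAssignment,
    ConsensusResult,
    Domain,
    SecondaryStructureAnnotation,
    Segment,
    validate_assignment,
)

__all__ = [
    "ParseError",
    "AssignmentTable",
    "read_assignments",
    "write_assignments",
    "read_cath_domall",
    "read_dssp",
    "write_dssp",
    "write_consensus_report",
    "read_consensus_report",
]

TSV_COLUMNS = ("pdb_id", "chain_id", "method", "domain_id", "start", "end")


class ParseError(ValueError):
    """A malformed input file; carries the file path and line number."""

    def __init__(self, path, line: "int | None", message: str):
        self.path = str(path)
        self.line = line
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")


@dataclass
class AssignmentTable:
    """Flat fragment-per-row view of assignments (the exchange format)."""

    rows: list[tuple[str, str, str, str, int, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(TSV_COLUMNS))

    @classmethod
    def from_sets(cls, sets: Iterable[AssignmentSet]) -> "AssignmentTable":
        rows = []
        for S in sets:
            for m in S.methods:
                a = S[m]
                for d in a.domains:
                    for f in d.fragments:
                        rows.append(
                            (a.pdb_id, a.chain_id, m, d.domain_id, f.start, f.end)
                        )
        return cls(rows)

    def to_sets(self, validate: bool = True) -> dict[tuple[str, str], AssignmentSet]:
        """Group rows into per-chain AssignmentSets (insertion order kept).

        The chain extent of every method on a chain is the min/max residue
        over *all* methods for that chain, so extents are comparable.
        """
        chains: dict[tuple[str, str], dict[str, dict[str, list[Segment]]]] = {}
        for pdb_id, chain_id, method, domain_id, start, end in self.rows:
            chains.setdefault((pdb_id, chain_id), {}).setdefault(method, {}).setdefault(
                domain_id, []
            ).append(Segment(int(start), int(end)))
        out: dict[tuple[str, str], AssignmentSet] = {}
        for (pdb_id, chain_id), methods in chains.items():
            lo = min(f.start for doms in methods.values() for frs in doms.values() for f in frs)
            hi = max(f.end for doms in methods.values() for frs in doms.values() for f in frs)
            assignments = {}
            for method, doms in methods.items():
                domains = tuple(
                    Domain(did, tuple(sorted(frs))) for did, frs in doms.items()
                )
                a = ChainAssignment(
                    pdb_id=pdb_id,
                    chain_id=chain_id,
                    method=method,
                    domains=domains,
                    chain_extent=Segment(lo, hi),
                )
                if validate:
                    violations = validate_assignment(a)
                    if violations:
                        detail = "; ".join(str(v) for v in violations)
                        raise ValueError(
                            f"invalid assignment for method {method!r} on chain "
                            f"{pdb_id}{chain_id}: {detail}"
                        )
                assignments[method] = a
            out[(pdb_id, chain_id)] = AssignmentSet(pdb_id, chain_id, assignments)
        return out


def _read_table_tsv(path) -> AssignmentTable:
    rows = []
    header: list[str] | None = None
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not raw or (raw[0].startswith("#")) or all(not c.strip() for c in raw):
                continue
            if header is None:
                header = [c.strip() for c in raw]
                if tuple(header) != TSV_COLUMNS:
                    raise ParseError(
                        path, lineno,
                        f"expected header {list(TSV_COLUMNS)}, got {header}",
                    )
                continue
            if len(raw) != len(TSV_COLUMNS):
                raise ParseError(
                    path, lineno, f"expected {len(TSV_COLUMNS)} fields, got {len(raw)}"
                )
            pdb_id, chain_id, method, domain_id, start_s, end_s = (c.strip() for c in raw)
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer residue range "
                                               f"{start_s!r}-{end_s!r}") from None
            if start < 1 or end < start:
                raise ParseError(path, lineno, f"malformed residue range {start}-{end}")
            rows.append((pdb_id, chain_id, method, domain_id, start, end))
    if header is None:
        raise ParseError(path, None, "missing header row")
    return AssignmentTable(rows)


def _read_table_json(path) -> AssignmentTable:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, Mapping) or "assignments" not in data:
        raise ParseError(path, None, "expected an object with an 'assignments' list")
    rows = []
    for i, rec in enumerate(data["assignments"]):
        try:
            row = tuple(rec[k] for k in TSV_COLUMNS)
        except (KeyError, TypeError):
            raise ParseError(path, None, f"record {i} missing required keys") from None
        start, end = int(row[4]), int(row[5])
        if start < 1 or end < start:
            raise ParseError(path, None, f"record {i}: malformed range {start}-{end}")
        rows.append((str(row[0]), str(row[1]), str(row[2]), str(row[3]), start, end))
    return AssignmentTable(rows)


def read_assignments(
    path, format: str = "tsv", validate: bool = True
) -> dict[tuple[str, str], AssignmentSet]:
    """Read a native TSV/JSON assignment file into per-chain sets."""
    if format == "tsv":
        table = _read_table_tsv(path)
    elif format == "json":
        table = _read_table_json(path)
    elif format == "domall":
        table = read_cath_domall(path)
    else:
        raise ValueError(f"unknown assignment format {format!r}")
    return table.to_sets(validate=validate)


def write_assignments(sets: "Iterable[AssignmentSet] | AssignmentSet",
                      path, format: str = "tsv") -> None:
    """Write assignment sets in the native TSV or JSON dialect."""
    if isinstance(sets, AssignmentSet):
        sets = [sets]
    table = AssignmentTable.from_sets(sets)
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(TSV_COLUMNS)
            w.writerows(table.rows)
    elif format == "json":
        recs = [dict(zip(TSV_COLUMNS, row)) for row in table.rows]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"assignments": recs}, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown assignment format {format!r}")


# --------------------------------------------------------------------------
# CATH Domall


def read_cath_domall(path) -> AssignmentTable:
    """Read a CATH Domall (CDDF) file as assignments of method "CATH".

    Record layout (whitespace-tokenized): a 5-character chain name
    (pdb id + chain letter), ``Dnn`` domain count, ``Fnn`` count of
    unassigned fragments, then for each domain a segment count followed by
     6 tokens per segment (chain, start, insertion code, chain, end,
    insertion code; ``-`` = no insertion code). Trailing unassigned
    fragments are skipped. Author residue numbers are used as the
    sequential coordinate; insertion-coded endpoints are accepted but the
    numeric part is used.
    """
    rows: list[tuple[str, str, str, str, int, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            try:
                name = tok[0]
                if len(name) != 5 or not tok[1].startswith("D") or not tok[2].startswith("F"):
                    raise ValueError("record must start with <pdb+chain> Dnn Fnn")
                pdb_id, chain_id = name[:4], name[4]
                n_dom = int(tok[1][1:])
                i = 3
                for d in range(1, n_dom + 1):
                    n_seg = int(tok[i]); i += 1
                    if n_seg < 1:
                        raise ValueError(f"domain {d} has segment count {n_seg}")
                    for _ in range(n_seg):
                        c1, start_s, _ic1, c2, end_s, _ic2 = tok[i : i + 6]
                        i += 6
                        if c1 != chain_id or c2 != chain_id:
                            raise ValueError(
                                f"segment chain {c1}/{c2} does not match record "
                                f"chain {chain_id}"
                            )
                        rows.append(
                            (pdb_id, chain_id, "CATH", f"D{d:02d}",
                             int(start_s), int(end_s))
                        )
            except (IndexError, ValueError) as exc:
                raise ParseError(path, lineno, f"unrecognized Domall record: {exc}") from None
    return AssignmentTable(rows)


# --------------------------------------------------------------------------
# DSSP


def read_dssp(path) -> dict[str, SecondaryStructureAnnotation]:
    """Parse classic DSSP text output into per-chain annotations.

    Residues are renumbered 1..n per chain in file order; blank SS columns
    become ``-``; gaps in the DSSP running index (chain-break ``!`` rows)
    terminate secondary-structure elements.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    try:
        dssp, keys = make_dssp_dict(str(path))
    except Exception as exc:
        raise ParseError(path, None, f"not parseable as DSSP: {exc}") from None
    if not keys:
        raise ParseError(path, None, "no residue records found")
    per_chain: dict[str, list[tuple[str, int, int, str]]] = {}
    for chain_id, res_id in keys:
        aa_ss = dssp[(chain_id, res_id)]
        ss = aa_ss[1]
        dssp_index = aa_ss[5]
        _, resseq, icode = res_id
        per_chain.setdefault(chain_id, []).append((ss, dssp_index, resseq, icode))
    out: dict[str, SecondaryStructureAnnotation] = {}
    for chain_id, recs in per_chain.items():
        codes: dict[int, str] = {}
        breaks: set[int] = set()
        numbering: dict[int, tuple[int, str]] = {}
        prev_index: int | None = None
        for i, (ss, dssp_index, resseq, icode) in enumerate(recs, start=1):
            codes[i] = ss if ss != " " else "-"
            numbering[i] = (resseq, icode.strip())
            if prev_index is not None and dssp_index != prev_index + 1:
                breaks.add(i)
            prev_index = dssp_index
        out[chain_id] = SecondaryStructureAnnotation.from_codes(
            codes, breaks=breaks, author_numbering=numbering
        )
    return out


_DSSP_HEADER = (
    "==== Secondary Structure Definition, sequential renumbering ====\n"
    "REFERENCE   synthetic fixture in classic DSSP layout\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
    "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA\n"
)


def write_dssp(
    codes: "str | Mapping[int, str]",
    path,
    chain_id: str = "A",
    breaks: Iterable[int] = (),
) -> None:
    """Write a minimal classic-layout DSSP file for one chain.

    Only the columns the reader consumes are meaningful (index, residue
    number, chain, SS code); hydrogen-bond/angle columns are zero-filled.
    ``breaks`` lists residue indices preceded by a chain break; a ``!``
    divider row is emitted there, as real DSSP output does.
    """
    if isinstance(codes, str):
        code_map = {i + 1: c for i, c in enumerate(codes)}
    else:
        code_map = {int(i): str(c) for i, c in codes.items()}
    break_set = set(breaks)
    lines = [_DSSP_HEADER]
    idx = 0
    hb = f"{0:7d},{0.0:4.1f}" + (f"{0:6d},{0.0:4.1f}" * 3)
    for resseq in sorted(code_map):
        if resseq in break_set:
            idx += 1
            lines.append(f"{idx:5d}        !              \n")
        idx += 1
        ss = code_map[resseq]
        if ss in ("-", ""):
            ss = " "
        line = f"{idx:5d}{resseq:5d} {chain_id} A  {ss} "
        line = line.ljust(34) + f"{0:4d}" + hb
        line = line.ljust(103) + f"{360.0:6.1f}{360.0:6.1f}"
        lines.append(line + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(lines)


# --------------------------------------------------------------------------
# Consensus reports


def _result_to_dict(result: ConsensusResult, S: AssignmentSet) -> dict:
    groups = []
    for g in result.groups:
        rep = S[g.representative]
        groups.append(
            {
                "members": list(g.members),
                "representative": g.representative,
                "reliability": round(g.reliability, 6),
                "domains": [
                    {
                        "id": d.domain_id,
                        "fragments": [[f.start, f.end] for f in d.fragments],
                    }
                    for d in rep.domains
                ],
            }
        )
    doc = {
        "pdb_id": S.pdb_id,
        "chain_id": S.chain_id,
        "mode": result.mode,
        "parameters": result.parameters.to_dict(),
        "groups": groups,
        "consensus": list(result.consensus),
        "status": result.status,
    }
    if result.flags:
        doc["flags"] = list(result.flags)
    if result.structure_class is not None:
        doc["structure_class"] = result.structure_class.value
    if result.weights is not None:
        doc["weights"] = {m: round(w, 6) for m, w in result.weights.weights.items()}
        doc["weight_rules"] = {
            m: rules for m, rules in result.weights.provenance.items() if rules
        }
    return doc


def format_consensus_text(result: ConsensusResult, S: AssignmentSet) -> str:
    """Human-readable consensus report (the CLI's default rendering)."""
    lines = [
        f"Chain {S.pdb_id}{S.chain_id} — {result.mode} consensus: {result.status}",
    ]
    if result.structure_class is not None:
        lines.append(f"Structure class: {result.structure_class.value}")
    for i, g in enumerate(result.groups):
        marker = "*" if i in result.consensus else " "
        rep = S[g.representative]
        doms = "; ".join(
            f"{d.domain_id}:" + ",".join(str(f) for f in d.fragments)
            for d in rep.domains
        )
        lines.append(
            f" {marker} group {i + 1} [{g.reliability:5.1f}%] "
            f"members={','.join(g.members)} rep={g.representative} domains {doms}"
        )
    for flag in result.flags:
        lines.append(f"note: {flag}")
    return "\n".join(lines)


def write_consensus_report(
    result: ConsensusResult, assignments: AssignmentSet, path, format: str = "json"
) -> None:
    """Write a consensus report as JSON (lossless), TSV, or plain text."""
    doc = _result_to_dict(result, assignments)
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    elif format == "tsv":
        rows = []
        for i, g in enumerate(doc["groups"]):
            rows.append(
                {
                    "pdb_id": doc["pdb_id"],
                    "chain_id": doc["chain_id"],
                    "mode": doc["mode"],
                    "status": doc["status"],
                    "group": i + 1,
                    "in_consensus": i in doc["consensus"],
                    "reliability": g["reliability"],
                    "representative": g["representative"],
                    "members": ",".join(g["members"]),
                    "domains": ";".join(
                        d["id"] + ":" + ",".join(f"{s}-{e}" for s, e in d["fragments"])
                        for d in g["domains"]
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif format == "text":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(format_consensus_text(result, assignments) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_consensus_report(path) -> dict:
    """Read back a JSON consensus report (round-trips losslessly)."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
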