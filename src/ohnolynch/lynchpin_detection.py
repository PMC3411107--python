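"""Lynchpin conservation calling from family alignments.

A *lynchpin* is a 14-3-3-binding phosphosite that is conserved (as Ser or
Thr) across every member of a vertebrate ohnologue family and aligns with a
Ser/Thr residue in at least one pro-orthologue from the invertebrate
chordates (amphioxus, tunicates). Each candidate site receives a 3-state
verdict:

* ``lynchpin``   — all covered members S/T at the column and ≥1 covered
  outgroup S/T;
* ``divergent``  — the column is covered but the S/T pattern fails;
* ``unassignable`` — a member row or all outgroup rows lack coverage at the
  column. Coverage means the column falls inside the row's leading/trailing
  gap runs — invertebrate database sequences are frequently incomplete, and
  truncation must not be confused with substitution. Internal gaps count as
  non-S/T residues (divergent), not missing coverage.

The pipeline consumes externally produced alignments; the pairwise global
aligner here exists so that fixtures need no external alignment tool and is
never silently substituted for a real multiple alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tabular_io import DataError, Msa, PhosphositeRecord

# ---------------------------------------------------------------------------
# Pairwise global alignment (fixture plumbing)
# ---------------------------------------------------------------------------

#: traceback states: diagonal (match), up (gap in b), left (gap in a)
MOVES = ("diagonal", "up", "left")


@dataclass(frozen=True)
class AlignParams:
    """Scoring for the internal Needleman–Wunsch aligner.

    A gap of length L costs ``gap_open + L * gap_extend``. ``matrix`` is
    either "identity" (uses match/mismatch) or a Biopython substitution
    matrix name such as "BLOSUM62". ``tie_break`` fixes the traceback
    preference order over {diagonal, up, left}, making alignments (not just
    scores) deterministic.
    """

    matrix: str = "identity"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 2.0
    gap_extend: float = 0.5
    tie_break: tuple[str, str, str] = MOVES

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise DataError("gap penalties must be ≥ 0")
        if sorted(self.tie_break) != sorted(MOVES):
            raise DataError(f"tie_break must permute {MOVES}")

    def score(self, x: str, y: str) -> float:
        if self.matrix == "identity":
            return self.match if x == y else self.mismatch
        from Bio.Align import substitution_matrices

        return float(substitution_matrices.load(self.matrix)[x, y])


def _score_fn(p: AlignParams):
    if p.matrix == "identity":
        return lambda x, y: p.match if x == y else p.mismatch
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(p.matrix)
    return lambda x, y: float(mat[x, y])


def needleman_wunsch(
    a: str, b: str, p: AlignParams = AlignParams()
) -> tuple[str, str, float]:
    """Global pairwise alignment with affine gap penalties.

    Returns ``(aligned_a, aligned_b, score)``; the score is the dynamic
    programming optimum and the traceback is deterministic under
    ``p.tie_break``.
    """
    if not a or not b:
        raise DataError("both sequences must be non-empty")
    s = _score_fn(p)
    go, ge = p.gap_open, p.gap_extend
    la, lb = len(a), len(b)
    NEG = -np.inf
    # M: a[i] aligned to b[j]; X: gap in b (consume a); Y: gap in a (consume b)
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -(go + ge * i)
    for j in range(1, lb + 1):
        Y[0, j] = -(go + ge * j)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i, j] = s(a[i - 1], b[j - 1]) + max(
                M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            )
            X[i, j] = max(
                M[i - 1, j] - (go + ge),
                X[i - 1, j] - ge,
                Y[i - 1, j] - (go + ge),
            )
            Y[i, j] = max(
                M[i, j - 1] - (go + ge),
                X[i, j - 1] - (go + ge),
                Y[i, j - 1] - ge,
            )
    state_of_move = {"diagonal": "M", "up": "X", "left": "Y"}
    order = [state_of_move[m] for m in p.tie_break]
    tables = {"M": M, "X": X, "Y": Y}
    score = max(M[la, lb], X[la, lb], Y[la, lb])
    state = next(st for st in order if tables[st][la, lb] == score)

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - s(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            cand = {
                "M": M[i, j],
                "X": X[i, j],
                "Y": Y[i, j],
            }
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            cand = {
                "M": M[i - 1, j] - (go + ge),
                "X": X[i - 1, j] - ge,
                "Y": Y[i - 1, j] - (go + ge),
            }
            target = X[i, j]
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            cand = {
                "M": M[i, j - 1] - (go + ge),
                "X": X[i, j - 1] - (go + ge),
                "Y": Y[i, j - 1] - ge,
            }
            target = Y[i, j]
            j -= 1
        if i == 0 and j == 0:
            break
        state = next(
            st
            for st in order
            if np.isclose(cand[st], target, rtol=0, atol=1e-9)
            and np.isfinite(cand[st])
        )
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


# ---------------------------------------------------------------------------
# Site ↔ column mapping
# ---------------------------------------------------------------------------


def map_site_to_column(msa: Msa, seq_id: str, pos: int) -> int:
    """1-based alignment column holding ungapped position ``pos`` of a row."""
    if seq_id not in msa.rows:
        raise DataError(f"{seq_id!r} not in alignment")
    row = msa.rows[seq_id]
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            count += 1
            if count == pos:
                return col
    raise DataError(
        f"position {pos} beyond ungapped length {count} of row {seq_id!r}"
    )


def column_to_site(msa: Msa, seq_id: str, column: int) -> int | None:
    """Inverse of :func:`map_site_to_column`; None when the column is a gap."""
    row = msa.rows[seq_id]
    if not (1 <= column <= len(row)):
        raise DataError(f"column {column} out of range")
    if row[column - 1] == "-":
        return None
    return len(row[:column].replace("-", ""))


# ---------------------------------------------------------------------------
# Lynchpin calling
# ---------------------------------------------------------------------------

STATUSES = ("lynchpin", "divergent", "unassignable")
NO_COVERAGE = "no-coverage"


@dataclass(frozen=True)
class LynchpinCall:
    family_id: str
    reference_site: tuple[str, int]
    status: str
    member_residues: dict[str, str]
    outgroup_residues: dict[str, str]
    reason: str = ""


@dataclass(frozen=True)
class LynchpinSummary:
    n_sites_evaluated: int
    n_lynchpins: int
    n_families_with_lynchpin: int
    n_unassignable: int


def _covered(row: str, column: int) -> bool:
    """True when the column lies inside the row's sequenced span.

    Leading/trailing gap runs model truncated (incomplete) sequences; a
    column inside them carries no evidence either way.
    """
    if not row.strip("-"):
        return False
    first = len(row) - len(row.lstrip("-"))
    last = len(row.rstrip("-")) - 1
    return first <= column - 1 <= last


def call_lynchpin(
    msa: Msa,
    members: Iterable[str],
    outgroups: Iterable[str],
    site: tuple[str, int],
    family_id: str = "",
    require_all_outgroups: bool = False,
) -> LynchpinCall:
    """3-state conservation verdict for one candidate site.

    Decision rule: (1) any member without coverage at the column, or all
    outgroups without coverage → unassignable; (2) else every member residue
    ∈ {S,T} and ≥1 covered outgroup residue ∈ {S,T} (all covered outgroups
    when ``require_all_outgroups``) → lynchpin; (3) else divergent.
    """
    members, outgroups = sorted(set(members)), sorted(set(outgroups))
    seq_id, pos = site
    if seq_id not in members:
        raise DataError(f"site sequence {seq_id!r} is not a member")
    if len(members) < 2:
        raise DataError("need ≥ 2 family members")
    if len(outgroups) < 1:
        raise DataError("need ≥ 1 outgroup")
    missing = [s for s in (*members, *outgroups) if s not in msa.rows]
    if missing:
        raise DataError(f"rows missing from alignment: {missing}")

    col = map_site_to_column(msa, seq_id, pos)

    def residue_at(sid: str) -> str:
        row = msa.rows[sid]
        return row[col - 1] if _covered(row, col) else NO_COVERAGE

    member_res = {sid: residue_at(sid) for sid in members}
    outgroup_res = {sid: residue_at(sid) for sid in outgroups}

    member_gap = [sid for sid, r in member_res.items() if r == NO_COVERAGE]
    covered_out = {s: r for s, r in outgroup_res.items() if r != NO_COVERAGE}
    if member_gap or not covered_out:
        reason = "member-truncated" if member_gap else "outgroups-truncated"
        status = "unassignable"
    else:
        members_st = all(r in ("S", "T") for r in member_res.values())
        if require_all_outgroups:
            out_ok = (
                len(covered_out) == len(outgroup_res)
                and all(r in ("S", "T") for r in covered_out.values())
            )
        else:
            out_ok = any(r in ("S", "T") for r in covered_out.values())
        status = "lynchpin" if members_st and out_ok else "divergent"
        reason = ""
    return LynchpinCall(
        family_id=family_id,
        reference_site=site,
        status=status,
        member_residues=member_res,
        outgroup_residues=outgroup_res,
        reason=reason,
    )


def scan_families(
    alignments: Mapping[str, Msa],
    sites: Sequence[PhosphositeRecord],
    roles: Mapping[str, Mapping[str, str]],
    tiers: tuple[str, ...] = ("gold",),
    require_all_outgroups: bool = False,
) -> tuple[list[LynchpinCall], LynchpinSummary]:
    """Call every candidate site across its family alignment.

    ``alignments`` maps family_id → Msa and ``roles`` maps family_id →
    {seq_id: "member"|"outgroup"}. A site whose protein appears in no
    alignment is recorded as unassignable with reason "no-alignment"; a
    protein appearing as member in two alignments is a hard error.
    """
    protein_to_family: dict[str, str] = {}
    for fid in sorted(alignments):
        for sid, role in roles[fid].items():
            if role == "member":
                if sid in protein_to_family:
                    raise DataError(f"{sid!r} is a member in two alignments")
                protein_to_family[sid] = fid

    calls: list[LynchpinCall] = []
    for s in sites:
        if s.tier not in tiers:
            continue
        fid = protein_to_family.get(s.protein_acc)
        if fid is None:
            calls.append(
                LynchpinCall(
                    family_id="",
                    reference_site=(s.protein_acc, s.position),
                    status="unassignable",
                    member_residues={},
                    outgroup_residues={},
                    reason="no-alignment",
                )
            )
            continue
        msa = alignments[fid]
        members = [sid for sid, r in roles[fid].items() if r == "member"]
        outgroups = [sid for sid, r in roles[fid].items() if r == "outgroup"]
        calls.append(
            call_lynchpin(
                msa,
                members,
                outgroups,
                (s.protein_acc, s.position),
                family_id=fid,
                require_all_outgroups=require_all_outgroups,
            )
        )
    calls.sort(key=lambda c: (c.family_id, c.reference_site[0], c.reference_site[1]))
    lynchpins = [c for c in calls if c.status == "lynchpin"]
    summary = LynchpinSummary(
        n_sites_evaluated=len(calls),
        n_lynchpins=len(lynchpins),
        n_families_with_lynchpin=len({c.family_id for c in lynchpins}),
        n_unassignable=sum(1 for c in calls if c.status == "unassignable"),
    )
    return calls, summary


def write_calls(calls: Sequence[LynchpinCall], path) -> None:
    rows = []
    for c in calls:
        rows.append(
            (
                c.family_id,
                c.reference_site[0],
                c.reference_site[1],
                c.status,
                c.reason,
                ";".join(f"{k}={v}" for k, v in sorted(c.member_residues.items())),
                ";".join(f"{k}={v}" for k, v in sorted(c.outgroup_residues.items())),
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "protein_acc",
            "position",
            "status",
            "reason",
            "member_residues",
            "outgroup_residues",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_roles(path) -> dict[str, dict[str, str]]:
    """Read a roles TSV (family_id, seq_id, role ∈ {member, outgroup})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("family_id", "seq_id", "role"):
        if col not in df.columns:
            raise DataError(f"roles table lacks column {col!r}")
    roles: dict[str, dict[str, str]] = {}
    for fid, sid, role in zip(df["family_id"], df["seq_id"], df["role"]):
        if role not in ("member", "outgroup"):
            raise DataError(f"unknown role {role!r} for {sid!r}")
        roles.setdefault(str(fid), {})[str(sid)] = str(role)
    return roles


def write_roles(roles: Mapping[str, Mapping[str, str]], path) -> None:
    rows = [
        (fid, sid, role)
        for fid in sorted(roles)
        for sid, role in sorted(roles[fid].items())
    ]
    pd.DataFrame(rows, columns=["family_id", "seq_id", "role"]).to_csv(
        path, sep="\t", index=False
    )
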