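"""Sequence-level screening of DYW deaminase domains.

Canonical DYW domains end in an Asp-x-Trp triplet (DYW, or variants such as
DLW/DNW), carry the cytidine-deaminase zinc-site signatures H-x-E and
C-x-x-C, and contain a "gating" glutamate that completes the catalytic
zinc's coordination sphere via a bound water.  The screen reports the
terminal triplet, signature motif positions, and the residue the query
carries at the gating column, located by global alignment to a reference
domain.
"""

from __future__ import annotations

import re
import tomllib
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

HXE = re.compile(r"(?=H.E)")
CXXC = re.compile(r"(?=C..C)")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentResult:
    """Global alignment with affine gaps; a gap of length k costs
    gap_open + k*gap_extend."""

    aligned_query: str
    aligned_ref: str
    score: float
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class DomainReport:
    protein_name: str
    terminal_triplet: str
    has_DxW: bool
    hxe_positions: tuple[int, ...]
    cxxc_positions: tuple[int, ...]
    gating_residue: str | None
    gating_position: int | None


def terminal_triplet(seq: str) -> tuple[str, bool]:
    """Last three residues and whether they match D-x-W (any middle residue)."""
    seq = seq.strip().upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 residues")
    triplet = seq[-3:]
    return triplet, triplet[0] == "D" and triplet[2] == "W"


def zinc_motif_scan(seq: str) -> tuple[list[int], list[int]]:
    """0-based start positions of all H-x-E and C-x-x-C matches
    (overlaps included)."""
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    hxe = [m.start() for m in HXE.finditer(seq)]
    cxxc = [m.start() for m in CXXC.finditer(seq)]
    return hxe, cxxc


def global_align(
    query: str,
    reference: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignmentResult:
    """Needleman–Wunsch/Gotoh global alignment with affine gap penalties.

    Traceback ties break deterministically: diagonal over up (gap in
    reference) over left (gap in query).
    """
    q, r = query.strip().upper(), reference.strip().upper()
    if not q or not r:
        raise AlignmentError("empty input sequence")
    n, m = len(q), len(r)
    NEG = float("-inf")
    first = gap_open + gap_extend  # cost of the first residue of a gap

    # M: q[i] aligned to r[j]; X: gap in reference (consumes q, "up");
    # Y: gap in query (consumes r, "left").  Adjacent gaps in opposite
    # sequences are permitted (full Gotoh recursion).
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        qi = q[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = match if qi == r[j - 1] else mismatch
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] + first, Xp[j] + gap_extend, Yp[j] + first)
            Yi[j] = max(Mi[j - 1] + first, Xi[j - 1] + first, Yi[j - 1] + gap_extend)

    def pick(candidates: list[tuple[str, float]], target: float) -> str:
        # tie preference: diagonal (M) > up (X) > left (Y)
        for st, val in candidates:
            if val == target:
                return st
        raise AlignmentError("traceback inconsistency")  # pragma: no cover

    i, j = n, m
    best = max(M[n][m], X[n][m], Y[n][m])
    state = pick([("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m])], best)
    aq: list[str] = []
    ar: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            aq.append(q[i - 1])
            ar.append(r[j - 1])
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            state = pick(
                [("M", M[i - 1][j - 1]), ("X", X[i - 1][j - 1]), ("Y", Y[i - 1][j - 1])],
                prev,
            )
            i, j = i - 1, j - 1
        elif state == "X":
            aq.append(q[i - 1])
            ar.append("-")
            if i == 1 and j == 0:
                state = "M"  # boundary origin
                i -= 1
                continue
            state = pick(
                [
                    ("M", M[i - 1][j] + first),
                    ("X", X[i - 1][j] + gap_extend),
                    ("Y", Y[i - 1][j] + first),
                ],
                X[i][j],
            )
            i -= 1
        else:
            aq.append("-")
            ar.append(r[j - 1])
            if i == 0 and j == 1:
                state = "M"
                j -= 1
                continue
            state = pick(
                [
                    ("M", M[i][j - 1] + first),
                    ("X", X[i][j - 1] + first),
                    ("Y", Y[i][j - 1] + gap_extend),
                ],
                Y[i][j],
            )
            j -= 1
    return AlignmentResult(
        aligned_query="".join(reversed(aq)),
        aligned_ref="".join(reversed(ar)),
        score=float(best),
        match=match,
        mismatch=mismatch,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def gating_residue(
    query: str,
    reference: str,
    ref_gating_position: int,
    **align_kwargs: float,
) -> tuple[str | None, int | None]:
    """Residue of ``query`` aligned to the reference gating column.

    ``ref_gating_position`` is 0-based in the ungapped reference.  Returns
    ``(None, None)`` when the query has a gap at that column.
    """
    reference = reference.strip().upper()
    if not 0 <= ref_gating_position < len(reference):
        raise AlignmentError(
            f"ref_gating_position {ref_gating_position} outside reference "
            f"(length {len(reference)})"
        )
    aln = global_align(query, reference, **align_kwargs)
    ref_idx = -1
    for col, (qc, rc) in enumerate(zip(aln.aligned_query, aln.aligned_ref)):
        if rc != "-":
            ref_idx += 1
            if ref_idx == ref_gating_position:
                if qc == "-":
                    return None, None
                qpos = sum(1 for c in aln.aligned_query[: col + 1] if c != "-") - 1
                return qc, qpos
    raise AlignmentError("gating column not found in alignment")  # pragma: no cover


def screen_protein(
    name: str,
    seq: str,
    reference: str | None = None,
    ref_gating_position: int | None = None,
) -> DomainReport:
    """Full hallmark screen of one protein C-terminal sequence."""
    triplet, has_dxw = terminal_triplet(seq)
    hxe, cxxc = zinc_motif_scan(seq)
    residue: str | None = None
    qpos: int | None = None
    if reference is not None and ref_gating_position is not None:
        residue, qpos = gating_residue(seq, reference, ref_gating_position)
    return DomainReport(
        protein_name=name,
        terminal_triplet=triplet,
        has_DxW=has_dxw,
        hxe_positions=tuple(hxe),
        cxxc_positions=tuple(cxxc),
        gating_residue=residue,
        gating_position=qpos,
    )


def screen_fasta(
    proteins_fasta: str | Path,
    reference: str | None = None,
    ref_gating_position: int | None = None,
) -> list[DomainReport]:
    return [
        screen_protein(
            rec.id, str(rec.seq), reference, ref_gating_position
        )
        for rec in SeqIO.parse(str(proteins_fasta), "fasta")
    ]


def default_reference() -> tuple[str, int]:
    """Packaged reference DYW domain and its 0-based gating-glutamate position.

    The sequence is a constructed stand-in carrying the canonical hallmarks
    (H-x-E and C-x-x-C zinc motifs, gating glutamate, terminal DYW); it is
    synthetic, not a natural protein — substitute a curated domain for real
    screens.
    """
    import importlib.resources

    data = importlib.resources.files("ppredit") / "data"
    with importlib.resources.as_file(data / "dyw_reference_synthetic.fasta") as p:
        rec = next(SeqIO.parse(str(p), "fasta"))
    with importlib.resources.as_file(data / "dyw_reference_synthetic.toml") as p:
        meta = tomllib.loads(Path(p).read_text())
    return str(rec.seq), int(meta["gating_position"])


def reports_to_frame(reports):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "name": r.protein_name,
                "terminal_triplet": r.terminal_triplet,
                "has_DxW": int(r.has_DxW),
                "n_hxe": len(r.hxe_positions),
                "n_cxxc": len(r.cxxc_positions),
                "gating_residue": r.gating_residue or "NA",
                "gating_position": (
                    r.gating_position if r.gating_position is not None else -1
                ),
            }
            for r in reports
        ],
        columns=[
            "name", "terminal_triplet", "has_DxW", "n_hxe", "n_cxxc",
            "gating_residue", "gating_position",
        ],
    )
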