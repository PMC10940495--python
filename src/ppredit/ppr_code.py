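"""PPR-code position weight matrices.

A PLS-class PPR protein recognises an RNA base per repeat motif through the
amino acids at motif position 6 and position 1' (the first residue of the
following motif).  Given a motif annotation (from an external predictor) and
a weighting table mapping ``(motif class, aa6, aa1')`` to nucleotide
probabilities, this module builds the per-position nucleotide preference
matrix (PWM) used for genome scanning.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

NUCLEOTIDES = ("A", "C", "G", "U")
MOTIF_CLASSES = ("P", "L", "S", "P2", "L2", "S2")
#: subclass → base class fallback when the code table has no subclass row
BASE_CLASS = {"P2": "P", "L2": "L", "S2": "S", "P": "P", "L": "L", "S": "S"}

UNIFORM = np.full(4, 0.25)


class MotifTableError(ValueError):
    """Malformed or inconsistent motif annotation."""


class CodeTableError(ValueError):
    """Malformed PPR-code weighting table."""


@dataclass(frozen=True)
class PPRMotif:
    """One annotated PPR repeat motif.

    ``start``/``end`` are 1-based inclusive residue coordinates in the full
    protein; ``sequence`` must equal the corresponding protein slice.
    """

    index: int
    motif_class: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise MotifTableError(
                f"motif {self.index}: unknown class {self.motif_class!r}"
            )
        if self.end < self.start:
            raise MotifTableError(f"motif {self.index}: end < start")
        if len(self.sequence) != self.end - self.start + 1:
            raise MotifTableError(
                f"motif {self.index}: sequence length {len(self.sequence)} "
                f"does not match span {self.start}-{self.end}"
            )
        if len(self.sequence) < 6:
            raise MotifTableError(f"motif {self.index}: fewer than 6 residues")


@dataclass(frozen=True)
class PPRProtein:
    name: str
    full_sequence: str
    motifs: tuple[PPRMotif, ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for m in self.motifs:
            if m.start <= prev_end:
                raise MotifTableError(
                    f"motif {m.index}: overlaps previous motif or is unsorted"
                )
            if m.end > len(self.full_sequence):
                raise MotifTableError(
                    f"motif {m.index}: span exceeds protein length "
                    f"{len(self.full_sequence)}"
                )
            if self.full_sequence[m.start - 1 : m.end] != m.sequence:
                raise MotifTableError(
                    f"motif {m.index}: sequence disagrees with protein slice"
                )
            prev_end = m.end


@dataclass(frozen=True)
class CodeTable:
    """Weighting table: (motif class, aa6, aa1') → base probabilities (ACGU)."""

    rows: Mapping[tuple[str, str, str], np.ndarray]
    provenance: str = ""

    def lookup(
        self, motif_class: str, aa6: str, aa1prime: str
    ) -> tuple[np.ndarray, bool]:
        """Return ``(probabilities, fallback_flag)``.

        Missing combinations yield a flagged uniform vector; subclass keys
        (P2/L2/S2) fall back to their base class when absent.
        """
        aa6, aa1prime = aa6.upper(), aa1prime.upper()
        for cls in dict.fromkeys([motif_class, BASE_CLASS.get(motif_class, motif_class)]):
            row = self.rows.get((cls, aa6, aa1prime))
            if row is not None:
                return row, False
        return UNIFORM.copy(), True


@dataclass(frozen=True)
class PWM:
    """Per-motif nucleotide probabilities, N→C order = 5'→3' RNA positions."""

    probs: np.ndarray  # (L, 4) over A,C,G,U
    source_protein: str = ""
    motif_classes: tuple[str, ...] = ()
    aa6: tuple[str, ...] = ()
    aa1prime: tuple[str, ...] = ()
    fallback: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError("PWM must be a non-empty (L, 4) matrix")
        if (p < 0).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("every PWM column must be a probability vector")
        object.__setattr__(self, "probs", p)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        """Most probable base per position, as DNA (U→T); ties → first of ACGU."""
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


def read_protein_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record protein FASTA, returning ``(name, sequence)``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise MotifTableError(
            f"expected exactly one protein record in {path}, got {len(records)}"
        )
    return records[0].id, str(records[0].seq).upper()


def parse_motif_table(path: str | Path, protein_fasta: str | Path) -> PPRProtein:
    """Parse a motif annotation TSV plus its accompanying protein FASTA.

    The TSV has columns ``index  class  start  end  sequence`` with 1-based
    inclusive residue coordinates.
    """
    name, full_seq = read_protein_fasta(protein_fasta)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"index", "class", "start", "end", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise MotifTableError(f"motif table missing columns: {sorted(missing)}")
    if df.empty:
        raise MotifTableError("no motifs")
    motifs = [
        PPRMotif(
            index=int(r["index"]),
            motif_class=str(r["class"]).strip(),
            start=int(r["start"]),
            end=int(r["end"]),
            sequence=str(r["sequence"]).strip().upper(),
        )
        for _, r in df.iterrows()
    ]
    motifs.sort(key=lambda m: m.start)
    return PPRProtein(name=name, full_sequence=full_seq, motifs=tuple(motifs))


def specificity_pair(protein: PPRProtein, i: int) -> tuple[str, str]:
    """Amino acids at motif position 6 and position 1' of motif ``i``.

    Position 1' is the first residue of the next motif; for the last motif it
    is the protein residue immediately after the motif span (E-domain side).
    """
    if not 0 <= i < len(protein.motifs):
        raise IndexError(f"motif index {i} out of range")
    motif = protein.motifs[i]
    aa6 = motif.sequence[5]
    if i + 1 < len(protein.motifs):
        aa1prime = protein.motifs[i + 1].sequence[0]
    else:
        if motif.end >= len(protein.full_sequence):
            raise MotifTableError(
                f"motif {motif.index}: no 1' residue (motif ends at the "
                "protein terminus)"
            )
        aa1prime = protein.full_sequence[motif.end]
    return aa6, aa1prime


def nucleotide_preference(
    table: CodeTable, motif_class: str, aa6: str, aa1prime: str
) -> tuple[np.ndarray, bool]:
    """Nucleotide probabilities for one specificity pair; see CodeTable.lookup."""
    return table.lookup(motif_class, aa6, aa1prime)


def build_pwm(protein: PPRProtein, table: CodeTable) -> PWM:
    """One PWM column per motif, in N→C order."""
    if not protein.motifs:
        raise MotifTableError("protein has no motifs")
    columns, classes, a6s, a1s, flags = [], [], [], [], []
    for i, motif in enumerate(protein.motifs):
        try:
            aa6, aa1 = specificity_pair(protein, i)
        except MotifTableError as exc:
            raise MotifTableError(f"motif {motif.index}: {exc}") from exc
        probs, fb = table.lookup(motif.motif_class, aa6, aa1)
        columns.append(probs)
        classes.append(motif.motif_class)
        a6s.append(aa6)
        a1s.append(aa1)
        flags.append(fb)
    return PWM(
        probs=np.vstack(columns),
        source_protein=protein.name,
        motif_classes=tuple(classes),
        aa6=tuple(a6s),
        aa1prime=tuple(a1s),
        fallback=tuple(flags),
    )


def read_code_table(path: str | Path, provenance: str = "") -> CodeTable:
    """Load a weighting-table TSV (``class aa6 aa1prime pA pC pG pU``).

    Rows whose probabilities deviate from sum 1 by more than 0.01 are a
    load-time error; smaller deviations are renormalised.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"class", "aa6", "aa1prime", "pA", "pC", "pG", "pU"}
    missing = required - set(df.columns)
    if missing:
        raise CodeTableError(f"code table missing columns: {sorted(missing)}")
    rows: dict[tuple[str, str, str], np.ndarray] = {}
    for _, r in df.iterrows():
        probs = np.array([float(r[c]) for c in ("pA", "pC", "pG", "pU")])
        if (probs < 0).any():
            raise CodeTableError(f"negative probability in row {tuple(r[:3])}")
        total = probs.sum()
        if abs(total - 1.0) > 0.01:
            raise CodeTableError(
                f"row {(r['class'], r['aa6'], r['aa1prime'])} sums to {total:.4f}"
            )
        key = (str(r["class"]).strip(), str(r["aa6"]).upper(), str(r["aa1prime"]).upper())
        rows[key] = probs / total
    return CodeTable(rows=rows, provenance=provenance or str(path))


def default_code_table() -> CodeTable:
    """The packaged default weighting table.

    A synthetic reconstruction of published PPR-code combination→base
    preferences, shipped as configuration; substitute a measured table for
    production predictions.
    """
    ref = importlib.resources.files("ppredit") / "data" / "ppr_code_table_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_code_table(path, provenance="ppredit synthetic default")


def write_pwm(pwm: PWM, path: str | Path) -> None:
    """Write a PWM TSV (one row per motif position)."""
    n = len(pwm)
    df = pd.DataFrame(
        {
            "position": np.arange(n),
            "motif_class": pwm.motif_classes or [""] * n,
            "aa6": pwm.aa6 or [""] * n,
            "aa1prime": pwm.aa1prime or [""] * n,
            "pA": pwm.probs[:, 0],
            "pC": pwm.probs[:, 1],
            "pG": pwm.probs[:, 2],
            "pU": pwm.probs[:, 3],
            "fallback": [int(f) for f in (pwm.fallback or [False] * n)],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pwm(path: str | Path) -> PWM:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return PWM(
        probs=df[["pA", "pC", "pG", "pU"]].to_numpy(float),
        motif_classes=tuple(df["motif_class"].astype(str)),
        aa6=tuple(df["aa6"].astype(str)),
        aa1prime=tuple(df["aa1prime"].astype(str)),
        fallback=tuple(bool(x) for x in df["fallback"]),
    )
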