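"""Per-site C-to-U editing efficiency from alignments, pileups or Sanger peaks.

Editing efficiency at a site is the fraction of reads carrying the edited
base out of edited + unedited reads: ``T/(C+T)`` at a plus-strand site and,
in genome-forward counts, ``A/(G+A)`` at a minus-strand site.  Reads showing
a third base at the site are excluded from the denominator but retained in
the reported total depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

BASES = ("A", "C", "G", "T")

#: canonical pileup-table columns (the on-disk dialect)
PILEUP_COLUMNS = [
    "seq_id", "pos0", "strand", "ref_base", "library_id", "nA", "nC", "nG", "nT",
]


class SiteError(ValueError):
    pass


@dataclass(frozen=True)
class EditSite:
    """A C-to-U editing site: reference C on '+', reference G on '−'
    (genome-forward terms)."""

    seq_id: str
    pos: int  # 0-based
    strand: str
    ref_base: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SiteError(f"{self.label or self.pos}: strand must be + or -")
        expected = "C" if self.strand == "+" else "G"
        if self.ref_base.upper() != expected:
            raise SiteError(
                f"{self.label or self.pos}: ref_base {self.ref_base!r} "
                f"inconsistent with strand {self.strand} (expected {expected})"
            )


@dataclass(frozen=True)
class PileupCounts:
    site: EditSite
    library_id: str
    counts: dict[str, int]  # genome-forward base counts

    def __post_init__(self) -> None:
        if any(self.counts.get(b, 0) < 0 for b in BASES):
            raise SiteError("negative base count")

    @property
    def depth_total(self) -> int:
        return sum(self.counts.get(b, 0) for b in BASES)


@dataclass(frozen=True)
class EditingMeasurement:
    site: EditSite
    library_id: str
    fraction: float  # nan when depth_used == 0
    depth_used: int
    depth_total: int
    low_coverage: bool


def count_bases(
    alignments: str | Path,
    reference: str | Path,
    sites: Sequence[EditSite],
    *,
    min_base_quality: int = 20,
    min_mapping_quality: int = 0,
    library_id: str | None = None,
) -> list[PileupCounts]:
    """Count bases over each site from a SAM/BAM file, one library per file.

    A single sequential pass over the alignments; reads below the mapping
    quality threshold, and bases below the base-quality threshold, are
    skipped.  Deletions and reference skips at a site contribute nothing.
    The default mapping-quality threshold of 0 keeps multi-mapping reads.
    """
    from Bio import SeqIO

    ref_seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(reference), "fasta")}
    by_pos: dict[tuple[str, int], list[int]] = {}
    for i, site in enumerate(sites):
        if site.seq_id not in ref_seqs:
            raise SiteError(f"site {site.label or i}: unknown reference {site.seq_id}")
        ref = ref_seqs[site.seq_id]
        if not 0 <= site.pos < len(ref):
            raise SiteError(f"site {site.label or i}: position outside reference")
        if ref[site.pos] != site.ref_base.upper():
            raise SiteError(
                f"site {site.label or i}: reference base {ref[site.pos]} "
                f"disagrees with declared {site.ref_base}"
            )
        by_pos.setdefault((site.seq_id, site.pos), []).append(i)

    counters = [{b: 0 for b in BASES} for _ in sites]
    lib = library_id or Path(alignments).stem
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.query_sequence is None:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                key = (read.reference_name, rpos)
                targets = by_pos.get(key)
                if targets is None:
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                base = read.query_sequence[qpos].upper()
                if base in BASES:
                    for t in targets:
                        counters[t][base] += 1
    return [
        PileupCounts(site=site, library_id=lib, counts=counters[i])
        for i, site in enumerate(sites)
    ]


def editing_fraction(
    counts: PileupCounts, *, min_depth: int = 20
) -> EditingMeasurement:
    """Edited-read fraction for one site/library.

    '+' site: T/(C+T); '−' site: A/(G+A), counts genome-forward.  Zero
    informative depth yields fraction NaN, never an exception.
    """
    c = counts.counts
    if counts.site.strand == "+":
        edited, unedited = c.get("T", 0), c.get("C", 0)
    else:
        edited, unedited = c.get("A", 0), c.get("G", 0)
    depth_used = edited + unedited
    fraction = edited / depth_used if depth_used > 0 else math.nan
    return EditingMeasurement(
        site=counts.site,
        library_id=counts.library_id,
        fraction=fraction,
        depth_used=depth_used,
        depth_total=counts.depth_total,
        low_coverage=depth_used < min_depth,
    )


def discover_sites(
    pileups: Iterable[PileupCounts],
    *,
    min_fraction: float = 0.05,
    min_depth: int = 20,
) -> list[EditSite]:
    """Call candidate C-to-U sites from pileups over reference C/G positions.

    A position is called when its edited fraction is ≥ ``min_fraction`` with
    informative depth ≥ ``min_depth`` in at least one library.  Only C→T on
    '+' and G→A on '−' are ever considered (C-to-U semantics); other
    reference bases never yield calls.
    """
    called: dict[tuple[str, int, str], EditSite] = {}
    for pc in pileups:
        site = pc.site
        if site.ref_base.upper() not in ("C", "G"):
            continue
        m = editing_fraction(pc, min_depth=min_depth)
        if m.depth_used >= min_depth and not math.isnan(m.fraction) \
                and m.fraction >= min_fraction:
            called.setdefault((site.seq_id, site.pos, site.strand), site)
    return sorted(called.values(), key=lambda s: (s.seq_id, s.pos, s.strand))


def sanger_fraction(peak_heights: dict[str, float], strand: str) -> float:
    """Editing fraction from Sanger chromatogram peak heights.

    Applies the same two-base proportion as :func:`editing_fraction` to
    relative peak heights (T/(C+T) on '+'); both relevant peaks zero → NaN.
    """
    if strand not in "+-":
        raise SiteError("strand must be + or -")
    if any(v < 0 for v in peak_heights.values()):
        raise SiteError("negative peak height")
    if strand == "+":
        edited, unedited = peak_heights.get("T", 0.0), peak_heights.get("C", 0.0)
    else:
        edited, unedited = peak_heights.get("A", 0.0), peak_heights.get("G", 0.0)
    total = edited + unedited
    return edited / total if total > 0 else math.nan


# ---------------------------------------------------------------------------
# pileup / site / measurement table I/O

def sites_from_bed(path: str | Path) -> list[EditSite]:
    """Read sites from BED6 (0-based half-open; name = site label)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise SiteError(f"BED6 line with {len(fields)} fields: {line!r}")
            seq_id, start, _end, name, _score, strand = fields[:6]
            pos = int(start)
            sites.append(
                EditSite(
                    seq_id=seq_id,
                    pos=pos,
                    strand=strand,
                    ref_base="C" if strand == "+" else "G",
                    label=name,
                )
            )
    return sites


def sites_to_bed(sites: Sequence[EditSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.seq_id}\t{s.pos}\t{s.pos + 1}\t{s.label or '.'}\t0\t{s.strand}\n"
            )


def pileups_to_frame(pileups: Iterable[PileupCounts]) -> pd.DataFrame:
    rows = [
        {
            "seq_id": pc.site.seq_id,
            "pos0": pc.site.pos,
            "strand": pc.site.strand,
            "ref_base": pc.site.ref_base,
            "library_id": pc.library_id,
            "nA": pc.counts.get("A", 0),
            "nC": pc.counts.get("C", 0),
            "nG": pc.counts.get("G", 0),
            "nT": pc.counts.get("T", 0),
        }
        for pc in pileups
    ]
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def write_pileup_tsv(pileups: Iterable[PileupCounts], path: str | Path) -> None:
    pileups_to_frame(pileups).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(
    path: str | Path, labels: dict[tuple[str, int], str] | None = None
) -> list[PileupCounts]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise SiteError(f"pileup table missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        default = f"{r['seq_id']}:{int(r['pos0'])}{r['strand']}"
        label = (labels or {}).get((r["seq_id"], int(r["pos0"])), default)
        site = EditSite(
            seq_id=str(r["seq_id"]),
            pos=int(r["pos0"]),
            strand=str(r["strand"]),
            ref_base=str(r["ref_base"]),
            label=label,
        )
        out.append(
            PileupCounts(
                site=site,
                library_id=str(r["library_id"]),
                counts={b: int(r[f"n{b}"]) for b in BASES},
            )
        )
    return out


def measurements_to_frame(
    measurements: Iterable[EditingMeasurement],
) -> pd.DataFrame:
    rows = [
        {
            "site_label": m.site.label,
            "seq_id": m.site.seq_id,
            "pos0": m.site.pos,
            "strand": m.site.strand,
            "library_id": m.library_id,
            "fraction": m.fraction,
            "depth_used": m.depth_used,
            "depth_total": m.depth_total,
            "low_coverage": int(m.low_coverage),
        }
        for m in measurements
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site_label", "seq_id", "pos0", "strand", "library_id",
            "fraction", "depth_used", "depth_total", "low_coverage",
        ],
    )
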