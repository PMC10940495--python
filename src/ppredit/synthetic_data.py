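"""Seeded generators for every input the pipeline consumes.

The editing simulator emulates the structure of a chloroplast RNA-seq
editing study: a ~150 kb plastome-like reference, a set of C-to-U editing
sites, three control and four silenced libraries of 250-nt reads, and
per-site editing reduced in the silenced condition.  Between-replicate
variation is Beta-distributed around the condition mean; read counts at a
site are Binomial in the realized fraction, with a uniform per-base
sequencing-error channel.  Every generator is a pure function of its
configuration and seed, and each run emits a truth table for recovery
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .editing_quant import BASES, EditSite, PileupCounts
from .ppr_code import PWM

_IDX = {b: i for i, b in enumerate("ACGT")}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the editing simulator.

    Defaults mirror the emulated study: 3 control vs 4 silenced (test)
    libraries, 250-nt reads, 23 edited sites on a 150 kb circular plastome
    with chloroplast-like GC content, strong editing in controls and a
    marked reduction under silencing.
    """

    genome_length: int = 150_000
    gc_content: float = 0.38
    n_edit_sites: int = 23
    f_control: float | Sequence[float] = 0.85
    f_test: float | Sequence[float] = 0.55
    n_control: int = 3
    n_test: int = 4
    depth_mean: float = 300.0
    overdispersion: float = 200.0  # beta concentration; 0 disables scatter
    seq_error_rate: float = 0.002
    read_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or not 0 <= self.gc_content <= 1:
            raise SimulationError("invalid genome parameters")
        if self.n_edit_sites < 0 or self.n_control < 1 or self.n_test < 1:
            raise SimulationError("invalid design counts")
        for f in np.atleast_1d(np.asarray(self.f_control, dtype=float)).tolist() + \
                np.atleast_1d(np.asarray(self.f_test, dtype=float)).tolist():
            if not 0 <= f <= 1:
                raise SimulationError(f"editing fraction {f} outside [0,1]")
        if self.depth_mean <= 0 or self.overdispersion < 0:
            raise SimulationError("invalid depth/overdispersion")
        if not 0 <= self.seq_error_rate < 1 or self.read_length < 1:
            raise SimulationError("invalid read parameters")

    @property
    def library_ids(self) -> list[str]:
        return [f"ctrl_{i+1}" for i in range(self.n_control)] + [
            f"test_{i+1}" for i in range(self.n_test)
        ]

    @property
    def design(self) -> dict[str, str]:
        return {
            lib: ("control" if lib.startswith("ctrl") else "test")
            for lib in self.library_ids
        }


#: specificity pairs (aa6, aa1') of the bundled example editing factor
EXAMPLE_PAIRS = [
    ("T", "N"), ("T", "D"), ("N", "D"), ("N", "N"), ("S", "N"),
    ("T", "N"), ("N", "S"), ("T", "D"), ("S", "D"), ("N", "D"),
    ("T", "N"), ("N", "N"), ("T", "D"),
]


def example_ppr_protein(name: str = "PLS13"):
    """A reproducible 13-motif PLS protein for demonstrations and tests.

    Motifs are 35 aa, classes cycle P→L→S, and the specificity pairs
    (position 6 and 1') are drawn from well-populated rows of the packaged
    code table.  The C-terminus carries an E-domain stub ending in DYW.
    """
    from .ppr_code import PPRMotif, PPRProtein

    classes = [["P", "L", "S"][i % 3] for i in range(len(EXAMPLE_PAIRS))]
    parts = []
    for i, (a6, _) in enumerate(EXAMPLE_PAIRS):
        first = EXAMPLE_PAIRS[i - 1][1] if i > 0 else "M"
        parts.append(first + "AAAA" + a6 + "A" * 29)
    full = "".join(parts) + EXAMPLE_PAIRS[-1][1] + "EEEDYW"
    motifs, start = [], 1
    for i, part in enumerate(parts):
        motifs.append(
            PPRMotif(index=i, motif_class=classes[i], start=start,
                     end=start + 34, sequence=part)
        )
        start += 35
    return PPRProtein(name=name, full_sequence=full, motifs=tuple(motifs))


def simulate_genome(length: int, gc: float = 0.38, seed: int = 0) -> str:
    """I.i.d. random genome: P(G)=P(C)=gc/2, P(A)=P(T)=(1−gc)/2."""
    if length <= 0 or not 0 <= gc <= 1:
        raise SimulationError("invalid genome parameters")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def plant_motif_sites(
    genome: str,
    pwm: PWM,
    n: int,
    mode: str = "consensus",
    seed: int = 0,
    max_tries: int = 10_000,
) -> tuple[str, pd.DataFrame]:
    """Plant ``n`` non-overlapping PWM sites, each on a random strand.

    Returns the modified genome and a truth table with columns
    ``start, strand, sequence`` (sequence genome-forward).  mode
    'consensus' plants the PWM consensus; 'sampled' draws each base from
    the PWM columns.
    """
    from .motif_scan import reverse_complement

    if mode not in ("consensus", "sampled"):
        raise SimulationError(f"unknown site mode {mode!r}")
    L = len(pwm)
    if n * L > len(genome) // 2:
        raise SimulationError("too many sites for genome length")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise SimulationError("could not place sites without overlap")
        start = int(rng.integers(0, len(genome) - L + 1))
        if all(abs(start - s) >= L for s in chosen):
            chosen.append(start)
    seq = list(genome)
    rows = []
    for start in sorted(chosen):
        if mode == "consensus":
            site = pwm.consensus
        else:
            site = "".join(
                "ACGT"[rng.choice(4, p=pwm.probs[j])] for j in range(L)
            )
        strand = "+" if rng.random() < 0.5 else "-"
        planted = site if strand == "+" else reverse_complement(site)
        seq[start : start + L] = planted
        rows.append(
            {"start": start, "strand": strand, "sequence": planted, "motif": site}
        )
    truth = pd.DataFrame(rows, columns=["start", "strand", "sequence", "motif"])
    return "".join(seq), truth


def _site_positions(
    genome: str, n: int, rng: np.random.Generator, min_separation: int
) -> list[tuple[int, str]]:
    """Pick n reference C/G positions at least min_separation apart."""
    if n == 0:
        return []
    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    candidates = np.flatnonzero((arr == ord("C")) | (arr == ord("G")))
    if len(candidates) == 0:
        raise SimulationError("genome has no C/G positions")
    rng.shuffle(candidates)
    import bisect

    chosen: list[int] = []
    for pos in candidates:
        p = int(pos)
        i = bisect.bisect_left(chosen, p)
        left_ok = i == 0 or p - chosen[i - 1] >= min_separation
        right_ok = i == len(chosen) or chosen[i] - p >= min_separation
        if left_ok and right_ok:
            chosen.insert(i, p)
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise SimulationError(
            f"could only place {len(chosen)}/{n} sites with separation "
            f"{min_separation}; increase genome_length"
        )
    chosen.sort()
    return [(p, "+" if genome[p] == "C" else "-") for p in chosen]


def _apply_errors(
    n_edited: int, n_unedited: int, site: EditSite, e: float, rng: np.random.Generator
) -> dict[str, int]:
    """Distribute edited/unedited reads over observed bases with a uniform
    per-read error channel (probability e of reading a uniform other base)."""
    edited_base = "T" if site.strand == "+" else "A"
    unedited_base = "C" if site.strand == "+" else "G"
    counts = {b: 0 for b in BASES}
    for true_base, n_reads in ((edited_base, n_edited), (unedited_base, n_unedited)):
        if n_reads == 0:
            continue
        probs = np.full(4, e / 3)
        probs[_IDX[true_base]] = 1 - e
        draw = rng.multinomial(n_reads, probs)
        for b, k in zip("ACGT", draw):
            counts[b] += int(k)
    return counts


def simulate_editing_pileups(
    config: SimConfig, genome: str | None = None, seq_id: str = "chloroplast"
) -> tuple[list[PileupCounts], dict[str, str], pd.DataFrame, str]:
    """Simulate per-site per-library pileups under the configured design.

    Returns ``(pileups, design, truth, genome)``.  The truth table carries
    one row per site × library with the condition mean, the realized
    (Beta-drawn) fraction and the realized depth.  Sites are separated by at
    least the read length when the genome allows, so reads emitted for one
    site never cover another.
    """
    rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = simulate_genome(config.genome_length, config.gc_content, config.seed)
    min_sep = config.read_length
    if config.n_edit_sites * min_sep > len(genome):
        min_sep = max(1, len(genome) // max(config.n_edit_sites * 2, 1))
    positions = _site_positions(genome, config.n_edit_sites, rng, min_sep)

    f_ctrl = np.broadcast_to(
        np.asarray(config.f_control, dtype=float), (config.n_edit_sites,)
    )
    f_test = np.broadcast_to(
        np.asarray(config.f_test, dtype=float), (config.n_edit_sites,)
    )
    design = config.design

    pileups: list[PileupCounts] = []
    truth_rows = []
    for k, (pos, strand) in enumerate(positions):
        label = f"site_{k+1:03d}"
        site = EditSite(
            seq_id=seq_id,
            pos=pos,
            strand=strand,
            ref_base="C" if strand == "+" else "G",
            label=label,
        )
        for lib in config.library_ids:
            mean_f = f_ctrl[k] if design[lib] == "control" else f_test[k]
            if config.overdispersion > 0 and 0 < mean_f < 1:
                a = mean_f * config.overdispersion
                b = (1 - mean_f) * config.overdispersion
                realized = float(rng.beta(a, b))
            else:
                realized = float(mean_f)
            depth = int(rng.poisson(config.depth_mean))
            n_edited = int(rng.binomial(depth, realized)) if depth > 0 else 0
            counts = _apply_errors(
                n_edited, depth - n_edited, site, config.seq_error_rate, rng
            )
            pileups.append(PileupCounts(site=site, library_id=lib, counts=counts))
            truth_rows.append(
                {
                    "site_label": label,
                    "seq_id": seq_id,
                    "pos0": pos,
                    "strand": strand,
                    "library_id": lib,
                    "condition": design[lib],
                    "true_mean": mean_f,
                    "realized_fraction": realized,
                    "depth": depth,
                    "n_edited": n_edited,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return pileups, design, truth, genome


def emit_alignments(
    config: SimConfig,
    pileups: Sequence[PileupCounts],
    genome: str,
    out_dir: str | Path,
) -> list[Path]:
    """Write one SAM file per library with perfectly mapped reads.

    Reads are ``read_length`` nt (clipped at genome ends) and tile each
    site; the bases observed at a site reproduce its pileup counts exactly,
    so a pileup recomputed from these alignments equals the direct pileup
    table site by site.  Mapping quality 60, base quality 30 throughout.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    glen = len(genome)
    by_lib: dict[str, list[PileupCounts]] = {lib: [] for lib in config.library_ids}
    for pc in pileups:
        by_lib.setdefault(pc.library_id, []).append(pc)
    paths = []
    for lib in sorted(by_lib):
        path = out_dir / f"reads_{lib}.sam"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            seq_ids = sorted({pc.site.seq_id for pc in by_lib[lib]})
            for sid in seq_ids:
                fh.write(f"@SQ\tSN:{sid}\tLN:{glen}\n")
            fh.write("@PG\tID:ppredit\tPN:ppredit\n")
            rid = 0
            for pc in sorted(by_lib[lib], key=lambda p: (p.site.seq_id, p.site.pos)):
                pos = pc.site.pos
                site_bases = [b for b in BASES for _ in range(pc.counts.get(b, 0))]
                for r, base in enumerate(site_bases):
                    rid += 1
                    # stagger read starts so the site stays covered
                    offset = r % config.read_length
                    start = max(0, min(pos - offset, glen - config.read_length))
                    end = min(start + config.read_length, glen)
                    bases = list(genome[start:end])
                    bases[pos - start] = base
                    seq = "".join(bases)
                    fh.write(
                        f"{lib}.{rid}\t0\t{pc.site.seq_id}\t{start + 1}\t60\t"
                        f"{len(seq)}M\t*\t0\t0\t{seq}\t{'?' * len(seq)}\n"
                    )
        paths.append(path)
    return paths
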