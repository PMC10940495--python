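#!/usr/bin/env python
"""Quantify C-to-U editing efficiency per site and library.

Computes edited-read fractions from the simulated pileups, verifies them
against a recount from the emitted SAM alignments on one library, and
summarises per-condition means.
"""

from pathlib import Path

import pandas as pd

from ppredit import editing_quant as eq

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    bed_sites = eq.sites_from_bed(SCRATCH / "sites.bed")
    labels = {(s.seq_id, s.pos): s.label for s in bed_sites}
    pileups = eq.read_pileup_tsv(SCRATCH / "pileups.tsv", labels=labels)
    measurements = [eq.editing_fraction(p) for p in pileups]
    frame = eq.measurements_to_frame(measurements)
    frame.to_csv(RESULTS / "measurements.tsv", sep="\t", index=False)

    # cross-check the SAM route on one library
    lib = "ctrl_1"
    sites = sorted({p.site for p in pileups}, key=lambda s: s.pos)
    recount = eq.count_bases(
        SCRATCH / "sam" / f"reads_{lib}.sam", SCRATCH / "genome.fasta",
        sites, library_id=lib,
    )
    direct = {p.site.pos: p.counts for p in pileups if p.library_id == lib}
    mismatches = sum(rc.counts != direct[rc.site.pos] for rc in recount)

    design = pd.read_csv(SCRATCH / "design.tsv", sep="\t")
    merged = frame.merge(design, on="library_id")
    by_cond = merged.groupby("condition")["fraction"].mean()

    print(f"{len(measurements)} measurements over {len(sites)} sites")
    print(f"SAM-vs-pileup count mismatches ({lib}): {mismatches}")
    print("mean editing fraction by condition:")
    for cond, f in by_cond.items():
        print(f"  {cond}: {f:.3f}")
    print(f"low-coverage measurements: {int(frame['low_coverage'].sum())}")


if __name__ == "__main__":
    main()
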