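#!/usr/bin/env python
"""Generate the synthetic study inputs every later step consumes.

Emulated design: a 150 kb chloroplast-like genome (38% GC) carrying five
planted binding sites for the example 13-motif PLS protein, 23 C-to-U
editing sites quantified in 3 control and 4 silenced 250-nt-read libraries,
with editing reduced from ~0.85 to ~0.55 under silencing.

Outputs: bulky intermediates (genome, pileups, SAM) under scratch/analysis/;
compact tables (motif table, truth summaries) under results/.
"""

from pathlib import Path

from ppredit import editing_quant as eq
from ppredit import ppr_code as pc
from ppredit import synthetic_data as sd

SEED = 20240315
SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    protein = sd.example_ppr_protein()
    with open(SCRATCH / "protein.fasta", "w") as fh:
        fh.write(f">{protein.name}\n{protein.full_sequence}\n")
    with open(RESULTS / "motif_table.tsv", "w") as fh:
        fh.write("index\tclass\tstart\tend\tsequence\n")
        for m in protein.motifs:
            fh.write(f"{m.index}\t{m.motif_class}\t{m.start}\t{m.end}\t{m.sequence}\n")

    pwm = pc.build_pwm(protein, pc.default_code_table())
    genome = sd.simulate_genome(150_000, gc=0.38, seed=SEED)
    genome, motif_truth = sd.plant_motif_sites(genome, pwm, 5, "consensus",
                                               seed=SEED + 1)
    motif_truth.to_csv(RESULTS / "truth_motifs.tsv", sep="\t", index=False)

    cfg = sd.SimConfig(seed=SEED + 2)
    pileups, design, edit_truth, genome2 = sd.simulate_editing_pileups(
        cfg, genome=genome
    )
    with open(SCRATCH / "genome.fasta", "w") as fh:
        fh.write(">chloroplast\n")
        for i in range(0, len(genome2), 70):
            fh.write(genome2[i : i + 70] + "\n")
    eq.write_pileup_tsv(pileups, SCRATCH / "pileups.tsv")
    sites = sorted({p.site for p in pileups}, key=lambda s: s.pos)
    eq.sites_to_bed(sites, SCRATCH / "sites.bed")
    with open(SCRATCH / "design.tsv", "w") as fh:
        fh.write("library_id\tcondition\n")
        for lib, cond in design.items():
            fh.write(f"{lib}\t{cond}\n")
    edit_truth.to_csv(SCRATCH / "truth_editing.tsv", sep="\t", index=False)
    sd.emit_alignments(cfg, pileups, genome2, SCRATCH / "sam")

    print(f"protein: {protein.name}, {len(protein.motifs)} PLS motifs")
    print(f"genome: {len(genome2)} nt, {len(motif_truth)} planted binding sites")
    print(f"editing: {cfg.n_edit_sites} sites x {len(design)} libraries "
          f"({cfg.n_control} control, {cfg.n_test} silenced)")
    print(f"inputs in {SCRATCH}/, truth tables in {RESULTS}/")


if __name__ == "__main__":
    main()
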