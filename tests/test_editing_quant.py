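"""Editing quantification: base counting, fractions, discovery, Sanger peaks."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppredit import editing_quant as eq
from ppredit import synthetic_data as sd


def make_site(strand="+", pos=100, label="s1"):
    return eq.EditSite(
        seq_id="chr", pos=pos, strand=strand,
        ref_base="C" if strand == "+" else "G", label=label,
    )


def write_sam(path, reads, glen=300):
    """reads: list of (name, pos0, seq, qual_char)"""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n@SQ\tSN:chr\tLN:%d\n" % glen)
        for name, pos0, seq, q in reads:
            fh.write(
                f"{name}\t0\tchr\t{pos0 + 1}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t{q * len(seq)}\n"
            )


class TestCountBases:
    @pytest.fixture()
    def reference(self, tmp_path):
        genome = ("A" * 100) + "C" + ("A" * 199)  # C at pos 100
        ref = tmp_path / "ref.fasta"
        ref.write_text(">chr\n" + genome + "\n")
        return ref, genome

    def test_simple_counts(self, tmp_path, reference):
        ref, genome = reference
        sam = tmp_path / "a.sam"
        write_sam(sam, [
            ("r1", 90, genome[90:120], "I"),
            ("r2", 95, genome[95:130], "I"),
            ("r3", 98, genome[98:110][:2] + "T" + genome[101:110], "I"),
        ])
        counts = eq.count_bases(sam, ref, [make_site()])
        assert counts[0].counts == {"A": 0, "C": 2, "G": 0, "T": 1}

    def test_low_quality_base_excluded(self, tmp_path, reference):
        ref, genome = reference
        sam = tmp_path / "a.sam"
        write_sam(sam, [("r1", 95, genome[95:110], "+")])  # phred 10 < 20
        counts = eq.count_bases(sam, ref, [make_site()])
        assert counts[0].depth_total == 0

    def test_deletion_spanning_site_excluded(self, tmp_path, reference):
        ref, genome = reference
        sam = tmp_path / "a.sam"
        seq = genome[95:100] + genome[101:110]  # 5M1D9M skips the C
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:chr\tLN:300\n")
            fh.write(f"r1\t0\tchr\t96\t60\t5M1D9M\t*\t0\t0\t{seq}\t{'I' * len(seq)}\n")
        counts = eq.count_bases(sam, ref, [make_site()])
        assert counts[0].depth_total == 0

    def test_mapping_quality_filter(self, tmp_path, reference):
        ref, genome = reference
        sam = tmp_path / "a.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:chr\tLN:300\n")
            fh.write(f"r1\t0\tchr\t96\t0\t15M\t*\t0\t0\t{genome[95:110]}\t{'I' * 15}\n")
        # mapq 0 kept at the default threshold (multi-mappers retained)...
        assert eq.count_bases(sam, ref, [make_site()])[0].depth_total == 1
        # ...but excluded when a positive threshold is requested
        assert eq.count_bases(
            sam, ref, [make_site()], min_mapping_quality=10
        )[0].depth_total == 0

    def test_reference_disagreement_rejected(self, tmp_path, reference):
        ref, _ = reference
        sam = tmp_path / "a.sam"
        write_sam(sam, [])
        with pytest.raises(eq.SiteError, match="disagrees"):
            eq.count_bases(sam, ref, [make_site(pos=50)])  # ref has A at 50

    def test_site_outside_reference_rejected(self, tmp_path, reference):
        ref, _ = reference
        sam = tmp_path / "a.sam"
        write_sam(sam, [])
        with pytest.raises(eq.SiteError, match="outside"):
            eq.count_bases(sam, ref, [make_site(pos=5000)])


class TestEditingFraction:
    def test_plus_strand(self):
        pc_ = eq.PileupCounts(make_site("+"), "lib1", {"A": 0, "C": 30, "G": 0, "T": 70})
        m = eq.editing_fraction(pc_)
        assert m.fraction == pytest.approx(0.70)
        assert m.depth_used == 100 and not m.low_coverage

    def test_minus_strand_uses_forward_counts(self):
        site = make_site("-")
        pc_ = eq.PileupCounts(site, "lib1", {"A": 60, "C": 0, "G": 20, "T": 0})
        m = eq.editing_fraction(pc_)
        assert m.fraction == pytest.approx(0.75)

    def test_third_base_noise_excluded_from_denominator(self):
        pc_ = eq.PileupCounts(make_site("+"), "l", {"A": 1, "C": 0, "G": 9, "T": 0})
        m = eq.editing_fraction(pc_)
        assert math.isnan(m.fraction)
        assert m.depth_used == 0 and m.depth_total == 10

    def test_low_coverage_flagged_not_dropped(self):
        pc_ = eq.PileupCounts(make_site("+"), "l", {"A": 0, "C": 5, "G": 0, "T": 5})
        m = eq.editing_fraction(pc_, min_depth=20)
        assert m.low_coverage and m.fraction == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_fraction_bounds(self, nc, nt):
        pc_ = eq.PileupCounts(make_site("+"), "l", {"A": 0, "C": nc, "G": 0, "T": nt})
        m = eq.editing_fraction(pc_)
        if nc + nt == 0:
            assert math.isnan(m.fraction)
        else:
            assert 0 <= m.fraction <= 1
            assert m.depth_used == nc + nt

    def test_estimates_within_binomial_error(self):
        # 1,000 simulated sites at depth 500: >= 99% within 3 binomial SE
        import numpy as np

        rng = np.random.default_rng(42)
        inside = 0
        n = 1000
        for _ in range(n):
            f = rng.uniform(0.02, 0.98)
            d = 500
            k = rng.binomial(d, f)
            pc_ = eq.PileupCounts(
                make_site("+"), "l", {"A": 0, "C": d - k, "G": 0, "T": k}
            )
            m = eq.editing_fraction(pc_)
            se = math.sqrt(f * (1 - f) / d)
            inside += abs(m.fraction - f) <= 3 * se
        assert inside / n >= 0.99


class TestDiscoverSites:
    def test_planted_site_discovered(self):
        pc_ = eq.PileupCounts(make_site("+"), "l", {"A": 0, "C": 50, "G": 0, "T": 50})
        sites = eq.discover_sites([pc_])
        assert len(sites) == 1 and sites[0].pos == 100

    def test_low_fraction_not_discovered(self):
        pc_ = eq.PileupCounts(make_site("+"), "l", {"A": 0, "C": 99, "G": 0, "T": 1})
        assert eq.discover_sites([pc_]) == []

    def test_one_passing_library_suffices(self):
        deep = eq.PileupCounts(make_site("+"), "l1", {"A": 0, "C": 50, "G": 0, "T": 50})
        shallow = eq.PileupCounts(make_site("+"), "l2", {"A": 0, "C": 2, "G": 0, "T": 1})
        assert len(eq.discover_sites([shallow, deep])) == 1


class TestSangerFraction:
    @pytest.mark.parametrize(
        "heights,strand,expected",
        [
            ({"C": 400, "T": 600}, "+", 0.6),
            ({"C": 1000, "T": 0}, "+", 0.0),
            ({"G": 200, "A": 600}, "-", 0.75),
        ],
    )
    def test_two_base_proportion(self, heights, strand, expected):
        assert eq.sanger_fraction(heights, strand) == pytest.approx(expected)

    def test_no_relevant_peaks_is_na(self):
        assert math.isnan(eq.sanger_fraction({"C": 0, "T": 0, "G": 800}, "+"))


class TestReverseComplementSymmetry:
    def test_fractions_invariant_under_revcomp(self, tmp_path):
        """Reverse-complementing reference + alignments and flipping site
        strands leaves every editing fraction unchanged."""
        from ppredit.motif_scan import reverse_complement

        cfg = sd.SimConfig(
            genome_length=20_000, n_edit_sites=6, depth_mean=80, seed=9
        )
        pileups, _, _, genome = sd.simulate_editing_pileups(cfg)
        fwd_dir = tmp_path / "fwd"
        sd.emit_alignments(cfg, pileups, genome, fwd_dir)
        (fwd_dir / "ref.fasta").write_text(">chloroplast\n" + genome + "\n")

        # mirror world
        rc = reverse_complement(genome)
        L = len(genome)
        rev_dir = tmp_path / "rev"
        rev_dir.mkdir()
        (rev_dir / "ref.fasta").write_text(">chloroplast\n" + rc + "\n")
        sites = sorted({p.site for p in pileups}, key=lambda s: s.pos)
        flipped = [
            eq.EditSite(
                seq_id="chloroplast",
                pos=L - 1 - s.pos,
                strand="-" if s.strand == "+" else "+",
                ref_base="G" if s.strand == "+" else "C",
                label=s.label,
            )
            for s in sites
        ]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for sam in sorted(fwd_dir.glob("reads_*.sam")):
            lib = sam.stem.replace("reads_", "")
            fwd_counts = eq.count_bases(sam, fwd_dir / "ref.fasta", sites,
                                        library_id=lib)
            # mirror every read
            out = rev_dir / sam.name
            with open(sam) as src, open(out, "w") as dst:
                for line in src:
                    if line.startswith("@"):
                        dst.write(line)
                        continue
                    f = line.rstrip("\n").split("\t")
                    seq = f[9]
                    start = int(f[3]) - 1
                    new_start = L - (start + len(seq))
                    f[3] = str(new_start + 1)
                    f[9] = reverse_complement(seq)
                    f[1] = "16"
                    dst.write("\t".join(f) + "\n")
            rev_counts = eq.count_bases(out, rev_dir / "ref.fasta", flipped,
                                        library_id=lib)
            by_label_f = {c.site.label: eq.editing_fraction(c) for c in fwd_counts}
            by_label_r = {c.site.label: eq.editing_fraction(c) for c in rev_counts}
            for label, mf in by_label_f.items():
                mr = by_label_r[label]
                assert mf.depth_used == mr.depth_used
                if mf.depth_used:
                    assert mf.fraction == mr.fraction
            # forward counts complement-mirror exactly
            for cf, cr in zip(fwd_counts, [dict((c.site.label, c) for c in rev_counts)[c2.site.label] for c2 in fwd_counts]):
                assert {comp[b]: n for b, n in cf.counts.items()} == cr.counts


class TestPileupIO:
    def test_tsv_roundtrip(self, tmp_path):
        cfg = sd.SimConfig(genome_length=10_000, n_edit_sites=4, seed=3)
        pileups, _, _, _ = sd.simulate_editing_pileups(cfg)
        path = tmp_path / "pileup.tsv"
        eq.write_pileup_tsv(pileups, path)
        again = eq.read_pileup_tsv(path)
        assert [(p.site.pos, p.library_id, p.counts) for p in pileups] == [
            (p.site.pos, p.library_id, p.counts) for p in again
        ]

    def test_bed_roundtrip(self, tmp_path):
        sites = [make_site("+", 10, "a"), make_site("-", 50, "b")]
        path = tmp_path / "sites.bed"
        eq.sites_to_bed(sites, path)
        assert eq.sites_from_bed(path) == sites
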