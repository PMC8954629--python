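import numpy as np
import pytest

from tissuespec.cre import (
    DEFAULT_MOTIFS,
    IUPAC,
    Motif,
    Promoter,
    extract_promoters,
    group_frequencies,
    iupac_to_regex,
    reverse_complement,
    scan_motifs,
)

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def brute_force_hits(seq, pattern):
    """Position-by-position sliding-window IUPAC match, both strands."""
    found = set()
    for strand, pat in (("+", pattern), ("-", reverse_complement(pattern))):
        w = len(pat)
        for i in range(len(seq) - w + 1):
            if all(seq[i + j] in IUPAC_SETS[pat[j]] for j in range(w)):
                found.add((i, strand))
    return found


def promoter(gene, seq):
    return Promoter(gene, "chr1", 0, len(seq), "+", seq, False)


def write_genome(tmp_path, contigs, gff_lines):
    fasta = tmp_path / "genome.fa"
    with open(fasta, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    gff = tmp_path / "models.gff3"
    gff.write_text("##gff-version 3\n" + "\n".join(gff_lines) + "\n")
    return fasta, gff


class TestExtractPromoters:
    def test_plus_strand_coordinates(self, tmp_path, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4000)])
        # CDS starts at 1-based position 3001 -> promoter = bases 1001..3000
        lines = [
            f"chr1\tt\tgene\t3001\t3300\t.\t+\t.\tID=gA",
            f"chr1\tt\tmRNA\t3001\t3300\t.\t+\t.\tID=gA.t1;Parent=gA",
            f"chr1\tt\tCDS\t3001\t3300\t.\t+\t0\tID=gA.cds;Parent=gA.t1",
        ]
        fasta, gff = write_genome(tmp_path, {"chr1": seq}, lines)
        (p,) = extract_promoters(fasta, gff)
        assert (p.start, p.end, p.strand, p.truncated) == (1000, 3000, "+", False)
        assert p.sequence == seq[1000:3000]

    def test_minus_strand_is_reverse_complement(self, tmp_path, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4000)])
        # CDS 101..400 on minus strand -> promoter = revcomp(bases 401..2400)
        lines = [
            f"chr1\tt\tgene\t101\t400\t.\t-\t.\tID=gB",
            f"chr1\tt\tCDS\t101\t400\t.\t-\t0\tID=gB.cds;Parent=gB",
        ]
        fasta, gff = write_genome(tmp_path, {"chr1": seq}, lines)
        (p,) = extract_promoters(fasta, gff)
        assert (p.start, p.end, p.strand) == (400, 2400, "-")
        assert p.sequence == reverse_complement(seq[400:2400])

    def test_contig_edge_truncates(self, tmp_path, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        lines = [
            f"chr1\tt\tgene\t500\t800\t.\t+\t.\tID=gC",
            f"chr1\tt\tCDS\t500\t800\t.\t+\t0\tID=gC.cds;Parent=gC",
        ]
        fasta, gff = write_genome(tmp_path, {"chr1": seq}, lines)
        (p,) = extract_promoters(fasta, gff)
        assert len(p) == 499 and p.truncated
        assert p.sequence == seq[0:499]

    def test_gene_without_cds_skipped_with_warning(self, tmp_path, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        lines = [f"chr1\tt\tgene\t2500\t2800\t.\t+\t.\tID=gD"]
        fasta, gff = write_genome(tmp_path, {"chr1": seq}, lines)
        with pytest.warns(UserWarning, match="no CDS"):
            assert extract_promoters(fasta, gff) == []

    def test_interval_roundtrip(self, tmp_path, rng):
        # re-fetching the reported interval reproduces the stored sequence
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 6000)])
        lines = []
        for i, (start, strand) in enumerate([(2500, "+"), (3000, "-"), (5500, "+")]):
            lines += [
                f"chr1\tt\tgene\t{start}\t{start + 99}\t.\t{strand}\t.\tID=g{i}",
                f"chr1\tt\tCDS\t{start}\t{start + 99}\t.\t{strand}\t0\tID=g{i}.c;Parent=g{i}",
            ]
        fasta, gff = write_genome(tmp_path, {"chr1": seq}, lines)
        for p in extract_promoters(fasta, gff):
            window = seq[p.start : p.end]
            if p.strand == "-":
                window = reverse_complement(window)
            assert window == p.sequence


class TestScanMotifs:
    def test_literal_forward_match(self):
        hits = scan_motifs([promoter("g", "GGTATAAAGG")], [Motif("TATA-box", "TATAAA", "common")])
        assert len(hits) == 1
        assert hits.iloc[0][["position", "strand"]].tolist() == [2, "+"]

    def test_reverse_complement_match(self):
        hits = scan_motifs([promoter("g", "CCATTGGC")], [Motif("CAAT-box", "CCAAT", "common")])
        assert len(hits) == 1
        assert hits.iloc[0]["strand"] == "-"

    def test_palindrome_counts_twice_unless_collapsed(self):
        gbox = Motif("G-box", "CACGTG", "light-responsive")
        hits = scan_motifs([promoter("g", "TTCACGTGTT")], [gbox])
        assert len(hits) == 2 and set(hits["strand"]) == {"+", "-"}
        hits = scan_motifs([promoter("g", "TTCACGTGTT")], [gbox], collapse_palindromes=True)
        assert len(hits) == 1

    def test_overlapping_occurrences_all_counted(self):
        hits = scan_motifs(
            [promoter("g", "AAAAAA")], [Motif("polyA", "AAAA", "other")], strands="forward"
        )
        assert sorted(hits["position"]) == [0, 1, 2]

    def test_matches_sliding_window_oracle(self, rng):
        patterns = [
            Motif("m1", "TATAWAW", "common"),
            Motif("m2", "CANNTG", "other"),
            Motif("m3", "ACGTGKC", "ABA-responsive"),
            Motif("m4", "RYCGAC", "other"),
        ]
        for i in range(20):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
            hits = scan_motifs([promoter("g", seq)], patterns)
            for m in patterns:
                got = {
                    (int(r.position), r.strand)
                    for r in hits[hits["motif"] == m.name].itertuples()
                }
                assert got == brute_force_hits(seq, m.pattern), m.name

    def test_invalid_iupac_letter_names_the_motif(self):
        with pytest.raises(ValueError, match="badmotif"):
            Motif("badmotif", "ACGTX", "other")

    def test_order_invariance_and_total_additivity(self, rng):
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)]) for _ in range(5)]
        proms = [promoter(f"g{i}", s) for i, s in enumerate(seqs)]
        motifs = DEFAULT_MOTIFS[:6]
        h1 = scan_motifs(proms, motifs)
        h2 = scan_motifs(proms[::-1], motifs)
        key = ["gene_id", "motif", "position", "strand"]
        assert sorted(map(tuple, h1[key].to_numpy())) == sorted(map(tuple, h2[key].to_numpy()))
        per_motif = sum(len(scan_motifs(proms, [m])) for m in motifs)
        assert len(h1) == per_motif


class TestGroupFrequencies:
    def test_mean_sites_per_promoter(self):
        proms = [promoter("g1", "ATTCTCTAAC" * 3), promoter("g2", "ATTCTCTAACGG")]
        motif = Motif("TC-rich repeats", "ATTCTCTAAC", "stress-related")
        hits = scan_motifs(proms, [motif], strands="forward")
        freq = group_frequencies(hits, proms)
        assert freq["stress-related"] == pytest.approx(2.0)  # (3 + 1) / 2

    def test_zero_hits_everywhere(self):
        proms = [promoter("g1", "A" * 50)]
        freq = group_frequencies(scan_motifs(proms, [Motif("x", "CGCGCG", "other")]), proms)
        assert (freq == 0).all()

    def test_empty_promoter_set_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            group_frequencies(pd.DataFrame(columns=["gene_id", "group"]), [])

    def test_group_sum_equals_total_hit_rate(self, rng):
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)]) for _ in range(4)]
        proms = [promoter(f"g{i}", s) for i, s in enumerate(seqs)]
        hits = scan_motifs(proms, DEFAULT_MOTIFS)
        freq = group_frequencies(hits, proms)
        assert freq.sum() == pytest.approx(len(hits) / len(proms))


def test_reverse_complement_handles_degenerate_codes():
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("RYN") == "NRY"
    for code in IUPAC:
        assert reverse_complement(reverse_complement(code)) == code
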