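"""Gene-neighborhood classification of folK paralogs."""

import random

import pytest
from hypothesis import given, strategies as st

from thfkin.neighborhood import (
    GeneRecord,
    classify_folk,
    parse_annotations,
    summarize_genomes,
)

GFF_HEADER = "##gff-version 3\n"


def _gff_line(seqid, start, gene, strand="+"):
    end = start + 300
    return f"{seqid}\ttest\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID=c{seqid}_{start};gene={gene}\n"


def make_replicon(labels, genome="g", replicon="chr"):
    """GeneRecords from a dict {ordinal: gene label} over range(n)."""
    n = max(labels) + 1 if labels else 0
    return [
        GeneRecord(genome, replicon, i, labels.get(i), "+") for i in range(n)
    ]


def brute_force_class(labels, folk_pos, window=10, circular=False):
    """Independent exhaustive recount of the classification rule."""
    n = max(labels) + 1
    near = {}
    for target in ("panb", "folb"):
        hit = False
        for pos, g in labels.items():
            if g != target:
                continue
            d = abs(pos - folk_pos)
            if circular:
                d = min(d, n - d)
            if d <= window:
                hit = True
        near[target] = hit
    if near["panb"] and near["folb"]:
        return "both"
    if near["panb"]:
        return "panB-clustered"
    if near["folb"]:
        return "folB-clustered"
    return "neither"


class TestParsing:
    def test_gff3_ordinals_and_labels(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(
            GFF_HEADER
            + _gff_line("chr1", 100, "folB")
            + _gff_line("chr1", 500, "folK", "-")
            + _gff_line("chr1", 900, "panB")
        )
        recs = parse_annotations(path, genome_id="toy")
        assert [(r.ordinal, r.gene, r.strand) for r in recs] == [
            (0, "folb", "+"), (1, "folk", "-"), (2, "panb", "+")
        ]

    def test_ordinals_restart_per_replicon(self, tmp_path):
        path = tmp_path / "two.gff3"
        path.write_text(
            GFF_HEADER
            + _gff_line("chr1", 100, "folB")
            + _gff_line("chr1", 500, "folK")
            + _gff_line("plasmid", 100, "panB")
            + _gff_line("plasmid", 500, "folK")
        )
        recs = parse_annotations(path, genome_id="toy")
        assert [(r.replicon, r.ordinal) for r in recs] == [
            ("chr1", 0), ("chr1", 1), ("plasmid", 0), ("plasmid", 1)
        ]

    def test_shuffled_file_same_ordinals(self, tmp_path):
        lines = [
            _gff_line("chr1", s, g)
            for s, g in [(100, "folB"), (700, "folK"), (1500, "panB"), (2300, "x")]
        ]
        sorted_path = tmp_path / "sorted.gff3"
        sorted_path.write_text(GFF_HEADER + "".join(lines))
        shuffled_path = tmp_path / "shuffled.gff3"
        shuffled_path.write_text(GFF_HEADER + "".join(lines[::-1]))
        a = parse_annotations(sorted_path, genome_id="g")
        b = parse_annotations(shuffled_path, genome_id="g")
        assert [(r.ordinal, r.gene) for r in a] == [(r.ordinal, r.gene) for r in b]

    def test_tsv_gene_table(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "genome\treplicon\tordinal\tgene\tstrand\n"
            "g1\tchr\t0\tfolB\t+\n"
            "g1\tchr\t1\tfolK\t-\n"
        )
        recs = parse_annotations(path)
        assert recs[1].gene == "folk" and recs[1].strand == "-"

    def test_noncontiguous_ordinals_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "genome\treplicon\tordinal\tgene\tstrand\n"
            "g1\tchr\t0\tfolB\t+\n"
            "g1\tchr\t2\tfolK\t-\n"
        )
        with pytest.raises(ValueError, match="contiguous"):
            parse_annotations(path)


class TestClassification:
    def test_adjacent_panb_only(self):
        genes = make_replicon({3: "folk", 4: "panb"})
        (call,) = classify_folk(genes)
        assert call.call_class == "panB-clustered"
        assert call.dist_panb == 1 and call.dist_folb is None

    def test_window_boundary_inclusive(self):
        """folB at distance exactly 10 clusters; panB at 11 does not."""
        genes = make_replicon({0: "folb", 10: "folk", 21: "panb"})
        (call,) = classify_folk(genes, window=10)
        assert call.call_class == "folB-clustered"
        assert call.dist_folb == 10 and call.dist_panb == 11

    def test_brute_force_all_placements(self):
        """Every folK placement on a 25-gene replicon matches an
        independent exhaustive recount."""
        base = {5: "folb", 16: "panb"}
        for pos in range(25):
            if pos in base:
                continue
            labels = dict(base)
            labels[pos] = "folk"
            genes = make_replicon({**{24: None}, **labels})
            (call,) = classify_folk(genes, window=10)
            assert call.call_class == brute_force_class(labels, pos), pos

    def test_two_folk_genome_pattern(self):
        """Two folK copies, one near folB and one near panB (the
        A. baylyi ADP1 arrangement) give two distinct calls."""
        labels = {0: "folb", 2: "folk", 40: "folk", 41: "panb"}
        genes = make_replicon({**{50: None}, **labels})
        calls = classify_folk(genes)
        assert sorted(c.call_class for c in calls) == [
            "folB-clustered", "panB-clustered"
        ]

    def test_cross_replicon_distance_is_infinite(self):
        genes = make_replicon({0: "folk"}, replicon="chr") + make_replicon(
            {0: "panb"}, replicon="plasmid"
        )
        (call,) = classify_folk(genes)
        assert call.call_class == "neither" and call.dist_panb is None

    def test_circular_replicon_wraps(self):
        labels = {0: "folk", 29: "panb"}
        genes = make_replicon({**{29: "panb"}, **labels})
        (linear,) = classify_folk(genes, window=10)
        (circ,) = classify_folk(genes, window=10, circular=True)
        assert linear.call_class == "neither"
        assert circ.call_class == "panB-clustered" and circ.dist_panb == 1

    @given(
        folk=st.integers(0, 29),
        folb=st.integers(0, 29),
        panb=st.integers(0, 29),
        window=st.integers(1, 15),
    )
    def test_reversal_invariance(self, folk, folb, panb, window):
        if len({folk, folb, panb}) < 3:
            return
        labels = {folk: "folk", folb: "folb", panb: "panb"}
        fwd = make_replicon({**{29: None}, **labels})
        rev_labels = {29 - k: v for k, v in labels.items()}
        rev = make_replicon({**{29: None}, **rev_labels})
        (a,) = classify_folk(fwd, window=window)
        (b,) = classify_folk(rev, window=window)
        assert a.call_class == b.call_class

    @given(
        folk=st.integers(0, 29),
        folb=st.integers(0, 29),
        panb=st.integers(0, 29),
        window=st.integers(1, 14),
    )
    def test_window_monotonicity(self, folk, folb, panb, window):
        """Growing the window can only move calls toward 'both', never
        toward 'neither'."""
        if len({folk, folb, panb}) < 3:
            return
        rank = {"neither": 0, "folB-clustered": 1, "panB-clustered": 1, "both": 2}
        labels = {folk: "folk", folb: "folb", panb: "panb"}
        genes = make_replicon({**{29: None}, **labels})
        (small,) = classify_folk(genes, window=window)
        (large,) = classify_folk(genes, window=window + 1)
        assert rank[large.call_class] >= rank[small.call_class]


class TestSummary:
    def test_duplication_fraction(self):
        calls = []
        calls += classify_folk(make_replicon({0: "folb", 1: "folk"}, genome="g1"))
        calls += classify_folk(make_replicon({0: "folb", 1: "folk"}, genome="g2"))
        calls += classify_folk(make_replicon({0: "panb", 1: "folk"}, genome="g3"))
        calls += classify_folk(
            make_replicon({0: "folb", 2: "folk", 30: "folk", 31: "panb", 40: None},
                          genome="g4")
        )
        s = summarize_genomes(calls)
        assert s["n_genomes"] == 4
        assert s["duplicated_fraction"] == 0.25
        assert sum(s["pattern_fractions"].values()) == pytest.approx(1.0)

    def test_empty_cohort(self):
        s = summarize_genomes([])
        assert s["n_genomes"] == 0 and s["duplicated_fraction"] == 0.0

    def test_random_cohort_matches_recount(self):
        """Fractions from summarize_genomes equal a direct recount on a
        randomized synthetic cohort."""
        rng = random.Random(42)
        calls = []
        expected_dup = 0
        n_genomes = 30
        for gi in range(n_genomes):
            labels = {}
            n = 60
            for gene in ["folb", "panb"] + ["folk"] * rng.choice([1, 1, 1, 2]):
                pos = rng.randrange(n)
                while pos in labels:
                    pos = rng.randrange(n)
                labels[pos] = gene
            n_folk = sum(1 for v in labels.values() if v == "folk")
            if n_folk >= 2:
                expected_dup += 1
            genes = make_replicon({**{n - 1: labels.get(n - 1)}, **labels},
                                  genome=f"g{gi}")
            calls += classify_folk(genes)
        s = summarize_genomes(calls)
        # genomes where the randomized placement dropped folK entirely
        # (overwritten positions are prevented above, so none)
        assert s["n_genomes"] == n_genomes
        assert s["duplicated_fraction"] == pytest.approx(expected_dup / n_genomes)
        assert sum(s["pattern_fractions"].values()) == pytest.approx(1.0)
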