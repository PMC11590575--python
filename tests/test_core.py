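import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exorcise import (
    Alignment,
    Exon,
    ExonSet,
    GenomeIndex,
    GuideAnnotation,
    GuideLibrary,
    GuideRecord,
    annotate_guide,
    append_pam,
    cut_coordinate,
    exorcise_library,
    find_alignments,
    gene_level_mapping,
    revcomp,
    scan_genome,
)
from conftest import SPACER, naive_find, random_genome


class TestProbe:
    def test_pam_appended_at_three_prime_end(self):
        p = append_pam(SPACER)
        assert p.sequence == SPACER + "NGG"
        assert len(p) == 23

    def test_minimum_spacer_length(self):
        assert len(append_pam("A" * 17)) == 20
        with pytest.raises(ValueError):
            append_pam("A" * 16)

    def test_rna_alphabet_rejected(self):
        with pytest.raises(ValueError):
            append_pam("ACGUACGUACGUACGUACGU")


class TestFindAlignments:
    def test_plus_strand_with_pam_wildcard(self):
        g = GenomeIndex({"c": SPACER + "AGGTT"})
        assert find_alignments(append_pam(SPACER), g) == [
            Alignment("c", 0, 23, "+")
        ]

    def test_minus_strand_match(self):
        g = GenomeIndex({"c": "CCT" + revcomp(SPACER)})
        assert find_alignments(append_pam(SPACER), g) == [
            Alignment("c", 0, 23, "-")
        ]

    def test_genome_n_matches_nothing(self):
        g = GenomeIndex({"c": "N" * 60})
        assert find_alignments(append_pam(SPACER), g) == []
        # even at the PAM wildcard position
        g2 = GenomeIndex({"c": SPACER + "NGGTT"})
        assert find_alignments(append_pam(SPACER), g2) == []

    def test_overlapping_matches_all_reported(self):
        # a homopolymer probe matches at every offset of a homopolymer run
        g = GenomeIndex({"c": "A" * 30})
        hits = find_alignments(append_pam("A" * 17, "AAA"), g)
        assert hits == [Alignment("c", i, i + 20, "+") for i in range(11)]

    @settings(max_examples=30, deadline=None)
    @given(data=st.data())
    def test_matches_naive_oracle_on_random_genomes(self, data):
        seed = data.draw(st.integers(0, 2**31 - 1))
        import numpy as np

        r = np.random.default_rng(seed)
        genome = random_genome(r, max_len=3000)
        L = int(r.integers(17, 22))
        if r.random() < 0.6:
            # plant: lift a window from the genome so true hits occur
            contig = list(genome.contigs)[int(r.integers(0, len(genome)))]
            seq = genome[contig]
            start = int(r.integers(0, max(len(seq) - L, 1)))
            spacer = seq[start : start + L]
            if "N" in spacer or len(spacer) < L:
                spacer = "".join(r.choice(list("ACGT"), L))
        else:
            spacer = "".join(r.choice(list("ACGT"), L))
        probe = append_pam(spacer)
        assert find_alignments(probe, genome) == naive_find(probe.sequence, genome)

    def test_batch_scan_agrees_with_per_probe_search(self, rng):
        genome = random_genome(rng, max_len=5000)
        spacers = set()
        for _ in range(10):
            contig = list(genome.contigs)[int(rng.integers(0, len(genome)))]
            seq = genome[contig]
            i = int(rng.integers(0, max(len(seq) - 20, 1)))
            w = seq[i : i + 20]
            if "N" not in w and len(w) == 20:
                spacers.add(w)
        spacers.add("".join(rng.choice(list("ACGT"), 20)))
        batch = scan_genome(spacers, genome)
        for sp in spacers:
            assert batch[sp] == find_alignments(append_pam(sp), genome)


class TestCutCoordinate:
    @pytest.mark.parametrize(
        "aln,expected",
        [
            (Alignment("c", 0, 23, "+"), 17),
            (Alignment("c", 0, 23, "-"), 6),
            (Alignment("c", 100, 123, "+"), 117),
        ],
    )
    def test_cut_placement(self, aln, expected):
        assert cut_coordinate(aln, 20).coord == expected

    def test_cut_strictly_inside_alignment_span(self, rng):
        genome = random_genome(rng, max_len=4000)
        for _ in range(20):
            contig = list(genome.contigs)[int(rng.integers(0, len(genome)))]
            seq = genome[contig]
            i = int(rng.integers(0, max(len(seq) - 21, 1)))
            sp = seq[i : i + 21]
            if "N" in sp or len(sp) < 21:
                continue
            for a in find_alignments(append_pam(sp), genome):
                c = cut_coordinate(a, 21).coord
                assert a.match_start < c < a.match_end


class TestAnnotateGuide:
    def _cut(self, coord):
        a = Alignment("chr1", coord - 17, coord + 6, "+")
        return cut_coordinate(a, 20)

    def test_interior_cut_annotates_gene(self):
        exo = ExonSet([Exon("chr1", 10, 50, "GENEA")])
        anno = annotate_guide("g", [], [self._cut(17)], exo)
        assert anno.symbols == {"GENEA"}
        assert not anno.is_non_targeting

    def test_flush_cut_is_non_targeting(self):
        # a cut flush with the exon start is a boundary, not an overlap
        exo = ExonSet([Exon("chr1", 10, 50, "GENEA")])
        anno = annotate_guide("g", [], [self._cut(10)], exo)
        assert anno.is_non_targeting

    def test_no_cut_sites_is_non_targeting(self):
        exo = ExonSet([Exon("chr1", 10, 50, "GENEA")])
        assert annotate_guide("g", [], [], exo).is_non_targeting


class TestExorciseLibrary:
    def test_single_guide_annotated(self, toy_genome, toy_exome):
        lib = GuideLibrary([GuideRecord("g1", SPACER, "GENEA")])
        annos = exorcise_library(lib, toy_genome, toy_exome)
        # matches on both contigs: + cut at a:17 inside GENEA, - cut at b:6 inside GENEB
        assert annos[0].symbols == {"GENEA", "GENEB"}
        assert annos[0].n_alignments == 2

    def test_absent_guide_is_non_targeting(self, toy_genome, toy_exome):
        lib = GuideLibrary([GuideRecord("g", "T" * 20, "GENEX")])
        annos = exorcise_library(lib, toy_genome, toy_exome)
        assert annos[0].is_non_targeting and annos[0].n_alignments == 0

    def test_strand_symmetry_of_alignments_and_cuts(self, rng):
        genome = random_genome(rng, max_len=4000)
        mirrored = GenomeIndex({c: revcomp(s) for c, s in genome.items()})
        for _ in range(10):
            contig = list(genome.contigs)[int(rng.integers(0, len(genome)))]
            seq = genome[contig]
            i = int(rng.integers(0, max(len(seq) - 20, 1)))
            sp = seq[i : i + 20]
            if "N" in sp or len(sp) < 20:
                continue
            probe = append_pam(sp)
            fwd = find_alignments(probe, genome)
            rev = find_alignments(probe, mirrored)
            flip = {"+": "-", "-": "+"}
            expect = sorted(
                (
                    Alignment(
                        a.contig,
                        len(genome[a.contig]) - a.match_end,
                        len(genome[a.contig]) - a.match_start,
                        flip[a.strand],
                    )
                    for a in fwd
                ),
                key=lambda a: (a.contig, a.match_start, a.strand),
            )
            assert rev == expect
            # cut coordinates mirror as G - coord
            cuts_f = {(a.contig, cut_coordinate(a, 20).coord) for a in fwd}
            cuts_r = {(a.contig, cut_coordinate(a, 20).coord) for a in rev}
            assert cuts_r == {
                (c, len(genome[c]) - x) for c, x in cuts_f
            }


class TestGeneLevelMapping:
    def _lib_annos(self, original, gene_sets):
        lib = GuideLibrary(
            [
                GuideRecord(f"g{i}", "ACGT" * 5, original)
                for i in range(len(gene_sets))
            ]
        )
        annos = [
            GuideAnnotation(f"g{i}", genes=set(gs)) for i, gs in enumerate(gene_sets)
        ]
        return lib, annos

    def test_most_frequent_candidate_wins(self):
        lib, annos = self._lib_annos(
            "A",
            [{("B", "protein_coding")}, {("B", "protein_coding")}, {("C", "protein_coding")}],
        )
        assert gene_level_mapping(lib, annos).accepted_for("A") == "B"

    def test_tie_prefers_original_symbol(self):
        lib, annos = self._lib_annos(
            "A",
            [
                {("A", "protein_coding")},
                {("A", "protein_coding")},
                {("B", "protein_coding")},
                {("B", "protein_coding")},
            ],
        )
        assert gene_level_mapping(lib, annos).accepted_for("A") == "A"

    def test_tie_falls_through_biotype_hierarchy(self):
        lib, annos = self._lib_annos(
            "A",
            [
                {("B", "protein_coding")},
                {("B", "protein_coding")},
                {("C", "pseudogene")},
                {("C", "pseudogene")},
            ],
        )
        assert gene_level_mapping(lib, annos).accepted_for("A") == "B"

    def test_no_candidates_makes_no_mapping(self):
        lib, annos = self._lib_annos("A", [set(), set()])
        assert gene_level_mapping(lib, annos).entries == {}

    def test_permutation_invariance(self):
        lib, annos = self._lib_annos(
            "A",
            [
                {("B", "protein_coding")},
                {("C", "ncRNA")},
                {("B", "protein_coding")},
                {("D", "pseudogene")},
                {("C", "ncRNA")},
            ],
        )
        baseline = gene_level_mapping(lib, annos).accepted_for("A")
        pairs = list(zip(lib.guides, annos))
        r = random.Random(7)
        for _ in range(20):
            r.shuffle(pairs)
            lib2 = GuideLibrary(g for g, _ in pairs)
            annos2 = [a for _, a in pairs]
            assert gene_level_mapping(lib2, annos2).accepted_for("A") == baseline
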