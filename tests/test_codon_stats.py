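"""Codon usage tables and context matrices: counting, conditioning,
normalization, and TSV round trips."""

import numpy as np
import pytest

from codoncontext import (
    STANDARD_CODE,
    CodingSequence,
    build_context_matrix,
    build_usage_table,
    count_codon_pairs,
    read_matrix,
    write_matrix,
)
from codoncontext.codon_stats import (
    MatrixFormatError,
    read_usage_table,
    write_usage_table,
)


def idx(codon):
    return STANDARD_CODE.sense_codons.index(codon)


class TestCountCodonPairs:
    def test_single_pair(self):
        pairs, counts = count_codon_pairs([CodingSequence("g", "ATGTGT")])
        assert pairs.sum() == 1
        assert pairs[idx("ATG"), idx("TGT")] == 1
        assert counts == {"ATG": 1, "TGT": 1}

    def test_overlapping_adjacent_pairs(self):
        pairs, counts = count_codon_pairs([CodingSequence("g", "ATGTGTTGC")])
        assert pairs[idx("ATG"), idx("TGT")] == 1
        assert pairs[idx("TGT"), idx("TGC")] == 1
        assert pairs.sum() == 2
        assert counts == {"ATG": 1, "TGT": 1, "TGC": 1}

    def test_single_codon_gene_contributes_no_pairs(self):
        pairs, counts = count_codon_pairs([CodingSequence("g", "ATG")])
        assert pairs.sum() == 0
        assert counts == {"ATG": 1}

    def test_pairs_do_not_span_genes(self):
        # Two genes vs their concatenation: the junction pair differs.
        two = count_codon_pairs(
            [CodingSequence("a", "ATGTGT"), CodingSequence("b", "TGCAAA")]
        )[0]
        one = count_codon_pairs([CodingSequence("a", "ATGTGTTGCAAA")])[0]
        assert two.sum() == 2
        assert one.sum() == 3
        assert one[idx("TGT"), idx("TGC")] == 1
        assert two[idx("TGT"), idx("TGC")] == 0

    def test_trailing_stop_never_counted(self):
        pairs, counts = count_codon_pairs([CodingSequence("g", "ATGTGTTAA")])
        assert pairs.sum() == 1
        assert "TAA" not in counts

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="no sequences"):
            count_codon_pairs([])


class TestUsageTable:
    def test_hand_counted_relative_frequencies(self):
        genes = [
            CodingSequence("a", "ATGTGT"),
            CodingSequence("b", "ATGTGT"),
            CodingSequence("c", "ATGTGC"),
        ]
        t = build_usage_table(genes)
        rel = t.rel_freq
        assert rel["TGT"] == pytest.approx(2 / 3)
        assert rel["TGC"] == pytest.approx(1 / 3)
        assert rel["ATG"] == 1.0

    def test_single_codon_amino_acids_always_probability_one(self, small_genome):
        rel = build_usage_table(small_genome).rel_freq
        assert rel["ATG"] == 1.0
        assert rel["TGG"] == 1.0

    def test_per_thousand_sums_to_1000(self, small_genome):
        t = build_usage_table(small_genome)
        assert sum(t.per_thousand.values()) == pytest.approx(1000, abs=1e-6)

    def test_single_gene_single_codon(self):
        t = build_usage_table([CodingSequence("g", "ATG")])
        assert t.per_thousand["ATG"] == pytest.approx(1000)

    def test_rel_freq_sums_to_one_per_observed_group(self, small_genome):
        t = build_usage_table(small_genome)
        rel = t.rel_freq
        for aa, group in STANDARD_CODE.synonym_groups.items():
            if sum(t.counts[c] for c in group) > 0:
                assert sum(rel[c] for c in group) == pytest.approx(1.0, abs=1e-9)

    def test_trailing_stops_tallied_separately(self):
        t = build_usage_table([CodingSequence("g", "ATGTGTTAA")])
        assert t.stop_counts["TAA"] == 1
        assert t.n_codons_total == 2

    def test_round_trip(self, tmp_path, small_genome):
        t = build_usage_table(small_genome, source_label="lbl")
        p = tmp_path / "t.tsv"
        write_usage_table(t, p)
        back = read_usage_table(p)
        assert back.counts == t.counts
        assert back.stop_counts == t.stop_counts
        assert back.source_label == "lbl"


class TestContextMatrix:
    def test_met_cys_sixty_forty(self, met_cys_matrix):
        m = met_cys_matrix
        assert m.P[idx("ATG"), idx("TGT")] == pytest.approx(0.6)
        assert m.P[idx("ATG"), idx("TGC")] == pytest.approx(0.4)

    def test_shape_is_61_by_61_without_stop_codons(self, small_genome_matrix):
        m = small_genome_matrix
        assert m.P.shape == (61, 61)
        assert not set(m.labels) & {"TAA", "TAG", "TGA"}

    def test_single_codon_columns_are_one_where_observed(self, small_genome_matrix):
        m = small_genome_matrix
        for codon in ("ATG", "TGG"):
            col = m.P[:, idx(codon)]
            counts = m.pair_counts[:, idx(codon)]
            observed = counts > 0
            assert observed.any()
            assert np.all(col[observed] == 1.0)

    def test_observed_context_groups_sum_to_one(self, small_genome_matrix):
        m = small_genome_matrix
        for aa, group in STANDARD_CODE.synonym_groups.items():
            cols = [idx(c) for c in group]
            group_counts = m.pair_counts[:, cols].sum(axis=1)
            sums = m.P[:, cols].sum(axis=1)
            assert np.allclose(sums[group_counts > 0], 1.0, atol=1e-9)
            assert np.all(sums[group_counts == 0] == 0.0)

    def test_pair_counts_reproduce_non_initial_codon_counts(self, small_genome):
        m = build_context_matrix(small_genome)
        _, codon_counts = count_codon_pairs(small_genome)
        col_sums = m.pair_counts.sum(axis=0)
        from codoncontext.seq_core import codons_of

        first_codons = [codons_of(s)[0] for s in small_genome]
        for codon in STANDARD_CODE.sense_codons:
            expected = codon_counts.get(codon, 0) - first_codons.count(codon)
            assert col_sums[idx(codon)] == expected

    def test_order_invariance(self, small_genome):
        a = build_context_matrix(small_genome)
        b = build_context_matrix(list(reversed(small_genome)))
        assert np.array_equal(a.P, b.P)
        assert np.array_equal(a.pair_counts, b.pair_counts)

    def test_all_single_codon_genes_is_error(self):
        with pytest.raises(ValueError, match="no codon pairs"):
            build_context_matrix([CodingSequence("g", "ATG")])


class TestMatrixIO:
    def test_lossless_round_trip(self, tmp_path, small_genome_matrix):
        p = tmp_path / "m.tsv"
        write_matrix(small_genome_matrix, p)
        back = read_matrix(p)
        assert np.max(np.abs(back.P - small_genome_matrix.P)) < 1e-12
        assert np.array_equal(back.pair_counts, small_genome_matrix.pair_counts)
        assert back.n_genes == small_genome_matrix.n_genes
        assert back.source_label == small_genome_matrix.source_label

    def test_wrong_label_count_is_format_error(self, tmp_path, small_genome_matrix):
        p = tmp_path / "m.tsv"
        write_matrix(small_genome_matrix, p)
        lines = p.read_text().splitlines()
        # drop one codon column from header and every row
        header = lines[2].split("\t")
        body = [ln.split("\t") for ln in lines[3:]]
        p2 = tmp_path / "bad.tsv"
        p2.write_text(
            "\n".join(
                ["\t".join(header[:-1])] + ["\t".join(row[:-1]) for row in body]
            )
        )
        with pytest.raises(MatrixFormatError):
            read_matrix(p2)

    def test_negative_probability_is_format_error(self, tmp_path, small_genome_matrix):
        p = tmp_path / "m.tsv"
        write_matrix(small_genome_matrix, p)
        text = p.read_text()
        # corrupt the first numeric cell of the first data row
        lines = text.splitlines()
        parts = lines[3].split("\t")
        parts[1] = "-0.5"
        lines[3] = "\t".join(parts)
        bad = tmp_path / "neg.tsv"
        bad.write_text("\n".join(lines))
        with pytest.raises(MatrixFormatError, match="outside"):
            read_matrix(bad)
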