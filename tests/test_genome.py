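"""Genotype containers, haploid calling, marker filtering and table I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lohqtl.genome import (
    ALT,
    AlleleCounts,
    ChromosomeSpec,
    ConfigurationError,
    DiploidGenotype,
    GenotypeTableError,
    HaplotypeVector,
    HetSNPMap,
    NOCALL,
    REF,
    call_haploid_allele,
    combine_parents,
    diploids_to_table,
    filter_linked_markers,
    genotype_fractions,
    read_genotype_table,
    write_genotype_table,
)
from lohqtl.genome import MM, MP, PP


def hap(origins, mat="a", ace2="ACE2"):
    return HaplotypeVector(np.array(origins, dtype=np.int8), mat, ace2)


class TestHaploidCalling:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (2, 98, ALT),  # 0.98 > 0.95
            (100, 0, REF),  # no alternative reads at all
            (5, 95, NOCALL),  # exactly 0.95 is not strictly greater
            (0, 0, NOCALL),  # zero coverage
            (0, 1, ALT),
            (1, 10, NOCALL),
        ],
    )
    def test_threshold_rule(self, ref, alt, expected):
        assert call_haploid_allele(AlleleCounts(ref, alt)) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            AlleleCounts(-1, 5)

    def test_custom_threshold(self):
        assert call_haploid_allele(AlleleCounts(20, 80), threshold=0.75) == ALT


class TestDiploidDeduction:
    def test_distinct_parent_alleles_give_heterozygote(self):
        d = combine_parents(hap([0, 0, 1, 1]), hap([0, 1, 0, 1], mat="alpha"))
        assert list(d.codes) == [MM, MP, MP, PP]

    def test_identical_all_m_parents_fully_homozygous(self):
        d = combine_parents(hap([0] * 6), hap([0] * 6, mat="alpha"))
        assert genotype_fractions(d) == (0.0, 1.0, 0.0)

    def test_unrecombined_parents_reconstruct_heterozygous_parent(self):
        d = combine_parents(hap([0] * 6), hap([1] * 6, mat="alpha"))
        assert genotype_fractions(d) == (1.0, 0.0, 0.0)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            combine_parents(hap([0, 1]), hap([0, 1, 1]))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40).flatmap(
        lambda a: st.tuples(st.just(a), st.lists(st.integers(0, 1), min_size=len(a), max_size=len(a)))
    ))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_fractions_sum_to_one(self, pair):
        a, b = pair
        d1 = combine_parents(hap(a), hap(b, mat="alpha"))
        d2 = combine_parents(hap(b, mat="alpha"), hap(a))
        assert np.array_equal(d1.codes, d2.codes)
        f = genotype_fractions(d1)
        assert sum(f) == pytest.approx(1.0, abs=1e-12)


class TestGenotypeFractions:
    def test_direct_count(self):
        d = DiploidGenotype(np.array([MP, MP, MM, PP], dtype=np.int8))
        assert genotype_fractions(d) == (0.5, 0.25, 0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genotype_fractions(DiploidGenotype(np.array([], dtype=np.int8)))


class TestMarkerFilter:
    def test_map_without_markers_near_loci_is_identity(self):
        chroms = [ChromosomeSpec(3, 400_000, 100_000, {"MAT": 200_000}),
                  ChromosomeSpec(12, 800_000, 150_000, {"ACE2": 520_000}),
                  ChromosomeSpec(7, 700_000, 300_000)]
        ids = [3, 3, 12, 12, 7, 7]
        pos = [10_000, 390_000, 100_000, 700_000, 200_000, 500_000]
        hmap = HetSNPMap(chroms, np.array(ids), np.array(pos))
        idx = filter_linked_markers(hmap)
        assert len(idx) == hmap.n_markers

    def test_exact_offsets_around_mat(self):
        chroms = [ChromosomeSpec(3, 400_000, 100_000, {"MAT": 200_000}),
                  ChromosomeSpec(12, 800_000, 150_000, {"ACE2": 520_000})]
        offsets = [-120_000, -70_000, -50_000, -20_000, -1, 0, 10_000, 49_999, 50_001, 120_000]
        pos = sorted(200_000 + o for o in offsets)
        hmap = HetSNPMap(chroms, np.full(len(pos), 3), np.array(pos))
        kept = filter_linked_markers(hmap)
        inside = [p for p in pos if abs(p - 200_000) <= 50_000]
        assert len(inside) == 6
        assert len(kept) == len(pos) - len(inside)
        assert all(abs(hmap.positions[i] - 200_000) > 50_000 for i in kept)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            chroms = [
                ChromosomeSpec(3, 500_000, 100_000, {"MAT": int(rng.integers(60_000, 440_000))}),
                ChromosomeSpec(12, 900_000, 150_000, {"ACE2": int(rng.integers(80_000, 820_000))}),
                ChromosomeSpec(7, 700_000, 300_000),
            ]
            ids, pos = [], []
            for c in chroms:
                p = np.sort(rng.choice(np.arange(1, c.length), size=40, replace=False))
                ids += [c.id] * 40
                pos += list(p)
            hmap = HetSNPMap(chroms, np.array(ids), np.array(pos))
            kept = set(filter_linked_markers(hmap))
            mat = chroms[0].special_loci["MAT"]
            ace2 = chroms[1].special_loci["ACE2"]
            for i in range(hmap.n_markers):
                c, p = hmap.chrom_ids[i], hmap.positions[i]
                drop = (c == 3 and abs(p - mat) <= 50_000) or (c == 12 and abs(p - ace2) <= 75_000)
                assert (i not in kept) == drop

    def test_missing_locus_is_configuration_error(self):
        chroms = [ChromosomeSpec(3, 400_000, 100_000)]
        hmap = HetSNPMap(chroms, np.array([3, 3]), np.array([10_000, 20_000]))
        with pytest.raises(ConfigurationError):
            filter_linked_markers(hmap)


class TestTableIO:
    def test_round_trip_is_lossless(self, tmp_path, toy_map):
        rng = np.random.default_rng(0)
        strains = [f"s{i}" for i in range(5)]
        table = pd.DataFrame(
            {s: rng.choice(["MM", "MP", "PP"], size=toy_map.n_markers) for s in strains},
            index=toy_map.marker_ids, dtype=object,
        )
        path = tmp_path / "geno.tsv"
        write_genotype_table(path, toy_map, table)
        hmap2, table2 = read_genotype_table(path)
        assert hmap2.marker_ids == toy_map.marker_ids
        assert np.array_equal(hmap2.positions, toy_map.positions)
        assert np.array_equal(hmap2.chrom_ids, toy_map.chrom_ids)
        assert [c.special_loci for c in hmap2.chromosomes] == [c.special_loci for c in toy_map.chromosomes]
        pd.testing.assert_frame_equal(table, table2)
        # write the read-back objects again: byte-identical files
        path2 = tmp_path / "geno2.tsv"
        write_genotype_table(path2, hmap2, table2)
        assert path.read_bytes() == path2.read_bytes()

    def test_unknown_symbol_names_cell(self, tmp_path, toy_map):
        table = pd.DataFrame({"s1": ["MP"] * toy_map.n_markers}, index=toy_map.marker_ids, dtype=object)
        table.iloc[4, 0] = "XX"
        path = tmp_path / "bad.tsv"
        write_genotype_table(path, toy_map, table)
        with pytest.raises(GenotypeTableError, match="'XX'") as exc:
            read_genotype_table(path)
        assert "s1" in str(exc.value)

    def test_map_only_table_is_valid(self, tmp_path, toy_map):
        path = tmp_path / "map.tsv"
        write_genotype_table(path, toy_map)
        hmap2, table2 = read_genotype_table(path)
        assert table2.shape[1] == 0
        assert hmap2.n_markers == toy_map.n_markers

    def test_duplicate_marker_id_rejected(self, tmp_path, toy_map):
        path = tmp_path / "dup.tsv"
        write_genotype_table(path, toy_map)
        text = path.read_text().splitlines()
        # duplicate the first data row's marker id onto the second
        first = text[-toy_map.n_markers].split("\t")
        second = text[-toy_map.n_markers + 1].split("\t")
        second[2] = first[2]
        text[-toy_map.n_markers + 1] = "\t".join(second)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(GenotypeTableError, match="duplicate marker id"):
            read_genotype_table(path)

    def test_unsorted_positions_rejected(self, tmp_path, toy_map):
        path = tmp_path / "unsorted.tsv"
        write_genotype_table(path, toy_map)
        lines = path.read_text().splitlines()
        lines[-1], lines[-2] = lines[-2], lines[-1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(GenotypeTableError, match="sorted"):
            read_genotype_table(path)

    def test_diploids_to_table_round_trip(self, tmp_path, toy_map):
        rng = np.random.default_rng(1)
        dips = [DiploidGenotype(rng.integers(0, 3, toy_map.n_markers).astype(np.int8), f"d{i}")
                for i in range(3)]
        table = diploids_to_table(dips, toy_map)
        assert list(table.columns) == ["d0", "d1", "d2"]
        assert table.iloc[0, 0] in {"MM", "MP", "PP"}
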