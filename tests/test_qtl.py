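"""LOD scan, permutation thresholds, regions, inheritance, PVE, epistasis."""

import numpy as np
import pandas as pd
import pytest

from lohqtl.genome import MM, MP, PP, ChromosomeSpec, HetSNPMap
from lohqtl.qtl import (
    ADDITIVE,
    DOMINANT,
    OVERDOMINANT,
    PermutationSpec,
    ScanResult,
    call_regions,
    classify_inheritance,
    closed_form_single_marker_threshold,
    hk_scan,
    multi_qtl_pve,
    permutation_threshold,
    pve,
    relative_pve,
    scan_2d,
)


def brute_force_lod(g, y):
    """Independent oracle: direct least squares on (1, x, z)."""
    y = np.asarray(y, float)
    x = 1.0 - np.asarray(g, float)
    z = (np.asarray(g) == MP).astype(float)
    X = np.column_stack([np.ones(y.size), x, z])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    return (y.size / 2.0) * np.log10(rss0 / rss1)


class TestScan:
    def test_eight_strain_worked_fixture(self):
        """Staircase phenotype over PP/MP/MM classes: LOD equals the
        brute-force two-predictor fit, which works out to exactly 4."""
        g = np.array([[PP, PP, MP, MP, MP, MP, MM, MM]], dtype=np.int8).T
        y = np.array([1.0, 1, 2, 2, 3, 3, 4, 4])
        scan = hk_scan(g, y)
        assert scan.lod[0] == pytest.approx(brute_force_lod(g[:, 0], y), abs=1e-10)
        assert scan.lod[0] == pytest.approx(4.0, abs=1e-10)
        assert scan.favored[0] == "M"

    def test_scan_equals_brute_force_at_every_marker(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(60, 50)).astype(np.int8)
        y = rng.normal(size=60)
        scan = hk_scan(G, y)
        for m in range(50):
            assert scan.lod[m] == pytest.approx(brute_force_lod(G[:, m], y), abs=1e-8)

    def test_constant_phenotype_gives_zero_lod(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        scan = hk_scan(G, np.full(20, 3.0))
        assert np.all(scan.lod[scan.scanned] == 0.0)

    def test_monomorphic_marker_flagged_not_scored(self):
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, size=(20, 3)).astype(np.int8)
        G[:, 1] = MP
        scan = hk_scan(G, rng.normal(size=20))
        assert not scan.scanned[1]
        assert np.isnan(scan.lod[1])
        assert scan.favored[1] == ""

    def test_perfect_fit_reports_infinite_lod_with_warning(self):
        g = np.array([[PP, PP, MP, MP, MM, MM]], dtype=np.int8).T
        y = np.array([0.0, 0, 1, 1, 2, 2])
        with pytest.warns(UserWarning, match="exactly"):
            scan = hk_scan(g, y)
        assert np.isinf(scan.lod[0])

    def test_favored_allele_follows_high_homozygote(self):
        g = np.array([[MM, MM, MP, MP, PP, PP]], dtype=np.int8).T
        y_up = np.array([5.0, 4, 3.5, 2.5, 2, 1])
        assert hk_scan(g, y_up).favored[0] == "M"
        assert hk_scan(g, -y_up).favored[0] == "P"

    def test_too_few_strains_rejected(self):
        with pytest.raises(ValueError):
            hk_scan(np.zeros((3, 2), dtype=np.int8), np.zeros(3))


class TestPermutationThreshold:
    def test_single_marker_threshold_matches_f_distribution(self):
        """Nearest-rank 95th percentile of permuted max LOD at one marker
        agrees with the closed-form F(2, n-3) value at n = 78."""
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, size=(78, 1)).astype(np.int8)
        y = rng.normal(size=78)
        thr, runs = permutation_threshold(G, y, PermutationSpec(n_iterations=5000, n_runs=3), rng=4)
        assert thr == pytest.approx(closed_form_single_marker_threshold(78), abs=0.1)
        assert len(runs) == 3

    def test_invariant_to_marker_order_and_duplication(self):
        rng = np.random.default_rng(5)
        G = rng.integers(0, 3, size=(40, 8)).astype(np.int8)
        y = rng.normal(size=40)
        spec = PermutationSpec(n_iterations=500, n_runs=2)
        t1, _ = permutation_threshold(G, y, spec, rng=6)
        t2, _ = permutation_threshold(G[:, ::-1], y, spec, rng=6)
        t3, _ = permutation_threshold(np.hstack([G, G]), y, spec, rng=6)
        assert t1 == t2 == t3

    def test_threshold_decreases_as_alpha_increases(self):
        rng = np.random.default_rng(7)
        G = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        y = rng.normal(size=50)
        t_strict, _ = permutation_threshold(G, y, PermutationSpec(n_iterations=800, n_runs=1, alpha=0.05), rng=8)
        t_loose, _ = permutation_threshold(G, y, PermutationSpec(n_iterations=800, n_runs=1, alpha=0.20), rng=8)
        assert t_loose < t_strict


def synthetic_scan(lods, chrom_len=1_000_000):
    chroms = [ChromosomeSpec(3, chrom_len, 100, {"MAT": 50}),
              ChromosomeSpec(12, chrom_len, 100, {"ACE2": 50})]
    n = len(lods)
    hmap = HetSNPMap(chroms, np.full(n, 3), np.arange(1, n + 1) * 1000)
    scan = ScanResult(
        lod=np.asarray(lods, float),
        favored=np.array(["M"] * n, dtype=object),
        scanned=np.ones(n, dtype=bool),
        n_strains=78,
    )
    return scan, hmap


class TestRegions:
    def test_no_marker_above_threshold_gives_empty_list(self):
        scan, hmap = synthetic_scan([1.0, 2.0, 3.0])
        assert call_regions(scan, 4.11, hmap) == []

    def test_two_regions_from_brute_force_profile(self):
        scan, hmap = synthetic_scan([1.0, 5.0, 5.0, 1.0, 6.0])
        regions = call_regions(scan, 4.11, hmap)
        assert len(regions) == 2
        assert (regions[0].start_index, regions[0].end_index) == (1, 2)
        assert (regions[1].start_index, regions[1].end_index) == (4, 4)
        assert regions[1].peak_lod == 6.0

    def test_peak_tie_breaks_leftmost(self):
        scan, hmap = synthetic_scan([5.0, 5.0, 4.5])
        regions = call_regions(scan, 4.11, hmap)
        assert regions[0].peak_index == 0

    def test_gap_option_bridges_single_dip(self):
        scan, hmap = synthetic_scan([5.0, 1.0, 5.0])
        assert len(call_regions(scan, 4.11, hmap, gap=0)) == 2
        bridged = call_regions(scan, 4.11, hmap, gap=1)
        assert len(bridged) == 1
        assert (bridged[0].start_index, bridged[0].end_index) == (0, 2)


def three_class_phenotype(mean_mm, mean_mp, mean_pp, n_per=6, sd=0.15, seed=0):
    rng = np.random.default_rng(seed)
    codes = np.array([MM] * n_per + [MP] * n_per + [PP] * n_per, dtype=np.int8)
    y = np.concatenate([
        rng.normal(mean_mm, sd, n_per),
        rng.normal(mean_mp, sd, n_per),
        rng.normal(mean_pp, sd, n_per),
    ])
    return y, codes


class TestInheritanceClassification:
    def test_intermediate_heterozygote_is_additive(self):
        y, codes = three_class_phenotype(4.0, 2.0, 0.0)
        assert classify_inheritance(y, codes) == ADDITIVE

    def test_heterozygote_matching_one_homozygote_is_dominant(self):
        y, codes = three_class_phenotype(4.0, 4.0, 0.0)
        assert classify_inheritance(y, codes) == DOMINANT

    def test_heterozygote_outside_homozygote_range_is_overdominant(self):
        y, codes = three_class_phenotype(1.0, 5.0, 1.0)
        assert classify_inheritance(y, codes) == OVERDOMINANT

    def test_missing_class_returns_none(self):
        y = np.arange(10.0)
        codes = np.array([MM] * 5 + [MP] * 5, dtype=np.int8)
        assert classify_inheritance(y, codes) is None

    def test_indistinct_classes_default_to_additive(self):
        y, codes = three_class_phenotype(1.0, 1.0, 1.0, sd=1.0)
        assert classify_inheritance(y, codes) == ADDITIVE


class TestPVE:
    def test_phenotype_equal_to_additive_code_gives_full_pve(self):
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 3, 30).astype(np.int8)
        y = 1.0 - codes
        assert pve(y, codes) == pytest.approx(100.0, abs=1e-9)

    def test_independent_phenotype_gives_small_pve(self):
        rng = np.random.default_rng(10)
        codes = rng.integers(0, 3, 400).astype(np.int8)
        y = rng.normal(size=400)
        assert pve(y, codes) < 3.0  # expectation ~ 100 * 2/(n-1) = 0.5

    def test_pve_bounds_and_relative_normalisation(self):
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(5):
            codes = rng.integers(0, 3, 50).astype(np.int8)
            y = (1.0 - codes) * 0.5 + rng.normal(size=50)
            v = pve(y, codes)
            assert 0.0 <= v <= 100.0
            vals.append(v)
        rel = relative_pve(vals)
        assert max(rel) == 1.0
        assert all(0 <= r <= 1 for r in rel)

    def test_joint_pve_adds_for_orthogonal_loci_not_for_correlated(self):
        rng = np.random.default_rng(12)
        n = 300
        g1 = rng.integers(0, 3, n).astype(np.int8)
        g2 = rng.integers(0, 3, n).astype(np.int8)
        y = (1.0 - g1) + (1.0 - g2) + rng.normal(0, 0.8, n)
        p1, p2 = pve(y, g1), pve(y, g2)
        joint_orth, kept = multi_qtl_pve(np.column_stack([g1, g2]), y)
        assert kept == [0, 1]
        assert joint_orth == pytest.approx(p1 + p2, abs=3.0)
        # a duplicated locus adds nothing: joint stays near the single PVE
        joint_dup, kept_dup = multi_qtl_pve(np.column_stack([g1, g1]), y)
        assert joint_dup < p1 + p1 - 5.0

    def test_forward_selection_drops_noise_locus(self):
        rng = np.random.default_rng(13)
        n = 200
        g1 = rng.integers(0, 3, n).astype(np.int8)
        g_noise = rng.integers(0, 3, n).astype(np.int8)
        y = (1.0 - g1) * 1.2 + rng.normal(size=n)
        joint, kept = multi_qtl_pve(np.column_stack([g1, g_noise]), y)
        assert kept == [0]

    def test_fewer_strains_than_parameters_rejected(self):
        with pytest.raises(ValueError):
            pve(np.array([1.0, 2.0, 3.0]), np.array([MM, MP, PP], dtype=np.int8))


class TestTwoDimensionalScan:
    def make_map(self, n_per_chrom=4):
        chroms = [ChromosomeSpec(1, 500_000, 100, {}), ChromosomeSpec(2, 500_000, 100, {}),
                  ChromosomeSpec(3, 500_000, 100, {"MAT": 50}), ChromosomeSpec(12, 500_000, 100, {"ACE2": 50})]
        ids, pos = [], []
        for c in chroms:
            ids += [c.id] * n_per_chrom
            pos += [(k + 1) * 10_000 for k in range(n_per_chrom)]
        return HetSNPMap(chroms, np.array(ids), np.array(pos))

    def test_pure_additive_pair_has_no_interaction_lod(self):
        hmap = self.make_map()
        rng = np.random.default_rng(14)
        G = rng.integers(0, 3, size=(120, hmap.n_markers)).astype(np.int8)
        y = (1.0 - G[:, 0]) + (1.0 - G[:, 4]) + rng.normal(0, 0.2, 120)
        out = scan_2d(G, y, hmap, decimation=1)
        row = out[(out.marker_i == 0) & (out.marker_j == 4)].iloc[0]
        # no planted product term: interaction LOD stays at null scale
        # (E[LOD] = df/(2 ln 10) ~ 0.9 for the 4 extra parameters)
        assert row.interaction_lod < 2.5

    def test_planted_product_interaction_is_top_pair(self):
        hmap = self.make_map()
        rng = np.random.default_rng(15)
        G = rng.integers(0, 3, size=(150, hmap.n_markers)).astype(np.int8)
        y = 2.0 * (1.0 - G[:, 1]) * (1.0 - G[:, 5]) + rng.normal(0, 0.5, 150)
        out = scan_2d(G, y, hmap, decimation=1)
        top = out.loc[out.interaction_lod.idxmax()]
        assert (top.marker_i, top.marker_j) == (1, 5)

    def test_same_chromosome_pairs_skipped(self):
        hmap = self.make_map()
        rng = np.random.default_rng(16)
        G = rng.integers(0, 3, size=(50, hmap.n_markers)).astype(np.int8)
        out = scan_2d(G, rng.normal(size=50), hmap, decimation=1)
        ci = hmap.chrom_ids[out.marker_i.to_numpy()]
        cj = hmap.chrom_ids[out.marker_j.to_numpy()]
        assert np.all(ci != cj)
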