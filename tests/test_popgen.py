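import numpy as np
import pytest
from scipy.stats import hypergeom

from nichepop.popgen import (
    GenotypeMatrix,
    centroid_distances,
    diagnostic_snps,
    filter_snps,
    heterozygosity_percent,
    pairwise_fst,
    pairwise_kinship,
    ritland_kinship,
    spatial_autocorrelation,
    wc_theta,
)
from nichepop.geo_core import haversine_km
from nichepop.synthetic_data import SimConfig, gen_genotypes

NAN = np.nan


def make_gm(dosages, groups=None, coords=None):
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(
        d,
        [f"i{k}" for k in range(d.shape[0])],
        [f"l{k}" for k in range(d.shape[1])],
        groups,
        coords,
    )


class TestFilterSnps:
    @pytest.fixture
    def toy(self):
        # 6 individuals x 5 loci, hand-designed:
        # l0: 1/6 missing (16.7% > 10%)                        -> dropped (missingness)
        # l1: MAF exactly 0.05 is impossible with 12 alleles; use 1/12 = 0.083 > 0.05 kept
        # l2: monomorphic (MAF 0)                              -> dropped (MAF <= 0.05)
        # l3: MAF 0.5                                          -> kept
        # l4: no missing, MAF 1/12                             -> kept
        return make_gm([
            [NAN, 0, 0, 0, 0],
            [0,   0, 0, 1, 0],
            [0,   0, 0, 1, 0],
            [0,   0, 0, 1, 0],
            [0,   0, 0, 1, 1],
            [0,   1, 0, 2, 0],
        ])

    def test_hand_enumerated_survivors(self, toy):
        filtered, report = filter_snps(toy)
        assert filtered.locus_ids == ["l1", "l3", "l4"]
        assert report["dropped_missingness"] == 1
        assert report["dropped_maf"] == 1
        assert report["n_retained"] == 3

    def test_maf_boundary_is_strict_less_equal(self):
        # 10 individuals, 20 alleles: 1 alt -> MAF 0.05 exactly -> dropped
        col_005 = [1] + [0] * 9
        # 2 alt alleles in 20 -> MAF 0.10 -> kept
        col_010 = [1, 1] + [0] * 8
        gm = make_gm(np.column_stack([col_005, col_010]))
        filtered, _ = filter_snps(gm, min_maf=0.05)
        assert filtered.locus_ids == ["l1"]

    def test_permissive_thresholds_drop_only_monomorphic(self):
        gm = make_gm([[0, 1, NAN], [0, 1, NAN], [0, 2, NAN]])
        filtered, _ = filter_snps(gm, max_missing=1.0, min_maf=0.0)
        assert filtered.locus_ids == ["l1"]  # l0 monomorphic, l2 all-missing

    def test_all_monomorphic_warns_empty(self):
        gm = make_gm([[0, 2], [0, 2]])
        with pytest.warns(UserWarning, match="all loci removed"):
            filtered, report = filter_snps(gm)
        assert filtered.n_loci == 0
        assert report["n_retained"] == 0

    def test_idempotent(self):
        gm, _ = gen_genotypes(SimConfig(seed=1, n_individuals=20, n_loci=200,
                                        missing_fraction=0.05))
        once, _ = filter_snps(gm)
        twice, rep = filter_snps(once)
        assert twice.locus_ids == once.locus_ids
        assert rep["dropped_missingness"] == 0 and rep["dropped_maf"] == 0


class TestHeterozygosity:
    def test_fraction_of_called_loci(self):
        row = [1, 1] + [0] * 48
        gm = make_gm([row])
        assert heterozygosity_percent(gm).iloc[0] == pytest.approx(4.0)

    def test_all_missing_reported_nan(self):
        gm = make_gm([[NAN, NAN], [0, 1]])
        het = heterozygosity_percent(gm)
        assert np.isnan(het.iloc[0])
        assert het.iloc[1] == pytest.approx(50.0)

    def test_f1_between_fixed_parents_is_ten_percent(self):
        # 100 diagnostic loci het + 900 monomorphic hom -> 10%
        f1 = [1] * 100 + [0] * 900
        gm = make_gm([f1])
        assert heterozygosity_percent(gm).iloc[0] == pytest.approx(10.0)


class TestDiagnosticSnps:
    def test_fixed_difference_20v20_below_threshold(self):
        # 10 diploids per group, fixed alternate alleles
        d = [[0]] * 10 + [[2]] * 10
        gm = make_gm(d, groups=["a"] * 10 + ["b"] * 10)
        keep, pvals = diagnostic_snps(gm, "a", "b")
        assert keep[0]
        # exact hypergeometric oracle: point probability of the observed table
        point = hypergeom.pmf(20, 40, 20, 20)
        assert point == pytest.approx(1.0 / 137846528820.0 * 1.0, rel=1e-6)
        assert pvals.iloc[0] < 5e-8
        assert pvals.iloc[0] >= point  # two-sided p can't be below the point prob

    def test_identical_frequencies_excluded(self):
        d = [[1]] * 6 + [[1]] * 6
        gm = make_gm(d, groups=["a"] * 6 + ["b"] * 6)
        keep, pvals = diagnostic_snps(gm, "a", "b")
        assert not keep[0]
        assert pvals.iloc[0] == pytest.approx(1.0)

    def test_small_fixed_difference_not_significant(self):
        # 4 alleles per group (2 diploids), fixed: enumerating the 2x2 tables
        # with margins (4,4),(4,4) gives two-sided p = 2/C(8,4) = 1/35
        d = [[0], [0], [2], [2]]
        gm = make_gm(d, groups=["a", "a", "b", "b"])
        keep, pvals = diagnostic_snps(gm, "a", "b")
        assert pvals.iloc[0] == pytest.approx(2.0 / 70.0)
        assert not keep[0]

    def test_monomorphic_locus_never_retained(self):
        d = [[2]] * 4 + [[2]] * 4
        gm = make_gm(d, groups=["a"] * 4 + ["b"] * 4)
        keep, pvals = diagnostic_snps(gm, "a", "b")
        assert not keep[0] and pvals.iloc[0] == 1.0


class TestRitlandKinship:
    @pytest.mark.parametrize(
        "gi,gj,expected",
        [
            ([2], [2], 1.0),   # both homozygous reference-counted allele at p=0.5
            ([2], [0], -1.0),  # opposite homozygotes
            ([2], [1], 0.0),   # homozygote vs heterozygote
            ([0], [0], 1.0),   # both homozygous for the other allele
        ],
    )
    def test_hand_evaluated_single_locus(self, gi, gj, expected):
        assert ritland_kinship(gi, gj, [0.5]) == pytest.approx(expected)

    def test_no_usable_locus_nan(self):
        assert np.isnan(ritland_kinship([NAN], [1], [0.5]))
        assert np.isnan(ritland_kinship([1], [1], [1.0]))

    def test_unbiased_for_unrelated_pairs(self):
        """Mean kinship of unrelated HWE pairs with known p: within 0.01 of 0."""
        rng = np.random.default_rng(10)
        n_loci = 10_000
        p = rng.uniform(0.1, 0.9, n_loci)
        acc = []
        for _ in range(20):
            gi = rng.binomial(2, p).astype(float)
            gj = rng.binomial(2, p).astype(float)
            acc.append(ritland_kinship(gi, gj, p))
        assert abs(np.mean(acc)) < 0.01

    def test_matrix_matches_scalar(self):
        gm, _ = gen_genotypes(SimConfig(seed=2, n_individuals=5, n_loci=100))
        p = gm.allele_freq()
        mat = pairwise_kinship(gm)
        expected = ritland_kinship(gm.dosages[0], gm.dosages[3], p)
        assert mat[0, 3] == pytest.approx(expected)
        assert mat[3, 0] == pytest.approx(expected)


class TestSpatialAutocorrelation:
    def test_equal_count_binning(self):
        rng = np.random.default_rng(3)
        gm, _ = gen_genotypes(SimConfig(seed=3, n_populations=1, n_individuals=5,
                                        n_loci=50))
        prof = spatial_autocorrelation(gm, n_classes=2, n_permutations=5, seed=1)
        assert prof.pair_counts.tolist() == [5, 5]

    def test_envelope_coverage_under_independence(self):
        """Location-independent genotypes: class means inside the 95% envelope
        ~95% of the time."""
        inside = total = 0
        for seed in range(25):
            gm, _ = gen_genotypes(SimConfig(seed=4000 + seed, n_populations=1,
                                            n_individuals=30, n_loci=150,
                                            pop_spread_km=300.0))
            prof = spatial_autocorrelation(gm, n_classes=10, n_permutations=100,
                                           seed=seed)
            inside += int(((prof.mean_kinship >= prof.envelope_low)
                           & (prof.mean_kinship <= prof.envelope_high)).sum())
            total += 10
        assert 0.90 <= inside / total <= 0.99

    def test_ibd_kinship_decays_over_first_classes(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            gm, _ = gen_genotypes(SimConfig(seed=5000 + seed, n_populations=4,
                                            n_individuals=20, n_loci=300,
                                            target_fst=0.15, ibd_strength=0.8,
                                            pop_distance_km=300.0,
                                            pop_spread_km=100.0))
            prof = spatial_autocorrelation(gm, n_classes=10, n_permutations=5,
                                           seed=seed)
            k = prof.mean_kinship
            if k[0] > k[1] > k[2]:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_missing_coordinates_rejected(self):
        gm = make_gm([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="coordinates"):
            spatial_autocorrelation(gm, n_classes=1, n_permutations=2)


class TestFst:
    def test_fixed_alternate_groups_theta_one(self):
        d = [[0, 0, 0]] * 5 + [[2, 2, 2]] * 5
        gm = make_gm(d, groups=["a"] * 5 + ["b"] * 5)
        fst = pairwise_fst(gm)
        assert fst.theta[0, 1] == pytest.approx(1.0)

    def test_panmictic_groups_theta_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, 1000)
        d = rng.binomial(2, p, size=(100, 1000)).astype(float)
        gm = make_gm(d, groups=["a"] * 50 + ["b"] * 50)
        fst = pairwise_fst(gm)
        assert abs(fst.theta[0, 1]) < 0.02

    def test_balding_nichols_target_recovery(self):
        gm, _ = gen_genotypes(SimConfig(seed=11, n_populations=2, n_individuals=50,
                                        n_loci=1000, target_fst=0.2))
        fst = pairwise_fst(gm)
        assert fst.theta[0, 1] == pytest.approx(0.2, abs=0.05)

    def test_against_independent_wc84_oracle(self):
        """Ratio-of-sums theta equals a hand-coded per-locus WC84 on 20 loci."""
        rng = np.random.default_rng(12)
        d1 = rng.binomial(2, 0.3, size=(15, 20)).astype(float)
        d2 = rng.binomial(2, 0.7, size=(12, 20)).astype(float)

        def oracle(c1, c2):
            # direct transcription of the two-population variance components
            n1, n2 = len(c1), len(c2)
            p1, p2 = c1.mean() / 2, c2.mean() / 2
            h1, h2 = (c1 == 1).mean(), (c2 == 1).mean()
            r = 2
            nbar = (n1 + n2) / 2
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                       - hbar * (2 * nbar - 1) / (4 * nbar))
            c = hbar / 2
            return a, b, c

        num = den = 0.0
        for j in range(20):
            pbar = (d1[:, j].sum() + d2[:, j].sum()) / (2 * (len(d1) + len(d2)))
            if pbar in (0.0, 1.0):
                continue
            a, b, c = oracle(d1[:, j], d2[:, j])
            num += a
            den += a + b + c
        theta, n_used = wc_theta(d1, d2)
        assert theta == pytest.approx(num / den, abs=1e-12)

    def test_allele_label_swap_invariance(self):
        gm, _ = gen_genotypes(SimConfig(seed=13, n_populations=2, n_individuals=20,
                                        n_loci=100))
        t1 = pairwise_fst(gm).theta[0, 1]
        swapped = make_gm(2.0 - gm.dosages, groups=list(gm.groups))
        t2 = pairwise_fst(swapped).theta[0, 1]
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_all_monomorphic_pair_undefined(self):
        gm = make_gm([[0], [0], [0], [0]], groups=["a", "a", "b", "b"])
        fst = pairwise_fst(gm)
        assert np.isnan(fst.theta[0, 1])
        assert fst.n_loci_used[0, 1] == 0


class TestCentroids:
    def test_symmetric_points_equal_distance(self):
        coords = np.array([[0.0, 1.0], [0.0, -1.0]])
        gm = make_gm([[0], [0]], groups=["c", "c"], coords=coords)
        members, cents = centroid_distances(gm)
        d = members["distance_km"].to_numpy()
        assert d[0] == pytest.approx(d[1])

    def test_singleton_cluster_zero_flagged(self):
        coords = np.array([[5.0, 5.0]])
        gm = make_gm([[0]], groups=["solo"], coords=coords)
        members, _ = centroid_distances(gm)
        assert members["distance_km"].iloc[0] == 0.0
        assert members["singleton"].iloc[0]

    def test_three_point_toy_matches_hand_centroid(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 3.0]])
        gm = make_gm([[0]] * 3, groups=["c"] * 3, coords=coords)
        members, cents = centroid_distances(gm)
        centroid = (1.0, 1.0)  # coordinate-wise mean
        assert cents.loc["c", "lon"] == pytest.approx(1.0)
        assert cents.loc["c", "lat"] == pytest.approx(1.0)
        for i, pt in enumerate(coords):
            assert members["distance_km"].iloc[i] == pytest.approx(
                haversine_km(tuple(pt), centroid)
            )
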