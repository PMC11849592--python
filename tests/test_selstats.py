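"""SFS statistics: brute-force oracles, algebraic identities, calibration."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from paleoselect.selstats import (
    HaplotypeMatrix,
    PolarisationError,
    diversity_summary,
    fst,
    fu_li_constants,
    fu_li_d,
    fu_li_f,
    haplotype_partition,
    hwe_exact,
    sliding_tajima,
    tajima_constants,
    tajimas_d,
)
from conftest import msprime_sample, random_haplotype_matrix


def hm(rows, positions=None, polarised=True):
    rows = np.asarray(rows, dtype=np.int8)
    positions = (
        np.arange(1, rows.shape[1] + 1) * 10 if positions is None else positions
    )
    return HaplotypeMatrix(rows, positions, polarised=polarised)


def brute_force_summary(h):
    """Independent oracle: all-pairs Hamming differences, column counts."""
    a = h.alleles
    n = a.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    pi = np.mean([(a[i] != a[j]).sum() for i, j in pairs]) if pairs else 0.0
    counts = a.sum(axis=0)
    S = int(((counts > 0) & (counts < n)).sum())
    eta_e = int((counts == 1).sum())
    return S, eta_e, float(pi)


class TestDiversitySummary:
    def test_identical_haplotypes(self):
        s = diversity_summary(hm([[0, 0, 0], [0, 0, 0]]))
        assert s.S == 0 and s.pi == 0

    def test_hand_counted_three_haplotypes(self):
        # pairs differ by 2, 1, 1 -> pi = 4/3
        s = diversity_summary(hm([[0, 0, 0], [0, 1, 1], [0, 0, 1]]))
        assert s.S == 2
        assert s.pi == pytest.approx(4 / 3)
        assert s.eta_e == 1

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(200):
            h = random_haplotype_matrix(rng)
            s = diversity_summary(h)
            S, eta_e, pi = brute_force_summary(h)
            assert s.S == S
            assert s.eta_e == eta_e
            assert s.pi == pytest.approx(pi, rel=1e-12)

    def test_unpolarised_input_has_no_eta_e(self):
        s = diversity_summary(hm([[0, 1], [1, 0]], polarised=False))
        assert s.eta_e is None

    def test_missing_sites_dropped_complete_case(self):
        h = hm([[0, -1, 1], [1, 0, 0], [0, 0, 1]])
        s = diversity_summary(h)
        assert s.S == 2  # middle column excluded


class TestTajimasD:
    def test_two_haplotypes_identity_zero(self):
        assert tajimas_d(hm([[0, 1, 0], [1, 0, 1]])).value == 0.0

    def test_no_segregating_sites_undefined(self):
        res = tajimas_d(hm([[0, 0], [0, 0], [0, 0], [0, 0]]))
        assert res.value is None

    def test_matches_step_by_step_constants_oracle(self, rng):
        """Re-derive D from first principles on a random 6 x 10 matrix."""
        h = random_haplotype_matrix(rng, max_n=6, max_sites=10)
        while diversity_summary(h).S == 0 or h.n_haplotypes < 4:
            h = random_haplotype_matrix(rng, max_n=6, max_sites=10)
        n = h.n_haplotypes
        S, _, pi = brute_force_summary(h)
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        expected = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajimas_d(h).value == pytest.approx(expected, rel=1e-12)

    def test_matches_tskit_on_coalescent_samples(self):
        """Independent implementation check against tskit's Tajima's D."""
        for seed in (11, 29, 47):
            h, ts = msprime_sample(20, seed)
            ours = tajimas_d(h).value
            theirs = float(ts.Tajimas_D())
            assert ours == pytest.approx(theirs, rel=1e-6)

    def test_label_invariance(self, rng):
        h = random_haplotype_matrix(rng, max_n=10, max_sites=20)
        perm = rng.permutation(h.n_haplotypes)
        assert tajimas_d(h).value == tajimas_d(h.subset_haplotypes(perm)).value

    def test_singleton_excess_drives_d_negative(self):
        # star-like: every mutation private to one haplotype
        n, s_per = 12, 3
        rows = np.zeros((n, n * s_per), dtype=np.int8)
        for i in range(n):
            rows[i, i * s_per : (i + 1) * s_per] = 1
        res = tajimas_d(hm(rows))
        assert res.value < 0


class TestFuLi:
    def test_numerator_identity_gives_zero(self):
        # n = 4: a1 = 11/6; eta = 11 with eta_e = 6 makes eta = a1 * eta_e
        n = 4
        cols = []
        for i in range(6):  # 6 singletons spread over haplotypes
            col = np.zeros(n, dtype=np.int8)
            col[i % n] = 1
            cols.append(col)
        for _ in range(5):  # 5 doubletons
            col = np.zeros(n, dtype=np.int8)
            col[[0, 1]] = 1
            cols.append(col)
        h = hm(np.stack(cols, axis=1))
        s = diversity_summary(h)
        assert s.eta == 11 and s.eta_e == 6
        assert fu_li_d(h).value == pytest.approx(0.0, abs=1e-12)

    def test_star_matrix_negative_d(self):
        n = 20
        rows = np.eye(n, dtype=np.int8)
        assert fu_li_d(hm(rows)).value < 0

    def test_unpolarised_rejected(self):
        with pytest.raises(PolarisationError):
            fu_li_d(hm([[0, 1], [1, 0], [1, 1], [0, 0]], polarised=False))

    def test_constants_against_direct_formula(self):
        c = fu_li_constants(10)
        an = sum(1 / i for i in range(1, 10))
        bn = sum(1 / i**2 for i in range(1, 10))
        cn = 2 * (10 * an - 2 * 9) / (9 * 8)
        v_d = 1 + an**2 / (bn + an**2) * (cn - 11 / 9)
        assert c["v_d"] == pytest.approx(v_d, rel=1e-12)
        assert c["u_d"] == pytest.approx(an - 1 - v_d, rel=1e-12)

    def test_neutral_means_near_zero(self):
        """Mean D and F over neutral coalescent samples stay in the
        documented neutral band."""
        ds, fs = [], []
        for seed in range(1, 201):
            h, _ = msprime_sample(20, 7000 + seed, theta=5.0)
            if diversity_summary(h).S == 0:
                continue
            ds.append(fu_li_d(h).value)
            fs.append(fu_li_f(h).value)
        assert -0.3 <= np.mean(ds) <= 0.15
        assert -0.3 <= np.mean(fs) <= 0.15

    def test_simulated_significance_is_calibrated_under_null(self):
        hits = total = 0
        for seed in range(1, 61):
            h, _ = msprime_sample(15, 9000 + seed, theta=5.0)
            if diversity_summary(h).S == 0:
                continue
            res = fu_li_d(h, significance="simulated", n_reps=400, seed=5)
            total += 1
            hits += res.p_value < 0.05
        assert hits / total <= 0.12


class TestHaplotypePartition:
    def test_split_sizes(self):
        h = hm([[0, 1], [1, 0], [0, 1], [1, 1], [0, 0]], positions=[10, 20])
        car, non = haplotype_partition(h, 10, 1)
        assert car.n_haplotypes == 2 and non.n_haplotypes == 3
        assert car.n_haplotypes + non.n_haplotypes == h.n_haplotypes

    def test_focal_column_excluded(self):
        h = hm([[0, 1], [1, 0], [0, 1], [1, 1]], positions=[10, 20])
        car, non = haplotype_partition(h, 10, 1)
        assert list(car.positions) == [20] == list(non.positions)

    def test_all_carriers_leaves_empty_class(self):
        h = hm([[1, 0], [1, 1], [1, 0], [1, 1]], positions=[10, 20])
        car, non = haplotype_partition(h, 10, 1)
        assert non.n_haplotypes == 0

    def test_merged_classes_reproduce_classic_statistic(self, rng):
        h = random_haplotype_matrix(rng, max_n=12, max_sites=20)
        while h.n_sites < 3:
            h = random_haplotype_matrix(rng, max_n=12, max_sites=20)
        focal = int(h.positions[h.n_sites // 2])
        car, non = haplotype_partition(h, focal, 1)
        merged = HaplotypeMatrix(
            np.vstack([car.alleles, non.alleles]), car.positions, True
        )
        mask = h.positions != focal
        full = h.subset_sites(mask)
        a = diversity_summary(merged)
        b = diversity_summary(full)
        assert (a.S, a.eta_e) == (b.S, b.eta_e)
        assert a.pi == pytest.approx(b.pi, rel=1e-12)


class TestSlidingTajima:
    def test_uniform_matrix_all_undefined(self):
        h = hm(np.zeros((6, 5), dtype=np.int8), positions=[10, 20, 30, 40, 5000])
        windows = sliding_tajima(h, window_bp=1000, step_bp=500)
        assert windows and all(w[2].value is None for w in windows)

    def test_single_window_equals_full_statistic(self, rng):
        h = random_haplotype_matrix(rng, max_n=10, max_sites=20)
        span = (int(h.positions[0]), int(h.positions[-1]) + 1)
        windows = sliding_tajima(
            h, window_bp=span[1] - span[0], step_bp=10**6, region=span
        )
        assert len(windows) == 1
        assert windows[0][2].value == tajimas_d(h).value

    def test_oversized_window_rejected(self):
        h = hm([[0, 1], [1, 0]], positions=[10, 20])
        with pytest.raises(ValueError):
            sliding_tajima(h, window_bp=10_000, step_bp=100, region=(10, 21))


class TestFst:
    def test_identical_frequencies_zero(self):
        assert fst([20], [100], [20], [100]) == pytest.approx(0.0, abs=1e-9)

    def test_fixed_difference_one(self):
        assert fst([0], [50], [50], [50]) == pytest.approx(1.0)

    def test_hand_evaluated_hudson_formula(self):
        p1, p2, n1, n2 = 0.2, 0.8, 50, 50
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / 49 - p2 * (1 - p2) / 49
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert fst([10], [50], [40], [50]) == pytest.approx(num / den, rel=1e-9)

    def test_monomorphic_everywhere_undefined(self):
        assert fst([0, 50], [50, 50], [0, 50], [50, 50]) is None

    def test_ratio_of_averages_not_average_of_ratios(self):
        k1, n1 = [10, 1], [50, 50]
        k2, n2 = [40, 2], [50, 50]
        multi = fst(k1, n1, k2, n2)
        per_site = [fst([a], [b], [c], [d]) for a, b, c, d in zip(k1, n1, k2, n2)]
        nums, dens = [], []
        for a, b, c, d in zip(k1, n1, k2, n2):
            p1, p2 = a / b, c / d
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (b - 1) - p2 * (1 - p2) / (d - 1)
            dens.append(p1 * (1 - p2) + p2 * (1 - p1))
            nums.append(num)
        assert multi == pytest.approx(np.mean(nums) / np.mean(dens), rel=1e-9)
        assert multi != pytest.approx(np.mean(per_site), rel=1e-3)

    def test_wc_estimator_available_and_bounded(self):
        value = fst([10], [50], [40], [50], estimator="wc")
        assert 0 < value <= 1


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Full enumeration over heterozygote counts with fixed allele counts."""
    N = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    probs = {}
    for h in range(na % 2, min(na, 2 * N - na) + 1, 2):
        aa = (na - h) // 2
        AA = N - aa - h
        if AA < 0:
            continue
        p = (
            math.factorial(N)
            / (math.factorial(AA) * math.factorial(h) * math.factorial(aa))
            * 2**h
            * math.factorial(na)
            * math.factorial(2 * N - na)
            / math.factorial(2 * N)
        )
        probs[h] = p
    obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-9))


class TestHWE:
    def test_monomorphic_sample(self):
        assert hwe_exact(5, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts", [(1, 0, 1), (5, 2, 5), (10, 1, 0), (3, 7, 2), (0, 10, 0)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-9
        )

    def test_p_roughly_uniform_under_hwe(self, rng):
        """Under random mating the exact test p-values are close to uniform
        (conservative discreteness aside)."""
        ps = []
        for _ in range(400):
            p = rng.uniform(0.2, 0.8)
            genotypes = rng.binomial(2, p, size=200)
            ps.append(
                hwe_exact(
                    int((genotypes == 0).sum()),
                    int((genotypes == 1).sum()),
                    int((genotypes == 2).sum()),
                )
            )
        # exact conditional p-values are super-uniform; check no excess of
        # small p-values and a sane spread
        ps = np.array(ps)
        assert (ps < 0.05).mean() <= 0.07
        assert ps.mean() > 0.4
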