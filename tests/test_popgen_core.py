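"""Statistic correctness against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from subgenome_scan import (
    GenotypeMatrix, PopulationMap, afs, classify_sharing, dxy_window,
    hudson_fst_window, sharing_percentages, site_pi, tajimas_d, window_scan,
)
from subgenome_scan.popgen_core import SharingClass, site_pi_vector


# ---------------------------------------------------------------------------
# oracles, written directly from the definitions
# ---------------------------------------------------------------------------

def pi_by_pair_enumeration(alt, n):
    """Count differing pairs over all C(n,2) allele pairs."""
    alleles = [1] * alt + [0] * (n - alt)
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def dxy_by_pair_enumeration(alt1, n1, alt2, n2):
    """All cross-population allele pairs."""
    a1 = [1] * alt1 + [0] * (n1 - alt1)
    a2 = [1] * alt2 + [0] * (n2 - alt2)
    diff = sum(x != y for x in a1 for y in a2)
    return diff / (n1 * n2)


def hudson_by_formula(ac1, n1, ac2, n2):
    """Direct evaluation of the within/between heterozygosity form of the
    Hudson estimator, summed over sites."""
    num = den = 0.0
    for a1, m1, a2, m2 in zip(ac1, n1, ac2, n2):
        p1, p2 = a1 / m1, a2 / m2
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (m1 - 1) - p2 * (1 - p2) / (m2 - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


def tajima_from_scratch(n, S, pi_sum):
    """Independent evaluation of the 1989 constants."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestSitePi:
    def test_monomorphic_is_zero(self):
        assert site_pi(0, 10) == 0.0
        assert site_pi(10, 10) == 0.0

    def test_two_of_four(self):
        assert site_pi(2, 4) == pytest.approx(4 / 6)

    def test_singleton_of_ten(self):
        assert site_pi(1, 10) == pytest.approx(9 / 45)

    def test_undefined_below_two_alleles(self):
        assert math.isnan(site_pi(0, 1))

    @given(st.integers(2, 24), st.data())
    def test_matches_pair_enumeration(self, n, data):
        alt = data.draw(st.integers(0, n))
        assert site_pi(alt, n) == pytest.approx(
            pi_by_pair_enumeration(alt, n), abs=1e-12)


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert math.isnan(tajimas_d(10, 0, 0.0))

    def test_excess_of_singletons_negative(self):
        # 20 singleton variants among n=20 alleles: pi per site = 2*19/380
        n, S = 20, 20
        pi_sum = S * site_pi(1, n)
        assert tajimas_d(n, S, pi_sum) < 0

    def test_matches_independent_evaluation(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            S = int(rng.integers(1, 30))
            pi_sum = float(rng.uniform(0, S))
            assert tajimas_d(n, S, pi_sum) == pytest.approx(
                tajima_from_scratch(n, S, pi_sum), abs=1e-12)


class TestHudsonFst:
    def test_fixed_differences_give_one(self):
        n = np.full(50, 40)
        assert hudson_fst_window(np.zeros(50), n, n.copy(), n) == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self, rng):
        ac = rng.integers(1, 40, size=100)
        n = np.full(100, 40)
        assert abs(hudson_fst_window(ac, n, ac, n)) <= 0.05

    def test_single_site_against_formula(self):
        got = hudson_fst_window([4], [20], [16], [20])
        p1, p2, n1, n2 = 0.2, 0.8, 20, 20
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert got == pytest.approx(num / den, abs=1e-12)

    def test_window_matches_formula_oracle(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 30))
            n1 = rng.integers(4, 30, size=k)
            n2 = rng.integers(4, 30, size=k)
            ac1 = rng.integers(0, n1 + 1)
            ac2 = rng.integers(0, n2 + 1)
            if (ac1 + ac2).sum() in (0, (n1 + n2).sum()):
                continue
            assert hudson_fst_window(ac1, n1, ac2, n2) == pytest.approx(
                hudson_by_formula(ac1, n1, ac2, n2), abs=1e-12)


class TestDxy:
    def test_fixed_difference_one(self):
        assert dxy_window([0], [10], [10], [10]) == pytest.approx(1.0)

    def test_half_half(self):
        assert dxy_window([5], [10], [5], [10]) == pytest.approx(0.5)

    def test_same_monomorphic_zero(self):
        assert dxy_window([0, 0], [10, 10], [0, 0], [10, 10]) == 0.0

    def test_matches_pair_enumeration(self, rng):
        for _ in range(25):
            n1, n2 = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            a1, a2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            assert dxy_window([a1], [n1], [a2], [n2]) == pytest.approx(
                dxy_by_pair_enumeration(a1, n1, a2, n2), abs=1e-12)


class TestSharing:
    def test_fixed_difference(self):
        cls, _ = classify_sharing({"A": (0, 12), "B": (12, 12)})
        assert cls is SharingClass.FIXED_DIFFERENCE

    def test_private(self):
        cls, who = classify_sharing({"A": (3, 12), "B": (0, 12)})
        assert cls is SharingClass.PRIVATE and who == "A"

    def test_shared(self):
        cls, _ = classify_sharing({"A": (3, 12), "B": (5, 12)})
        assert cls is SharingClass.SHARED

    def test_all_missing_undefined(self):
        cls, _ = classify_sharing({"A": (0, 0), "B": (0, 0)})
        assert cls is SharingClass.UNDEFINED

    def test_percentages_conserve_total(self, cohort):
        out = sharing_percentages(cohort.gm, cohort.pop_map)
        assert out["percent"].sum() == pytest.approx(100.0)


class TestAfs:
    def test_single_site_lands_in_right_bin(self):
        assert list(afs([0.05], 10)) == [1] + [0] * 9

    def test_folded_half_single_bin(self):
        out = afs([0.5] * 7, 10, folded=True)
        assert out[-1] == 7 and out.sum() == 7

    def test_conservation(self, rng):
        f = rng.random(500)
        assert afs(f, 13).sum() == 500


class TestWindowScan:
    def _toy(self, rng, n_sites=60, n_samples=12, length=250_000):
        pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        gt = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
        gt[rng.random(gt.shape) < 0.1] = -1
        samples = [f"s{i}" for i in range(n_samples)]
        gm = GenotypeMatrix(np.array(["chrZ"] * n_sites, dtype=object), pos,
                            np.array(["A"] * n_sites, dtype=object),
                            np.array(["T"] * n_sites, dtype=object), gt, samples)
        pops = PopulationMap({s: ("p1" if i < 6 else "p2")
                              for i, s in enumerate(samples)},
                             {s: False for s in samples})
        return gm, pops

    def test_tiling_of_250kb_chromosome(self, rng):
        gm, pops = self._toy(rng)
        ws = window_scan(gm, pops, 100_000, {"chrZ": 250_000}, min_sites=1)
        spans = [(w.start, w.end, w.partial) for w in ws]
        assert spans == [(0, 100_000, False), (100_000, 200_000, False),
                         (200_000, 250_000, True)]

    def test_matches_site_by_site_oracle(self, rng):
        """Brute-force recomputation of every statistic on a 2-window toy
        matrix equals window_scan output."""
        gm, pops = self._toy(rng, n_sites=80, length=200_000)
        ws = window_scan(gm, pops, 100_000, {"chrZ": 200_000}, min_sites=1)
        idx = {p: pops.sample_index(gm.sample_ids, p) for p in ("p1", "p2")}
        for w in ws:
            inwin = (gm.pos - 1 >= w.start) & (gm.pos - 1 < w.end)
            assert w.n_variant_sites == inwin.sum()
            for p in ("p1", "p2"):
                pis, ns, seg = [], [], 0
                for i in np.flatnonzero(inwin):
                    g = gm.gt[i, idx[p]]
                    g = g[g >= 0]
                    n = 2 * len(g)
                    if n < 2:
                        continue
                    a = int(g.sum())
                    pis.append(pi_by_pair_enumeration(a, n))
                    ns.append(n)
                    seg += 0 < a < n
                assert w.pi[p] == pytest.approx(np.mean(pis), abs=1e-12)
                exp_d = tajima_from_scratch(int(round(np.mean(ns))), seg,
                                            sum(pis)) if seg else math.nan
                assert w.tajima_d[p] == pytest.approx(exp_d, abs=1e-12, nan_ok=True)
            # pairwise statistics against the direct formulas
            a1, c1 = gm.allele_counts(idx["p1"])
            a2, c2 = gm.allele_counts(idx["p2"])
            sel = np.flatnonzero(inwin)
            usable = (c1[sel] >= 2) & (c2[sel] >= 2)
            s = sel[usable]
            assert w.fst[("p1", "p2")] == pytest.approx(
                hudson_by_formula(a1[s], c1[s], a2[s], c2[s]), abs=1e-12)
            exp_dxy = np.mean([dxy_by_pair_enumeration(a1[i], c1[i], a2[i], c2[i])
                               for i in s])
            assert w.dxy[("p1", "p2")] == pytest.approx(exp_dxy, abs=1e-12)

    def test_sample_permutation_invariance(self, rng):
        gm, pops = self._toy(rng)
        perm = rng.permutation(gm.n_samples)
        gm2 = GenotypeMatrix(gm.chrom, gm.pos, gm.ref, gm.alt,
                             gm.gt[:, perm],
                             [gm.sample_ids[i] for i in perm])
        w1 = window_scan(gm, pops, 100_000, {"chrZ": 250_000}, min_sites=1)
        w2 = window_scan(gm2, pops, 100_000, {"chrZ": 250_000}, min_sites=1)
        for a, b in zip(w1, w2):
            assert a.pi == b.pi and a.fst == b.fst and a.dxy == b.dxy

    def test_sparse_window_undefined_not_zero(self, rng):
        gm, pops = self._toy(rng, n_sites=15)
        ws = window_scan(gm, pops, 100_000, {"chrZ": 250_000}, min_sites=10)
        sparse = [w for w in ws if w.n_variant_sites < 10]
        assert sparse and all(math.isnan(v) for w in sparse
                              for v in w.pi.values())

    def test_unknown_population_errors(self, rng):
        gm, pops = self._toy(rng)
        with pytest.raises(KeyError):
            pops.sample_index(gm.sample_ids + ["ghost"], "p1")
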