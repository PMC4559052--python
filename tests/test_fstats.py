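"""Heterozygosities, W&C F-statistics, HWE, LD and AMOVA."""

import numpy as np
import pytest

import colonystruct as cs
from colonystruct.fstats import _enumerate_het_distribution
from conftest import amova_oracle, dataset_from_arrays, wc_oracle


class TestHeterozygosity:
    def test_unbiased_formula_biallelic(self):
        # p = q = 0.5, n = 10: H_E = (20/19) * 0.5
        genos = np.array([[[0, 1]]] * 5 + [[[0, 0]]] * 2 + [[[1, 1]]] * 2 + [[[0, 1]]])
        # adjust to exactly 10 copies each: 6 het + 2 AA + 2 BB -> p=0.5
        ds = dataset_from_arrays(genos, ["c"] * 10)
        res = cs.observed_expected_het(ds)
        assert res["per_locus"]["L1"]["H_E"] == pytest.approx(20 / 19 * 0.5, abs=1e-12)
        assert res["per_locus"]["L1"]["H_O"] == pytest.approx(0.6)

    def test_four_allele_case(self):
        # p = (0.25,) * 4, n = 100: H_E = (200/199) * 0.75
        rows = [[i, j] for i in range(4) for j in range(4)] * 7  # 112 rows, trim
        genos = np.array(rows[:100])[:, None, :]
        # force exactly 50 copies per allele: use balanced homozygotes
        genos = np.array([[[k, k]] for k in range(4)] * 25)
        ds = dataset_from_arrays(genos, ["c"] * 100)
        res = cs.observed_expected_het(ds)
        assert res["per_locus"]["L1"]["H_E"] == pytest.approx(200 / 199 * 0.75, abs=1e-12)
        assert res["per_locus"]["L1"]["H_O"] == 0.0

    def test_monomorphic(self):
        ds = dataset_from_arrays(np.zeros((5, 1, 2), dtype=int), ["c"] * 5)
        res = cs.observed_expected_het(ds)
        assert res["per_locus"]["L1"]["H_E"] == 0.0
        assert res["per_locus"]["L1"]["H_O"] == 0.0


class TestWcFstats:
    def test_all_heterozygotes_single_group(self):
        ds = dataset_from_arrays(np.array([[[0, 1]]] * 10), ["c"] * 10)
        res = cs.wc_fstats(ds, np.zeros(10))
        assert res.overall["F_IS"] == pytest.approx(-1.0, abs=1e-12)
        assert res.overall["F_IS"] == pytest.approx(
            wc_oracle(ds, np.zeros(10))["F_IS"], abs=1e-10
        )

    def test_fixed_groups_give_fst_one(self):
        genos = np.array([[[0, 0]]] * 6 + [[[1, 1]]] * 6)
        ds = dataset_from_arrays(genos, ["a"] * 6 + ["b"] * 6)
        res = cs.wc_fstats(ds, "colony")
        assert res.overall["F_ST"] == pytest.approx(1.0, abs=1e-12)

    def test_panmixia_limit(self):
        rng = np.random.default_rng(0)
        genos = rng.integers(0, 4, size=(5000, 1, 2))
        ds = dataset_from_arrays(genos, ["c"] * 5000)
        assert abs(cs.wc_fstats(ds, np.zeros(5000)).overall["F_IS"]) < 0.02

    def test_oracle_equivalence_random(self, random_small_dataset):
        rng = np.random.default_rng(42)
        for _ in range(30):
            ds = random_small_dataset(rng)
            got = cs.wc_fstats(ds, "colony").overall
            want = wc_oracle(ds, ds.colony_codes)
            for k in ("F_IS", "F_ST", "F_IT"):
                if np.isnan(want[k]):
                    assert np.isnan(got[k])
                else:
                    assert got[k] == pytest.approx(want[k], abs=1e-10)

    def test_monomorphic_flagged(self):
        ds = dataset_from_arrays(np.zeros((6, 1, 2), dtype=int), ["a"] * 3 + ["b"] * 3)
        res = cs.wc_fstats(ds, "colony")
        assert np.isnan(res.overall["F_ST"])

    def test_permutation_p_values(self):
        genos = np.array([[[0, 0]]] * 8 + [[[1, 1]]] * 8)
        ds = dataset_from_arrays(genos, ["a"] * 8 + ["b"] * 8)
        res = cs.wc_fstats(ds, "colony", n_perm=99, seed=1)
        assert res.p_fst == pytest.approx(1 / 100)  # complete fixation
        assert res.p_fis is not None and 0 < res.p_fis <= 1

    def test_pairwise_fst(self):
        ds, truth = cs.sim_dataset(
            cs.SimConfig(colonies_per_cluster=10, family_mix=(1, 0, 0), seed=31)
        )
        cl = {t.colony_id: t.cluster for t in truth}
        rep = cs.make_resamples(ds, cs.make_resample_plan(ds, 1, seed=0))[0]
        out = cs.pairwise_fst(rep, cl, n_perm=99, seed=2)
        (key, val), = out.items()
        assert val["F_ST"] > 0.05
        assert val["p"] <= 0.05


def pairing_het_distribution(copies):
    """Exhaustive distribution of heterozygote counts over all pairings."""
    copies = list(copies)
    dist = {}

    def rec(rem, het):
        if not rem:
            dist[het] = dist.get(het, 0) + 1
            return
        first, rest = rem[0], rem[1:]
        for i in range(len(rest)):
            rec(rest[:i] + rest[i + 1 :], het + (first != rest[i]))

    rec(copies, 0)
    total = sum(dist.values())
    return {h: c / total for h, c in dist.items()}


class TestHweDeficiency:
    def test_enumeration_matches_pairing_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(2, 6))
            genos = rng.integers(0, 3, size=(n, 1, 2))
            ds = dataset_from_arrays(genos, ["c"] * n)
            copies = ds.genotypes[:, 0, :].ravel().tolist()
            if len(set(copies)) < 2:
                continue
            dist = pairing_het_distribution(copies)
            het_obs = int((ds.genotypes[:, 0, 0] != ds.genotypes[:, 0, 1]).sum())
            expected_p = sum(p for h, p in dist.items() if h <= het_obs)
            res = cs.hwe_deficiency_test(ds, 0)
            assert res.method == "enumeration"
            assert res.p_value == pytest.approx(expected_p, abs=1e-10)

    def test_all_heterozygotes_p_one(self):
        ds = dataset_from_arrays(np.array([[[0, 1]]] * 4), ["c"] * 4)
        res = cs.hwe_deficiency_test(ds, 0)
        assert res.p_value == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        ds = dataset_from_arrays(np.zeros((4, 1, 2), dtype=int), ["c"] * 4)
        res = cs.hwe_deficiency_test(ds, 0)
        assert res.p_value == 1.0
        assert res.method == "monomorphic"

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(4)
        genos = rng.integers(0, 2, size=(8, 1, 2))
        ds = dataset_from_arrays(genos, ["c"] * 8)
        exact = cs.hwe_deficiency_test(ds, 0)
        mc = cs.hwe_deficiency_test(ds, 0, max_tables=1, mc_reps=20_000, seed=5)
        assert mc.method == "monte_carlo"
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_levene_distribution_sums_to_one(self):
        dist = _enumerate_het_distribution(np.array([4, 4]), max_tables=1000)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        # 2 copies of each of two alleles, n=2: P(het table {AB,AB}) = 2/3
        dist2 = _enumerate_het_distribution(np.array([2, 2]), max_tables=1000)
        assert dist2[2] == pytest.approx(2 / 3, abs=1e-12)
        assert dist2[0] == pytest.approx(1 / 3, abs=1e-12)

    def test_inbred_colonies_detected(self):
        # pooled extended-family workers show heterozygote deficiency
        ds, _ = cs.sim_dataset(
            cs.SimConfig(
                n_clusters=1,
                colonies_per_cluster=40,
                family_mix=(0, 1, 0),
                neotenic_generations=3,
                seed=6,
            )
        )
        ps = [
            cs.hwe_deficiency_test(ds, l, mc_reps=2000, seed=l).p_value
            for l in range(ds.n_loci)
        ]
        assert np.median(ps) < 0.01


class TestLinkage:
    def test_duplicated_locus_maximal_association(self):
        rng = np.random.default_rng(7)
        col = rng.integers(0, 3, size=(40, 1, 2))
        genos = np.concatenate([col, col], axis=1)
        ds = dataset_from_arrays(genos, ["c"] * 40)
        p = cs.ld_test(ds, 0, 1, mc_reps=199, seed=8)
        assert p == pytest.approx(1 / 200)

    def test_degenerate_table(self):
        genos = np.zeros((10, 2, 2), dtype=int)
        genos[:, 1, :] = np.random.default_rng(9).integers(0, 2, size=(10, 2))
        ds = dataset_from_arrays(genos, ["c"] * 10)
        assert cs.ld_test(ds, 0, 1, mc_reps=99) == 1.0

    def test_scan_pair_count_and_threshold(self):
        ds, _ = cs.sim_dataset(cs.SimConfig(colonies_per_cluster=3, seed=10))
        scan = cs.ld_scan(ds, mc_reps=49, seed=11)
        assert scan["n_pairs"] == 15
        assert scan["bonferroni_alpha"] == pytest.approx(0.05 / 15)


class TestAmova:
    def test_identical_individuals_zero_components(self):
        ds = dataset_from_arrays(np.zeros((8, 2, 2), dtype=int), ["a"] * 4 + ["b"] * 4)
        res = cs.amova(ds)
        assert all(abs(v) < 1e-12 for v in res.ss.values())

    def test_fixed_colonies_all_among(self):
        genos = np.array([[[0, 0]]] * 5 + [[[1, 1]]] * 5)
        ds = dataset_from_arrays(genos, ["a"] * 5 + ["b"] * 5)
        res = cs.amova(ds)
        assert res.percent["among_colonies"] == pytest.approx(100.0, abs=1e-9)

    def test_oracle_equivalence_random(self, random_small_dataset):
        rng = np.random.default_rng(12)
        for _ in range(25):
            ds = random_small_dataset(rng)
            got = cs.amova(ds)
            want = amova_oracle(ds)
            for k in got.ss:
                assert got.ss[k] == pytest.approx(want["ss"][k], abs=1e-10)
            for k in ("a", "b", "c"):
                assert got.sigma2[k] == pytest.approx(want["sigma2"][k], abs=1e-10)
            assert sum(got.percent.values()) == pytest.approx(100.0, abs=1e-6)

    def test_total_ss_invariant_to_labels(self, random_small_dataset):
        rng = np.random.default_rng(13)
        ds = random_small_dataset(rng)
        base = cs.amova(ds)
        perm = rng.permutation(ds.n_individuals)
        shuffled = dataset_from_arrays(
            ds.genotypes, [ds.colony_ids[i] for i in perm]
        )
        other = cs.amova(shuffled)
        assert sum(base.ss.values()) == pytest.approx(sum(other.ss.values()), abs=1e-9)

    def test_permutation_p(self):
        genos = np.array([[[0, 0]]] * 5 + [[[1, 1]]] * 5)
        ds = dataset_from_arrays(genos, ["a"] * 5 + ["b"] * 5)
        res = cs.amova(ds, n_perm=199, seed=14)
        assert res.p_among_colonies < 0.05


def test_hwe_null_p_values_valid():
    """Exact conditional p-values are valid under the null: P(p <= a) <= a
    (super-uniform, the guarantee of an exact discrete test), yet not
    degenerate (small p-values do occur at close to their nominal rate)."""
    from conftest import dataset_from_arrays as _mk

    rng = np.random.default_rng(78)
    ps = []
    for _ in range(300):
        k = rng.integers(2, 5)
        p = rng.dirichlet(np.ones(k))
        genos = rng.choice(k, size=(20, 1, 2), p=p)
        ds = _mk(genos, ["c"] * 20)
        ps.append(
            cs.hwe_deficiency_test(
                ds, 0, max_tables=50_000, mc_reps=2000, seed=int(rng.integers(2**31))
            ).p_value
        )
    ps = np.array(ps)
    for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
        rate = np.mean(ps <= alpha)
        slack = 2.6 * np.sqrt(alpha * (1 - alpha) / len(ps))
        assert rate <= alpha + slack, (alpha, rate)
    assert np.mean(ps <= 0.05) >= 0.005
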