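"""F_ST / R_ST estimation from STR genotypes and Slatkin linearisation."""

import numpy as np
import pytest

from morphokin.core import DistanceMatrix, STRGenotypeTable
from morphokin.popgen import FstOptions, pairwise_fst, slatkin_linearize


def make_table(genos_by_pop, loci=None):
    """Build a table from {pop: (n, L, 2) array-like}."""
    ids, pops, rows = [], [], []
    for pop, genos in genos_by_pop.items():
        genos = np.asarray(genos)
        for i, g in enumerate(genos):
            ids.append(f"{pop}_{i}")
            pops.append(pop)
            rows.append(g)
    rows = np.asarray(rows)
    loci = loci or [f"L{j}" for j in range(rows.shape[1])]
    return STRGenotypeTable(ids, pops, loci, rows)


def weir_cockerham_theta_from_frequencies(pop_genotypes):
    """Independent oracle: the classical frequency-form variance components.

    ``pop_genotypes``: list of (n_i, 2) allele arrays, one per population.
    Computes a, b, c per allele from sample sizes, allele frequencies and
    observed heterozygosities, sums over alleles, and returns theta.
    """
    r = len(pop_genotypes)
    n = np.array([len(g) for g in pop_genotypes], dtype=float)
    nbar = n.mean()
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    alleles = np.unique(np.concatenate([np.asarray(g).ravel() for g in pop_genotypes]))
    num = den = 0.0
    for allele in alleles:
        p = np.array([(np.asarray(g) == allele).mean() for g in pop_genotypes])
        h = np.array(
            [((np.asarray(g) == allele).sum(axis=1) == 1).mean() for g in pop_genotypes]
        )
        pbar = (n * p).sum() / n.sum()
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / n.sum()
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestWeirCockerham:
    def test_single_locus_worked_case(self):
        # pop1: 10 individuals A/A; pop2: 5 A/A and 5 B/B (A=10, B=12)
        pop1 = np.full((10, 1, 2), 10)
        pop2 = np.concatenate([np.full((5, 1, 2), 10), np.full((5, 1, 2), 12)])
        table = make_table({"P1": pop1, "P2": pop2})
        theta = pairwise_fst(table)["P1", "P2"]
        # hand-derived from the variance-component formulas:
        # per allele a = 1/9, b = 5/36, c = 0 -> theta = (2/9)/(2/9 + 5/18)
        assert theta == pytest.approx(4.0 / 9.0, abs=1e-12)
        oracle = weir_cockerham_theta_from_frequencies(
            [pop1[:, 0, :], pop2[:, 0, :]]
        )
        assert theta == pytest.approx(oracle, abs=1e-12)

    def test_random_tables_match_frequency_oracle(self, rng):
        for _ in range(5):
            g1 = rng.integers(8, 12, size=(12, 3, 2))
            g2 = rng.integers(9, 14, size=(9, 3, 2))
            table = make_table({"P1": g1, "P2": g2})
            theta = pairwise_fst(table)["P1", "P2"]
            oracle = _multilocus_oracle([g1, g2])
            assert theta == pytest.approx(oracle, abs=1e-12)
            # the multilocus ratio lies within the per-locus ratio range
            thetas = [
                weir_cockerham_theta_from_frequencies([g1[:, l, :], g2[:, l, :]])
                for l in range(3)
            ]
            assert min(thetas) - 1e-9 <= theta <= max(thetas) + 1e-9

    def test_fixed_differences_give_one(self):
        table = make_table(
            {"P1": np.full((8, 4, 2), 10), "P2": np.full((8, 4, 2), 20)}
        )
        assert pairwise_fst(table)["P1", "P2"] == pytest.approx(1.0, abs=1e-12)

    def test_panmictic_null_near_zero(self):
        rng = np.random.default_rng(42)
        pool = rng.integers(8, 16, size=(100, 50, 2))
        table = make_table({"P1": pool[:50], "P2": pool[50:]})
        raw = pairwise_fst(table).raw_values[0, 1]
        assert -0.02 <= raw <= 0.02

    def test_invariance_to_individual_and_locus_order(self, rng):
        g1 = rng.integers(8, 13, size=(10, 4, 2))
        g2 = rng.integers(8, 13, size=(11, 4, 2))
        t1 = pairwise_fst(make_table({"P1": g1, "P2": g2}))["P1", "P2"]
        perm_ind = rng.permutation(10)
        perm_loc = rng.permutation(4)
        t2 = pairwise_fst(
            make_table({"P1": g1[perm_ind][:, perm_loc], "P2": g2[:, perm_loc]})
        )["P1", "P2"]
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_missing_data_pairwise_deletion(self, rng):
        g1 = rng.integers(8, 13, size=(10, 2, 2))
        g2 = rng.integers(8, 13, size=(10, 2, 2))
        # locus 1 entirely missing in P1 must not contribute
        g1m = g1.copy()
        g1m[:, 1, :] = -1
        with_missing = pairwise_fst(make_table({"P1": g1m, "P2": g2}))["P1", "P2"]
        only_locus0 = pairwise_fst(
            make_table({"P1": g1[:, :1], "P2": g2[:, :1]})
        )["P1", "P2"]
        assert with_missing == pytest.approx(only_locus0, abs=1e-12)

    def test_no_shared_locus_errors(self):
        g1 = np.full((5, 1, 2), 10)
        g2 = np.full((5, 1, 2), -1)
        with pytest.raises(ValueError, match="P2"):
            pairwise_fst(make_table({"P1": g1, "P2": g2}))

    def test_monotone_in_simulated_divergence(self):
        # stronger drift -> larger median multilocus F_ST
        medians = []
        for drift in (0.02, 0.08, 0.2):
            vals = []
            for s in range(20):
                rng = np.random.default_rng(10_000 + s)
                thetas_tab = []
                freqs0 = rng.dirichlet(np.full(4, 2.0), size=30)
                genos = {}
                for pop in ("P1", "P2"):
                    f = np.clip(
                        freqs0 + rng.normal(0, drift, size=freqs0.shape), 1e-3, None
                    )
                    f /= f.sum(axis=1, keepdims=True)
                    g = np.stack(
                        [
                            rng.choice(4, size=(20, 2), p=f[l]) + 8
                            for l in range(30)
                        ],
                        axis=1,
                    )
                    genos[pop] = g
                vals.append(pairwise_fst(make_table(genos))["P1", "P2"])
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]


def _multilocus_oracle(pop_genos):
    """Components-level multilocus Weir-Cockerham oracle (frequency form)."""
    num = den = 0.0
    n_loci = pop_genos[0].shape[1]
    for l in range(n_loci):
        per_pop = [g[:, l, :] for g in pop_genos]
        r = len(per_pop)
        n = np.array([len(g) for g in per_pop], dtype=float)
        nbar = n.mean()
        nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
        alleles = np.unique(np.concatenate([g.ravel() for g in per_pop]))
        for allele in alleles:
            p = np.array([(g == allele).mean() for g in per_pop])
            h = np.array([((g == allele).sum(axis=1) == 1).mean() for g in per_pop])
            pbar = (n * p).sum() / n.sum()
            s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n * h).sum() / n.sum()
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


class TestRst:
    def test_equals_weir_cockerham_for_two_equidistant_sizes(self, rng):
        # with exactly two allele sizes the indicator and size ANOVAs are
        # affine re-codings of each other, so the estimates must coincide
        for _ in range(5):
            g1 = rng.choice([10, 14], size=(12, 3, 2))
            g2 = rng.choice([10, 14], size=(10, 3, 2))
            table = make_table({"P1": g1, "P2": g2})
            wc = pairwise_fst(table, FstOptions(estimator="weir_cockerham"))
            rst = pairwise_fst(table, FstOptions(estimator="rst_allele_size"))
            assert rst["P1", "P2"] == pytest.approx(wc["P1", "P2"], abs=1e-9)

    def test_size_scale_invariance(self, rng):
        g1 = rng.integers(8, 14, size=(10, 4, 2))
        g2 = rng.integers(8, 14, size=(10, 4, 2))
        opts = FstOptions(estimator="rst_allele_size")
        t1 = pairwise_fst(make_table({"P1": g1, "P2": g2}), opts)["P1", "P2"]
        t2 = pairwise_fst(make_table({"P1": g1 * 3, "P2": g2 * 3}), opts)["P1", "P2"]
        assert t1 == pytest.approx(t2, abs=1e-9)


class TestSlatkinLinearize:
    def test_closed_forms(self):
        m = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        vals = m.values.copy()
        vals[0, 1] = vals[1, 0] = 0.5
        vals[0, 2] = vals[2, 0] = 0.0455
        lin = slatkin_linearize(DistanceMatrix(["a", "b", "c"], vals))
        assert lin["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert lin["a", "c"] == pytest.approx(0.04767, abs=1e-5)
        assert lin["b", "c"] == 0.0

    def test_preserves_symmetry_and_diagonal(self, rng):
        raw = rng.uniform(0, 0.8, size=(5, 5))
        vals = (raw + raw.T) / 2
        np.fill_diagonal(vals, 0.0)
        lin = slatkin_linearize(DistanceMatrix(list("abcde"), vals))
        assert np.abs(lin.values - lin.values.T).max() == 0.0
        assert np.diag(lin.values).max() == 0.0

    def test_fixation_rejected(self):
        vals = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="linearise"):
            slatkin_linearize(DistanceMatrix(["a", "b"], vals))
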