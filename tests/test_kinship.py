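import numpy as np
import pandas as pd
import pytest

from orchardpop.datatypes import PedigreeTable
from orchardpop.kinship import (
    KinshipMatrix,
    cluster_share,
    grm,
    inbreeding_f,
    kinship_correlation,
    kinship_network,
    pedigree_kinship,
)
from orchardpop.simulate import SimulationConfig, gene_drop, simulate_founders

from conftest import make_genotypes


def mc_gene_drop_relatedness(pedigree, n_drops=10_000, seed=0):
    """Monte-Carlo oracle: drop one unlinked locus through the pedigree
    ``n_drops`` times; relatedness(i,j) = 2 * P(random allele of i is IBD
    to random allele of j)."""
    rng = np.random.default_rng(seed)
    order = pedigree.topological_order()
    parent_of = {r["individual"]: (r["sire"], r["dam"])
                 for _, r in pedigree.df.iterrows()}
    n = len(order)
    acc = np.zeros((n, n))
    for d in range(n_drops):
        alleles = {}
        counter = 0
        for ind in order:
            sire, dam = parent_of.get(ind, (None, None))
            a = []
            for p in (sire, dam):
                if p is None:
                    a.append(counter)
                    counter += 1
                else:
                    a.append(alleles[p][rng.integers(2)])
            alleles[ind] = a
        for i, x in enumerate(order):
            ax = alleles[x]
            for j, y in enumerate(order):
                ay = alleles[y]
                share = sum(ax[u] == ay[v] for u in range(2) for v in range(2))
                acc[i, j] += share / 4.0
    return order, 2 * acc / n_drops


class TestGrm:
    def test_duplicate_samples_equal_self_and_cross(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(5, 200)).astype(float)
        d[1] = d[0]
        k = grm(make_genotypes(d))
        assert k.values[0, 1] == pytest.approx(k.values[0, 0])
        assert k.values[0, 1] == pytest.approx(k.values[1, 1])

    def test_independent_founders_near_zero(self):
        # with in-sample frequencies the centering makes every row of K sum
        # to ~0, so the off-diagonal mean is -mean(diag)/(n-1), near zero
        cfg = SimulationConfig(n_founders=100, n_variants=3000, seed=1)
        g = simulate_founders(cfg)
        k = grm(g)
        n = 100
        off = k.values[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 0.02
        expected = -np.trace(k.values) / n / (n - 1)
        assert off.mean() == pytest.approx(expected, abs=0.005)
        np.testing.assert_allclose(k.values.sum(axis=0), 0.0, atol=0.5)

    def test_parent_offspring_mean_half(self):
        # 200 independent parent pairs -> offspring; mean relatedness 0.5
        cfg = SimulationConfig(n_founders=400, n_variants=2000,
                               chrom_lengths={"Chr1": 25_000_000}, seed=2)
        founders = simulate_founders(cfg)
        rows = [dict(individual=f, sire=None, dam=None, relation_type="cross")
                for f in founders.samples]
        for i in range(200):
            rows.append(dict(individual=f"kid{i}", sire=f"F{2*i:03d}",
                             dam=f"F{2*i+1:03d}", relation_type="cross"))
        ped = PedigreeTable(pd.DataFrame(rows))
        geno, _ = gene_drop(founders, ped, cfg)
        k = grm(geno)
        vals = [k.get(f"F{2*i:03d}", f"kid{i}") for i in range(200)]
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(6, 300)).astype(float)
        g = make_genotypes(d)
        k1 = grm(g)
        perm = rng.permutation(6)
        g2 = g.subset_samples(perm)
        k2 = grm(g2)
        for a in range(6):
            for b in range(6):
                assert k2.values[a, b] == pytest.approx(
                    k1.values[perm[a], perm[b]], abs=1e-10
                )

    def test_mean_imputation_keeps_psd(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(20, 500)).astype(float)
        d[rng.random(d.shape) < 0.1] = np.nan
        k = grm(make_genotypes(d))
        w = np.linalg.eigvalsh(k.values)
        assert w.min() > -1e-10


class TestPedigreeKinship:
    def _ped(self, rows):
        return PedigreeTable(pd.DataFrame(
            rows, columns=["individual", "sire", "dam", "relation_type"]
        ))

    def test_founder_self_and_unrelated(self):
        ped = self._ped([("A", None, None, "cross"), ("B", None, None, "cross")])
        k = pedigree_kinship(ped)
        assert k.get("A", "A") == 1.0
        assert k.get("A", "B") == 0.0

    def test_parent_offspring_half(self):
        ped = self._ped([("A", None, None, "cross"), ("B", None, None, "cross"),
                         ("C", "A", "B", "cross")])
        k = pedigree_kinship(ped)
        assert k.get("A", "C") == 0.5
        assert k.get("C", "C") == 1.0  # non-inbred

    def test_full_sibs_half_and_selfing_inbreeding(self):
        ped = self._ped([("A", None, None, "cross"), ("B", None, None, "cross"),
                         ("C", "A", "B", "cross"), ("D", "A", "B", "cross"),
                         ("E", "C", "C", "cross")])
        k = pedigree_kinship(ped)
        assert k.get("C", "D") == 0.5
        # selfed offspring of non-inbred C: F = 0.5, self = 1.5
        assert k.get("E", "E") == 1.5

    def test_sport_pair_configured_value(self):
        ped = self._ped([("A", None, None, "cross"), ("S", "A", None, "sport")])
        k = pedigree_kinship(ped, sport_value=0.97)
        assert k.get("A", "S") == 0.97

    def test_sport_inherits_source_relationships(self):
        ped = self._ped([("A", None, None, "cross"), ("B", None, None, "cross"),
                         ("C", "A", "B", "cross"), ("S", "A", None, "sport")])
        k = pedigree_kinship(ped)
        # clone of A relates to A's child like A does
        assert k.get("S", "C") == k.get("A", "C") == 0.5

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            self._ped([("A", "B", None, "cross"), ("B", "A", None, "cross")])

    def test_matches_monte_carlo_gene_drop(self):
        # three-generation, 9-member pedigree incl. a half-sib arm
        ped = self._ped([
            ("A", None, None, "cross"), ("B", None, None, "cross"),
            ("C", None, None, "cross"), ("D", "A", "B", "cross"),
            ("E", "A", "C", "cross"), ("F", "D", "E", "cross"),
            ("G", "D", "E", "cross"), ("H", "F", "G", "cross"),
            ("I", "F", "B", "cross"),
        ])
        k = pedigree_kinship(ped)
        order, mc = mc_gene_drop_relatedness(ped, n_drops=10_000, seed=5)
        for i, x in enumerate(order):
            for j, y in enumerate(order):
                assert k.get(x, y) == pytest.approx(mc[i, j], abs=0.02)


class TestKinshipCorrelation:
    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(6)
        v = rng.random((4, 4))
        v = (v + v.T) / 2
        k = KinshipMatrix(samples=list("abcd"), values=v, source="snp")
        pairs = [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")]
        r, p = kinship_correlation(k, k, pairs)
        assert r == pytest.approx(1.0)

    def test_clean_simulation_high_correlation(self):
        cfg = SimulationConfig(
            n_founders=30, n_variants=5000,
            chrom_lengths={f"Chr{c}": 25_000_000 for c in range(1, 9)}, seed=7,
        )
        founders = simulate_founders(cfg)
        from orchardpop.simulate import random_pedigree
        ped = random_pedigree(founders.samples, n_generations=2,
                              offspring_per_cross=3, seed=7)
        geno, _ = gene_drop(founders, ped, cfg)
        k_snp = grm(geno)
        k_ped = pedigree_kinship(ped)
        non_founders = [s for s in geno.samples if not s.startswith("F")]
        pairs = [(a, b) for i, a in enumerate(non_founders)
                 for b in non_founders[i + 1:]]
        r, _ = kinship_correlation(k_snp, k_ped, pairs)
        assert r >= 0.9

    def test_degenerate_constant_input(self):
        v = np.full((3, 3), 0.5)
        k = KinshipMatrix(samples=list("abc"), values=v, source="pedigree")
        k2 = KinshipMatrix(samples=list("abc"),
                           values=np.eye(3) * 0.3 + 0.1, source="snp")
        with pytest.raises(ValueError, match="constant|undefined"):
            kinship_correlation(k2, k, [("a", "b"), ("a", "c"), ("b", "c")])

    def test_too_few_pairs(self):
        k = KinshipMatrix(samples=list("ab"), values=np.eye(2), source="snp")
        with pytest.raises(ValueError):
            kinship_correlation(k, k, [("a", "b")])


class TestInbreedingF:
    def test_fully_homozygous_at_half_freq(self):
        # panel with p = 0.5 everywhere; one fully homozygous sample
        d = np.array([[0, 2, 0, 2]] * 2 + [[1, 1, 1, 1]] * 2, dtype=float)
        f = inbreeding_f(make_genotypes(d))
        assert f[0] == pytest.approx(1.0)

    def test_fully_heterozygous_negative_one(self):
        d = np.array([[0, 2, 0, 2], [2, 0, 2, 0], [1, 1, 1, 1]], dtype=float)
        f = inbreeding_f(make_genotypes(d))
        # E_hom = m/2 => (0 - m/2)/(m - m/2) = -1
        assert f[2] == pytest.approx(-1.0)

    def test_selfing_chain_approaches_theory(self):
        # three generations of selfing: F = 1 - (1/2)^3 = 0.875
        cfg = SimulationConfig(n_founders=60, n_variants=3000,
                               chrom_lengths={"Chr1": 20_000_000}, seed=8)
        founders = simulate_founders(cfg)
        rows = [dict(individual=f, sire=None, dam=None, relation_type="cross")
                for f in founders.samples]
        for i in range(30):
            prev = f"F{i:03d}"
            for g in range(3):
                name = f"self{i}_{g}"
                rows.append(dict(individual=name, sire=prev, dam=prev,
                                 relation_type="cross"))
                prev = name
        ped = PedigreeTable(pd.DataFrame(rows))
        geno, _ = gene_drop(founders, ped, cfg)
        idx = [geno.samples.index(f"self{i}_2") for i in range(30)]
        f = inbreeding_f(geno)
        assert abs(np.mean(f[idx]) - 0.875) < 0.05

    def test_all_missing_sample_nan(self):
        d = np.array([[0, 1], [2, 1], [np.nan, np.nan]], dtype=float)
        f = inbreeding_f(make_genotypes(d))
        assert np.isnan(f[2])


class TestKinshipNetwork:
    def _k(self, values, samples=None):
        values = np.asarray(values, dtype=float)
        samples = samples or [f"s{i}" for i in range(len(values))]
        return KinshipMatrix(samples=samples, values=values, source="snp")

    def test_complete_triangle(self):
        v = np.zeros((5, 5))
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            v[i, j] = v[j, i] = 0.6
        res = kinship_network(self._k(v))
        assert len(res.clusters) == 1
        c = res.clusters[0]
        assert c.size == 3
        assert sorted(c.degrees.values()) == [2, 2, 2]
        assert set(res.isolated) == {"s3", "s4"}

    def test_threshold_strictly_greater(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.45  # exactly at threshold: no edge
        res = kinship_network(self._k(v))
        assert res.clusters == [] and res.small_groups == []

    def test_components_match_exhaustive_dfs(self):
        rng = np.random.default_rng(9)
        n = 12
        v = rng.random((n, n)) * 0.8
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        res = kinship_network(self._k(v), min_cluster=2)
        # brute-force DFS oracle
        adj = {i: [j for j in range(n) if j != i and v[i, j] > 0.45]
               for i in range(n)}
        seen, comps = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u])
            seen |= comp
            comps.append({f"s{j}" for j in comp})
        oracle = sorted(
            (frozenset(c) for c in comps if len(c) >= 2), key=len, reverse=True
        )
        mine = [frozenset(c.members) for c in res.clusters]
        assert sorted(mine, key=len, reverse=True) == oracle

    def test_four_families_recovered(self):
        recovered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 40
            v = np.zeros((n, n))
            fam = np.repeat(np.arange(4), 10)
            for i in range(n):
                for j in range(i + 1, n):
                    base = 0.5 if fam[i] == fam[j] else 0.0
                    val = base + rng.normal(0, 0.02)
                    v[i, j] = v[j, i] = val
            np.fill_diagonal(v, 1.0)
            res = kinship_network(self._k(v))
            ok = len(res.clusters) == 4 and all(
                len({fam[int(m[1:])] for m in c.members}) == 1
                and c.size == 10
                for c in res.clusters
            )
            recovered += ok
        assert recovered >= 95

    def test_cluster_share_rendering(self):
        from orchardpop.kinship import KinCluster
        clusters = [
            KinCluster("Clr1", [f"a{i}" for i in range(59)], {}, 0.0),
            KinCluster("Clr2", [f"b{i}" for i in range(142)], {}, 0.0),
        ]
        shares = cluster_share(clusters)
        assert shares["Clr1"] == "29.35%"

    def test_cluster_share_single_and_empty(self):
        from orchardpop.kinship import KinCluster
        assert cluster_share([]) == {}
        one = [KinCluster("Clr1", ["x", "y", "z"], {}, 0.0)]
        assert cluster_share(one)["Clr1"] == "100.00%"
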