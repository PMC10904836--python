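import math

import numpy as np
import pytest

import radhaplo as rh
import radhaplo.popgen as popgen
from radhaplo.catalog import DistanceMatrix

from .conftest import two_pop_matrix
from .oracles import (
    brute_force_amova3,
    brute_force_phist,
    exhaustive_mantel_p,
    naive_mismatch,
)


def random_instance(rng, max_samples=8, max_loci=6, n_pops=2):
    """Random haploid instance with >=2 genotyped samples per population."""
    while True:
        n = int(rng.integers(2 * n_pops, max_samples + 1))
        L = int(rng.integers(1, max_loci + 1))
        g = rng.choice([-1, 0, 1, 2], size=(n, L), p=[0.15, 0.4, 0.3, 0.15]).astype(np.int16)
        # every sample needs at least one genotyped locus
        for i in range(n):
            if (g[i] == -1).all():
                g[i, rng.integers(L)] = 0
        labels = np.array([i % n_pops for i in range(n)])
        try:
            for i in range(n):
                for j in range(n):
                    naive_mismatch(g[i], g[j])
        except ValueError:
            continue
        return g, labels


class TestDiversity:
    def test_unbiased_estimator_hand_value(self):
        # one site, alleles {A,A,T,T}: (4/3)(1 - 0.5^2 - 0.5^2) = 2/3
        g = np.array([[0], [0], [1], [1]], dtype=np.int16)
        samples = ("x1", "x2", "x3", "x4")
        m = rh.SnpMatrix(samples, ("L1",), g, (("A", "T"),))
        scheme = rh.PopScheme(assignment={s: "P" for s in samples})
        rows = rh.diversity_table(m, {}, scheme)
        assert rows[0].pi == pytest.approx(2 / 3)
        assert rows[0].gene_diversity == pytest.approx(2 / 3)
        assert rows[0].n_variant == 1

    def test_fixed_population_has_zero_diversity(self):
        g = np.array([[0], [0], [0]], dtype=np.int16)
        samples = ("x1", "x2", "x3")
        m = rh.SnpMatrix(samples, ("L1",), g, (("A",),))
        scheme = rh.PopScheme(assignment={s: "P" for s in samples})
        rows = rh.diversity_table(m, {}, scheme)
        assert rows[0].pi == 0.0 and rows[0].gene_diversity == 0.0

    def test_all_sites_basis_dilutes_by_invariant_tags(self):
        g = np.array([[0], [0], [1], [1]], dtype=np.int16)
        samples = ("x1", "x2", "x3", "x4")
        m = rh.SnpMatrix(samples, ("L1",), g, (("A", "T"),))
        scheme = rh.PopScheme(assignment={s: "P" for s in samples})
        invariant = {"I1": frozenset(samples), "I2": frozenset(samples), "I3": frozenset(samples)}
        rows = rh.diversity_table(m, invariant, scheme, basis="all_sites")
        assert rows[0].n_sites_total == 4
        assert rows[0].pi == pytest.approx((2 / 3) / 4)
        rows_v = rh.diversity_table(m, invariant, scheme, basis="variant_only")
        assert rows_v[0].pi == pytest.approx(2 / 3)

    def test_undersampled_population_reports_nan_not_zero(self):
        g = np.array([[0], [-1]], dtype=np.int16)
        m = rh.SnpMatrix(("x1", "x2"), ("L1",), g, (("A",),))
        scheme = rh.PopScheme(assignment={"x1": "P", "x2": "P"})
        rows = rh.diversity_table(m, {}, scheme)
        assert math.isnan(rows[0].pi)

    def test_private_counts_match_truth_sidecar(self, mimic, mimic_filtered):
        _, first, _ = mimic_filtered
        rows = rh.diversity_table(first.matrix, first.invariant_presence, mimic.scheme)
        got = {r.population: r.n_private for r in rows}
        expected = {pop: len(ids) for pop, ids in mimic.truth["private"].items()}
        # habitat-unique loci are private to a habitat, not to one population,
        # so only the injected per-population private tags should be counted
        assert got == expected


class TestPairwisePhist:
    def test_fixed_differences_give_exactly_one(self):
        m, scheme = two_pop_matrix([[0, 0, 0]] * 4, [[1, 1, 1]] * 4)
        phi = rh.pairwise_phist(m, scheme)
        assert phi.values[0, 1] == 1.0

    def test_brute_force_equality(self, rng):
        for _ in range(60):
            g, labels = random_instance(rng)
            m, scheme = two_pop_matrix(g[labels == 0], g[labels == 1])
            expected = brute_force_phist(
                list(m.genotype), [0] * (labels == 0).sum() + [1] * (labels == 1).sum()
            )
            got = rh.pairwise_phist(m, scheme).values[0, 1]
            if math.isnan(expected):
                assert math.isnan(got) or got == 0.0
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_split_population_centred_on_zero_with_negatives(self, rng):
        phis = []
        for rep in range(40):
            freqs = rng.uniform(0.2, 0.8, size=30)
            g = (rng.random((20, 30)) < freqs).astype(np.int16)
            m, scheme = two_pop_matrix(g[:10], g[10:])
            phis.append(rh.pairwise_phist(m, scheme).values[0, 1])
        phis = np.array(phis)
        assert abs(phis.mean()) < 0.05
        assert (phis < 0).any()  # small negatives occur, as in real data

    def test_order_invariance(self, mimic, mimic_filtered):
        _, _, matrix = mimic_filtered
        phi1 = rh.pairwise_phist(matrix, mimic.scheme)
        perm = list(reversed(range(matrix.n_loci)))
        m2 = matrix.subset_loci(perm)
        order = list(reversed(list(matrix.samples)))
        m2 = m2.subset_samples(order)
        phi2 = rh.pairwise_phist(m2, mimic.scheme)
        np.testing.assert_allclose(
            phi1.values, phi2.reorder(phi1.labels).values, atol=1e-12
        )

    def test_pair_with_no_shared_loci_rejected(self):
        g = np.array([[0, -1], [0, -1], [-1, 0], [-1, 0]], dtype=np.int16)
        m, scheme = two_pop_matrix(g[:2], g[2:])
        with pytest.raises(ValueError, match="shares no genotyped"):
            rh.pairwise_phist(m, scheme)


class TestAmova:
    def test_identical_individuals_degenerate_convention(self):
        m, scheme = two_pop_matrix([[0, 0]] * 3, [[0, 0]] * 3)
        res = popgen.two_level_amova(popgen.mismatch_distances(m.genotype), ["A"] * 3 + ["B"] * 3)
        assert all(v == 0 for v in res.variance_components.values())
        assert res.percentages["within_populations"] == 100.0

    def test_fixed_group_differences_put_all_variance_among_groups(self):
        g = np.array([[0, 0]] * 4 + [[1, 1]] * 4, dtype=np.int16)
        samples = tuple(f"x{i}" for i in range(8))
        m = rh.SnpMatrix(samples, ("L1", "L2"), g, (("A", "T"), ("A", "T")))
        pops = ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"]
        scheme = rh.PopScheme(assignment=dict(zip(samples, pops)))
        res = rh.amova(m, scheme, {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"})
        assert res.percentages["among_groups"] == pytest.approx(100.0)
        assert res.phi["phi_ct"] == pytest.approx(1.0)
        assert sum(res.df.values()) == 7

    def test_brute_force_equality_three_level(self, rng):
        for _ in range(25):
            # 12 samples, 4 populations, 2 groups
            g, _ = random_instance(rng, max_samples=12, max_loci=5, n_pops=4)
            n = g.shape[0] - g.shape[0] % 4
            g = g[:n]
            samples = tuple(f"x{i}" for i in range(n))
            labels = [f"p{i % 4}" for i in range(n)]
            m = rh.SnpMatrix(
                samples, tuple(f"L{j}" for j in range(g.shape[1])), g,
                (("A", "C", "G", "T"),) * g.shape[1],
            )
            scheme = rh.PopScheme(assignment=dict(zip(samples, labels)))
            groups = {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"}
            res = rh.amova(m, scheme, groups)
            sa, sb, sc = brute_force_amova3(list(g), labels, groups)
            assert res.variance_components["among_groups"] == pytest.approx(sa, abs=1e-12)
            assert res.variance_components["among_populations"] == pytest.approx(sb, abs=1e-12)
            assert res.variance_components["within_populations"] == pytest.approx(sc, abs=1e-12)
            assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_two_populations_matches_pairwise_phist(self, rng):
        g, labels = random_instance(rng, max_samples=8, max_loci=6)
        m, scheme = two_pop_matrix(g[labels == 0], g[labels == 1])
        res = rh.amova(m, scheme, None)
        phi = rh.pairwise_phist(m, scheme).values[0, 1]
        assert res.phi["phi_st"] == pytest.approx(phi, abs=1e-12)

    def test_single_group_falls_back_to_two_level(self):
        m, scheme = two_pop_matrix([[0, 1]] * 3, [[1, 0]] * 3)
        res = rh.amova(m, scheme, {"A": "g1", "B": "g1"})
        assert set(res.variance_components) == {"among_populations", "within_populations"}


class TestMantel:
    @staticmethod
    def _dm(values, kind="genetic"):
        v = np.asarray(values, dtype=float)
        labels = tuple(f"l{i}" for i in range(len(v)))
        return DistanceMatrix(labels, v, kind)

    def test_collinear_matrices_give_r_one(self):
        base = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        gen = self._dm(base * 0.1)
        geo = self._dm(base * 50, kind="geographic")
        res = rh.mantel_ibd(gen, geo, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.1 / 50)

    def test_table2_reproduces_published_r_squared(self):
        genetic, geographic = rh.load_table2()
        res = rh.mantel_ibd(genetic, geographic, n_perm=999, seed=1)
        assert res.r_squared * 100 == pytest.approx(38.9, abs=0.05)

    def test_exhaustive_permutation_p_matches_enumeration_oracle(self, rng):
        n = 4
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((n, n))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        gen = self._dm(a / a.max())
        geo = self._dm(b * 100, kind="geographic")
        res = rh.mantel_ibd(gen, geo, exhaustive=True)
        expected = exhaustive_mantel_p(geo.values.tolist(), gen.values.tolist())
        assert res.p_value == pytest.approx(expected, abs=1e-12)
        assert res.n_perm == 24

    def test_matches_skbio_r(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        n = 8
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((n, n))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        gen = self._dm(a / a.max())
        geo = self._dm(b * 100, kind="geographic")
        res = rh.mantel_ibd(gen, geo, n_perm=99, seed=3)
        r_ref, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(geo.values, geo.labels),
            skbio_distance.DistanceMatrix(gen.values, gen.labels),
            method="pearson",
            permutations=0,
        )
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)

    def test_label_mismatch_and_constant_matrix_rejected(self):
        gen = self._dm(np.array([[0, 0.1, 0.1], [0.1, 0, 0.1], [0.1, 0.1, 0]]))
        geo = DistanceMatrix(("x", "y", "z"), np.zeros((3, 3)), "geographic")
        with pytest.raises(ValueError, match="labels"):
            rh.mantel_ibd(gen, geo, seed=0)
        geo2 = self._dm(np.ones((3, 3)) - np.eye(3), kind="geographic")
        with pytest.raises(ValueError, match="constant"):
            rh.mantel_ibd(gen, geo2, seed=0)


class TestHaversine:
    def test_identical_points(self):
        assert rh.haversine_km(55.7, 12.6, 55.7, 12.6) == 0.0

    def test_antipodal_closed_form(self):
        assert rh.haversine_km(0, 0, 0, 180) == pytest.approx(math.pi * 6371.0, abs=0.1)

    def test_symmetry(self, rng):
        for _ in range(20):
            lat1, lat2 = rng.uniform(-90, 90, 2)
            lon1, lon2 = rng.uniform(-180, 180, 2)
            assert rh.haversine_km(lat1, lon1, lat2, lon2) == pytest.approx(
                rh.haversine_km(lat2, lon2, lat1, lon1)
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rh.haversine_km(91, 0, 0, 0)
        with pytest.raises(ValueError):
            rh.haversine_km(0, 181, 0, 0)
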