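import itertools
import math

import numpy as np
import pytest

import radhaplo as rh
from radhaplo.catalog import DistanceMatrix
from radhaplo.structure import ClusterRun

from .conftest import two_pop_matrix
from .oracles import brute_force_amova3, dirichlet_multinomial_lnp, gibbs_lnp_limit


def euclidean_dm(points):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(tuple(f"x{i}" for i in range(n)), d, "geographic")


class TestPcoa:
    def test_equilateral_triangle_splits_fifty_fifty(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = rh.pcoa(DistanceMatrix(("a", "b", "c"), d, "geographic"))
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        assert res.percent_explained == pytest.approx([50.0, 50.0])

    def test_recovers_planar_configuration(self, rng):
        pts = rng.normal(size=(10, 2))
        res = rh.pcoa(euclidean_dm(pts))
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, res.coordinates[:, :2])
        assert disparity < 1e-9
        # Euclidean input: no negative eigenvalues beyond numerical noise
        assert res.eigenvalues.min() > -1e-9 * max(1.0, res.eigenvalues.max())

    def test_matches_skbio_on_euclidean_input(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        import skbio

        pts = rng.normal(size=(7, 3))
        dm = euclidean_dm(pts)
        res = rh.pcoa(dm)
        ref = skbio_ord.pcoa(skbio.DistanceMatrix(dm.values, dm.labels))
        np.testing.assert_allclose(
            res.eigenvalues[:3], np.asarray(ref.eigvals)[:3], atol=1e-8
        )

    def test_table2_phist_ordination_shape(self):
        genetic, _ = rh.load_table2()
        res = rh.pcoa(genetic)
        assert res.coordinates.shape[0] == 8
        assert res.percent_explained.sum() == pytest.approx(100.0, abs=1e-9)
        assert res.percent_explained[0] >= res.percent_explained[1]

    def test_lingoes_correction_removes_negative_eigenvalues(self):
        genetic, _ = rh.load_table2()
        res = rh.pcoa(genetic, correction="lingoes")
        assert res.eigenvalues.min() > -1e-8


class TestGibbsNoadmix:
    def test_k1_matches_closed_form_oracles(self, rng):
        cfg = rh.SimConfig(
            seed=5, n_populations=2, samples_per_population=10, n_loci=30,
            divergence_F=0.2, missing_rate=0.1, n_private_per_pop=0,
            n_habitat_unique=0, n_contaminant=0, n_diploid_artifact=0, n_invariant_loci=0,
        )
        mat = rh.first_snp_matrix(rh.simulate_catalog(cfg).catalog).matrix
        counts = []
        for j in range(mat.n_loci):
            col = mat.genotype[:, j]
            col = col[col >= 0]
            counts.append(np.bincount(col, minlength=len(mat.allele_labels[j])))
        limit = gibbs_lnp_limit(counts)  # exact target of the estimator
        marginal = dirichlet_multinomial_lnp(counts)  # true ln P(D)
        run = rh.gibbs_noadmix(mat, 1, burnin=500, reps=4000, seed=9)
        assert run.log_prob_data == pytest.approx(limit, abs=2.0)
        # the mean-minus-half-variance estimator is a documented
        # approximation to the marginal likelihood; agreement is coarse
        assert run.log_prob_data == pytest.approx(marginal, rel=0.12)

    def test_separable_populations_fully_resolved_at_k2(self):
        m, scheme = two_pop_matrix([[0] * 20] * 6, [[1] * 20] * 6)
        run = rh.gibbs_noadmix(m, 2, burnin=200, reps=400, seed=4)
        a = {run.assignments[s] for s in m.samples[:6]}
        b = {run.assignments[s] for s in m.samples[6:]}
        assert a == {0} and b == {1}  # canonical relabeling: first sample -> 0
        assert np.allclose(run.membership.sum(axis=1), 1.0)
        assert run.membership[:, 0][:6].min() > 0.99

    def test_k_bounds_validated(self):
        m, _ = two_pop_matrix([[0]] * 2, [[1]] * 2)
        with pytest.raises(ValueError):
            rh.gibbs_noadmix(m, 0, seed=1)
        with pytest.raises(ValueError):
            rh.gibbs_noadmix(m, 5, seed=1)
        with pytest.raises(ValueError):
            rh.gibbs_noadmix(m, 2)


def runs_from(means_by_k, spread):
    out = []
    for k, mean in means_by_k.items():
        for delta in (spread, -spread):
            out.append(
                ClusterRun(K=k, assignments={}, membership=np.zeros((0, k)),
                           log_prob_data=mean + delta, seed=0)
            )
    return out


class TestEvanno:
    def test_linear_means_give_zero_delta_k(self):
        runs = runs_from({1: -100.0, 2: -90.0, 3: -80.0, 4: -70.0}, spread=1.0)
        res = rh.evanno(runs)
        for k in (2, 3):
            assert res.delta_k[k] == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_delta_k(self):
        # means (-100, -80, -75, -74), sd = 1 (spread 1/sqrt(2) over 2 runs)
        spread = 1 / math.sqrt(2)
        runs = runs_from({1: -100.0, 2: -80.0, 3: -75.0, 4: -74.0}, spread=spread)
        res = rh.evanno(runs)
        assert res.delta_k[2] == pytest.approx(abs(-75 - 2 * -80 + -100) / 1.0)  # = 15
        assert res.delta_k[3] == pytest.approx(abs(-74 - 2 * -75 + -80) / 1.0)  # = 4
        assert res.best_k == 2

    def test_invariant_to_constant_shift(self):
        runs = runs_from({1: -100.0, 2: -80.0, 3: -75.0, 4: -74.0}, spread=0.5)
        shifted = [
            ClusterRun(r.K, r.assignments, r.membership, r.log_prob_data + 500.0, r.seed)
            for r in runs
        ]
        a, b = rh.evanno(runs), rh.evanno(shifted)
        assert a.best_k == b.best_k
        for k in a.delta_k:
            if not math.isnan(a.delta_k[k]):
                assert a.delta_k[k] == pytest.approx(b.delta_k[k], rel=1e-9)

    def test_zero_sd_reported_as_undefined(self):
        runs = runs_from({1: -100.0, 2: -80.0, 3: -75.0, 4: -74.0}, spread=0.0)
        # all interior sd = 0 -> no defined delta K at all
        with pytest.raises(ValueError, match="undefined"):
            rh.evanno(runs)

    def test_requires_consecutive_k_and_replicates(self):
        runs = runs_from({1: -100.0, 3: -75.0, 4: -74.0}, spread=0.5)
        with pytest.raises(ValueError, match="consecutive"):
            rh.evanno(runs)


class TestKClusterAmova:
    def test_k_equals_p_gives_singleton_groups(self, mimic, mimic_filtered):
        _, _, matrix = mimic_filtered
        res = rh.k_cluster_amova(matrix, mimic.scheme, 8, annealing_steps=10, n_starts=1, seed=0)
        assert len(set(res.grouping.values())) == 8

    def test_annealing_matches_exhaustive_bipartitions(self, rng):
        # 4 populations, k=2: enumerate all 7 bipartitions with the
        # brute-force AMOVA oracle and compare optima
        g, _ = (rng.choice([0, 1], size=(16, 8)).astype(np.int16), None)
        samples = tuple(f"x{i}" for i in range(16))
        pops = [f"p{i % 4}" for i in range(16)]
        m = rh.SnpMatrix(samples, tuple(f"L{j}" for j in range(8)), g, (("A", "T"),) * 8)
        scheme = rh.PopScheme(assignment=dict(zip(samples, pops)))
        best_obj = -math.inf
        pop_names = sorted(set(pops))
        for split in itertools.chain.from_iterable(
            itertools.combinations(pop_names, r) for r in (1, 2)
        ):
            if len(split) == 2 and pop_names[0] not in split:
                continue  # avoid double-counting complements
            groups = {p: ("g1" if p in split else "g2") for p in pop_names}
            sa, _, _ = brute_force_amova3(list(g), pops, groups)
            best_obj = max(best_obj, sa)
        res = rh.k_cluster_amova(m, scheme, 2, annealing_steps=500, n_starts=5, seed=2)
        assert res.objective == pytest.approx(best_obj, abs=1e-10)

    def test_recovers_constructed_groups(self, mimic, mimic_filtered):
        _, _, matrix = mimic_filtered
        res = rh.k_cluster_amova(matrix, mimic.scheme, 3, annealing_steps=2000, n_starts=5, seed=1)
        # partition equality with the constructed clusters
        want = mimic.cluster_groups
        by_group: dict[str, set] = {}
        for pop, g in res.grouping.items():
            by_group.setdefault(g, set()).add(pop)
        want_parts = {}
        for pop, g in want.items():
            want_parts.setdefault(g, set()).add(pop)
        assert set(map(frozenset, by_group.values())) == set(map(frozenset, want_parts.values()))

    def test_objective_never_decreases_with_more_starts(self, mimic, mimic_filtered):
        _, _, matrix = mimic_filtered
        one = rh.k_cluster_amova(matrix, mimic.scheme, 3, annealing_steps=300, n_starts=1, seed=3)
        many = rh.k_cluster_amova(matrix, mimic.scheme, 3, annealing_steps=300, n_starts=6, seed=3)
        assert many.objective >= one.objective - 1e-12

    def test_k_validation(self, mimic, mimic_filtered):
        _, _, matrix = mimic_filtered
        with pytest.raises(ValueError):
            rh.k_cluster_amova(matrix, mimic.scheme, 0, seed=1)
        with pytest.raises(ValueError):
            rh.k_cluster_amova(matrix, mimic.scheme, 9, seed=1)
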