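import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import radhaplo as rh
import radhaplo.filters as flt

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mimic():
    """Fixed-seed study-mimic bundle shared by end-to-end tests."""
    return rh.make_study_mimic(seed=1)


def filtered_chain(m):
    """Blacklist → diploid → first-SNP → p/r presence, with intermediates."""
    params = flt.FilterParams()
    cat_bl = flt.apply_blacklist(m.catalog, set(m.truth["contaminant_ids"]))
    cat_hap = flt.apply_blacklist(cat_bl, flt.detect_diploid_loci(cat_bl, params))
    first = flt.first_snp_matrix(cat_hap)
    matrix = flt.presence_filter(first.matrix, m.scheme, params)
    return cat_hap, first, matrix


@pytest.fixture(scope="session")
def mimic_filtered(mimic):
    return filtered_chain(mimic)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def two_pop_matrix(genotypes_a, genotypes_b):
    """Build a SnpMatrix + PopScheme from explicit per-population genotype rows."""
    g = np.array(list(genotypes_a) + list(genotypes_b), dtype=np.int16)
    n_a = len(genotypes_a)
    samples = tuple(f"a{i}" for i in range(n_a)) + tuple(f"b{i}" for i in range(len(genotypes_b)))
    labels = tuple(
        tuple("ACGT"[: max(int(g[g[:, j] >= 0, j].max(initial=0)) + 1, 1)])
        for j in range(g.shape[1])
    )
    matrix = rh.SnpMatrix(samples=samples, loci=tuple(f"L{j}" for j in range(g.shape[1])),
                          genotype=g, allele_labels=labels)
    scheme = rh.PopScheme(assignment={s: ("A" if s.startswith("a") else "B") for s in samples})
    return matrix, scheme
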