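"""Independent brute-force oracles, written from the definitions.

These deliberately share no code with the package: distances, sums of
squares and alignments are computed by naive loops so they can serve as
references for the vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


def naive_mismatch(g_i, g_j) -> float:
    d = 0
    shared = 0
    for a, b in zip(g_i, g_j):
        if a == MISSING or b == MISSING:
            continue
        shared += 1
        if a != b:
            d += 1
    if shared == 0:
        raise ValueError("no shared loci")
    return float(d)


def brute_force_phist(genotype, pop_labels) -> float:
    """Two-level AMOVA Phi_ST from the definitional sums of squares."""
    N = len(pop_labels)
    pops = sorted(set(pop_labels))
    d2 = [[naive_mismatch(genotype[i], genotype[j]) for j in range(N)] for i in range(N)]
    ss_total = sum(d2[i][j] for i in range(N) for j in range(i + 1, N)) / N
    ss_within = 0.0
    sizes = {}
    for p in pops:
        members = [i for i, lab in enumerate(pop_labels) if lab == p]
        sizes[p] = len(members)
        ss_within += sum(
            d2[i][j] for i in members for j in members if i < j
        ) / len(members)
    ss_among = ss_total - ss_within
    df_among = len(pops) - 1
    df_within = N - len(pops)
    ms_within = ss_within / df_within
    ms_among = ss_among / df_among
    n_c = (N - sum(n * n for n in sizes.values()) / N) / df_among
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_c
    if sigma_a + sigma_w == 0:
        return math.nan
    return sigma_a / (sigma_a + sigma_w)


def brute_force_amova3(genotype, pop_labels, group_of_pop):
    """Three-level AMOVA variance components from first principles.

    Returns (sigma_a, sigma_b, sigma_c) for among-groups, among-populations
    within groups, within-populations.
    """
    N = len(pop_labels)
    pops = sorted(set(pop_labels))
    grps = sorted(set(group_of_pop.values()))
    d2 = [[naive_mismatch(genotype[i], genotype[j]) for j in range(N)] for i in range(N)]

    def pair_sum(members):
        return sum(d2[i][j] for i in members for j in members if i < j)

    ss_total = pair_sum(range(N)) / N
    ss_wp = 0.0
    pop_sizes = {}
    for p in pops:
        members = [i for i, lab in enumerate(pop_labels) if lab == p]
        pop_sizes[p] = len(members)
        ss_wp += pair_sum(members) / len(members)
    ss_wg = 0.0
    grp_sizes = {}
    for g in grps:
        members = [i for i, lab in enumerate(pop_labels) if group_of_pop[lab] == g]
        grp_sizes[g] = len(members)
        ss_wg += pair_sum(members) / len(members)
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg
    P, G = len(pops), len(grps)
    ms_wp = ss_wp / (N - P)
    ms_ap = ss_ap / (P - G)
    ms_ag = ss_ag / (G - 1)
    pop_in_grp_sq = sum(
        sum(pop_sizes[p] ** 2 for p in pops if group_of_pop[p] == g) / grp_sizes[g] for g in grps
    )
    n1 = (N - pop_in_grp_sq) / (P - G)
    n2 = (pop_in_grp_sq - sum(n * n for n in pop_sizes.values()) / N) / (G - 1)
    n3 = (N - sum(n * n for n in grp_sizes.values()) / N) / (G - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - ms_wp) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def exhaustive_mantel_p(x_matrix, y_matrix) -> float:
    """One-sided upper Mantel p over all relabelings of y (identity included)."""
    n = len(x_matrix)
    iu = [(i, j) for i in range(n) for j in range(i + 1, n)]
    x = np.array([x_matrix[i][j] for i, j in iu], dtype=float)

    def corr(perm):
        y = np.array([y_matrix[perm[i]][perm[j]] for i, j in iu], dtype=float)
        return np.corrcoef(x, y)[0, 1]

    r_obs = corr(tuple(range(n)))
    count = sum(1 for perm in itertools.permutations(range(n)) if corr(perm) >= r_obs - 1e-12)
    return count / math.factorial(n)


def best_ungapped_score(query: str, subject: str, match=1, mismatch=-2) -> int:
    """Exhaustive ungapped local alignment: best segment over all diagonals."""
    best = 0
    for offset in range(-(len(query) - 1), len(subject)):
        # max-subarray along this diagonal
        run = 0
        for qi in range(len(query)):
            ti = qi + offset
            if ti < 0 or ti >= len(subject):
                continue
            s = match if query[qi] == subject[ti] else mismatch
            run = max(0, run) + s
            best = max(best, run)
    return best


def dirichlet_multinomial_lnp(counts_per_locus) -> float:
    """Closed-form ln marginal of one cluster with Dirichlet(1) priors."""
    from scipy.special import gammaln

    total = 0.0
    for counts in counts_per_locus:
        counts = np.asarray(counts)
        A = len(counts)
        n = counts.sum()
        total += gammaln(A) - gammaln(n + A) + gammaln(counts + 1).sum()
    return float(total)


def gibbs_lnp_limit(counts_per_locus) -> float:
    """Exact infinite-MCMC limit of the mean-minus-half-variance ln P(D)
    estimator for a single cluster (posterior Dirichlet moments of log
    frequencies via digamma/trigamma)."""
    from scipy.special import polygamma, psi

    mean = 0.0
    var = 0.0
    for counts in counts_per_locus:
        counts = np.asarray(counts, dtype=float)
        A = len(counts)
        n = counts.sum()
        alpha = counts + 1.0
        a0 = n + A
        mean += float((counts * (psi(alpha) - psi(a0))).sum())
        tri = polygamma(1, alpha)
        tri0 = polygamma(1, a0)
        var += float((counts**2 * tri).sum() - (counts.sum()) ** 2 * tri0)
    return mean - var / 2.0
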