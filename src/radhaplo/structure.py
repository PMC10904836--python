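"""Ordination and model-based clustering for haploid SNP matrices.

Three complementary views of population structure:

* :func:`pcoa` — metric ordination of any distance matrix by Gower double
  centering and eigendecomposition.
* :func:`gibbs_noadmix` — a Gibbs sampler for the no-admixture,
  independent-allele-frequencies Bayesian clustering model (each haploid
  individual belongs wholly to one of K clusters whose per-locus allele
  frequencies carry a symmetric Dirichlet(1) prior), with the number of
  clusters chosen by the Evanno ΔK second-difference statistic
  (:func:`evanno`).
* :func:`k_cluster_amova` — simulated-annealing search for the assignment
  of populations to k groups that maximizes the among-group variance
  component of the hierarchical AMOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import eigh

from .catalog import DistanceMatrix, PopScheme, SnpMatrix
from .popgen import AmovaResult, mismatch_distances, two_level_amova

MISSING = SnpMatrix.MISSING


# ---------------------------------------------------------------------------
# Principal coordinates analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PcoaResult:
    """Coordinates on positive-eigenvalue axes plus the full spectrum.

    ``percent_explained`` divides each positive eigenvalue by the sum of
    positive eigenvalues; negative eigenvalues (possible for non-Euclidean
    matrices such as Phi_ST) are reported in ``eigenvalues`` but excluded
    from the percentage denominator and carry no coordinate axis.
    """

    labels: tuple[str, ...]
    coordinates: np.ndarray  # n_labels x n_positive_axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_explained: np.ndarray  # per positive axis


def pcoa(distance: DistanceMatrix, correction: str | None = None) -> PcoaResult:
    """Classical PCoA: eigendecomposition of the doubly centered −½·d²."""
    d = distance.values
    n = d.shape[0]
    d2 = d**2
    if correction == "lingoes":
        # Add the smallest constant to squared off-diagonal distances that
        # makes the matrix Euclidean-embeddable.
        lam = eigh(_gower(d2), eigvals_only=True)
        c = max(0.0, -float(lam.min()))
        d2 = d2 + 2 * c * (1 - np.eye(n))
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    B = _gower(d2)
    eigvals, eigvecs = eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    positive = eigvals > 1e-12 * max(1.0, abs(eigvals[0]))
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    percent = 100.0 * eigvals[positive] / pos_sum if pos_sum > 0 else np.array([])
    return PcoaResult(
        labels=distance.labels,
        coordinates=coords,
        eigenvalues=eigvals,
        percent_explained=percent,
    )


def _gower(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


# ---------------------------------------------------------------------------
# No-admixture Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterRun:
    """One MCMC run at fixed K.

    ``assignments`` gives the modal post-burn-in cluster per sample after
    canonical relabeling (clusters ordered by the first sample index of
    their membership); ``membership`` holds the posterior membership
    fractions (rows sum to 1); ``log_prob_data`` is the estimated ln P(D).
    """

    K: int
    assignments: dict[str, int]
    membership: np.ndarray
    log_prob_data: float
    seed: int


def gibbs_noadmix(
    matrix: SnpMatrix,
    K: int,
    burnin: int = 10_000,
    reps: int = 20_000,
    seed: int | None = None,
) -> ClusterRun:
    """Gibbs sampler for the no-admixture / independent-alleles model.

    Alternates (i) sampling cluster allele frequencies from their
    Dirichlet(1 + counts) full conditional and (ii) sampling each
    individual's cluster from its full conditional under a uniform prior.
    ln P(D) is estimated from the post-burn-in log-likelihood trace by the
    mean-minus-half-variance estimator.
    """
    if seed is None:
        raise ValueError("seed is required")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_samples:
        raise ValueError("K cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    G = matrix.genotype
    N, L = G.shape
    A = max((len(lab) for lab in matrix.allele_labels), default=1)
    A = max(A, 1)
    valid = np.zeros((L, A), dtype=bool)
    for j, labels in enumerate(matrix.allele_labels):
        valid[j, : len(labels)] = True
    nonmiss = G != MISSING
    Gc = np.where(nonmiss, G, 0)
    onehot = np.zeros((N, L, A))
    onehot[np.arange(N)[:, None], np.arange(L)[None, :], Gc] = 1.0
    onehot[~nonmiss] = 0.0
    lrange = np.arange(L)

    z = rng.integers(0, K, size=N)
    ll_trace = np.empty(reps)
    occupancy = np.zeros((N, K))
    for sweep in range(burnin + reps):
        counts = np.stack([onehot[z == k].sum(axis=0) for k in range(K)])  # K,L,A
        gam = rng.standard_gamma(1.0 + counts)
        gam[:, ~valid] = 0.0
        freqs = gam / gam.sum(axis=2, keepdims=True)
        logf = np.log(np.clip(freqs, 1e-300, None))
        # log-likelihood of each sample under each cluster
        LL = logf[:, lrange[None, :], Gc]  # K,N,L
        LL = np.where(nonmiss[None, :, :], LL, 0.0).sum(axis=2).T  # N,K
        gumbel = -np.log(-np.log(rng.random((N, K))))
        z = np.argmax(LL + gumbel, axis=1)
        if sweep >= burnin:
            t = sweep - burnin
            ll_trace[t] = LL[np.arange(N), z].sum()
            occupancy[np.arange(N), z] += 1.0

    log_prob = float(ll_trace.mean() - ll_trace.var() / 2.0)
    membership = occupancy / reps
    modal = membership.argmax(axis=1)
    # canonical relabeling: clusters ordered by first member index
    order: list[int] = []
    for i in range(N):
        if modal[i] not in order:
            order.append(int(modal[i]))
    for k in range(K):
        if k not in order:
            order.append(k)
    relabel = {old: new for new, old in enumerate(order)}
    modal = np.array([relabel[int(k)] for k in modal])
    membership = membership[:, order]
    return ClusterRun(
        K=K,
        assignments={s: int(modal[i]) for i, s in enumerate(matrix.samples)},
        membership=membership,
        log_prob_data=log_prob,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Evanno ΔK
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvannoResult:
    """Per-K summary of ln P(D) with the ΔK statistic and the chosen K."""

    k_values: tuple[int, ...]
    mean_lnp: dict[int, float]
    sd_lnp: dict[int, float]
    delta_k: dict[int, float]  # NaN where undefined (boundary or sd = 0)
    best_k: int


def evanno(runs: Sequence[ClusterRun]) -> EvannoResult:
    """Evanno ΔK = |L″(K)| / sd(L(K)) over replicate runs per K."""
    by_k: dict[int, list[float]] = {}
    for run in runs:
        by_k.setdefault(run.K, []).append(run.log_prob_data)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    for k, vals in by_k.items():
        if len(vals) < 2:
            raise ValueError(f"K={k}: need >= 2 runs")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    delta: dict[int, float] = {}
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            delta[k] = math.nan
        elif sd[k] == 0:
            delta[k] = math.nan  # undefined, not infinite
        else:
            delta[k] = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
    defined = {k: v for k, v in delta.items() if not math.isnan(v)}
    if not defined:
        raise ValueError("delta K undefined at every interior K")
    best = max(defined, key=defined.__getitem__)
    return EvannoResult(
        k_values=tuple(ks), mean_lnp=mean, sd_lnp=sd, delta_k=delta, best_k=best
    )


# ---------------------------------------------------------------------------
# AMOVA-based k-clustering of populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KClusterResult:
    """Best assignment of populations to k groups and its objective."""

    k: int
    grouping: dict[str, str]
    objective: float


def _group_sums(matrix: SnpMatrix, scheme: PopScheme):
    """Precompute per-population pair sums of squared distances."""
    d2 = mismatch_distances(matrix.genotype)
    pops = scheme.populations
    idx = {p: [i for i, s in enumerate(matrix.samples) if scheme.population_of(s) == p] for p in pops}
    sizes = np.array([len(idx[p]) for p in pops], dtype=float)
    P = len(pops)
    W = np.zeros(P)  # within-population unordered pair sums
    X = np.zeros((P, P))  # cross-population unordered pair sums
    for a in range(P):
        ia = idx[pops[a]]
        sub = d2[np.ix_(ia, ia)]
        W[a] = sub[np.triu_indices(len(ia), 1)].sum()
        for b in range(a + 1, P):
            X[a, b] = X[b, a] = d2[np.ix_(ia, idx[pops[b]])].sum()
    return pops, sizes, W, X


def _among_group_component(
    assign: np.ndarray, sizes: np.ndarray, W: np.ndarray, X: np.ndarray
) -> float:
    """σ²(among groups) of the hierarchical AMOVA for a group assignment."""
    P = len(sizes)
    N = sizes.sum()
    groups = np.unique(assign)
    G = len(groups)
    total_pairs = W.sum() + X[np.triu_indices(P, 1)].sum()
    ss_total = total_pairs / N
    ss_wp = (W / sizes).sum()
    if G == P:  # two-level design: among populations is the top stratum
        ss_ap = ss_total - ss_wp
        ms_wp = ss_wp / (N - P)
        ms_ap = ss_ap / (P - 1)
        n_c = (N - (sizes**2).sum() / N) / (P - 1)
        return float((ms_ap - ms_wp) / n_c)
    if G < 2 or P - G < 1:
        return math.nan
    grp_sizes = np.array([sizes[assign == g].sum() for g in groups])
    ss_wg = 0.0
    pop_in_grp_sq = 0.0
    for gi, g in enumerate(groups):
        members = np.flatnonzero(assign == g)
        s = W[members].sum()
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                s += X[members[ai], members[bi]]
        ss_wg += s / grp_sizes[gi]
        pop_in_grp_sq += (sizes[members] ** 2).sum() / grp_sizes[gi]
    ss_wp_term = ss_wp
    ss_ap = ss_wg - ss_wp_term
    ss_ag = ss_total - ss_wg
    ms_wp = ss_wp_term / (N - P)
    ms_ap = ss_ap / (P - G)
    ms_ag = ss_ag / (G - 1)
    n1 = (N - pop_in_grp_sq) / (P - G)
    n2 = (pop_in_grp_sq - (sizes**2).sum() / N) / (G - 1)
    n3 = (N - (grp_sizes**2).sum() / N) / (G - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - ms_wp) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return float(sigma_a)


def k_cluster_amova(
    matrix: SnpMatrix,
    scheme: PopScheme,
    k: int,
    annealing_steps: int = 50_000,
    n_starts: int = 20,
    seed: int | None = None,
) -> KClusterResult:
    """Search population-to-group assignments maximizing σ²(among groups)."""
    if seed is None:
        raise ValueError("seed is required")
    if k < 1:
        raise ValueError("k must be >= 1")
    pops, sizes, W, X = _group_sums(matrix, scheme)
    P = len(pops)
    if k > P:
        raise ValueError("k cannot exceed the number of populations")
    if k == 1:
        return KClusterResult(k=1, grouping={p: "group1" for p in pops}, objective=math.nan)
    if k == P:
        assign = np.arange(P)
        obj = _among_group_component(assign, sizes, W, X)
        return KClusterResult(
            k=k, grouping={p: f"group{i + 1}" for i, p in enumerate(pops)}, objective=obj
        )

    rng = np.random.default_rng(seed)
    best_assign: np.ndarray | None = None
    best_obj = -math.inf
    temps = np.geomspace(1.0, 1e-3, max(2, annealing_steps))

    def score(a: np.ndarray) -> float:
        v = _among_group_component(a, sizes, W, X)
        return -math.inf if math.isnan(v) else v

    for _ in range(n_starts):
        assign = np.concatenate([np.arange(k), rng.integers(0, k, size=P - k)])
        rng.shuffle(assign)
        cur = score(assign)
        if cur > best_obj:
            best_obj, best_assign = cur, assign.copy()
        for t in temps:
            p = int(rng.integers(P))
            g_new = int(rng.integers(k))
            if g_new == assign[p]:
                continue
            if (assign == assign[p]).sum() == 1:
                continue  # never empty a group
            old = assign[p]
            assign[p] = g_new
            cand = score(assign)
            if cand >= cur or rng.random() < math.exp((cand - cur) / max(t, 1e-12)):
                cur = cand
                if cur > best_obj:
                    best_obj, best_assign = cur, assign.copy()
            else:
                assign[p] = old

    assert best_assign is not None
    # stable group naming by first population in each group
    label_of: dict[int, str] = {}
    for i, g in enumerate(best_assign):
        if int(g) not in label_of:
            label_of[int(g)] = f"group{len(label_of) + 1}"
    return KClusterResult(
        k=k,
        grouping={p: label_of[int(g)] for p, g in zip(pops, best_assign)},
        objective=float(best_obj),
    )
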