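"""Within- and between-population statistics for haploid SNP matrices.

Differentiation is quantified by AMOVA-based Phi statistics computed on
squared inter-individual distances, where the distance between two haploid
multilocus genotypes is the number of mismatching loci among loci
non-missing in both (pairwise deletion).  Negative variance components are
retained, so slightly negative Phi_ST values — expected when within-
population variance exceeds the between-population estimate — are
representable.

Isolation-by-distance is tested with a Mantel matrix-permutation test of
the pairwise genetic distances against geographic distances in km, with an
OLS regression of Phi_ST on untransformed km for the IBD plot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalog import DistanceMatrix, PopScheme, SnpMatrix

logger = logging.getLogger(__name__)

MISSING = SnpMatrix.MISSING


# ---------------------------------------------------------------------------
# Inter-individual distances
# ---------------------------------------------------------------------------


def mismatch_distances(genotype: np.ndarray) -> np.ndarray:
    """Pairwise locus-mismatch counts with pairwise deletion.

    Raises when some pair of individuals shares no genotyped locus (the
    distance is then undefined).
    """
    G = np.asarray(genotype)
    nonmiss = G != MISSING
    n = G.shape[0]
    D = np.zeros((n, n))
    shared_ok = True
    for i in range(n):
        both = nonmiss[i] & nonmiss
        D[i] = ((G[i] != G) & both).sum(axis=1)
        shared = both.sum(axis=1)
        shared[i] = 1
        if np.any(shared == 0):
            shared_ok = False
    if not shared_ok:
        raise ValueError("some pair of individuals shares no genotyped locus")
    return D


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmovaResult:
    """Hierarchical AMOVA decomposition with Phi statistics.

    Strata are ``among_groups``, ``among_populations`` (within groups) and
    ``within_populations``; for the two-level design the group stratum is
    absent.  ``percentages`` uses components as computed (negative values
    retained) unless built with ``truncate=True``.
    """

    ss: dict[str, float]
    df: dict[str, int]
    variance_components: dict[str, float]
    percentages: dict[str, float]
    phi: dict[str, float]


def _pair_sums(d2: np.ndarray, labels: np.ndarray) -> dict:
    """Sum of squared distances over unordered pairs, per grouping level."""
    iu = np.triu_indices(len(labels), 1)
    return float(d2[iu].sum())


def _within_sum(d2: np.ndarray, member_idx: np.ndarray) -> float:
    sub = d2[np.ix_(member_idx, member_idx)]
    iu = np.triu_indices(len(member_idx), 1)
    return float(sub[iu].sum())


def two_level_amova(d2: np.ndarray, pop_labels: Sequence) -> AmovaResult:
    """AMOVA with strata among/within populations on squared distances."""
    labels = np.asarray(pop_labels)
    N = len(labels)
    pops, counts = np.unique(labels, return_counts=True)
    P = len(pops)
    if P < 2:
        raise ValueError("need at least two populations")
    if N - P < 1:
        raise ValueError("no within-population degrees of freedom")
    ss_total = _pair_sums(d2, labels) / N
    ss_wp = sum(
        _within_sum(d2, np.flatnonzero(labels == p)) / n_p for p, n_p in zip(pops, counts)
    )
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, N - P
    ms_wp = ss_wp / df_wp
    ms_ap = ss_ap / df_ap
    n_c = (N - (counts**2).sum() / N) / df_ap
    sigma_w = ms_wp
    sigma_a = (ms_ap - ms_wp) / n_c
    total = sigma_a + sigma_w
    phi_st = sigma_a / total if total != 0 else math.nan
    components = {"among_populations": sigma_a, "within_populations": sigma_w}
    return AmovaResult(
        ss={"among_populations": ss_ap, "within_populations": ss_wp, "total": ss_total},
        df={"among_populations": df_ap, "within_populations": df_wp},
        variance_components=components,
        percentages=_percentages(components),
        phi={"phi_st": phi_st},
    )


def _percentages(components: Mapping[str, float], truncate: bool = False) -> dict[str, float]:
    vals = {k: (max(v, 0.0) if truncate else v) for k, v in components.items()}
    total = sum(vals.values())
    if total == 0:
        out = {k: 0.0 for k in vals}
        out["within_populations"] = 100.0  # degenerate data: all variance within
        return out
    return {k: 100.0 * v / total for k, v in vals.items()}


def amova(
    matrix: SnpMatrix,
    scheme: PopScheme,
    groups: Mapping[str, str] | None = None,
    truncate_negative: bool = False,
) -> AmovaResult:
    """Three-level AMOVA: among groups / among populations / within.

    ``groups`` maps every population to a group label.  With a single group
    (or ``None``) the analysis falls back to the two-level design with a
    warning.  Unbalanced designs use the standard n-coefficients from the
    expected mean squares.
    """
    scheme.require_covers(matrix.samples)
    pop_labels = np.asarray([scheme.population_of(s) for s in matrix.samples])
    d2 = mismatch_distances(matrix.genotype)

    group_of = dict(groups) if groups else {}
    if groups:
        missing = set(scheme.populations) - set(group_of)
        if missing:
            raise ValueError(f"groups missing population(s) {sorted(missing)[:5]}")
    n_groups = len(set(group_of.values())) if groups else 1
    if n_groups < 2:
        if groups is not None:
            logger.warning("single group supplied; falling back to two-level AMOVA")
        return two_level_amova(d2, pop_labels)

    grp_labels = np.asarray([group_of[p] for p in pop_labels])
    N = len(pop_labels)
    pops, pop_counts = np.unique(pop_labels, return_counts=True)
    grps, grp_counts = np.unique(grp_labels, return_counts=True)
    P, G = len(pops), len(grps)
    if P - G < 1:
        raise ValueError("three-level AMOVA needs more populations than groups")

    ss_total = _pair_sums(d2, pop_labels) / N
    ss_wp = sum(
        _within_sum(d2, np.flatnonzero(pop_labels == p)) / n for p, n in zip(pops, pop_counts)
    )
    ss_within_groups = sum(
        _within_sum(d2, np.flatnonzero(grp_labels == g)) / n for g, n in zip(grps, grp_counts)
    )
    ss_ap = ss_within_groups - ss_wp
    ss_ag = ss_total - ss_within_groups
    df = {"among_groups": G - 1, "among_populations": P - G, "within_populations": N - P}
    ms_wp = ss_wp / df["within_populations"]
    ms_ap = ss_ap / df["among_populations"]
    ms_ag = ss_ag / df["among_groups"]

    # Unbalanced-design coefficients from the expected mean squares.
    pop_in_grp_sq = 0.0
    for g, n_g in zip(grps, grp_counts):
        sizes = pop_counts[[i for i, p in enumerate(pops) if group_of[p] == g]]
        pop_in_grp_sq += (sizes**2).sum() / n_g
    n1 = (N - pop_in_grp_sq) / df["among_populations"]
    n2 = (pop_in_grp_sq - (pop_counts**2).sum() / N) / df["among_groups"]
    n3 = (N - (grp_counts**2).sum() / N) / df["among_groups"]

    sigma_c = ms_wp
    sigma_b = (ms_ap - ms_wp) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    components = {
        "among_groups": sigma_a,
        "among_populations": sigma_b,
        "within_populations": sigma_c,
    }
    total = sigma_a + sigma_b + sigma_c
    phi = {
        "phi_ct": sigma_a / total if total != 0 else math.nan,
        "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else math.nan,
        "phi_st": (sigma_a + sigma_b) / total if total != 0 else math.nan,
    }
    return AmovaResult(
        ss={
            "among_groups": ss_ag,
            "among_populations": ss_ap,
            "within_populations": ss_wp,
            "total": ss_total,
        },
        df=df,
        variance_components=components,
        percentages=_percentages(components, truncate=truncate_negative),
        phi=phi,
    )


def pairwise_phist(matrix: SnpMatrix, scheme: PopScheme) -> DistanceMatrix:
    """Pairwise Phi_ST between all populations via two-level haploid AMOVA."""
    scheme.require_covers(matrix.samples)
    pops = scheme.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    nonmiss_per_sample = (matrix.genotype != MISSING).sum(axis=1)
    by_pop: dict[str, list[int]] = {p: [] for p in pops}
    for i, s in enumerate(matrix.samples):
        if nonmiss_per_sample[i] > 0:
            by_pop[scheme.population_of(s)].append(i)
    for p, members in by_pop.items():
        if len(members) < 2:
            raise ValueError(f"population {p} has fewer than 2 genotyped samples")

    values = np.zeros((len(pops), len(pops)))
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            idx = by_pop[pops[a]] + by_pop[pops[b]]
            labels = [0] * len(by_pop[pops[a]]) + [1] * len(by_pop[pops[b]])
            d2 = mismatch_distances(matrix.genotype[idx, :])
            res = two_level_amova(d2, labels)
            values[a, b] = values[b, a] = res.phi["phi_st"]
    return DistanceMatrix(tuple(pops), values, "genetic")


# ---------------------------------------------------------------------------
# Within-population diversity (Table-1-shaped summary)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopDiversity:
    """Per-population summary: site counts, private loci, π, gene diversity.

    ``pi`` is the unbiased per-site nucleotide diversity n/(n−1)·(1−Σp²)
    averaged over the configured site basis; ``gene_diversity`` is the same
    estimator averaged over sites variant within the population (the Nei
    unbiased within-population gene diversity).
    """

    population: str
    n_sites_total: int
    n_variant: int
    n_private: int
    pi: float
    gene_diversity: float


def diversity_table(
    matrix: SnpMatrix,
    invariant_presence: Mapping[str, frozenset[str]],
    scheme: PopScheme,
    basis: str = "all_sites",
) -> list[PopDiversity]:
    """Per-population diversity summary.

    ``basis`` selects the π denominator: ``all_sites`` divides the summed
    per-site diversity by all sites present in the population (variant
    matrix loci plus invariant tags), matching the convention of averaging
    π over every genotyped site; ``variant_only`` averages over the
    population's variant sites alone.
    """
    if basis not in ("all_sites", "variant_only"):
        raise ValueError("basis must be 'all_sites' or 'variant_only'")
    scheme.require_covers(matrix.samples)
    sample_idx = {s: i for i, s in enumerate(matrix.samples)}
    pops = scheme.populations
    presence_other: dict[str, set[str]] = {}  # locus -> pops where present
    rows: list[PopDiversity] = []

    # Locus presence per population (matrix loci + invariant tags).
    nonmiss = matrix.genotype != MISSING
    pop_members = {p: [sample_idx[s] for s in scheme.samples_of(p) if s in sample_idx] for p in pops}
    for p in pops:
        idx = pop_members[p]
        present_loci = {matrix.loci[j] for j in np.flatnonzero(nonmiss[idx, :].any(axis=0))}
        present_loci |= {
            lid for lid, samples in invariant_presence.items() if any(s in samples for s in scheme.samples_of(p))
        }
        for lid in present_loci:
            presence_other.setdefault(lid, set()).add(p)

    for p in pops:
        idx = pop_members[p]
        G = matrix.genotype[idx, :]
        nm = G != MISSING
        n_inv = sum(
            1 for samples in invariant_presence.values() if any(s in samples for s in scheme.samples_of(p))
        )
        h_sum = 0.0
        n_variant = 0
        n_usable = 0
        for j in range(matrix.n_loci):
            col = G[nm[:, j], j]
            n = col.size
            if n < 2:
                continue
            n_usable += 1
            _, counts = np.unique(col, return_counts=True)
            if len(counts) > 1:
                n_variant += 1
            freqs = counts / n
            h_sum += n / (n - 1) * (1.0 - float((freqs**2).sum()))
        n_present_variant = int(nonmiss[idx, :].any(axis=0).sum())
        n_sites_total = n_present_variant + n_inv
        if n_usable == 0:
            pi = math.nan
            gd = math.nan
        else:
            if basis == "all_sites":
                pi = h_sum / n_sites_total if n_sites_total else math.nan
            else:
                pi = h_sum / n_variant if n_variant else 0.0
            gd = h_sum / n_variant if n_variant else 0.0
        n_private = sum(
            1
            for lid, where in presence_other.items()
            if where == {p}
        )
        rows.append(
            PopDiversity(
                population=p,
                n_sites_total=n_sites_total,
                n_variant=n_variant,
                n_private=n_private,
                pi=pi,
                gene_diversity=gd,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Mantel isolation-by-distance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MantelResult:
    """Mantel correlation with permutation p and the IBD regression line."""

    r: float
    r_squared: float
    p_value: float
    n_perm: int
    slope: float
    intercept: float


def mantel_ibd(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test of genetic on geographic distance with label permutation.

    ``r`` is the Pearson correlation over the n(n−1)/2 unordered pairs; the
    p-value permutes one matrix's labels (rows and columns jointly),
    one-sided upper, with the add-one estimator (#{r_perm ≥ r_obs}+1)/(n_perm+1).
    With ``exhaustive=True`` all n! relabelings are enumerated instead and
    p = #{r_perm ≥ r_obs}/n! (the identity counts itself); feasible for
    small n only.
    """
    if seed is None and not exhaustive:
        raise ValueError("seed is required for the permutation test")
    if set(genetic.labels) != set(geographic.labels):
        raise ValueError("genetic and geographic matrices have different labels")
    geographic = geographic.reorder(genetic.labels)
    n = len(genetic.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    x = geographic.condensed()
    y = genetic.condensed()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)

    iu, ju = np.triu_indices(n, 1)
    M = genetic.values
    xc = x - x.mean()
    xnorm = math.sqrt(float(xc @ xc))

    def _count_ge(perms: np.ndarray) -> int:
        yp = M[perms[:, iu], perms[:, ju]]  # (b, n_pairs)
        yc = yp - yp.mean(axis=1, keepdims=True)
        ynorm = np.sqrt((yc**2).sum(axis=1))
        r_perm = (yc @ xc) / (ynorm * xnorm)
        return int((r_perm >= r - 1e-12).sum())

    if exhaustive:
        from itertools import permutations

        all_perms = np.array(list(permutations(range(n))), dtype=np.int64)
        n_perm = len(all_perms)
        p = _count_ge(all_perms) / n_perm
    else:
        rng = np.random.default_rng(seed)
        count = 0
        done = 0
        while done < n_perm:
            b = min(256, n_perm - done)
            perms = np.empty((b, n), dtype=np.int64)
            for k in range(b):
                perms[k] = rng.permutation(n)
            count += _count_ge(perms)
            done += b
        p = (count + 1) / (n_perm + 1)
    return MantelResult(
        r=r,
        r_squared=r * r,
        p_value=float(p),
        n_perm=n_perm,
        slope=float(slope),
        intercept=float(intercept),
    )


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two points in decimal degrees."""
    for lat in (lat1, lat2):
        if abs(lat) > 90:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if abs(lon) > 180:
            raise ValueError(f"longitude out of range: {lon}")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))
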