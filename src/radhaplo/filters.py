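"""Locus filtering between the raw RAD catalog and the analysis-ready SNP matrix.

The fixed application order in the pipeline is:

1. :func:`apply_blacklist` — remove loci flagged as contaminants (e.g. by an
   upstream taxonomic classifier whose output is supplied as a blacklist).
2. :func:`detect_diploid_loci` + blacklist — drop tags where samples carry
   more than one haplotype; haploid organisms cannot be heterozygous, so a
   multi-haplotype sample is evidence of paralogy or diploid contamination.
3. :func:`first_snp_matrix` — one SNP per tag (the smallest offset) to avoid
   tightly linked sites; invariant tags are carried separately so diversity
   denominators can include them.
4. :func:`presence_filter` — Stacks-style p/r selection: keep a locus when at
   least ``p`` populations each have it genotyped in at least fraction ``r``
   of their assigned individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog import LocusCatalog, PopScheme, RadLocus, SnpMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-9  # guards float r*n comparisons at exact thresholds


@dataclass(frozen=True)
class FilterParams:
    """p/r presence thresholds plus the diploid-evidence threshold.

    ``p``: minimum number of populations that must contain a locus.
    ``r``: minimum fraction of a population's assigned individuals that must
    be genotyped for the population to count as containing the locus.
    """

    p: int = 6
    r: float = 0.5
    diploid_sample_threshold: int = 1

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not (0 < self.r <= 1):
            raise ValueError("r must lie in (0, 1]")
        if self.diploid_sample_threshold < 1:
            raise ValueError("diploid_sample_threshold must be >= 1")


def apply_blacklist(catalog: LocusCatalog, blacklist_ids: Iterable[str]) -> LocusCatalog:
    """Remove blacklisted loci; unknown ids are ignored with a warning."""
    blacklist = set(blacklist_ids)
    present = set(catalog.locus_ids)
    stray = blacklist - present
    if stray:
        logger.warning("blacklist contains %d id(s) absent from catalog", len(stray))
    kept = tuple(loc for loc in catalog.loci if loc.locus_id not in blacklist)
    logger.info("blacklist removed %d of %d loci", len(catalog.loci) - len(kept), len(catalog.loci))
    return LocusCatalog(loci=kept, samples=catalog.samples)


def detect_diploid_loci(catalog: LocusCatalog, params: FilterParams = FilterParams()) -> set[str]:
    """Flag loci where >= threshold samples carry more than one haplotype."""
    flagged = set()
    for loc in catalog.loci:
        n_multi = sum(1 for haps in loc.calls.values() if len(haps) > 1)
        if n_multi >= params.diploid_sample_threshold:
            flagged.add(loc.locus_id)
    return flagged


@dataclass(frozen=True)
class FirstSnpResult:
    """SNP matrix (one column per variant tag) plus invariant-tag presence.

    ``invariant_presence`` maps each zero-SNP locus id to the frozenset of
    samples genotyped there; these tags enter diversity denominators but
    carry no genotype column.
    """

    matrix: SnpMatrix
    invariant_presence: Mapping[str, frozenset[str]]

    @property
    def n_invariant(self) -> int:
        return len(self.invariant_presence)


def first_snp_matrix(catalog: LocusCatalog) -> FirstSnpResult:
    """Build the samples x loci matrix from the first SNP of each variant tag.

    Raises if any sample still shows two alleles at the chosen site — that
    means the diploid blacklist was not applied first.
    """
    samples = catalog.samples
    sample_index = {s: i for i, s in enumerate(samples)}
    variant: list[RadLocus] = []
    invariant: dict[str, frozenset[str]] = {}
    for loc in catalog.loci:
        if loc.is_variant:
            variant.append(loc)
        else:
            invariant[loc.locus_id] = frozenset(loc.calls)

    genotype = np.full((len(samples), len(variant)), SnpMatrix.MISSING, dtype=np.int16)
    allele_labels: list[tuple[str, ...]] = []
    for j, loc in enumerate(variant):
        site_alleles: dict[str, int] = {}
        for sample, haps in loc.calls.items():
            first_site = {hap[0] for hap in haps}
            if len(first_site) > 1:
                raise ValueError(
                    f"locus {loc.locus_id}: sample {sample} has two alleles at the first SNP; "
                    "apply the diploid blacklist before building the matrix"
                )
            allele = first_site.pop()
            if allele not in site_alleles:
                site_alleles[allele] = len(site_alleles)
            genotype[sample_index[sample], j] = site_alleles[allele]
        allele_labels.append(tuple(site_alleles))

    matrix = SnpMatrix(
        samples=samples,
        loci=tuple(loc.locus_id for loc in variant),
        genotype=genotype,
        allele_labels=tuple(allele_labels),
    )
    return FirstSnpResult(matrix=matrix, invariant_presence=invariant)


def _presence_counts(matrix: SnpMatrix, scheme: PopScheme) -> tuple[np.ndarray, np.ndarray]:
    """Per-population non-missing counts (pops x loci) and population sizes."""
    scheme.require_covers(matrix.samples)
    pops = scheme.populations
    nonmissing = matrix.genotype != SnpMatrix.MISSING
    counts = np.zeros((len(pops), matrix.n_loci), dtype=np.int64)
    sizes = np.zeros(len(pops), dtype=np.int64)
    pop_of = {p: i for i, p in enumerate(pops)}
    for i, sample in enumerate(matrix.samples):
        k = pop_of[scheme.population_of(sample)]
        counts[k] += nonmissing[i]
        sizes[k] += 1
    return counts, sizes


def presence_filter(matrix: SnpMatrix, scheme: PopScheme, params: FilterParams) -> SnpMatrix:
    """Stacks-style p/r selection; retained loci preserve input order."""
    counts, sizes = _presence_counts(matrix, scheme)
    contains = counts >= (params.r * sizes[:, None] - _EPS)  # pop "contains" locus
    n_containing = contains.sum(axis=0)
    keep = np.flatnonzero(n_containing >= params.p)
    logger.info(
        "presence filter p=%d r=%.3g kept %d of %d loci", params.p, params.r, keep.size, matrix.n_loci
    )
    return matrix.subset_loci(keep)


def shared_loci_sweep(
    matrix: SnpMatrix,
    scheme: PopScheme,
    populations: Sequence[str],
    fractions: Sequence[float],
) -> dict[float, int]:
    """Count loci genotyped in >= t of individuals of *every* listed population.

    Mirrors the shared-locus sweep across coverage thresholds (typically
    0.2–0.8) used to probe locus sharing among closely situated populations.
    """
    if not populations:
        raise ValueError("populations list must be non-empty")
    known = set(scheme.populations)
    stray = [p for p in populations if p not in known]
    if stray:
        raise ValueError(f"unknown population(s): {stray}")
    counts, sizes = _presence_counts(matrix, scheme)
    idx = [list(scheme.populations).index(p) for p in populations]
    out: dict[float, int] = {}
    for t in fractions:
        ok = counts[idx] >= (t * sizes[idx, None] - _EPS)
        out[float(t)] = int(ok.all(axis=0).sum())
    return out


def group_unique_loci(
    data: SnpMatrix | LocusCatalog,
    scheme: PopScheme,
    grouping: Mapping[str, str],
) -> dict[str, set[str]]:
    """Loci genotyped in >=1 sample of exactly one group (e.g. one habitat).

    ``grouping`` maps every population to a group label; works on either a
    SNP matrix (non-missing = genotyped) or a full catalog (call present =
    genotyped), since the habitat contrast runs on the pre-selection catalog.
    """
    missing = set(scheme.populations) - set(grouping)
    if missing:
        raise ValueError(f"grouping does not cover population(s) {sorted(missing)[:5]}")
    group_labels = sorted(set(grouping.values()))
    if len(group_labels) < 2:
        raise ValueError("uniqueness is undefined for a single group")

    def group_of(sample: str) -> str:
        return grouping[scheme.population_of(sample)]

    presence: dict[str, set[str]] = {}  # locus -> groups where genotyped
    if isinstance(data, SnpMatrix):
        scheme.require_covers(data.samples)
        nonmissing = data.genotype != SnpMatrix.MISSING
        for i, sample in enumerate(data.samples):
            g = group_of(sample)
            for j in np.flatnonzero(nonmissing[i]):
                presence.setdefault(data.loci[j], set()).add(g)
    else:
        scheme.require_covers(
            {s for loc in data.loci for s in loc.calls}
        )
        for loc in data.loci:
            for sample in loc.calls:
                presence.setdefault(loc.locus_id, set()).add(group_of(sample))

    out: dict[str, set[str]] = {g: set() for g in group_labels}
    for locus_id, groups in presence.items():
        if len(groups) == 1:
            out[next(iter(groups))].add(locus_id)
    return out
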