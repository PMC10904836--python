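"""Synthetic haploid RAD-seq worlds with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: haploid biallelic SNP tags whose population allele frequencies
follow the Balding–Nichols model (a Beta distribution with the ancestral
frequency as mean and variance scaled by a drift parameter F), uniform
missingness, population-private tags, habitat-restricted tags whose
sequences re-appear inside annotated transcripts, bacterial-contaminant
tags, and diploid-artifact tags.  Every injected feature is recorded in a
truth sidecar so filters and the habitat contrast can be tested closed-loop.

All randomness flows from one explicit integer seed; there is no global
RNG state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import (
    AnnotationTable,
    LocusCatalog,
    PopScheme,
    RadLocus,
    write_annotations,
    write_catalog,
    write_popmap,
)

_BASES = np.array(list("ACGT"))

# GO vocabulary used for designated habitat-linked transcripts.  Saline
# themes follow the osmoregulation biology of brackish/marine strains
# (chloride channels, osmolyte transport); freshwater themes follow ion
# homeostasis under low salinity.
SALINE_GO_TERMS: tuple[tuple[str, str], ...] = (
    ("F:0005247", "voltage-gated chloride channel activity"),
    ("P:0031460", "glycine betaine transport"),
    ("F:0005381", "iron ion transmembrane transporter activity"),
)
FRESHWATER_GO_TERMS: tuple[tuple[str, str], ...] = (
    ("P:0003096", "renal sodium ion transport"),
    ("P:0055074", "calcium ion homeostasis"),
)
_DECOY_GO_TERMS: tuple[tuple[str, str], ...] = (
    ("P:0006412", "translation"),
    ("C:0005737", "cytoplasm"),
    ("F:0003824", "catalytic activity"),
)

# Loci per designated GO term; with the default 34 habitat-unique loci per
# group this yields two saline terms of 17 loci each, echoing the scale of
# the strongest habitat-linked term counts.
_LOCI_PER_GO_TERM = 17


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults mirror the study design scale.

    Eight populations of haploid individuals, a few hundred shared biallelic
    tags, 10% missing calls, tens of private tags per population, 34
    habitat-restricted tags per habitat, a ~3% bacterial-contaminant
    fraction and a handful of diploid artifacts.
    """

    seed: int
    n_populations: int = 8
    samples_per_population: int = 19
    n_loci: int = 345
    divergence_F: float | Sequence[float] = 0.3
    missing_rate: float = 0.1
    n_private_per_pop: int = 10
    n_habitat_unique: int = 34
    n_contaminant: int = 12
    n_diploid_artifact: int = 6
    n_invariant_loci: int = 40
    consensus_length: int = 120
    # Optional hierarchical structure: assign populations to groups whose
    # frequencies drift from the ancestral pool with group_F before the
    # per-population drift is applied.
    group_of_pop: tuple[int, ...] | None = None
    group_F: float = 0.0
    habitat_of_pop: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_populations",
            "samples_per_population",
            "n_loci",
            "n_private_per_pop",
            "n_habitat_unique",
            "n_contaminant",
            "n_diploid_artifact",
            "n_invariant_loci",
            "consensus_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_populations < 1 or self.samples_per_population < 1:
            raise ValueError("need at least one population and one sample per population")
        for f in self.pop_F():
            if not (0 < f < 1):
                raise ValueError("divergence_F values must lie in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.group_of_pop is not None and len(self.group_of_pop) != self.n_populations:
            raise ValueError("group_of_pop must list one group per population")
        if self.habitat_of_pop is not None:
            if len(self.habitat_of_pop) != self.n_populations:
                raise ValueError("habitat_of_pop must list one habitat per population")
            if set(self.habitat_of_pop) - {"freshwater", "saline"}:
                raise ValueError("habitats must be freshwater or saline")

    def pop_F(self) -> tuple[float, ...]:
        if isinstance(self.divergence_F, (int, float)):
            return (float(self.divergence_F),) * self.n_populations
        if len(self.divergence_F) != self.n_populations:
            raise ValueError("divergence_F sequence must match n_populations")
        return tuple(float(f) for f in self.divergence_F)

    def habitats(self) -> tuple[str, ...]:
        if self.habitat_of_pop is not None:
            return self.habitat_of_pop
        half = (self.n_populations + 1) // 2
        return tuple("saline" if i < half else "freshwater" for i in range(self.n_populations))


@dataclass(frozen=True)
class SimBundle:
    """A simulated catalog + population scheme + truth sidecar."""

    catalog: LocusCatalog
    scheme: PopScheme
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_catalog(self.catalog, outdir / "catalog.tsv")
        write_popmap(self.scheme, outdir / "popmap.tsv")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))


def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray, F: float) -> np.ndarray:
    """Draw descendant allele frequencies: Beta with mean p_anc, var p(1-p)F."""
    if F < 1e-9:
        return p_anc.copy()
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    return rng.beta(a, b)


def _random_consensus(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _snp_locus(
    rng: np.random.Generator, locus_id: str, length: int
) -> tuple[str, int, str, str]:
    """Random consensus with one SNP site; returns (consensus, pos, ref, alt)."""
    consensus = _random_consensus(rng, length)
    pos = int(rng.integers(0, length))
    ref = consensus[pos]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return consensus, pos, ref, alt


def _calls_from_freq(
    rng: np.random.Generator,
    samples: Sequence[str],
    freq_ref: float,
    ref: str,
    alt: str,
    missing_rate: float,
) -> dict[str, tuple[str, ...]]:
    calls: dict[str, tuple[str, ...]] = {}
    draws = rng.random(len(samples)) < freq_ref
    missing = rng.random(len(samples)) < missing_rate
    for s, is_ref, is_missing in zip(samples, draws, missing):
        if is_missing:
            continue
        calls[s] = (ref if is_ref else alt,)
    if not calls and samples:  # keep every locus genotyped somewhere
        calls[samples[0]] = (ref,)
    return calls


def simulate_catalog(config: SimConfig) -> SimBundle:
    """Generate a catalog + scheme with a complete truth sidecar."""
    rng = np.random.default_rng(config.seed)
    P = config.n_populations
    pops = [f"pop{i + 1}" for i in range(P)]
    habitats = config.habitats()
    groups = config.group_of_pop
    samples_by_pop = {
        pop: [f"{pop}_s{j + 1}" for j in range(config.samples_per_population)]
        for pop in pops
    }
    all_samples = [s for pop in pops for s in samples_by_pop[pop]]
    assignment = {s: pop for pop in pops for s in samples_by_pop[pop]}
    region = {
        pop: (f"grp{groups[i] + 1}" if groups is not None else f"region{i + 1}")
        for i, pop in enumerate(pops)
    }
    scheme = PopScheme(
        assignment=assignment,
        region=region,
        habitat={pop: habitats[i] for i, pop in enumerate(pops)},
        groups={pop: region[pop] for pop in pops} if groups is not None else None,
    )
    pop_F = config.pop_F()

    loci: list[RadLocus] = []
    truth: dict = {
        "contaminant_ids": [],
        "diploid_ids": [],
        "habitat_unique": {"saline": [], "freshwater": []},
        "private": {pop: [] for pop in pops},
    }

    # Shared biallelic tags under (possibly hierarchical) Balding–Nichols drift.
    n_base = config.n_loci
    p_anc = rng.uniform(0.05, 0.95, size=n_base)
    if groups is not None and config.group_F > 0:
        n_groups = max(groups) + 1
        p_group = np.empty((n_groups, n_base))
        for g in range(n_groups):
            p_group[g] = np.clip(_balding_nichols(rng, p_anc, config.group_F), 0.01, 0.99)
        parent = lambda i: p_group[groups[i]]  # noqa: E731
    else:
        parent = lambda i: p_anc  # noqa: E731
    p_pop = np.empty((P, n_base))
    for i in range(P):
        p_pop[i] = _balding_nichols(rng, parent(i), pop_F[i])

    for l in range(n_base):
        locus_id = f"L{l + 1:05d}"
        consensus, pos, ref, alt = _snp_locus(rng, locus_id, config.consensus_length)
        calls: dict[str, tuple[str, ...]] = {}
        for i, pop in enumerate(pops):
            calls.update(
                _calls_from_freq(rng, samples_by_pop[pop], p_pop[i, l], ref, alt, config.missing_rate)
            )
        loci.append(RadLocus(locus_id, consensus, (pos,), calls))

    # Invariant tags (no SNP) shared across populations.
    for l in range(config.n_invariant_loci):
        locus_id = f"I{l + 1:04d}"
        consensus = _random_consensus(rng, config.consensus_length)
        calls = {}
        missing = rng.random(len(all_samples)) < config.missing_rate
        for s, is_missing in zip(all_samples, missing):
            if not is_missing:
                calls[s] = ("",)
        if not calls:
            calls[all_samples[0]] = ("",)
        loci.append(RadLocus(locus_id, consensus, (), calls))

    # Population-private tags: genotyped only within one population.
    for i, pop in enumerate(pops):
        for l in range(config.n_private_per_pop):
            locus_id = f"P{pop}_{l + 1:03d}"
            consensus, pos, ref, alt = _snp_locus(rng, locus_id, config.consensus_length)
            freq = rng.uniform(0.1, 0.9)
            calls = _calls_from_freq(rng, samples_by_pop[pop], freq, ref, alt, config.missing_rate)
            loci.append(RadLocus(locus_id, consensus, (pos,), calls))
            truth["private"][pop].append(locus_id)

    # Habitat-restricted tags: never genotyped in the other habitat.
    for habitat in ("saline", "freshwater"):
        members = [s for pop in pops if scheme.habitat[pop] == habitat for s in samples_by_pop[pop]]
        if not members:
            continue
        for l in range(config.n_habitat_unique):
            locus_id = f"H{habitat[:3]}_{l + 1:03d}"
            consensus, pos, ref, alt = _snp_locus(rng, locus_id, config.consensus_length)
            freq = rng.uniform(0.1, 0.9)
            calls = _calls_from_freq(rng, members, freq, ref, alt, config.missing_rate)
            loci.append(RadLocus(locus_id, consensus, (pos,), calls))
            truth["habitat_unique"][habitat].append(locus_id)

    # Bacterial-contaminant tags: random presence across samples; flagged.
    for l in range(config.n_contaminant):
        locus_id = f"C{l + 1:03d}"
        consensus, pos, ref, alt = _snp_locus(rng, locus_id, config.consensus_length)
        subset = [s for s in all_samples if rng.random() < 0.4]
        if not subset:
            subset = [all_samples[0]]
        calls = _calls_from_freq(rng, subset, rng.uniform(0.2, 0.8), ref, alt, 0.0)
        loci.append(RadLocus(locus_id, consensus, (pos,), calls))
        truth["contaminant_ids"].append(locus_id)

    # Diploid artifacts: >=1 sample carries two distinct alleles at the tag.
    for l in range(config.n_diploid_artifact):
        locus_id = f"D{l + 1:03d}"
        consensus, pos, ref, alt = _snp_locus(rng, locus_id, config.consensus_length)
        calls = dict(
            _calls_from_freq(rng, all_samples, rng.uniform(0.3, 0.7), ref, alt, config.missing_rate)
        )
        genotyped = list(calls)
        n_dip = int(rng.integers(1, max(2, len(genotyped) // 3)))
        for s in rng.choice(genotyped, size=min(n_dip, len(genotyped)), replace=False):
            calls[s] = (ref, alt) if calls[s][0] == ref else (alt, ref)
        calls = {s: tuple(sorted(h)) for s, h in calls.items()}
        loci.append(RadLocus(locus_id, consensus, (pos,), calls))
        truth["diploid_ids"].append(locus_id)

    catalog = LocusCatalog(loci=tuple(loci), samples=tuple(all_samples))
    return SimBundle(catalog=catalog, scheme=scheme, truth=truth)


# ---------------------------------------------------------------------------
# Transcriptome simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimTranscriptome:
    """Simulated transcripts (id → sequence) plus their annotation table."""

    transcripts: Mapping[str, str]
    annotations: AnnotationTable
    truth: dict  # embedding map + designated GO terms per habitat

    def write(self, fasta_path: str | Path, annotation_path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=tid, description="") for tid, seq in self.transcripts.items()
        ]
        with open(fasta_path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        write_annotations(self.annotations, annotation_path)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _embed(
    rng: np.random.Generator, insert: str, flank: int, n_mismatch: int, revcomp: bool
) -> str:
    """Insert (possibly mutated/reverse-complemented) sequence between flanks.

    Mismatch positions are spaced at least 25 bp apart so that an exact
    11-mer anchor always survives for the seeded aligner.
    """
    s = list(insert)
    if n_mismatch:
        positions = list(range(5, len(s) - 5, 25))
        picks = rng.choice(len(positions), size=min(n_mismatch, len(positions)), replace=False)
        for k in picks:
            pos = positions[int(k)]
            s[pos] = str(rng.choice([b for b in "ACGT" if b != s[pos]]))
    core = "".join(s)
    if revcomp:
        core = reverse_complement(core)
    left = _random_consensus(rng, flank)
    right = _random_consensus(rng, flank)
    return left + core + right


def simulate_transcriptome(
    bundle: SimBundle,
    config: SimConfig,
    n_decoys: int = 20,
    flank: int = 80,
) -> SimTranscriptome:
    """Build transcripts embedding the habitat-restricted tag sequences.

    Each habitat's unique loci are distributed round-robin over that
    habitat's designated GO terms; each embedding transcript carries the
    term as its top annotation.  Decoy transcripts contain no embedded
    locus; some are annotated with neutral terms, some not at all.
    """
    if "habitat_unique" not in bundle.truth:
        raise ValueError("catalog bundle lacks the habitat-unique truth sidecar")
    rng = np.random.default_rng([config.seed, 104729])
    by_id = {loc.locus_id: loc for loc in bundle.catalog.loci}
    transcripts: dict[str, str] = {}
    annotations: dict[str, tuple[tuple[str, tuple[str, ...]], ...]] = {}
    embedding: dict[str, str] = {}
    designated: dict[str, dict[str, str]] = {"saline": {}, "freshwater": {}}
    term_pool = {"saline": SALINE_GO_TERMS, "freshwater": FRESHWATER_GO_TERMS}

    t_index = 0
    for habitat in ("saline", "freshwater"):
        unique_ids = bundle.truth["habitat_unique"][habitat]
        if not unique_ids:
            continue
        n_terms = min(len(term_pool[habitat]), max(1, len(unique_ids) // _LOCI_PER_GO_TERM))
        terms = term_pool[habitat][:n_terms]
        for term, label in terms:
            designated[habitat][term] = label
        for k, locus_id in enumerate(unique_ids):
            term, label = terms[k % n_terms]
            t_index += 1
            tid = f"T{t_index:04d}"
            n_mismatch = k % 3  # 0, 1 or 2 mismatches
            revcomp = k % 5 == 0
            transcripts[tid] = _embed(rng, by_id[locus_id].consensus, flank, n_mismatch, revcomp)
            annotations[tid] = ((label, (term,)),)
            embedding[locus_id] = tid

    for d in range(n_decoys):
        t_index += 1
        tid = f"T{t_index:04d}"
        transcripts[tid] = _random_consensus(rng, int(rng.integers(200, 400)))
        if d % 2 == 0:
            term, label = _DECOY_GO_TERMS[d % len(_DECOY_GO_TERMS)]
            annotations[tid] = ((label, (term,)),)

    truth = dict(bundle.truth)
    truth["embedding"] = embedding
    truth["designated_go"] = designated
    return SimTranscriptome(
        transcripts=transcripts,
        annotations=AnnotationTable(rows=annotations),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Study-mimic bundle
# ---------------------------------------------------------------------------

# Eight populations in four regions and two habitats, grouped into three
# genetic clusters: Antarctic saline lakes (moderate within-group drift),
# hydrologically connected Baltic saline sites (near-zero mutual divergence),
# and freshwater lakes including a strongly drifted Lake-Baikal-like
# population.  Between-group drift is high, mirroring the near-1 pairwise
# Phi_ST observed between regions.
_MIMIC_POPS = (
    # (population, region, habitat, group index, within-group F)
    ("ANT-Highway", "ANT", "saline", 0, 0.15),
    ("ANT-McNeil", "ANT", "saline", 0, 0.15),
    ("ANT-Vereteno", "ANT", "saline", 0, 0.15),
    ("BAL-GulfOfFinland", "BAL", "saline", 1, 0.02),
    ("BAL-Tvarminne", "BAL", "saline", 1, 0.02),
    ("SCA-Copenhagen", "SCA", "freshwater", 2, 0.30),
    ("SCA-Erken", "SCA", "freshwater", 2, 0.30),
    ("SIB-Baikal", "SIB", "freshwater", 2, 0.60),
)
_MIMIC_GROUPS = ("antarctic", "baltic", "freshwater")


@dataclass(frozen=True)
class StudyMimic:
    """Fixed-design end-to-end bundle: catalog, scheme, transcriptome."""

    bundle: SimBundle
    transcriptome: SimTranscriptome
    config: SimConfig

    @property
    def catalog(self) -> LocusCatalog:
        return self.bundle.catalog

    @property
    def scheme(self) -> PopScheme:
        return self.bundle.scheme

    @property
    def truth(self) -> dict:
        return self.transcriptome.truth

    @property
    def cluster_groups(self) -> dict[str, str]:
        return {pop: _MIMIC_GROUPS[g] for pop, _, _, g, _ in _MIMIC_POPS}


def make_study_mimic(seed: int = 1, samples_per_population: int = 12, n_loci: int = 200) -> StudyMimic:
    """Small fixed-design bundle mirroring the 8-population study layout."""
    config = SimConfig(
        seed=seed,
        n_populations=8,
        samples_per_population=samples_per_population,
        n_loci=n_loci,
        divergence_F=tuple(f for *_, f in _MIMIC_POPS),
        missing_rate=0.1,
        n_private_per_pop=8,
        n_habitat_unique=34,
        n_contaminant=12,
        n_diploid_artifact=6,
        n_invariant_loci=40,
        group_of_pop=tuple(g for _, _, _, g, _ in _MIMIC_POPS),
        group_F=0.8,
        habitat_of_pop=tuple(h for _, _, h, _, _ in _MIMIC_POPS),
    )
    bundle = simulate_catalog(config)
    # Rename generic pop1..pop8 to the study-like labels.
    names = {f"pop{i + 1}": _MIMIC_POPS[i][0] for i in range(8)}
    regions = {name: reg for name, reg, *_ in _MIMIC_POPS}
    assignment = {
        s.replace(old, names[old]): names[old]
        for s, old in ((s, p) for s, p in bundle.scheme.assignment.items())
    }
    scheme = PopScheme(
        assignment=assignment,
        region={names[p]: regions[names[p]] for p in names},
        habitat={names[p]: bundle.scheme.habitat[p] for p in names},
        groups={name: _MIMIC_GROUPS[g] for name, _, _, g, _ in _MIMIC_POPS},
    )
    renamed_loci = tuple(
        RadLocus(
            loc.locus_id,
            loc.consensus,
            loc.snp_positions,
            {_rename_sample(s, names): haps for s, haps in loc.calls.items()},
        )
        for loc in bundle.catalog.loci
    )
    catalog = LocusCatalog(
        loci=renamed_loci,
        samples=tuple(_rename_sample(s, names) for s in bundle.catalog.samples),
    )
    truth = dict(bundle.truth)
    truth["private"] = {names[pop]: ids for pop, ids in bundle.truth["private"].items()}
    bundle = SimBundle(catalog=catalog, scheme=scheme, truth=truth)
    transcriptome = simulate_transcriptome(bundle, config)
    return StudyMimic(bundle=bundle, transcriptome=transcriptome, config=config)


def _rename_sample(sample: str, names: Mapping[str, str]) -> str:
    pop, _, rest = sample.partition("_")
    return f"{names[pop]}_{rest}"
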