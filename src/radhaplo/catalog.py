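"""Domain containers and on-disk formats for haploid RAD-seq data.

The central object is the :class:`LocusCatalog`: a collection of RAD tags
(short consensus sequences anchored at restriction sites) with per-sample
haploid allele calls.  Every downstream stage — blacklisting, diploid
detection, SNP-matrix construction, population statistics, clustering and
the habitat contrast — consumes these containers and never re-reads raw
files.

Conventions
-----------
* ``snp_positions`` are **0-based** offsets into the consensus sequence.
* A haploid call is one haplotype string (one character per SNP position).
  A sample carrying more than one distinct haplotype at a tag marks a
  putative diploid/paralogous locus.
* Missing data: a sample simply has no call at a locus.  In the catalog
  TSV an explicit ``.`` in the alleles column is also accepted as missing.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

_VALID_ALLELES = frozenset("ACGT")
_VALID_CONSENSUS = frozenset("ACGTN")

CATALOG_COLUMNS = ("locus_id", "consensus", "snp_positions", "sample_id", "alleles")


class CatalogFormatError(ValueError):
    """Malformed on-disk catalog/popmap/distance input."""


@dataclass(frozen=True)
class RadLocus:
    """One RAD tag: consensus sequence, SNP offsets, per-sample haploid calls.

    ``calls`` maps sample id to the tuple of *distinct* haplotypes observed
    for that sample (each haplotype has one character per SNP position).
    """

    locus_id: str
    consensus: str
    snp_positions: tuple[int, ...]
    calls: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValueError("locus_id must be non-empty")
        if set(self.consensus) - _VALID_CONSENSUS:
            bad = sorted(set(self.consensus) - _VALID_CONSENSUS)
            raise ValueError(f"locus {self.locus_id}: consensus has invalid characters {bad}")
        pos = self.snp_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"locus {self.locus_id}: snp_positions must be strictly increasing")
        if pos and (pos[0] < 0 or pos[-1] >= len(self.consensus)):
            raise ValueError(f"locus {self.locus_id}: snp offset out of range 0..{len(self.consensus) - 1}")
        n = len(pos)
        for sample, haps in self.calls.items():
            if not haps:
                raise ValueError(f"locus {self.locus_id}: sample {sample} has an empty call list")
            for hap in haps:
                if len(hap) != n:
                    raise ValueError(
                        f"locus {self.locus_id}: sample {sample} haplotype {hap!r} "
                        f"does not match {n} SNP position(s)"
                    )
                if set(hap) - _VALID_ALLELES:
                    raise ValueError(
                        f"locus {self.locus_id}: sample {sample} allele not in A/C/G/T: {hap!r}"
                    )

    @property
    def is_variant(self) -> bool:
        return len(self.snp_positions) > 0

    def is_multiallelic_sample(self, sample: str) -> bool:
        """True when the sample shows >1 distinct haplotype at this tag."""
        return len(self.calls.get(sample, ())) > 1


@dataclass(frozen=True)
class LocusCatalog:
    """Ordered collection of :class:`RadLocus` plus the sample roster."""

    loci: tuple[RadLocus, ...]
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate locus ids: {dup[:5]}")
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample ids")
        roster = set(self.samples)
        for loc in self.loci:
            stray = set(loc.calls) - roster
            if stray:
                raise ValueError(
                    f"locus {loc.locus_id}: calls for unknown sample(s) {sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(loc.locus_id for loc in self.loci)

    def get(self, locus_id: str) -> RadLocus:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)


@dataclass(frozen=True)
class SnpMatrix:
    """Samples x loci haploid genotype matrix (one SNP per RAD tag).

    ``genotype`` holds allele-index codes; :data:`MISSING` (−1) marks a
    sample not genotyped at a locus.  ``allele_labels[j]`` lists the
    nucleotide labels that codes at locus ``j`` index into.
    """

    MISSING = -1

    samples: tuple[str, ...]
    loci: tuple[str, ...]
    genotype: np.ndarray
    allele_labels: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        g = np.asarray(self.genotype, dtype=np.int16)
        object.__setattr__(self, "genotype", g)
        if g.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotype shape {g.shape} != (samples={len(self.samples)}, loci={len(self.loci)})"
            )
        if len(self.allele_labels) != len(self.loci):
            raise ValueError("allele_labels must have one entry per locus")
        for j, labels in enumerate(self.allele_labels):
            col = g[:, j]
            valid = col[col != self.MISSING]
            if valid.size and (valid.min() < 0 or valid.max() >= len(labels)):
                raise ValueError(f"locus {self.loci[j]}: genotype code out of range")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        return self.genotype == self.MISSING

    def subset_loci(self, keep: Sequence[int]) -> "SnpMatrix":
        keep = list(keep)
        return SnpMatrix(
            samples=self.samples,
            loci=tuple(self.loci[j] for j in keep),
            genotype=self.genotype[:, keep],
            allele_labels=tuple(self.allele_labels[j] for j in keep),
        )

    def subset_samples(self, keep: Sequence[str]) -> "SnpMatrix":
        idx = [self.samples.index(s) for s in keep]
        return SnpMatrix(
            samples=tuple(keep),
            loci=self.loci,
            genotype=self.genotype[idx, :],
            allele_labels=self.allele_labels,
        )


HABITATS = ("freshwater", "saline")


@dataclass(frozen=True)
class PopScheme:
    """Sample → population assignment with per-population region/habitat.

    ``groups`` optionally nests populations into higher-level groups for
    hierarchical AMOVA (e.g. the regions identified in an ordination).
    """

    assignment: Mapping[str, str]
    region: Mapping[str, str] = field(default_factory=dict)
    habitat: Mapping[str, str] = field(default_factory=dict)
    groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        pops = set(self.assignment.values())
        for pop, hab in self.habitat.items():
            if hab not in HABITATS:
                raise ValueError(f"habitat for {pop} must be one of {HABITATS}, got {hab!r}")
        for mapping, what in ((self.region, "region"), (self.habitat, "habitat")):
            stray = set(mapping) - pops
            if stray:
                raise ValueError(f"{what} given for unknown population(s) {sorted(stray)[:5]}")
        if self.groups is not None:
            missing = pops - set(self.groups)
            if missing:
                raise ValueError(f"groups missing population(s) {sorted(missing)[:5]}")

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pop in self.assignment.values():
            seen.setdefault(pop)
        return tuple(seen)

    def samples_of(self, pop: str) -> tuple[str, ...]:
        return tuple(s for s, p in self.assignment.items() if p == pop)

    def population_of(self, sample: str) -> str:
        return self.assignment[sample]

    def require_covers(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.assignment]
        if missing:
            raise ValueError(f"samples without population assignment: {missing[:5]}")

    def habitat_grouping(self) -> dict[str, str]:
        """Population → habitat map, requiring habitat for every population."""
        missing = [p for p in self.populations if p not in self.habitat]
        if missing:
            raise ValueError(f"populations without habitat: {missing[:5]}")
        return {p: self.habitat[p] for p in self.populations}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix over labelled units.

    ``kind`` is ``"genetic"`` (Phi_ST-like, in [−1, 1]) or ``"geographic"``
    (kilometres, non-negative).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.array_equal(v, v.T):
            raise ValueError("distance matrix must be exactly symmetric")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        if self.kind == "geographic":
            if np.any(v < 0):
                raise ValueError("geographic distances must be non-negative")
        elif self.kind == "genetic":
            if np.any(v < -1 - 1e-9) or np.any(v > 1 + 1e-9):
                raise ValueError("genetic distances must lie in [-1, 1]")
        else:
            raise ValueError(f"kind must be 'genetic' or 'geographic', got {self.kind!r}")
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major pair order."""
        iu = np.triu_indices(len(self.labels), 1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(lab) for lab in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.kind)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# Catalog TSV dialect
# ---------------------------------------------------------------------------
#
# One header line (CATALOG_COLUMNS, tab-separated), optionally preceded by a
# "#samples:\ts1,s2,..." comment declaring the sample roster order.  One row
# per (locus, sample, haplotype); repeated rows per sample record additional
# haplotypes (putative diploids).  A row with sample_id "." declares a locus
# with no genotyped samples; alleles "." marks an explicitly missing call.


def read_catalog(path: str | Path) -> LocusCatalog:
    """Read the catalog TSV dialect into a validated :class:`LocusCatalog`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()
    declared_samples: list[str] | None = None
    lineno = 0
    if lines and lines[0].startswith("#samples:"):
        roster = lines[0].split("\t", 1)
        declared_samples = roster[1].split(",") if len(roster) == 2 and roster[1] else []
        lines = lines[1:]
        lineno = 1
    if not lines:
        raise CatalogFormatError(f"{path}: no loci (empty file)")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != CATALOG_COLUMNS:
        raise CatalogFormatError(f"{path}:{lineno + 1}: bad header {header}")
    body = lines[1:]
    if not any(line.strip() for line in body):
        raise CatalogFormatError(f"{path}: no loci")

    # locus_id -> (consensus, snp_positions, {sample: [haplotypes]})
    loci: dict[str, tuple[str, tuple[int, ...], dict[str, list[str]]]] = {}
    seen_samples: dict[str, None] = {}
    for offset, line in enumerate(body, start=lineno + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise CatalogFormatError(f"{path}:{offset}: expected 5 columns, got {len(fields)}")
        locus_id, consensus, pos_field, sample_id, allele_field = fields
        try:
            positions = tuple(int(p) for p in pos_field.split(",")) if pos_field else ()
        except ValueError as exc:
            raise CatalogFormatError(f"{path}:{offset}: bad snp_positions {pos_field!r}") from exc
        if locus_id in loci:
            prev_cons, prev_pos, calls = loci[locus_id]
            if prev_cons != consensus or prev_pos != positions:
                raise CatalogFormatError(
                    f"{path}:{offset}: locus {locus_id} redefined with different consensus/positions"
                )
        else:
            calls = {}
            loci[locus_id] = (consensus, positions, calls)
        if sample_id == ".":
            continue
        seen_samples.setdefault(sample_id)
        if allele_field == ".":
            continue  # explicitly missing call
        hap = "".join(allele_field.split(",")) if allele_field else ""
        calls.setdefault(sample_id, [])
        if hap not in calls[sample_id]:
            calls[sample_id].append(hap)

    samples = tuple(declared_samples) if declared_samples is not None else tuple(seen_samples)
    try:
        rad_loci = tuple(
            RadLocus(
                locus_id=lid,
                consensus=cons,
                snp_positions=pos,
                calls={s: tuple(sorted(haps)) for s, haps in calls.items()},
            )
            for lid, (cons, pos, calls) in loci.items()
        )
        return LocusCatalog(loci=rad_loci, samples=samples)
    except ValueError as exc:
        raise CatalogFormatError(f"{path}: {exc}") from exc


def write_catalog(catalog: LocusCatalog, path: str | Path) -> None:
    """Write a catalog in canonical form (loci sorted by id, roster order)."""
    path = Path(path)
    out: list[str] = [f"#samples:\t{','.join(catalog.samples)}"]
    out.append("\t".join(CATALOG_COLUMNS))
    order = {s: i for i, s in enumerate(catalog.samples)}
    for loc in sorted(catalog.loci, key=lambda l: l.locus_id):
        pos_field = ",".join(str(p) for p in loc.snp_positions)
        if not loc.calls:
            out.append("\t".join([loc.locus_id, loc.consensus, pos_field, ".", "."]))
            continue
        for sample in sorted(loc.calls, key=order.__getitem__):
            for hap in sorted(loc.calls[sample]):
                out.append(
                    "\t".join([loc.locus_id, loc.consensus, pos_field, sample, ",".join(hap)])
                )
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------


def read_popmap(path: str | Path) -> PopScheme:
    """Read sample→population TSV (columns sample, population, region[, habitat])."""
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise CatalogFormatError(f"{path}: empty popmap")
    header = lines[0].split("\t")
    required = ["sample", "population", "region"]
    if header[: len(required)] != required:
        raise CatalogFormatError(f"{path}: header must start with {required}, got {header}")
    has_habitat = len(header) > 3 and header[3] == "habitat"
    assignment: dict[str, str] = {}
    region: dict[str, str] = {}
    habitat: dict[str, str] = {}
    for offset, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < 3:
            raise CatalogFormatError(f"{path}:{offset}: expected >=3 columns")
        sample, pop, reg = fields[0], fields[1], fields[2]
        if sample in assignment:
            raise CatalogFormatError(f"{path}:{offset}: duplicate sample {sample}")
        assignment[sample] = pop
        if pop in region and region[pop] != reg:
            raise CatalogFormatError(f"{path}:{offset}: population {pop} mapped to two regions")
        region[pop] = reg
        if has_habitat:
            hab = fields[3]
            if hab not in HABITATS:
                raise CatalogFormatError(
                    f"{path}:{offset}: habitat must be freshwater or saline, got {hab!r}"
                )
            if pop in habitat and habitat[pop] != hab:
                raise CatalogFormatError(f"{path}:{offset}: population {pop} has two habitats")
            habitat[pop] = hab
    return PopScheme(assignment=assignment, region=region, habitat=habitat)


def write_popmap(scheme: PopScheme, path: str | Path) -> None:
    cols = ["sample", "population", "region"]
    if scheme.habitat:
        cols.append("habitat")
    rows = ["\t".join(cols)]
    for sample, pop in scheme.assignment.items():
        row = [sample, pop, scheme.region.get(pop, pop)]
        if scheme.habitat:
            row.append(scheme.habitat[pop])
        rows.append("\t".join(row))
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Combined Phi_ST / geographic-distance table (Table-2 layout)
# ---------------------------------------------------------------------------


def read_distance_table2(path: str | Path) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Read a square TSV whose upper triangle is Phi_ST, lower triangle km.

    Returns (genetic, geographic) matrices sharing one label order.
    """
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    header = lines[0].split("\t")
    if header[0] not in ("", "population"):
        raise CatalogFormatError(f"{path}: first header cell must be empty or 'population'")
    labels = header[1:]
    n = len(labels)
    if len(lines) - 1 != n:
        raise CatalogFormatError(f"{path}: non-square table ({len(lines) - 1} rows, {n} columns)")
    raw = np.full((n, n), np.nan)
    for i, line in enumerate(lines[1:]):
        fields = line.split("\t")
        if fields[0] != labels[i]:
            raise CatalogFormatError(
                f"{path}: row label {fields[0]!r} does not match column label {labels[i]!r}"
            )
        if len(fields) - 1 != n:
            raise CatalogFormatError(f"{path}: row {labels[i]} has {len(fields) - 1} cells")
        for j, cell in enumerate(fields[1:]):
            if i == j:
                continue
            raw[i, j] = float(cell)
    genetic = np.zeros((n, n))
    geographic = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            genetic[i, j] = genetic[j, i] = raw[i, j]
            geographic[i, j] = geographic[j, i] = raw[j, i]
    lab = tuple(labels)
    return (
        DistanceMatrix(lab, genetic, "genetic"),
        DistanceMatrix(lab, geographic, "geographic"),
    )


def load_table2() -> tuple[DistanceMatrix, DistanceMatrix]:
    """Load the packaged 8-population Phi_ST / km matrices."""
    source = importlib.resources.files("radhaplo.data") / "table2_phist_km.tsv"
    with importlib.resources.as_file(source) as p:
        return read_distance_table2(p)


# ---------------------------------------------------------------------------
# Exports: haploid VCF and STRUCTURE one-row-per-haploid format
# ---------------------------------------------------------------------------


def write_vcf(matrix: SnpMatrix, path: str | Path) -> None:
    """Write the SNP matrix as a minimal haploid VCF (GT = allele index)."""
    out = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
    ]
    for lid in matrix.loci:
        out.append(f"##contig=<ID={lid}>")
    out.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples))
    for j, lid in enumerate(matrix.loci):
        labels = matrix.allele_labels[j]
        ref = labels[0]
        alt = ",".join(labels[1:]) if len(labels) > 1 else "."
        gts = [
            "." if code == SnpMatrix.MISSING else str(int(code))
            for code in matrix.genotype[:, j]
        ]
        out.append(f"{lid}\t1\t{lid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    Path(path).write_text("\n".join(out) + "\n")


def write_structure(matrix: SnpMatrix, scheme: PopScheme, path: str | Path) -> None:
    """Write STRUCTURE input: one row per haploid individual, −9 = missing."""
    scheme.require_covers(matrix.samples)
    pops = {p: i + 1 for i, p in enumerate(scheme.populations)}
    rows = []
    for i, sample in enumerate(matrix.samples):
        codes = [
            "-9" if code == SnpMatrix.MISSING else str(int(code))
            for code in matrix.genotype[i, :]
        ]
        rows.append("\t".join([sample, str(pops[scheme.population_of(sample)])] + codes))
    Path(path).write_text("\n".join(rows) + "\n")


GO_TERM_RE = re.compile(r"^[A-Z]:\d{7}$")


@dataclass(frozen=True)
class AnnotationTable:
    """Transcript → ordered annotations, each (label, list of GO terms)."""

    rows: Mapping[str, tuple[tuple[str, tuple[str, ...]], ...]]

    def __post_init__(self) -> None:
        for tid, annots in self.rows.items():
            for label, terms in annots:
                for term in terms:
                    if not GO_TERM_RE.match(term):
                        raise ValueError(f"{tid}: malformed GO term {term!r}")

    def annotations_of(self, transcript_id: str) -> tuple[tuple[str, tuple[str, ...]], ...]:
        return self.rows.get(transcript_id, ())


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read annotation TSV: transcript_id, rank, label, semicolon-joined GO terms."""
    rows: dict[str, list[tuple[int, str, tuple[str, ...]]]] = {}
    for offset, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("transcript_id\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise CatalogFormatError(f"{path}:{offset}: expected 4 columns")
        tid, rank, label, terms = fields
        go = tuple(t for t in terms.split(";") if t)
        rows.setdefault(tid, []).append((int(rank), label, go))
    return AnnotationTable(
        rows={
            tid: tuple((label, go) for _, label, go in sorted(annots))
            for tid, annots in rows.items()
        }
    )


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    out = ["transcript_id\trank\tannotation_label\tgo_terms"]
    for tid in table.rows:
        for rank, (label, terms) in enumerate(table.rows[tid], start=1):
            out.append(f"{tid}\t{rank}\t{label}\t{';'.join(terms)}")
    Path(path).write_text("\n".join(out) + "\n")
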