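"""End-to-end orchestration: simulate → filter → stats → structure → contrast.

A run is a pure function of (inputs, config, seed).  Every stage logs its
parameter values and removal counts; a manifest JSON records the seed,
stage list and a checksum of every artifact so two runs with identical
config produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import filters as flt
from . import popgen, structure
from .contrast import ContrastParams, TranscriptomeIndex, filter_contrast, tally_contrast
from .simulate import SimBundle, SimConfig, make_study_mimic, simulate_catalog, simulate_transcriptome

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "stats", "structure", "contrast")


@dataclass
class RunConfig:
    """Pipeline configuration; see `RunConfig.from_yaml` for the file format."""

    seed: int
    outdir: str
    simulate: dict = field(default_factory=dict)  # SimConfig overrides, or study_mimic: true
    inputs: dict = field(default_factory=dict)  # catalog/popmap/transcriptome/annotations paths
    filter: dict = field(default_factory=dict)  # p, r, diploid_threshold, blacklist
    stats: dict = field(default_factory=dict)  # n_perm, geographic (path to Table-2-style TSV)
    structure: dict = field(default_factory=dict)  # kmin, kmax, burnin, reps, iters
    contrast: dict = field(default_factory=dict)  # min_count, min_fold

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw or "outdir" not in raw:
            raise ValueError("config must set seed and outdir")
        known = {f for f in cls.__dataclass_fields__}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config key(s): {sorted(stray)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in fixed order; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": [], "artifacts": {}}
    artifacts: dict[str, Path] = {}

    def record(stage: str, **info: Any) -> None:
        manifest["stages"].append({"stage": stage, **info})

    # -- simulate / load ---------------------------------------------------
    if config.inputs:
        catalog = cat.read_catalog(config.inputs["catalog"])
        scheme = cat.read_popmap(config.inputs["popmap"])
        index = (
            TranscriptomeIndex.from_fasta(config.inputs["transcriptome"])
            if "transcriptome" in config.inputs
            else None
        )
        annotations = (
            cat.read_annotations(config.inputs["annotations"])
            if "annotations" in config.inputs
            else None
        )
        blacklist = set()
        if config.filter.get("blacklist"):
            blacklist = set(Path(config.filter["blacklist"]).read_text().split())
        record("simulate", skipped=True, loaded=sorted(config.inputs))
    else:
        sim_opts = dict(config.simulate)
        if sim_opts.pop("study_mimic", False):
            mimic = make_study_mimic(seed=config.seed, **sim_opts)
            bundle, trans = mimic.bundle, mimic.transcriptome
        else:
            sim_config = SimConfig(seed=config.seed, **sim_opts)
            bundle = simulate_catalog(sim_config)
            trans = simulate_transcriptome(bundle, sim_config)
        bundle = SimBundle(bundle.catalog, bundle.scheme, trans.truth)
        bundle.write(outdir)
        trans.write(outdir / "transcriptome.fasta", outdir / "annotations.tsv")
        for name in ("catalog.tsv", "popmap.tsv", "truth.json", "transcriptome.fasta", "annotations.tsv"):
            artifacts[name] = outdir / name
        catalog, scheme = bundle.catalog, bundle.scheme
        index = TranscriptomeIndex(trans.transcripts)
        annotations = trans.annotations
        blacklist = set(bundle.truth.get("contaminant_ids", ()))
        record("simulate", n_loci=len(catalog), n_samples=len(catalog.samples))

    # -- filter ------------------------------------------------------------
    params = flt.FilterParams(
        p=config.filter.get("p", 6),
        r=config.filter.get("r", 0.5),
        diploid_sample_threshold=config.filter.get("diploid_threshold", 1),
    )
    n0 = len(catalog)
    catalog_bl = flt.apply_blacklist(catalog, blacklist)
    diploid = flt.detect_diploid_loci(catalog_bl, params)
    catalog_hap = flt.apply_blacklist(catalog_bl, diploid)
    first = flt.first_snp_matrix(catalog_hap)
    matrix = flt.presence_filter(first.matrix, scheme, params)
    report = {
        "input_loci": n0,
        "blacklisted": n0 - len(catalog_bl),
        "diploid": len(diploid),
        "variant_tags": first.matrix.n_loci,
        "invariant_tags": first.n_invariant,
        "after_presence_filter": matrix.n_loci,
        "p": params.p,
        "r": params.r,
    }
    (outdir / "filter_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    _write_matrix_tsv(matrix, outdir / "snp_matrix.tsv")
    artifacts["filter_report.json"] = outdir / "filter_report.json"
    artifacts["snp_matrix.tsv"] = outdir / "snp_matrix.tsv"
    record("filter", **report)

    # -- stats -------------------------------------------------------------
    # diversity (incl. private loci) is summarized before the p/r selection,
    # which by construction removes population-private tags
    diversity = popgen.diversity_table(first.matrix, first.invariant_presence, scheme)
    pd.DataFrame([asdict(d) for d in diversity]).to_csv(
        outdir / "diversity.tsv", sep="\t", index=False, float_format="%.6g"
    )
    phist = popgen.pairwise_phist(matrix, scheme)
    _write_square_tsv(phist, outdir / "phist.tsv")
    groups = scheme.groups
    if groups is None:
        n_regions = len(set(scheme.region.values()))
        if 2 <= n_regions < len(scheme.populations):
            groups = dict(scheme.region)
        else:
            groups = None  # two-level fallback
    amova_res = popgen.amova(matrix, scheme, groups)
    (outdir / "amova.json").write_text(
        json.dumps(
            {
                "ss": amova_res.ss,
                "df": amova_res.df,
                "variance_components": amova_res.variance_components,
                "percentages": amova_res.percentages,
                "phi": amova_res.phi,
            },
            indent=1,
            sort_keys=True,
        )
    )
    mantel_out = None
    if config.stats.get("geographic"):
        _, geographic = cat.read_distance_table2(config.stats["geographic"])
        mantel = popgen.mantel_ibd(
            phist, geographic, n_perm=config.stats.get("n_perm", 999), seed=config.seed
        )
        mantel_out = asdict(mantel)
        (outdir / "mantel.json").write_text(json.dumps(mantel_out, indent=1, sort_keys=True))
        artifacts["mantel.json"] = outdir / "mantel.json"
    for name in ("diversity.tsv", "phist.tsv", "amova.json"):
        artifacts[name] = outdir / name
    record("stats", n_populations=len(phist.labels), mantel=bool(mantel_out))

    # -- structure ---------------------------------------------------------
    ord_res = structure.pcoa(phist)
    coords = pd.DataFrame(
        ord_res.coordinates,
        index=list(ord_res.labels),
        columns=[f"axis{i + 1}" for i in range(ord_res.coordinates.shape[1])],
    )
    coords.to_csv(outdir / "pcoa.tsv", sep="\t", float_format="%.6g")
    kmin = config.structure.get("kmin", 1)
    kmax = config.structure.get("kmax", 5)
    iters = config.structure.get("iters", 3)
    burnin = config.structure.get("burnin", 1000)
    reps = config.structure.get("reps", 2000)
    runs = []
    for K in range(kmin, kmax + 1):
        for it in range(iters):
            runs.append(
                structure.gibbs_noadmix(
                    matrix, K, burnin=burnin, reps=reps, seed=config.seed * 1000 + K * 10 + it
                )
            )
    ev = structure.evanno(runs)
    ev_rows = [
        {
            "K": k,
            "mean_lnP": ev.mean_lnp[k],
            "sd_lnP": ev.sd_lnp[k],
            "delta_K": ev.delta_k[k],
        }
        for k in ev.k_values
    ]
    pd.DataFrame(ev_rows).to_csv(outdir / "evanno.tsv", sep="\t", index=False, float_format="%.6g")
    best_run = max((r for r in runs if r.K == ev.best_k), key=lambda r: r.log_prob_data)
    q = pd.DataFrame(
        best_run.membership,
        index=list(matrix.samples),
        columns=[f"Q{k + 1}" for k in range(best_run.K)],
    )
    q.insert(0, "population", [scheme.population_of(s) for s in matrix.samples])
    q.to_csv(outdir / "assignments.tsv", sep="\t", float_format="%.4f")
    for name in ("pcoa.tsv", "evanno.tsv", "assignments.tsv"):
        artifacts[name] = outdir / name
    record("structure", best_k=ev.best_k, k_grid=[kmin, kmax], iters=iters)

    # -- contrast ----------------------------------------------------------
    contrast_done = False
    if index is not None and annotations is not None and scheme.habitat:
        cparams = ContrastParams(
            min_count=config.contrast.get("min_count", 10),
            min_fold=config.contrast.get("min_fold", 10.0),
        )
        unique = flt.group_unique_loci(catalog_hap, scheme, scheme.habitat_grouping())
        table, log = tally_contrast(unique, catalog_hap, index, annotations, cparams)
        salt, fresh = filter_contrast(table, cparams)
        table.to_csv(outdir / "go_contrast.tsv", sep="\t", index=False)
        log.to_csv(outdir / "go_contrast_loci.tsv", sep="\t", index=False)
        (outdir / "contrast_unique_terms.json").write_text(
            json.dumps({"saltwater_unique": salt, "freshwater_unique": fresh}, indent=1)
        )
        for name in ("go_contrast.tsv", "go_contrast_loci.tsv", "contrast_unique_terms.json"):
            artifacts[name] = outdir / name
        record(
            "contrast",
            n_unique_loci={g: len(v) for g, v in unique.items()},
            saltwater_unique=len(salt),
            freshwater_unique=len(fresh),
        )
        contrast_done = True
    else:
        record("contrast", skipped=True)

    manifest["artifacts"] = {name: _sha256(path) for name, path in sorted(artifacts.items())}
    manifest["contrast_done"] = contrast_done
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_matrix_tsv(matrix: cat.SnpMatrix, path: Path) -> None:
    df = pd.DataFrame(matrix.genotype, index=list(matrix.samples), columns=list(matrix.loci))
    df.to_csv(path, sep="\t")


def _write_square_tsv(dm: cat.DistanceMatrix, path: Path) -> None:
    df = pd.DataFrame(dm.values, index=list(dm.labels), columns=list(dm.labels))
    df.index.name = "population"
    df.to_csv(path, sep="\t", float_format="%.6g")


def report_tables(bundle_dir: str | Path) -> dict[str, Path]:
    """Regenerate the three report-style TSVs from a completed run directory.

    table1: per-population diversity summary; table2: merged square matrix
    (Phi_ST above the diagonal, geographic km below when available);
    table3: GO contrast counts.  Regeneration is idempotent.
    """
    bundle_dir = Path(bundle_dir)
    manifest_path = bundle_dir / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"{bundle_dir} is not a completed run (no manifest.json)")
    out: dict[str, Path] = {}

    div = pd.read_csv(bundle_dir / "diversity.tsv", sep="\t")
    table1 = div.rename(
        columns={
            "population": "Population",
            "n_sites_total": "Total RAD sites",
            "n_variant": "Variant sites",
            "n_private": "Private loci",
            "pi": "Nucleotide diversity (pi)",
            "gene_diversity": "Nei heterozygosity",
        }
    )
    table1.to_csv(bundle_dir / "table1.tsv", sep="\t", index=False)
    out["table1"] = bundle_dir / "table1.tsv"

    phist = pd.read_csv(bundle_dir / "phist.tsv", sep="\t", index_col=0)
    merged = phist.copy()
    geo_path = bundle_dir / "geographic.tsv"
    if geo_path.exists():
        geo = pd.read_csv(geo_path, sep="\t", index_col=0)
        n = len(merged)
        for i in range(n):
            for j in range(i):
                merged.iloc[i, j] = geo.iloc[i, j]
    merged.to_csv(bundle_dir / "table2.tsv", sep="\t")
    out["table2"] = bundle_dir / "table2.tsv"

    contrast_path = bundle_dir / "go_contrast.tsv"
    if contrast_path.exists():
        table3 = pd.read_csv(contrast_path, sep="\t")
        table3.to_csv(bundle_dir / "table3.tsv", sep="\t", index=False)
        out["table3"] = bundle_dir / "table3.tsv"
    return out
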