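"""End-to-end pipeline: discover -> quantify -> test -> intersect -> correlate.

Consumes an on-disk cohort (per-sample VCFs plus annotation files and a
sample sheet), runs every analysis stage, writes TSV outputs and a
deterministic JSON summary, and logs versions, seed and a config hash. Any
stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    GeneModels,
    KnownSiteCatalog,
    RepeatTrack,
    read_fasta,
    read_position_bed,
)
from .config import ThresholdSet
from .differential import (
    average_glm,
    differential_editing,
    pca_on_sites,
    select_differential,
)
from .editing_quant import build_matrix, sample_average_editing
from .integration import editing_expression_correlations, intersect_gene_sets
from .site_discovery import QcOptions, discover_sites, summarize_editome
from .vcfio import read_variant_calls

logger = logging.getLogger(__name__)

#: file names expected inside a fixture directory
FIXTURE_FILES = {
    "vcf_dir": "vcf",
    "samples": "samples.tsv",
    "gff": "genes.gff3",
    "repeats": "repeats.bed",
    "snps": "snps.bed",
    "catalog": "catalog.tsv",
    "genome": "genome.fa",
    "expression": "expression.tsv",
    "coverage": "coverage.tsv",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _resolve_paths(config: Dict) -> Dict[str, Optional[Path]]:
    paths: Dict[str, Optional[Path]] = {}
    fixture = config.get("fixture_dir")
    for key, default_name in FIXTURE_FILES.items():
        if key in config and config[key] is not None:
            paths[key] = Path(config[key])
        elif fixture is not None:
            cand = Path(fixture) / default_name
            paths[key] = cand if cand.exists() else None
        else:
            paths[key] = None
    required = ("vcf_dir", "samples", "gff", "catalog")
    missing = [k for k in required if paths.get(k) is None]
    if missing:
        raise PipelineError(f"stage 'inputs': missing required inputs {missing}")
    return paths


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: Dict, out_dir: Optional[str] = None) -> Dict:
    """Run the full analysis described by ``config`` and return the summary.

    Config keys: ``fixture_dir`` (directory of standard fixture files) or
    explicit paths (``vcf_dir``, ``samples``, ``gff``, ``repeats``, ``snps``,
    ``catalog``, ``genome``, ``expression``, ``coverage``); ``out``;
    ``thresholds`` (mapping); ``qc`` (mapping of QcOptions fields);
    ``min_samples_called``; ``family``; ``p_threshold``;
    ``key_gene_min_sets``; ``seed``.
    """
    out = Path(out_dir or config.get("out", "editome_out"))
    out.mkdir(parents=True, exist_ok=True)
    paths = _resolve_paths(config)
    thresholds = ThresholdSet(**config.get("thresholds", {}))
    qc = QcOptions(**config.get("qc", {}))
    p_threshold = float(config.get("p_threshold", 0.05))
    family = config.get("family", "binomial")
    case_label = config.get("case_label", "sepsis")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:  # noqa: BLE001 - reported with stage name
            raise PipelineError(f"stage '{name}' failed: {e}") from e

    # --- load -------------------------------------------------------------
    samples = stage("load", pd.read_csv, paths["samples"], sep="\t")
    gene_models = stage("load", GeneModels.from_gff3, paths["gff"])
    catalog = stage("load", KnownSiteCatalog.from_tsv, paths["catalog"])
    repeats = (
        stage("load", RepeatTrack.from_bed, paths["repeats"]) if paths["repeats"] else None
    )
    snp_trees = (
        stage("load", read_position_bed, paths["snps"]) if paths["snps"] else None
    )
    genome = stage("load", read_fasta, paths["genome"]) if paths["genome"] else None
    if genome is None and qc.homopolymer_filter:
        qc = QcOptions(**{**qc.__dict__, "homopolymer_filter": False})
        logger.warning("no reference genome supplied; homopolymer filter disabled")
    expression = (
        stage("load", pd.read_csv, paths["expression"], sep="\t", index_col=0)
        if paths["expression"]
        else None
    )
    coverage = (
        stage("load", pd.read_csv, paths["coverage"], sep="\t", index_col=0)
        if paths["coverage"]
        else None
    )

    def _read_calls():
        calls = {}
        for sid in samples["sample_id"]:
            vcf = Path(paths["vcf_dir"]) / f"{sid}.vcf"
            if not vcf.exists():
                logger.warning("no VCF for sample %s", sid)
                calls[sid] = []
            else:
                calls[sid] = read_variant_calls(vcf, sample_id=sid)
        return calls

    calls = stage("read_vcfs", _read_calls)

    # --- discover ---------------------------------------------------------
    disc = stage(
        "discover",
        discover_sites,
        calls,
        gene_models,
        catalog,
        thresholds=thresholds,
        snp_trees=snp_trees,
        genome=genome,
        repeats=repeats,
        qc_options=qc,
        min_samples_called=int(config.get("min_samples_called", 1)),
    )
    disc.to_frame().to_csv(out / "sites.tsv", sep="\t", index=False)
    disc.audit.to_csv(out / "audit.tsv", sep="\t", index=False)
    summary_sites = summarize_editome(disc.sites, disc.site_samples, samples)

    # --- quantify ---------------------------------------------------------
    matrix = stage(
        "quantify", build_matrix, disc.sites, calls, samples,
        coverage=coverage, thresholds=thresholds,
    )
    matrix.to_long().to_csv(out / "matrix.tsv", sep="\t", index=False)
    averages = stage("quantify", sample_average_editing, matrix)
    averages.to_csv(out / "sample_averages.tsv", sep="\t", index=False)

    # --- average-editing comparisons ---------------------------------------
    avg_tests: Dict[str, Dict] = {}
    regions = list(pd.unique(samples["region"]))
    ok_avg = averages[averages["ok"]]
    if len(regions) == 2:
        eff, p, lrt = stage(
            "average_glm", average_glm, ok_avg["mean_level"], ok_avg["region"], regions[0]
        )
        avg_tests["region_comparison"] = {
            "regions": regions, "effect": eff, "p_value": p, "lrt_stat": lrt,
        }
    for region in regions:
        sub = ok_avg[ok_avg["region"] == region]
        if sub["group"].nunique() == 2 and sub.groupby("group").size().min() >= 2:
            eff, p, lrt = stage(
                "average_glm", average_glm, sub["mean_level"], sub["group"], case_label
            )
            avg_tests[f"{region}_case_vs_control"] = {
                "effect": eff, "p_value": p, "lrt_stat": lrt,
            }

    # --- differential (pooled and per region) ------------------------------
    comparisons: Dict[str, Dict] = {}
    gene_sets: Dict[str, set] = {}
    diff_frames = {}

    def run_comparison(name: str, sample_mask: pd.Series):
        sub_samples = matrix.samples[sample_mask].reset_index(drop=True)
        sub = type(matrix)(
            sites=matrix.sites,
            samples=sub_samples,
            ref=matrix.ref[sub_samples["sample_id"]],
            alt=matrix.alt[sub_samples["sample_id"]],
            covered=matrix.covered[sub_samples["sample_id"]],
        )
        res = differential_editing(sub, case_label=case_label, family=family)
        res.to_csv(out / f"differential_{name}.tsv", sep="\t", index=False)
        diff_frames[name] = res
        sel_sites, sel_genes = select_differential(res, p_threshold=p_threshold)
        gene_sets[name] = set(sel_genes)
        entry: Dict = {"n_tested": int(res["testable"].sum()),
                       "n_differential_sites": len(sel_sites),
                       "n_differential_genes": len(sel_genes)}
        if len(sel_sites) >= 2:
            pca = pca_on_sites(sub.levels.loc[sel_sites])
            pd.concat(
                [pca.scores,
                 pd.DataFrame([pca.variance_fraction], index=["variance_fraction"],
                              columns=pca.scores.columns)],
            ).to_csv(out / f"pca_{name}.tsv", sep="\t")
            entry["pc1_variance_fraction"] = float(pca.variance_fraction[0])
        comparisons[name] = entry
        return sel_sites

    all_mask = pd.Series(True, index=matrix.samples.index)
    sel_all = stage("test", run_comparison, "all", all_mask)
    for region in regions:
        stage("test", run_comparison, region, matrix.samples["region"] == region)

    # --- intersect ----------------------------------------------------------
    key_genes = []
    if len(regions) >= 2:
        region_sets = {r: gene_sets[r] for r in regions}
        extra = config.get("extra_gene_sets", {})  # e.g. replication cohort lists
        for name, path in extra.items():
            region_sets[name] = set(
                pd.read_csv(path, sep="\t")["gene_id"].astype(str)
            )
        report = stage(
            "intersect", intersect_gene_sets, region_sets,
            int(config.get("key_gene_min_sets", 2)),
        )
        report.to_frame().to_csv(out / "intersection.tsv", sep="\t", index=False)
        key_genes = [
            {"gene_id": g, "sets": list(names)} for g, names in report.key_genes
        ]

    # --- correlate ----------------------------------------------------------
    n_correlations = 0
    if expression is not None and sel_all:
        corr = stage(
            "correlate", editing_expression_correlations, matrix, expression, sel_all
        )
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
        n_correlations = len(corr)

    summary = {
        "editome": summary_sites,
        "average_editing": avg_tests,
        "differential": comparisons,
        "key_genes": key_genes,
        "n_editing_expression_correlations": n_correlations,
        "n_ambiguous_strand_dropped": disc.n_ambiguous_dropped,
    }
    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    cfg_hash = hashlib.sha256(
        json.dumps({k: str(v) for k, v in sorted(config.items())}).encode()
    ).hexdigest()[:16]
    (out / "run_log.txt").write_text(
        f"editome {__version__}\nnumpy {np.__version__}\npandas {pd.__version__}\n"
        f"seed {config.get('seed', 'none')}\nconfig_hash {cfg_hash}\n"
    )
    return summary
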