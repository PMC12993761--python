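"""Synthetic two-region editing cohorts with known ground truth.

The generator emulates the statistical structure a brain RNA editome analysis
assumes: a toy multi-chromosome genome with stranded protein-coding and
noncoding genes; A-to-I editing sites placed mostly in introns and 3'-UTRs and
mostly inside Alu intervals; germline-like SNP contaminants at allele fraction
~0.5; sequencing-error sites below the callability threshold; per-site
disease effects on the logit of the editing level; and a global region-level
editing shift in one region's case samples. Read counts are binomial given a
logit-normal per-sample editing probability over negative-binomial coverage,
so the alternative allele frequency G/(A+G) carries realistic overdispersion.

Everything is driven by one :class:`numpy.random.Generator`; identical
(config, seed) reproduces fixtures byte for byte.
"""

from __future__ import annotations

import bisect
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from .annotation import (
    GeneModels,
    KnownSiteCatalog,
    RepeatTrack,
    homopolymer_run_length,
    write_fasta,
)
from .config import ConfigurationError, SimulationConfig
from .vcfio import write_sample_vcf

GROUPS = ("sepsis", "control")

_FRAC_OTHER_REPEAT = 0.08  # of non-Alu edit sites; fixed, see docs/methods.md
_N_CATALOG_DECOYS = 30
_SITE_MIN_SPACING = 50  # bp; lets repeat intervals avoid neighbouring sites
_BASELINE_TRUNC = (0.05, 0.95)


@dataclass
class Annotation:
    """Toy genome annotation plus the planted site skeleton."""

    gene_models: GeneModels
    genome: Dict[str, str]
    repeats: RepeatTrack
    catalog: KnownSiteCatalog
    sites: pd.DataFrame  # chrom,pos,strand,ref,alt,site_class,gene_id,functional_category,repeat_class,known_in_catalog


@dataclass
class SimulatedCohort:
    """Per-sample variant calls, coverage, expression and ground truth."""

    samples: pd.DataFrame  # sample_id, group, region, cohort
    truth: pd.DataFrame
    calls: Dict[str, pd.DataFrame]
    coverage: pd.DataFrame  # sites x samples read depth
    alt_counts: pd.DataFrame  # sites x samples alternative (G) reads
    expression: pd.DataFrame  # genes x samples (log2 scale)
    config: SimulationConfig


def _pc_gene(chrom: str, start: int, strand: str, gene_id: str):
    """Two-exon protein-coding gene: UTRs + 2 CDS exons + 1 intron (2150 bp)."""
    if strand == "+":
        utr5 = (start, start + 149)
        cds1 = (start + 150, start + 449)
        cds2 = (start + 1350, start + 1649)
        utr3 = (start + 1650, start + 2149)
        exons = [(start, start + 449), (start + 1350, start + 2149)]
        intron = (start + 450, start + 1349)
    else:
        utr3 = (start, start + 499)
        cds2 = (start + 500, start + 799)
        cds1 = (start + 1700, start + 1999)
        utr5 = (start + 2000, start + 2149)
        exons = [(start, start + 799), (start + 1700, start + 2149)]
        intron = (start + 800, start + 1699)
    gene = (gene_id, chrom, start, start + 2149, strand, "protein_coding")
    feats = [
        (gene_id, chrom, utr5[0], utr5[1], "5'UTR"),
        (gene_id, chrom, cds1[0], cds1[1], "CDS"),
        (gene_id, chrom, cds2[0], cds2[1], "CDS"),
        (gene_id, chrom, utr3[0], utr3[1], "3'UTR"),
    ] + [(gene_id, chrom, e[0], e[1], "exon") for e in exons]
    pools = {
        "5'UTR": [utr5],
        "CDS": [cds1, cds2],
        "3'UTR": [utr3],
        "intron": [intron],
    }
    return gene, feats, pools


def _nc_gene(chrom: str, start: int, strand: str, gene_id: str):
    """Single-exon noncoding gene (800 bp)."""
    gene = (gene_id, chrom, start, start + 799, strand, "lncRNA")
    feats = [(gene_id, chrom, start, start + 799, "exon")]
    return gene, feats, {"noncoding_exon": [(start, start + 799)]}


def _place(
    rng: np.random.Generator,
    pool: List[Tuple[str, int, int, Optional[str], Optional[str]]],
    positions: Dict[str, List[int]],
    margin: int = 5,
    min_spacing: int = _SITE_MIN_SPACING,
    max_tries: int = 500,
) -> Tuple[str, int, Optional[str], Optional[str]]:
    """Pick a position inside a random pool interval, >= min_spacing from
    every previously placed site on the chromosome."""
    for _ in range(max_tries):
        chrom, lo, hi, gene_id, strand = pool[int(rng.integers(len(pool)))]
        if hi - lo < 2 * margin + 1:
            continue
        pos = int(rng.integers(lo + margin, hi - margin + 1))
        lst = positions.setdefault(chrom, [])
        i = bisect.bisect_left(lst, pos)
        if i > 0 and pos - lst[i - 1] < min_spacing:
            continue
        if i < len(lst) and lst[i] - pos < min_spacing:
            continue
        bisect.insort(lst, pos)
        return chrom, pos, gene_id, strand
    raise RuntimeError("could not place a site; pool too crowded for min spacing")


def simulate_annotation(config: SimulationConfig, rng: np.random.Generator) -> Annotation:
    """Build a toy annotated genome and the planted site skeleton.

    Genes alternate strands across three chromosomes; edit sites are placed by
    the configured functional-category weights, SNP and error contaminants go
    into introns. ``frac_alu`` of edit sites receive a covering Alu interval,
    ``frac_known`` enter the known-site catalog (plus a fixed number of decoy
    catalog entries that were never simulated). No two sites share a
    coordinate and every site keeps a homopolymer-free, junction-distant
    context so the QC cascade does not remove planted true sites.
    """
    config.validate()
    n_total = config.n_edit_sites + config.n_snp_sites + config.n_error_sites
    n_pc = max(24, int(np.ceil(n_total / 8)))
    n_nc = max(3, n_pc // 10)
    chroms = ["chr1", "chr2", "chr3"]
    cursors = {c: 1001 for c in chroms}
    genes, feats = [], []
    pools: Dict[str, list] = {k: [] for k in ("CDS", "3'UTR", "5'UTR", "noncoding_exon", "intron")}
    gene_spans: Dict[str, list] = {c: [] for c in chroms}

    plan = [("pc", i) for i in range(n_pc)] + [("nc", i) for i in range(n_nc)]
    for k, (kind, i) in enumerate(plan):
        chrom = chroms[k % len(chroms)]
        strand = "+" if (k // len(chroms)) % 2 == 0 else "-"
        start = cursors[chrom]
        gid = f"GENE{'NC' if kind == 'nc' else ''}{i + 1:04d}"
        g, f, p = (_pc_gene if kind == "pc" else _nc_gene)(chrom, start, strand, gid)
        genes.append(g)
        feats.extend(f)
        for cat, ivs in p.items():
            pools[cat].extend((chrom, lo, hi, gid, strand) for lo, hi in ivs)
        gene_spans[chrom].append((g[2], g[3]))
        cursors[chrom] = g[3] + 1201

    # intergenic pool: gaps between genes, 200 bp clear of gene bodies
    intergenic = []
    for chrom in chroms:
        prev_end = 0
        for lo, hi in sorted(gene_spans[chrom]):
            if lo - prev_end > 500:
                intergenic.append((chrom, prev_end + 201, lo - 201, None, None))
            prev_end = hi
        intergenic.append((chrom, prev_end + 201, prev_end + 1000, None, None))
    pools["intergenic"] = intergenic

    gene_models = GeneModels(
        pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]),
        pd.DataFrame(feats, columns=["gene_id", "chrom", "start", "end", "kind"]),
    )

    # --- place sites ------------------------------------------------------
    cats = list(config.category_weights)
    weights = np.array([config.category_weights[c] for c in cats])
    edit_cats = [cats[j] for j in rng.choice(len(cats), size=config.n_edit_sites, p=weights)]
    positions: Dict[str, List[int]] = {}
    rows = []
    for cat in edit_cats:
        chrom, pos, gid, strand = _place(rng, pools[cat], positions)
        if strand is None:  # intergenic
            strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, pos, strand, gid, cat, "edit"))
    for _ in range(config.n_snp_sites):
        chrom, pos, gid, strand = _place(rng, pools["intron"], positions)
        rows.append((chrom, pos, strand, gid, "intron", "snp"))
    for _ in range(config.n_error_sites):
        chrom, pos, gid, strand = _place(rng, pools["intron"], positions)
        rows.append((chrom, pos, strand, gid, "intron", "error"))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "gene_id", "functional_category", "site_class"])
    sites["ref"] = np.where(sites["strand"] == "+", "A", "T")
    sites["alt"] = np.where(sites["strand"] == "+", "G", "C")

    is_edit = (sites["site_class"] == "edit").to_numpy()
    known = np.zeros(len(sites), dtype=bool)
    known[is_edit] = rng.random(int(is_edit.sum())) < config.frac_known
    sites["known_in_catalog"] = known

    # --- repeat intervals -------------------------------------------------
    alu = np.zeros(len(sites), dtype=bool)
    alu[is_edit] = rng.random(int(is_edit.sum())) < config.frac_alu
    other_rep = np.zeros(len(sites), dtype=bool)
    cand = is_edit & ~alu
    other_rep[cand] = rng.random(int(cand.sum())) < _FRAC_OTHER_REPEAT
    rep_rows = []
    chrom_len = {c: cursors[c] + 1000 for c in chroms}
    for idx in np.flatnonzero(alu | other_rep):
        chrom, pos = sites.at[idx, "chrom"], int(sites.at[idx, "pos"])
        name = "AluY" if alu[idx] else "L2"
        left = int(rng.integers(20, 281))
        start0 = pos - 1 - left
        end0 = start0 + 300
        lst = positions[chrom]
        i = lst.index(pos)
        if i > 0:
            start0 = max(start0, lst[i - 1])  # stay past the previous site
        if i + 1 < len(lst):
            end0 = min(end0, lst[i + 1] - 1)  # stop before the next site
        start0 = max(start0, 0)
        end0 = min(end0, chrom_len[chrom])
        rep_rows.append((chrom, start0, end0, name))
    repeats = RepeatTrack(pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "name"]))
    sites["repeat_class"] = [
        repeats.repeat_class(c, int(p)) for c, p in zip(sites["chrom"], sites["pos"])
    ]

    # --- catalog (known edit sites + never-simulated decoys) --------------
    cat_records = [
        (r.chrom, int(r.pos), r.strand)
        for r in sites[sites["known_in_catalog"]].itertuples(index=False)
    ]
    for _ in range(_N_CATALOG_DECOYS):
        chrom, pos, _, strand = _place(rng, pools["intergenic"], positions, min_spacing=10)
        cat_records.append((chrom, pos, "+" if rng.random() < 0.5 else "-"))
    catalog = KnownSiteCatalog.from_records(cat_records)

    # --- genome sequence --------------------------------------------------
    bases = np.array(list("ACGT"))
    genome: Dict[str, str] = {}
    seqs = {c: rng.choice(bases, size=chrom_len[c]).tolist() for c in chroms}
    for r in sites.itertuples(index=False):
        seqs[r.chrom][r.pos - 1] = r.ref
    for r in sites.itertuples(index=False):
        seq = seqs[r.chrom]
        # break any homopolymer run >= 5 covering the site
        for _ in range(50):
            window = "".join(seq[max(0, r.pos - 6) : r.pos + 5])
            if homopolymer_run_length(window, min(r.pos, 6)) < 5:
                break
            for off in range(-4, 5):
                if off != 0:
                    seq[r.pos - 1 + off] = str(rng.choice(bases))
    genome = {c: "".join(seqs[c]) for c in chroms}

    sites = sites[
        ["chrom", "pos", "strand", "ref", "alt", "site_class", "gene_id",
         "functional_category", "repeat_class", "known_in_catalog"]
    ].reset_index(drop=True)
    return Annotation(gene_models, genome, repeats, catalog, sites)


def _truncated_beta(rng: np.random.Generator, a: float, b: float, size: int) -> np.ndarray:
    lo, hi = _BASELINE_TRUNC
    x = rng.beta(a, b, size=size)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def logit_shift_for_level_shift(config: SimulationConfig, delta: float) -> float:
    """Logit shift whose expected absolute editing-level shift equals ``delta``
    under the configured (truncated) baseline distribution."""
    from scipy.optimize import brentq

    lo, hi = _BASELINE_TRUNC
    grid = np.linspace(lo, hi, 4001)
    w = beta_dist.pdf(grid, config.baseline_beta_a, config.baseline_beta_b)
    w = w / w.sum()

    def mean_shift(d: float) -> float:
        return float(np.sum(w * (expit(logit(grid) + d) - grid))) - delta

    return float(brentq(mean_shift, -10.0, 10.0, xtol=1e-10))


def simulate_cohort(
    config: SimulationConfig,
    annotation: Annotation,
    rng: np.random.Generator,
    cohort_label: str = "discovery",
) -> SimulatedCohort:
    """Draw allele counts, coverage and expression for a full cohort.

    Per site per sample: coverage ~ NB(mean, dispersion); the editing
    probability is inverse-logit(logit(baseline) + sample noise + planted
    disease/region effects); the alternative read count is binomial. SNP
    contaminants sit at allele fraction ~0.5 in every sample; error sites
    emit alternative reads at a fixed low rate. A VarScan-like caller only
    reports positions with at least one alternative read, so the per-sample
    call tables contain exactly those.
    """
    config.validate()
    sites = annotation.sites
    S = len(sites)
    sample_rows = []
    for region in config.regions:
        for group in GROUPS:
            for i in range(config.n_per_group):
                sample_rows.append((f"{region}_{group}_{i + 1:02d}", group, region, cohort_label))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "group", "region", "cohort"])
    N = len(samples)
    is_sepsis = (samples["group"] == "sepsis").to_numpy()
    in_shift_region = (samples["region"] == config.regions[0]).to_numpy() & is_sepsis

    site_class = sites["site_class"].to_numpy()
    idx_edit = np.flatnonzero(site_class == "edit")
    idx_snp = np.flatnonzero(site_class == "snp")
    idx_err = np.flatnonzero(site_class == "error")

    baseline = np.zeros(S)
    baseline[idx_edit] = _truncated_beta(
        rng, config.baseline_beta_a, config.baseline_beta_b, len(idx_edit)
    )
    baseline[idx_snp] = np.clip(rng.normal(0.5, 0.02, size=len(idx_snp)), 0.45, 0.55)
    baseline[idx_err] = config.error_rate

    diff_flag = np.zeros(S, dtype=bool)
    diff_flag[idx_edit] = rng.random(len(idx_edit)) < config.frac_differential
    effect = np.where(diff_flag, config.disease_effect_logit, 0.0)
    is_differential = effect != 0.0

    coverage = rng.negative_binomial(
        config.coverage_dispersion,
        config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean),
        size=(S, N),
    )

    p = np.empty((S, N))
    eta = logit(baseline[idx_edit])[:, None] + rng.normal(
        0.0, config.site_sd_logit, size=(len(idx_edit), N)
    )
    eta += effect[idx_edit][:, None] * is_sepsis[None, :]
    eta += config.region_shift_logit * in_shift_region[None, :]
    p[idx_edit] = expit(eta)
    p[idx_snp] = expit(
        logit(baseline[idx_snp])[:, None] + rng.normal(0.0, 0.05, size=(len(idx_snp), N))
    )
    p[idx_err] = baseline[idx_err][:, None]

    alt = rng.binomial(coverage, p)
    ref = coverage - alt
    bq = np.round(np.clip(rng.normal(36.0, 1.5, size=(S, N)), 28.0, 41.0), 2)

    site_ids = [f"{c}:{p_}:{s}" for c, p_, s in zip(sites["chrom"], sites["pos"], sites["strand"])]
    calls: Dict[str, pd.DataFrame] = {}
    for j, sid in enumerate(samples["sample_id"]):
        mask = alt[:, j] >= 1
        calls[sid] = pd.DataFrame(
            {
                "chrom": sites["chrom"].to_numpy()[mask],
                "pos": sites["pos"].to_numpy()[mask],
                "ref": sites["ref"].to_numpy()[mask],
                "alt": sites["alt"].to_numpy()[mask],
                "ref_count": ref[mask, j],
                "alt_count": alt[mask, j],
                "mean_base_quality": bq[mask, j],
                "sample_id": sid,
            }
        )

    # expression: log2 scale, optional coupling to editing at differential sites
    gene_ids = annotation.gene_models.genes["gene_id"].tolist()
    base_expr = rng.normal(8.0, 1.5, size=len(gene_ids))
    expr = base_expr[:, None] + rng.normal(
        0.0, config.expression_noise_sd, size=(len(gene_ids), N)
    )
    if config.expression_coupling != 0.0:
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        diff_sites = sites.index[is_differential]
        by_gene: Dict[str, list] = {}
        for i in diff_sites:
            g = sites.at[i, "gene_id"]
            if g is not None and not (isinstance(g, float) and np.isnan(g)):
                by_gene.setdefault(g, []).append(i)
        for g, rows_i in by_gene.items():
            signal = logit(np.clip(p[rows_i], 1e-6, 1 - 1e-6)).mean(axis=0)
            expr[gene_pos[g]] += config.expression_coupling * (signal - signal.mean())
    expression = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                              columns=samples["sample_id"].tolist())

    truth = sites.copy()
    truth.insert(0, "site_id", site_ids)
    truth["baseline_level"] = baseline
    truth["is_differential"] = is_differential
    truth["effect_logit"] = effect
    idx = pd.Index(site_ids, name="site_id")
    cols = samples["sample_id"].tolist()
    coverage_df = pd.DataFrame(coverage, index=idx, columns=cols)
    alt_df = pd.DataFrame(alt, index=idx, columns=cols)
    return SimulatedCohort(samples, truth, calls, coverage_df, alt_df, expression, config)


def write_fixture(
    annotation: Annotation, cohort: SimulatedCohort, outdir: str | os.PathLike
) -> Dict[str, Path]:
    """Write a complete on-disk fixture: one VCF per sample plus GFF3 gene
    models, repeat/SNP BEDs, catalog, expression, sample sheet, truth,
    coverage and the reference FASTA. Returns the path of each artifact."""
    out = Path(outdir)
    try:
        (out / "vcf").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create fixture directory {out}: {e}") from e
    contigs = {c: len(s) for c, s in annotation.genome.items()}
    paths: Dict[str, Path] = {}
    for sid, df in cohort.calls.items():
        p = out / "vcf" / f"{sid}.vcf"
        write_sample_vcf(p, sid, df, contigs)
    paths["vcf_dir"] = out / "vcf"
    paths["gff"] = out / "genes.gff3"
    annotation.gene_models.to_gff3(paths["gff"])
    paths["repeats"] = out / "repeats.bed"
    annotation.repeats.to_bed(paths["repeats"])
    paths["snps"] = out / "snps.bed"
    snp = cohort.truth[cohort.truth["site_class"] == "snp"]
    pd.DataFrame(
        {"chrom": snp["chrom"], "start": snp["pos"] - 1, "end": snp["pos"]}
    ).sort_values(["chrom", "start"]).to_csv(paths["snps"], sep="\t", header=False, index=False)
    paths["catalog"] = out / "catalog.tsv"
    annotation.catalog.to_tsv(paths["catalog"])
    paths["samples"] = out / "samples.tsv"
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
    paths["expression"] = out / "expression.tsv"
    cohort.expression.round(6).to_csv(paths["expression"], sep="\t")
    paths["truth"] = out / "truth.tsv"
    cohort.truth.round({"baseline_level": 6}).to_csv(paths["truth"], sep="\t", index=False)
    paths["coverage"] = out / "coverage.tsv"
    cohort.coverage.to_csv(paths["coverage"], sep="\t")
    paths["genome"] = out / "genome.fa"
    write_fasta(annotation.genome, paths["genome"])
    return paths


def simulate_fixture(
    config: SimulationConfig, outdir: str | os.PathLike
) -> Tuple[Annotation, SimulatedCohort, Dict[str, Path]]:
    """Convenience wrapper: annotation + cohort + on-disk fixture from one seed."""
    rng = np.random.default_rng(config.seed)
    ann = simulate_annotation(config, rng)
    cohort = simulate_cohort(config, ann, rng)
    paths = write_fixture(ann, cohort, outdir)
    return ann, cohort, paths
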