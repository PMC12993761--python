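"""High-confidence A-to-I editing-site discovery from per-sample variant calls.

A called SNV becomes an A-to-I candidate when it is an A-to-G change read on
the coding strand: A>G inside a +strand gene, or T>C inside a -strand gene
(inosine pairs like guanosine, so editing shows up as A>G on the edited
strand). High confidence is disjunctive: a candidate is kept if it is either
(1) present in the known-site catalog, or (2) a novel coding-strand A-to-G
call that survives a quality-control cascade (SNP overlap, homopolymer,
splice-junction proximity, multi-allelic). Call-level thresholds (base
quality, depths, AAF) always apply, to known and novel sites alike.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotation import (
    GeneModels,
    KnownSiteCatalog,
    RepeatTrack,
    homopolymer_run_length,
)
from .config import ConfigurationError, ThresholdSet
from .vcfio import VariantCall

A_TO_I = "A_to_I"
OTHER = "other"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class EditingSiteRecord:
    """A genomic site classified as A-to-I, in coding-strand orientation.

    Stored as A-reference / G-alternative on the host gene's coding strand;
    ``known`` means exact (chrom, pos, strand) membership in the catalog.
    """

    chrom: str
    pos: int  # 1-based
    strand: str
    gene_id: Optional[str] = None
    known: bool = False
    functional_category: str = "intergenic"
    repeat_class: str = "none"
    n_samples_called: int = 0

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


@dataclass(frozen=True)
class QcOptions:
    """Toggles and parameters of the QC cascade (novel sites only)."""

    snp_filter: bool = True
    homopolymer_filter: bool = True
    homopolymer_min_run: int = 5
    splice_filter: bool = True
    splice_window: int = 4
    multiallelic_filter: bool = True


def apply_call_thresholds(
    calls: Iterable[VariantCall], thresholds: ThresholdSet = ThresholdSet()
) -> List[VariantCall]:
    """Retain calls meeting all four thresholds (boundaries inclusive):
    mean base quality, alternative-allele depth, total depth, and AAF."""
    t = thresholds
    return [
        c
        for c in calls
        if c.mean_base_quality >= t.min_base_quality
        and c.alt_count >= t.min_alt_depth
        and c.depth >= t.min_depth
        and c.depth > 0
        and c.aaf >= t.min_aaf
    ]


def classify_edit_type(call: VariantCall, gene_models: GeneModels) -> str:
    """Classify a call as A_to_I, other, or ambiguous (genes on both strands).

    A_to_I iff A>G inside a +strand gene or T>C inside a -strand gene.
    """
    strand = gene_models.strand_at(call.chrom, call.pos)
    if strand == "ambiguous":
        # orientation undecidable only when the change could be A-to-G on
        # either strand; anything else is simply not an A-to-G change
        if (call.ref, call.alt) in (("A", "G"), ("T", "C")):
            return AMBIGUOUS
        return OTHER
    if strand == "+" and call.ref == "A" and call.alt == "G":
        return A_TO_I
    if strand == "-" and call.ref == "T" and call.alt == "C":
        return A_TO_I
    return OTHER


def annotate_known(
    chrom: str, pos: int, strand: str, catalog: KnownSiteCatalog
) -> bool:
    """Exact-coordinate membership of (chrom, pos, strand) in the catalog."""
    return (chrom, pos, strand) in catalog


def annotate_site(
    site: EditingSiteRecord,
    gene_models: GeneModels,
    repeats: Optional[RepeatTrack] = None,
) -> EditingSiteRecord:
    """Fill functional category (CDS > 3'UTR > 5'UTR > noncoding_exon >
    intron > intergenic), repeat class and host gene."""
    category = gene_models.functional_category(site.chrom, site.pos)
    gene = gene_models.host_gene(site.chrom, site.pos, strand=site.strand)
    if gene is None:
        gene = gene_models.host_gene(site.chrom, site.pos)
    rep = repeats.repeat_class(site.chrom, site.pos) if repeats is not None else "none"
    return replace(site, functional_category=category, repeat_class=rep, gene_id=gene)


def qc_cascade(
    sites: Sequence[EditingSiteRecord],
    snp_trees: Optional[Mapping] = None,
    genome: Optional[Mapping[str, str]] = None,
    gene_models: Optional[GeneModels] = None,
    multiallelic_positions: Optional[Set[Tuple[str, int]]] = None,
    options: QcOptions = QcOptions(),
) -> Tuple[List[EditingSiteRecord], pd.DataFrame]:
    """Apply the QC cascade to novel sites; known sites bypass every filter.

    Filters, in order: (1) SNP-interval overlap, (2) homopolymer run >=
    ``homopolymer_min_run``, (3) within ``splice_window`` nt of an annotated
    splice junction, (4) multi-allelic position. Returns the retained sites
    and an audit table with one row per filter; input count always equals
    retained + sum of removals.
    """
    if options.homopolymer_filter and genome is None:
        raise ConfigurationError(
            "homopolymer_filter requires reference context (genome); "
            "supply genome= or disable the filter"
        )
    if options.splice_filter and gene_models is None:
        raise ConfigurationError("splice_filter requires gene_models")
    removed = {"snp_overlap": 0, "homopolymer": 0, "splice_junction": 0, "multiallelic": 0}
    retained: List[EditingSiteRecord] = []
    n_known = 0
    for site in sites:
        if site.known:
            n_known += 1
            retained.append(site)
            continue
        if options.snp_filter and snp_trees is not None:
            tree = snp_trees.get(site.chrom)
            if tree is not None and tree.at(site.pos - 1):
                removed["snp_overlap"] += 1
                continue
        if options.homopolymer_filter:
            seq = genome.get(site.chrom)
            if seq is None:
                raise ConfigurationError(f"no reference sequence for {site.chrom}")
            if homopolymer_run_length(seq, site.pos) >= options.homopolymer_min_run:
                removed["homopolymer"] += 1
                continue
        if options.splice_filter and gene_models.near_splice_junction(
            site.chrom, site.pos, window=options.splice_window
        ):
            removed["splice_junction"] += 1
            continue
        if (
            options.multiallelic_filter
            and multiallelic_positions is not None
            and (site.chrom, site.pos) in multiallelic_positions
        ):
            removed["multiallelic"] += 1
            continue
        retained.append(site)
    audit = pd.DataFrame(
        {
            "filter": list(removed) + ["known_bypass", "retained", "input"],
            "n": list(removed.values()) + [n_known, len(retained), len(sites)],
        }
    )
    return retained, audit


@dataclass
class DiscoveryResult:
    """Outcome of discovery: annotated sites, QC audit, per-site sample sets."""

    sites: List[EditingSiteRecord]
    audit: pd.DataFrame
    site_samples: Dict[str, Set[str]]  # site_id -> samples with a passing call
    n_ambiguous_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return sites_to_frame(self.sites)


def discover_sites(
    calls_by_sample: Mapping[str, Iterable[VariantCall]],
    gene_models: GeneModels,
    catalog: KnownSiteCatalog,
    thresholds: ThresholdSet = ThresholdSet(),
    snp_trees: Optional[Mapping] = None,
    genome: Optional[Mapping[str, str]] = None,
    repeats: Optional[RepeatTrack] = None,
    qc_options: QcOptions = QcOptions(),
    min_samples_called: int = 1,
) -> DiscoveryResult:
    """Full discovery: thresholds -> orientation -> union -> QC -> annotation.

    Orientation of a call is taken from the catalog when the coordinate is a
    known site (catalog rescue, which also covers intergenic known sites),
    otherwise from the strand of the host gene. Sites whose orientation is
    undecidable (overlapping genes on both strands) are dropped and counted.
    """
    candidates: Dict[Tuple[str, int, str], Dict] = {}
    alleles_at: Dict[Tuple[str, int], Set[Tuple[str, str]]] = {}
    n_ambiguous = 0
    for sample_id, calls in calls_by_sample.items():
        for call in apply_call_thresholds(calls, thresholds):
            alleles_at.setdefault((call.chrom, call.pos), set()).add((call.ref, call.alt))
            cat_strand = catalog.strand_of(call.chrom, call.pos)
            if cat_strand is not None and (
                (cat_strand == "+" and (call.ref, call.alt) == ("A", "G"))
                or (cat_strand == "-" and (call.ref, call.alt) == ("T", "C"))
            ):
                strand, known = cat_strand, True
            else:
                kind = classify_edit_type(call, gene_models)
                if kind == AMBIGUOUS:
                    n_ambiguous += 1
                    continue
                if kind != A_TO_I:
                    continue
                strand = gene_models.strand_at(call.chrom, call.pos)
                known = False
            key = (call.chrom, call.pos, strand)
            entry = candidates.setdefault(key, {"samples": set(), "known": known})
            entry["samples"].add(call.sample_id or sample_id)
            entry["known"] = entry["known"] or known
    records = [
        EditingSiteRecord(
            chrom=c, pos=p, strand=s, known=v["known"], n_samples_called=len(v["samples"])
        )
        for (c, p, s), v in sorted(candidates.items())
        if len(v["samples"]) >= min_samples_called
    ]
    multi = {pos for pos, alleles in alleles_at.items() if len(alleles) > 1}
    retained, audit = qc_cascade(
        records,
        snp_trees=snp_trees,
        genome=genome,
        gene_models=gene_models,
        multiallelic_positions=multi,
        options=qc_options,
    )
    annotated = [annotate_site(s, gene_models, repeats) for s in retained]
    site_samples = {
        f"{c}:{p}:{s}": set(candidates[(c, p, s)]["samples"])
        for (c, p, s) in ((r.chrom, r.pos, r.strand) for r in annotated)
    }
    return DiscoveryResult(annotated, audit, site_samples, n_ambiguous)


def sites_to_frame(sites: Sequence[EditingSiteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "strand": [s.strand for s in sites],
            "gene_id": [s.gene_id for s in sites],
            "known": [s.known for s in sites],
            "functional_category": [s.functional_category for s in sites],
            "repeat_class": [s.repeat_class for s in sites],
            "n_samples_called": [s.n_samples_called for s in sites],
        }
    )


def summarize_editome(
    sites: Sequence[EditingSiteRecord],
    site_samples: Optional[Mapping[str, Set[str]]] = None,
    samples: Optional[pd.DataFrame] = None,
) -> Dict:
    """Cohort-level editome summary over the union of sites across samples.

    Reports the site and host-gene counts, functional-category fractions,
    known and repeat fractions, and (when the sample sheet is given)
    per-region site/gene counts over that region's samples.
    """
    n_sites = len(sites)
    genes = {s.gene_id for s in sites if s.gene_id}
    summary: Dict = {
        "n_sites": n_sites,
        "n_genes": len(genes),
        "known_fraction": (sum(s.known for s in sites) / n_sites) if n_sites else float("nan"),
        "category_fractions": {},
        "repeat_fractions": {},
    }
    if n_sites:
        cats = pd.Series([s.functional_category for s in sites])
        summary["category_fractions"] = (cats.value_counts() / n_sites).to_dict()
        reps = pd.Series([s.repeat_class for s in sites])
        summary["repeat_fractions"] = (reps.value_counts() / n_sites).to_dict()
    summary["alu_fraction"] = summary["repeat_fractions"].get("Alu", 0.0) if n_sites else float("nan")
    if site_samples is not None and samples is not None:
        per_region = {}
        by_id = {s.site_id: s for s in sites}
        for region, sub in samples.groupby("region"):
            ids = set(sub["sample_id"])
            region_sites = [
                by_id[sid]
                for sid, ss in site_samples.items()
                if sid in by_id and ss & ids
            ]
            per_region[region] = {
                "n_sites": len(region_sites),
                "n_genes": len({s.gene_id for s in region_sites if s.gene_id}),
            }
        summary["sites_per_region"] = per_region
    return summary
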