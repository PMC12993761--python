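"""Threshold cascade, strand-aware classification, QC cascade, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from intervaltree import IntervalTree

from editome import (
    ConfigurationError,
    EditingSiteRecord,
    GeneModels,
    KnownSiteCatalog,
    QcOptions,
    RepeatTrack,
    ThresholdSet,
    VariantCall,
    annotate_known,
    annotate_site,
    apply_call_thresholds,
    classify_edit_type,
    discover_sites,
    qc_cascade,
    summarize_editome,
)
from helpers_oracles import oracle_discovery, oracle_passes_thresholds


def _call(chrom="chr1", pos=150, ref="A", alt="G", rc=8, ac=2, bq=30.0, sample="s1"):
    return VariantCall(chrom, pos, ref, alt, rc, ac, bq, sample)


# -- call-level thresholds -------------------------------------------------

@pytest.mark.parametrize(
    "rc,ac,bq,kept",
    [
        (7, 2, 30.0, False),   # depth 9 < 10 despite AAF 0.22
        (8, 2, 25.0, True),    # every boundary met exactly
        (991, 9, 30.0, False), # AAF 0.009 < 1% despite deep coverage
        (8, 1, 30.0, False),   # alt depth 1 < 2
        (8, 2, 24.9, False),   # base quality below 25
    ],
)
def test_threshold_boundaries(rc, ac, bq, kept):
    calls = [_call(rc=rc, ac=ac, bq=bq)]
    assert (len(apply_call_thresholds(calls)) == 1) is kept


calls_strategy = st.lists(
    st.builds(
        _call,
        pos=st.integers(1, 500),
        rc=st.integers(0, 30),
        ac=st.integers(1, 10),
        bq=st.floats(20.0, 40.0, allow_nan=False),
    ),
    max_size=30,
)


@given(calls_strategy)
def test_thresholds_idempotent_order_invariant_and_match_oracle(calls):
    t = ThresholdSet()
    kept = apply_call_thresholds(calls, t)
    assert apply_call_thresholds(kept, t) == kept  # idempotent
    assert apply_call_thresholds(list(reversed(calls)), t) == list(reversed(kept))
    for c in calls:
        assert (c in kept) == oracle_passes_thresholds(c, t)


# -- classification --------------------------------------------------------

@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (150, "A", "G", "A_to_I"),   # A>G in + strand gene
        (1100, "T", "C", "A_to_I"),  # T>C in - strand gene
        (150, "C", "T", "other"),
        (150, "T", "C", "other"),    # wrong orientation for a + gene
        (2100, "A", "G", "ambiguous"),  # genes on both strands
        (2100, "C", "T", "other"),      # not an A-to-G change at all
        (5000, "A", "G", "other"),      # intergenic
    ],
)
def test_classify_edit_type(tiny_gene_models, pos, ref, alt, expected):
    assert classify_edit_type(_call(pos=pos, ref=ref, alt=alt), tiny_gene_models) == expected


def test_strand_symmetry_under_reverse_complement(tiny_gene_models):
    """Reverse-complementing the locus and swapping strands leaves the
    A-to-I classification unchanged (coordinates mapped accordingly)."""
    L = 3000
    genes = tiny_gene_models.genes.copy()
    feats = tiny_gene_models.features.copy()
    flip = {"+": "-", "-": "+"}
    genes_rc = genes.assign(
        start=L - genes["end"] + 1, end=L - genes["start"] + 1,
        strand=genes["strand"].map(flip),
    )
    feats_rc = feats.assign(start=L - feats["end"] + 1, end=L - feats["start"] + 1)
    gm_rc = GeneModels(genes_rc, feats_rc)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for pos, ref, alt in [(150, "A", "G"), (1100, "T", "C"), (150, "C", "T"), (5000, "A", "G")]:
        fwd = classify_edit_type(_call(pos=pos, ref=ref, alt=alt), tiny_gene_models)
        rc = classify_edit_type(
            _call(pos=L - pos + 1, ref=comp[ref], alt=comp[alt]), gm_rc
        )
        assert fwd == rc


def test_annotate_known_exact_coordinates():
    catalog = KnownSiteCatalog.from_records([("chr1", 100, "+")])
    assert annotate_known("chr1", 100, "+", catalog)
    assert not annotate_known("chr1", 101, "+", catalog)  # off by one -> novel
    assert not annotate_known("chr1", 100, "-", catalog)


# -- QC cascade ------------------------------------------------------------

def _site(pos, known=False):
    return EditingSiteRecord(chrom="chr1", pos=pos, strand="+", known=known)


@pytest.fixture()
def qc_inputs(tiny_gene_models):
    genome = {"chr1": "ACGT" * 200 + "AAAAAAA" + "ACGT" * 600}  # run at 801-807
    snp_trees = {"chr1": IntervalTree()}
    snp_trees["chr1"].addi(149, 150)  # covers pos 150 (0-based half-open)
    return genome, snp_trees, tiny_gene_models


def test_qc_filters_and_bypass(qc_inputs):
    genome, snp_trees, gm = qc_inputs
    sites = [
        _site(150),                 # SNP overlap -> filter 1
        _site(803),                 # inside AAAAAAA run -> filter 2
        _site(302),                 # 2 nt from exon boundary at 300 -> filter 3
        _site(650),                 # multi-allelic position -> filter 4
        _site(803, known=True),     # known bypasses the homopolymer filter
        _site(250),                 # clean novel site, retained
    ]
    retained, audit = qc_cascade(
        sites, snp_trees=snp_trees, genome=genome, gene_models=gm,
        multiallelic_positions={("chr1", 650)},
    )
    assert [s.pos for s in retained] == [803, 250]
    a = dict(zip(audit["filter"], audit["n"]))
    assert a["snp_overlap"] == 1 and a["homopolymer"] == 1
    assert a["splice_junction"] == 1 and a["multiallelic"] == 1
    # audit conservation: input = retained + sum of per-filter removals
    assert a["input"] == a["retained"] + a["snp_overlap"] + a["homopolymer"] + a[
        "splice_junction"
    ] + a["multiallelic"]


def test_qc_requires_reference_context(tiny_gene_models):
    with pytest.raises(ConfigurationError, match="homopolymer"):
        qc_cascade([_site(250)], genome=None, gene_models=tiny_gene_models)


def test_qc_filters_individually_toggleable(qc_inputs):
    genome, snp_trees, gm = qc_inputs
    retained, _ = qc_cascade(
        [_site(150), _site(803)], snp_trees=snp_trees, genome=genome, gene_models=gm,
        options=QcOptions(snp_filter=False, homopolymer_filter=False),
    )
    assert [s.pos for s in retained] == [150, 803]


# -- annotation ------------------------------------------------------------

def test_category_precedence_and_intergenic(tiny_gene_models):
    # pos 550: 3'UTR of GA -> 3'UTR wins over anything weaker
    rec = annotate_site(_site(550), tiny_gene_models)
    assert rec.functional_category == "3'UTR"
    assert rec.gene_id == "GA"
    rec = annotate_site(_site(400), tiny_gene_models)  # intron of GA
    assert rec.functional_category == "intron"
    rec = annotate_site(_site(5000), tiny_gene_models)
    assert rec.functional_category == "intergenic"
    assert rec.gene_id is None


def test_utr_beats_intron_for_overlapping_genes():
    """A site in an intron of one gene and the 3'UTR of an overlapping
    same-strand gene is annotated 3'UTR by precedence."""
    genes = pd.DataFrame(
        [
            ("GX", "chr1", 100, 1000, "+", "protein_coding"),
            ("GY", "chr1", 400, 1400, "+", "protein_coding"),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand", "biotype"],
    )
    feats = pd.DataFrame(
        [
            ("GX", "chr1", 100, 200, "exon"),
            ("GX", "chr1", 900, 1000, "exon"),  # 201-899 intron of GX
            ("GY", "chr1", 400, 600, "exon"),
            ("GY", "chr1", 400, 600, "3'UTR"),
        ],
        columns=["gene_id", "chrom", "start", "end", "kind"],
    )
    gm = GeneModels(genes, feats)
    rec = annotate_site(_site(500), gm)
    assert rec.functional_category == "3'UTR"


def test_annotation_fractions_on_fixture_match_planted(sim):
    ann, _ = sim
    gm, repeats = ann.gene_models, ann.repeats
    for r in ann.sites.sample(n=60, random_state=0).itertuples(index=False):
        rec = annotate_site(
            EditingSiteRecord(chrom=r.chrom, pos=int(r.pos), strand=r.strand), gm, repeats
        )
        assert rec.functional_category == r.functional_category
        assert rec.repeat_class == r.repeat_class


# -- summary ---------------------------------------------------------------

def test_summarize_counts_sites_and_genes():
    s1 = EditingSiteRecord("chr1", 10, "+", gene_id="G1", known=True,
                           functional_category="intron", repeat_class="Alu")
    s2 = EditingSiteRecord("chr1", 99, "+", gene_id="G1", known=False,
                           functional_category="3'UTR", repeat_class="none")
    one = summarize_editome([s1])
    assert one["n_sites"] == 1 and one["n_genes"] == 1
    two = summarize_editome([s1, s2])
    assert two["n_sites"] == 2 and two["n_genes"] == 1
    assert two["known_fraction"] == 0.5
    assert two["alu_fraction"] == 0.5


# -- full discovery vs brute-force oracle -----------------------------------

def test_discovery_matches_brute_force_oracle(fixture_dir):
    ann, cohort, _ = fixture_dir
    calls = {
        sid: [
            VariantCall(r.chrom, int(r.pos), r.ref, r.alt, int(r.ref_count),
                        int(r.alt_count), float(r.mean_base_quality), sid)
            for r in df.itertuples(index=False)
        ]
        for sid, df in cohort.calls.items()
    }
    snp = cohort.truth[cohort.truth["site_class"] == "snp"]
    snp_positions = set(zip(snp["chrom"], snp["pos"].astype(int)))
    snp_trees = {}
    for c, p in snp_positions:
        snp_trees.setdefault(c, IntervalTree()).addi(p - 1, p)
    result = discover_sites(
        calls, ann.gene_models, ann.catalog, snp_trees=snp_trees,
        genome=ann.genome, repeats=ann.repeats,
    )
    got = {(s.chrom, s.pos, s.strand) for s in result.sites}
    expected = oracle_discovery(
        calls, ann.gene_models.genes, ann.gene_models.features,
        set(ann.catalog.sites), snp_positions, ann.genome, ThresholdSet(),
    )
    assert got == expected
    assert len(got) > 100  # the fixture's edit sites are mostly recovered
    # audit conservation on real data
    a = dict(zip(result.audit["filter"], result.audit["n"]))
    assert a["input"] == a["retained"] + sum(
        a[k] for k in ("snp_overlap", "homopolymer", "splice_junction", "multiallelic")
    )


def test_discovery_known_fraction_near_planted(fixture_dir, small_config):
    from scipy.stats import binom

    ann, cohort, _ = fixture_dir
    calls = {
        sid: [
            VariantCall(r.chrom, int(r.pos), r.ref, r.alt, int(r.ref_count),
                        int(r.alt_count), float(r.mean_base_quality), sid)
            for r in df.itertuples(index=False)
        ]
        for sid, df in cohort.calls.items()
    }
    result = discover_sites(calls, ann.gene_models, ann.catalog,
                            genome=ann.genome, repeats=ann.repeats)
    edited_truth = cohort.truth[cohort.truth["site_class"] == "edit"]
    truth_known = dict(zip(edited_truth["site_id"], edited_truth["known_in_catalog"]))
    recs = [s for s in result.sites if s.site_id in truth_known]
    k = sum(s.known for s in recs)
    # known flags agree with the planted truth exactly
    assert all(s.known == truth_known[s.site_id] for s in recs)
    lo, hi = binom.ppf([0.005, 0.995], len(recs), small_config.frac_known)
    assert lo <= k <= hi
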