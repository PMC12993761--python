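"""Quantify editing levels and test for differential editing.

Builds the sites x samples editing matrix (level = G/(A+G)), computes
per-sample transcriptome-wide averages, then fits the per-site binomial GLM
with a likelihood-ratio test of sepsis vs control, and summarizes the
differential sites with a PCA.
"""

from pathlib import Path

import pandas as pd

from editome import (
    GeneModels,
    KnownSiteCatalog,
    average_glm,
    build_matrix,
    differential_editing,
    discover_sites,
    pca_on_sites,
    read_variant_calls,
    sample_average_editing,
    select_differential,
)

fix = Path("scratch/example_fixture")
if not fix.exists():
    raise SystemExit("run examples/01_simulate_cohort.py first")

samples = pd.read_csv(fix / "samples.tsv", sep="\t")
calls = {
    sid: read_variant_calls(fix / "vcf" / f"{sid}.vcf", sample_id=sid)
    for sid in samples["sample_id"]
}
from editome.annotation import read_fasta, read_position_bed

disc = discover_sites(
    calls, GeneModels.from_gff3(fix / "genes.gff3"),
    KnownSiteCatalog.from_tsv(fix / "catalog.tsv"),
    snp_trees=read_position_bed(fix / "snps.bed"),
    genome=read_fasta(fix / "genome.fa"),
)
coverage = pd.read_csv(fix / "coverage.tsv", sep="\t", index_col=0)
matrix = build_matrix(disc.sites, calls, samples, coverage=coverage)

averages = sample_average_editing(matrix)
for region, sub in averages.groupby("region"):
    eff, p, _ = average_glm(sub["mean_level"], sub["group"], case_label="sepsis")
    print(f"{region}: mean editing sepsis-control difference {eff:+.4f}  (GLM LRT p={p:.3g})")

res = differential_editing(matrix, case_label="sepsis")
sites, genes = select_differential(res, p_threshold=0.05)
print(f"differential sites at raw p<0.05: {len(sites)} in {len(genes)} genes")
if len(sites) >= 2:
    pca = pca_on_sites(matrix.levels.loc[sites])
    print(f"PC1 of the differential sites explains "
          f"{100 * pca.variance_fraction[0]:.1f}% of the variance")
# With the default generator the hippocampus shows a negative average-editing
# shift (the planted region effect) while both regions share the per-site
# disease effects; the q_value column carries BH-adjusted values alongside.
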