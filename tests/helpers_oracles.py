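"""Independent brute-force oracles used by the test suite.

Everything here re-derives results from first principles with plain loops and
no calls into the package's own query structures, so agreement with the
package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Set, Tuple

import numpy as np


def oracle_passes_thresholds(call, t) -> bool:
    """Literal restatement of the four call-level retention rules."""
    depth = call.ref_count + call.alt_count
    if call.mean_base_quality < t.min_base_quality:
        return False
    if call.alt_count < t.min_alt_depth:
        return False
    if depth < t.min_depth or depth == 0:
        return False
    if call.alt_count / depth < t.min_aaf:
        return False
    return True


def _gene_overlaps(genes_df, chrom: str, pos: int) -> List[Tuple[str, str]]:
    out = []
    for r in genes_df.itertuples(index=False):
        if r.chrom == chrom and r.start <= pos <= r.end:
            out.append((r.gene_id, r.strand))
    return out


def oracle_discovery(
    calls_by_sample: Dict[str, Iterable],
    genes_df,
    features_df,
    catalog_records: Set[Tuple[str, int, str]],
    snp_positions: Set[Tuple[str, int]],
    genome: Dict[str, str],
    thresholds,
    min_samples_called: int = 1,
    homopolymer_min_run: int = 5,
    splice_window: int = 4,
) -> Set[Tuple[str, int, str]]:
    """Re-derive the retained high-confidence site set rule by rule."""
    catalog_strand = {}
    for c, p, s in catalog_records:
        catalog_strand[(c, p)] = s

    # splice junctions: internal exon boundaries per gene
    junctions: Set[Tuple[str, int]] = set()
    ex = features_df[features_df["kind"] == "exon"]
    for gene_id, sub in ex.groupby("gene_id"):
        sub = sub.sort_values("start")
        rows = list(sub.itertuples(index=False))
        for a, b in zip(rows, rows[1:]):
            junctions.add((a.chrom, a.end))
            junctions.add((b.chrom, b.start))

    site_samples: Dict[Tuple[str, int, str], Set[str]] = {}
    site_known: Dict[Tuple[str, int, str], bool] = {}
    alleles: Dict[Tuple[str, int], Set[Tuple[str, str]]] = {}
    for sample, calls in calls_by_sample.items():
        for call in calls:
            if not oracle_passes_thresholds(call, thresholds):
                continue
            alleles.setdefault((call.chrom, call.pos), set()).add((call.ref, call.alt))
            cat = catalog_strand.get((call.chrom, call.pos))
            if cat == "+" and call.ref == "A" and call.alt == "G":
                strand, known = "+", True
            elif cat == "-" and call.ref == "T" and call.alt == "C":
                strand, known = "-", True
            else:
                overlaps = _gene_overlaps(genes_df, call.chrom, call.pos)
                strands = {s for _, s in overlaps}
                if len(strands) != 1:
                    continue  # intergenic or ambiguous
                strand = strands.pop()
                if strand == "+" and (call.ref, call.alt) == ("A", "G"):
                    known = False
                elif strand == "-" and (call.ref, call.alt) == ("T", "C"):
                    known = False
                else:
                    continue
            key = (call.chrom, call.pos, strand)
            site_samples.setdefault(key, set()).add(sample)
            site_known[key] = site_known.get(key, False) or known

    retained: Set[Tuple[str, int, str]] = set()
    for key, samples in site_samples.items():
        if len(samples) < min_samples_called:
            continue
        chrom, pos, strand = key
        if site_known[key]:
            retained.add(key)
            continue
        if (chrom, pos) in snp_positions:
            continue
        seq = genome[chrom]
        i = pos - 1
        run = 1
        j = i - 1
        while j >= 0 and seq[j] == seq[i]:
            run += 1
            j -= 1
        j = i + 1
        while j < len(seq) and seq[j] == seq[i]:
            run += 1
            j += 1
        if run >= homopolymer_min_run:
            continue
        if any(
            (chrom, jp) in junctions
            for jp in range(pos - splice_window, pos + splice_window + 1)
        ):
            continue
        if len(alleles[(chrom, pos)]) > 1:
            continue
        retained.add(key)
    return retained


def oracle_intersections(named_sets: Dict[str, Set[str]], min_sets: int = 2):
    """Power-set enumeration of Venn regions and key genes."""
    names = sorted(named_sets)
    all_genes = set().union(*named_sets.values())
    regions: Dict[Tuple[str, ...], Set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(all_genes)
            for n in combo:
                inside &= named_sets[n]
            for n in names:
                if n not in combo:
                    inside -= named_sets[n]
            if inside:
                regions[combo] = inside
    key = sorted(
        (
            (g, tuple(sorted(n for n in names if g in named_sets[n])))
            for g in all_genes
            if sum(g in named_sets[n] for n in names) >= min_sets
        ),
        key=lambda kv: (-len(kv[1]), kv[0]),
    )
    return regions, key


def oracle_spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p for Spearman rho via scipy per permutation."""
    from scipy.stats import spearmanr

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rho_obs = abs(spearmanr(x, y).statistic)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        total += 1
        if abs(spearmanr(x, y[list(perm)]).statistic) >= rho_obs - 1e-12:
            count += 1
    return count / total


def oracle_pca_fractions(X: np.ndarray) -> np.ndarray:
    """Variance fractions from an explicit eigendecomposition of the sample
    covariance of the (complete) samples x features matrix."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals = np.linalg.eigvalsh(cov)[::-1]
    vals = np.clip(vals, 0, None)
    return vals / vals.sum()
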