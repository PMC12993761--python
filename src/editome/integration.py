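"""Cross-cohort integration and validation-arm quantifications.

Covers the comparisons that turn per-comparison differential gene lists into
*key genes* (genes dysregulated in two or more named comparisons, e.g. both
brain regions or both cohorts), Spearman correlations between editing levels
and host-gene expression, and the two wet-lab quantifications the analysis
consumes as numbers: relative qPCR expression by the 2^-ddCt method and the
Sanger chromatogram peak-height editing level G/(A+G).

Spearman p-values use exact permutation enumeration for n <= 8 — cohort arms
of size 7 are too small for the t-approximation to be trusted — and the
t-approximation beyond that.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .editing_quant import EditingMatrix

logger = logging.getLogger(__name__)

#: largest n for which the exact permutation Spearman p-value is computed
EXACT_SPEARMAN_MAX_N = 8


# -- gene-set intersection -------------------------------------------------

@dataclass
class IntersectionReport:
    """Exact set algebra over named differential-gene sets.

    ``membership`` maps each gene to the sorted tuple of set names containing
    it; ``regions`` gives, for every non-empty combination of sets, the genes
    belonging to exactly those sets (the Venn regions); ``key_genes`` lists
    (gene, contributing sets) for genes in at least ``min_sets`` sets, sorted
    by number of contributing sets (descending) then name.
    """

    sets: Dict[str, Set[str]]
    membership: Dict[str, Tuple[str, ...]]
    regions: Dict[Tuple[str, ...], List[str]]
    key_genes: List[Tuple[str, Tuple[str, ...]]]
    min_sets: int = 2

    def intersection(self, *names: str) -> Set[str]:
        out = set(self.sets[names[0]])
        for n in names[1:]:
            out &= self.sets[n]
        return out

    def union(self, *names: str) -> Set[str]:
        out: Set[str] = set()
        for n in names:
            out |= self.sets[n]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "n_sets": len(names), "sets": ",".join(names)}
            for g, names in sorted(
                self.membership.items(), key=lambda kv: (-len(kv[1]), kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["gene_id", "n_sets", "sets"])


def intersect_gene_sets(
    named_sets: Mapping[str, Set[str]], min_sets: int = 2
) -> IntersectionReport:
    """Intersect named differential-gene sets and extract key genes.

    Key genes are genes differential in at least ``min_sets`` of the named
    comparisons. Empty sets are permitted; at least two sets are required.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 named gene sets")
    sets = {name: set(genes) for name, genes in named_sets.items()}
    membership: Dict[str, Tuple[str, ...]] = {}
    for gene in sorted(set().union(*sets.values())):
        membership[gene] = tuple(sorted(n for n, s in sets.items() if gene in s))
    regions: Dict[Tuple[str, ...], List[str]] = {}
    for gene, names in membership.items():
        regions.setdefault(names, []).append(gene)
    key = [
        (gene, names) for gene, names in membership.items() if len(names) >= min_sets
    ]
    key.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    return IntersectionReport(
        sets=sets, membership=membership, regions=regions, key_genes=key, min_sets=min_sets
    )


# -- Spearman correlation --------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its p-value and pair count."""

    rho: float
    p_value: float
    n: int
    method: str  # "exact" or "t-approx"
    undefined: bool = False


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of rank vectors (= Spearman rho with average ranks)."""
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
    return float((rxc * ryc).sum() / denom)


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = EXACT_SPEARMAN_MAX_N
) -> CorrelationResult:
    """Spearman rank correlation with an exact permutation p-value at small n.

    Rho uses average ranks for ties. For n <= ``exact_max_n`` the two-sided
    p-value is the fraction of all n! orderings of y whose |rho| reaches the
    observed |rho|; beyond that the usual t-approximation applies. Constant
    input leaves rho undefined (flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 paired non-missing values, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(float("nan"), float("nan"), n, "none", undefined=True)
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= exact_max_n:
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rank_corr(rx, ry[list(perm)])) >= target:
                count += 1
        return CorrelationResult(rho, count / total, n, "exact")
    p = float(spearmanr(x, y).pvalue)
    return CorrelationResult(rho, p, n, "t-approx")


def editing_expression_correlations(
    matrix: EditingMatrix,
    expression: pd.DataFrame,
    site_ids: Optional[Sequence[str]] = None,
    min_samples: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of each site's editing level with its host gene's
    expression across the samples where both are present.

    ``expression`` is genes x samples. Sites without a host gene, without
    expression, or with fewer than ``min_samples`` complete pairs are
    skipped (logged). Returns site_id, gene_id, rho, p_value, n, method.
    """
    lv = matrix.levels
    shared = [s for s in lv.columns if s in expression.columns]
    rows = []
    ids = list(site_ids) if site_ids is not None else list(lv.index)
    for sid in ids:
        if sid not in lv.index:
            continue
        gene = matrix.sites.at[sid, "gene_id"]
        if not isinstance(gene, str) or gene not in expression.index:
            logger.info("site %s: no host-gene expression; skipped", sid)
            continue
        e = expression.loc[gene, shared].to_numpy(dtype=float)
        v = lv.loc[sid, shared].to_numpy(dtype=float)
        ok = ~(np.isnan(v) | np.isnan(e))
        if ok.sum() < min_samples:
            logger.info("site %s: only %d complete pairs; skipped", sid, int(ok.sum()))
            continue
        res = spearman_correlation(v[ok], e[ok])
        rows.append(
            {
                "site_id": sid,
                "gene_id": gene,
                "rho": res.rho,
                "p_value": res.p_value,
                "n": res.n,
                "method": res.method,
                "undefined": res.undefined,
            }
        )
    return pd.DataFrame(
        rows, columns=["site_id", "gene_id", "rho", "p_value", "n", "method", "undefined"]
    )


# -- qPCR ddCt and Sanger quantification -----------------------------------

def ddct_fold_change(
    records: pd.DataFrame, calibrator: str, condition_col: str = "condition"
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression by the 2^-ddCt method.

    ``records`` needs columns sample_id, condition, target_ct, reference_ct
    (reference = housekeeping gene, e.g. ACTB). dCt = target_ct -
    reference_ct per sample; ddCt subtracts the calibrator condition's mean
    dCt; fold change = 2^-ddCt. Records with a missing Ct are skipped with a
    warning. Returns (per-sample table, per-condition mean +- SD summary).
    """
    df = records.copy()
    bad = df["target_ct"].isna() | df["reference_ct"].isna()
    if bad.any():
        for sid in df.loc[bad, "sample_id"]:
            logger.warning("qPCR record %s missing a Ct value; skipped", sid)
        df = df[~bad]
    if not (df[condition_col] == calibrator).any():
        raise ValueError(f"calibrator condition {calibrator!r} has no usable records")
    df = df.assign(dct=df["target_ct"] - df["reference_ct"])
    calib_mean = df.loc[df[condition_col] == calibrator, "dct"].mean()
    df = df.assign(ddct=df["dct"] - calib_mean)
    df = df.assign(fold_change=2.0 ** (-df["ddct"]))
    summary = (
        df.groupby(condition_col)["fold_change"]
        .agg(mean_fold="mean", sd_fold="std", n="count")
        .reset_index()
    )
    return df.reset_index(drop=True), summary


def sanger_editing_level(peak_height_a: float, peak_height_g: float) -> float:
    """Editing level from Sanger chromatogram peak heights at the edited
    position (coding-strand orientation): G / (A + G)."""
    if peak_height_a < 0 or peak_height_g < 0:
        raise ValueError("peak heights must be non-negative")
    total = peak_height_a + peak_height_g
    if total == 0:
        raise ValueError("both peaks zero; editing level undefined")
    return peak_height_g / total
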