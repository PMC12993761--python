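"""Differential editing statistics.

Per site, editing is compared between groups with a binomial generalized
linear model (logit link) on alternative read counts out of depth, with the
disease status as the single independent variable, and a likelihood-ratio
test of the group term against the intercept-only null (deviance difference
~ chi-square, df 1). For a single two-level factor the binomial MLE is the
group-pooled proportion, so the fit is closed form and vectorized across
sites; tests cross-check it against an iteratively fitted GLM.

Group comparisons of per-sample average editing (a continuous response) use
a Gaussian GLM on a two-level factor, again with an LRT between nested
models. Benjamini-Hochberg q-values are reported alongside raw p-values;
selection defaults to raw p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit, xlogy
from scipy.stats import chi2, f as f_dist

from .editing_quant import EditingMatrix

#: |beta| cap when a fitted group proportion is exactly 0 or 1 (flagged).
BETA_CAP = 15.0


def _binom_ll(alt: np.ndarray, depth: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood (without the combinatorial constant), summed
    over samples; 0*log(0) = 0 so boundary proportions are exact."""
    return (xlogy(alt, p) + xlogy(depth - alt, 1.0 - p)).sum(axis=-1)


def _safe_logit(p: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Logit with boundary capping; returns (value, was_degenerate)."""
    degenerate = (p <= 0.0) | (p >= 1.0)
    clipped = np.clip(p, expit(-BETA_CAP), expit(BETA_CAP))
    return logit(clipped), degenerate


def binomial_lrt_matrix(
    alt: np.ndarray,
    depth: np.ndarray,
    case_mask: np.ndarray,
    min_per_group: int = 2,
    family: str = "binomial",
) -> pd.DataFrame:
    """Vectorized per-site binomial GLM + LRT over a sites x samples array.

    Parameters
    ----------
    alt, depth
        (S, N) integer arrays; cells with depth 0 are treated as missing.
    case_mask
        Boolean (N,) array marking the case (e.g. sepsis) samples.
    min_per_group
        Minimum samples with data per group; sites below it are untestable
        (p, beta = NaN).
    family
        "binomial" (LRT vs chi-square df 1) or "quasibinomial" (dispersion
        estimated from Pearson residuals under the group model; F test).

    Returns one row per site: beta_group (logit-scale case-vs-control
    effect), group mean levels, lrt_stat, df, p_value, sample counts, and a
    degenerate flag for boundary fits.
    """
    if family not in ("binomial", "quasibinomial"):
        raise ValueError(f"unknown family {family!r}")
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    present = depth > 0
    n_case = (present & case_mask).sum(axis=1)
    n_ctrl = (present & ~case_mask).sum(axis=1)

    def pooled(mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        a = (alt * present * mask).sum(axis=1)
        d = (depth * present * mask).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, a / d, np.nan), d

    p_case, d_case = pooled(case_mask)
    p_ctrl, d_ctrl = pooled(~case_mask)
    a_all = (alt * present).sum(axis=1)
    d_all = (depth * present).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_all = np.where(d_all > 0, a_all / d_all, np.nan)

    alt_m = np.where(present, alt, 0.0)
    dep_m = np.where(present, depth, 0.0)
    p_fit = np.where(case_mask[None, :], p_case[:, None], p_ctrl[:, None])
    ll_alt = _binom_ll(alt_m, dep_m, np.clip(p_fit, 1e-300, 1.0))
    ll_null = _binom_ll(alt_m, dep_m, np.clip(p_all[:, None], 1e-300, 1.0))
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)

    b_case, deg_case = _safe_logit(p_case)
    b_ctrl, deg_ctrl = _safe_logit(p_ctrl)
    beta = b_case - b_ctrl
    degenerate = deg_case | deg_ctrl

    testable = (n_case >= min_per_group) & (n_ctrl >= min_per_group)
    # no information: zero (or saturated) alternative reads everywhere
    no_info = (a_all <= 0) | (a_all >= d_all)
    p_value = np.full(alt.shape[0], np.nan)
    if family == "binomial":
        p_value[testable] = chi2.sf(lrt[testable], df=1)
    else:
        n_used = n_case + n_ctrl
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = p_fit * dep_m
            pearson = np.where(
                present & (p_fit > 0) & (p_fit < 1),
                (alt_m - mu) ** 2 / np.clip(mu * (1.0 - p_fit), 1e-300, None),
                0.0,
            ).sum(axis=1)
        dof = np.maximum(n_used - 2, 1)
        phi = np.maximum(pearson / dof, 1.0)  # never deflate the null variance
        fstat = lrt / phi
        p_value[testable] = f_dist.sf(fstat[testable], 1, dof[testable])
    p_value = np.where(testable & no_info, 1.0, p_value)
    lrt = np.where(no_info, 0.0, lrt)
    beta = np.where(testable, beta, np.nan)
    return pd.DataFrame(
        {
            "beta_group": beta,
            "mean_case": p_case,
            "mean_control": p_ctrl,
            "lrt_stat": lrt,
            "df": 1,
            "p_value": p_value,
            "n_case": n_case,
            "n_control": n_ctrl,
            "degenerate": degenerate,
            "testable": testable,
        }
    )


def site_glm_lrt(
    ref_counts: Sequence[int],
    alt_counts: Sequence[int],
    groups: Sequence[str],
    case_label: str = "sepsis",
    family: str = "binomial",
    min_per_group: int = 2,
) -> dict:
    """Binomial GLM + LRT at a single site (see :func:`binomial_lrt_matrix`).

    ``groups`` holds the per-sample disease status; samples with zero depth
    count as missing. Returns a plain dict with the per-site statistics.
    """
    ref = np.asarray(ref_counts, dtype=float)[None, :]
    alt = np.asarray(alt_counts, dtype=float)[None, :]
    case = np.asarray([g == case_label for g in groups])
    out = binomial_lrt_matrix(alt, ref + alt, case, min_per_group=min_per_group, family=family)
    return out.iloc[0].to_dict()


def differential_editing(
    matrix: EditingMatrix,
    case_label: str = "sepsis",
    group_col: str = "group",
    family: str = "binomial",
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-site differential editing over an :class:`EditingMatrix`.

    Adds host gene, BH q-values and group means; rows follow the matrix's
    site order.
    """
    case = (matrix.samples[group_col] == case_label).to_numpy()
    depth = (matrix.ref + matrix.alt).to_numpy(dtype=float)
    depth = np.where(matrix.covered.to_numpy(), depth, 0.0)
    alt = np.where(matrix.covered.to_numpy(), matrix.alt.to_numpy(dtype=float), 0.0)
    res = binomial_lrt_matrix(alt, depth, case, min_per_group=min_per_group, family=family)
    res.insert(0, "site_id", matrix.ref.index.to_numpy())
    res.insert(1, "gene_id", matrix.sites["gene_id"].to_numpy())
    res["q_value"] = adjust_pvalues(res["p_value"].to_numpy())
    return res


def average_glm(
    values: Sequence[float],
    labels: Sequence[str],
    case_label: Optional[str] = None,
) -> Tuple[float, float, float]:
    """Gaussian GLM of a continuous response on a two-level factor, with an
    LRT p-value from the nested-model deviance difference.

    Returns (effect, p_value, lrt_stat) where effect is mean(case) minus
    mean(other). A constant response gives p = 1.
    """
    y = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    ok = ~np.isnan(y)
    y, lab = y[ok], lab[ok]
    levels = pd.unique(lab)
    if len(levels) != 2:
        raise ValueError(f"factor must have exactly 2 levels, got {list(levels)}")
    case = case_label if case_label is not None else levels[0]
    m1 = lab == case
    if m1.sum() < 2 or (~m1).sum() < 2:
        raise ValueError("need >= 2 samples per factor level")
    n = len(y)
    mu1, mu0 = y[m1].mean(), y[~m1].mean()
    effect = mu1 - mu0
    rss1 = ((y[m1] - mu1) ** 2).sum() + ((y[~m1] - mu0) ** 2).sum()
    rss0 = ((y - y.mean()) ** 2).sum()
    if rss0 <= 1e-300:  # constant response
        return 0.0, 1.0, 0.0
    lrt = n * np.log(rss0 / max(rss1, 1e-300))
    return float(effect), float(chi2.sf(lrt, df=1)), float(lrt)


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN-preserving, order-preserving)."""
    if method != "bh":
        raise ValueError(f"unsupported method {method!r}")
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def select_differential(
    results: pd.DataFrame,
    p_threshold: float = 0.05,
    use_q: bool = False,
    q_threshold: float = 0.05,
) -> Tuple[list, list]:
    """Select differential sites (default: raw p < 0.05) and the unique host
    genes of the selected sites."""
    col, thr = ("q_value", q_threshold) if use_q else ("p_value", p_threshold)
    sel = results[results[col] < thr]
    sites = sel["site_id"].tolist()
    genes = sorted({g for g in sel["gene_id"] if isinstance(g, str) and g})
    return sites, genes


@dataclass
class PcaResult:
    """PCA of samples over (differential) site levels."""

    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray  # non-increasing, sums to 1


def pca_on_sites(levels: pd.DataFrame) -> PcaResult:
    """PCA of the samples x sites editing-level matrix.

    Missing cells are imputed with the site mean, sites are centered, and
    components come from the SVD of the centered matrix; variance fractions
    are the normalized squared singular values.

    ``levels`` is sites x samples (matrix orientation); samples become PCA
    observations.
    """
    X = levels.to_numpy(dtype=float).T  # samples x sites
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 sites")
    col_mean = np.nanmean(X, axis=0)
    keep = ~np.isnan(col_mean)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 sites with any data")
    X = X[:, keep]
    col_mean = col_mean[keep]
    nan_mask = np.isnan(X)
    X[nan_mask] = np.broadcast_to(col_mean, X.shape)[nan_mask]
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    if total <= 0:
        raise ValueError("zero total variance; PCA undefined")
    frac = s**2 / total
    scores = pd.DataFrame(
        U * s,
        index=levels.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return PcaResult(scores=scores, variance_fraction=frac)
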