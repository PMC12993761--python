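"""Editing-level quantification: the sites x samples matrix and per-sample
transcriptome-wide averages.

The editing level at a site is G/(A+G) in coding-strand orientation — the
alternative allele frequency of the A-to-G call. A cell is *missing* (not
zero) when the sample has neither a passing call nor evidence of coverage:
VCFs only report variant positions, so absence of a call alone cannot
distinguish "unedited" from "unsequenced".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ThresholdSet
from .site_discovery import EditingSiteRecord, apply_call_thresholds
from .vcfio import VariantCall

logger = logging.getLogger(__name__)


def editing_level(ref_count: int, alt_count: int) -> float:
    """Editing level alt/(ref+alt), i.e. G/(A+G) on the coding strand."""
    depth = ref_count + alt_count
    if depth <= 0:
        raise ValueError("editing level undefined at zero depth; mark the cell missing")
    return alt_count / depth


@dataclass
class EditingMatrix:
    """Sites x samples editing levels with counts and a coverage mask.

    ``levels`` is ``alt / (ref + alt)`` wherever ``covered`` and NaN
    elsewhere; all three count/mask frames share the same index (site_id)
    and columns (sample_id).
    """

    sites: pd.DataFrame  # one row per site (site_id index)
    samples: pd.DataFrame  # sample_id, group, region, cohort
    ref: pd.DataFrame
    alt: pd.DataFrame
    covered: pd.DataFrame

    @property
    def levels(self) -> pd.DataFrame:
        depth = self.ref + self.alt
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = self.alt / depth
        return lv.where(self.covered & (depth > 0))

    def to_long(self) -> pd.DataFrame:
        """Long-format table: site_id, sample_id, ref_count, alt_count, level."""
        lv = self.levels
        rows = []
        for sid in self.ref.columns:
            mask = self.covered[sid]
            sub = pd.DataFrame(
                {
                    "site_id": self.ref.index[mask],
                    "sample_id": sid,
                    "ref_count": self.ref.loc[mask, sid].to_numpy(),
                    "alt_count": self.alt.loc[mask, sid].to_numpy(),
                    "level": lv.loc[mask, sid].to_numpy(),
                }
            )
            rows.append(sub)
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["site_id", "sample_id", "ref_count", "alt_count", "level"]
        )


def build_matrix(
    sites: Sequence[EditingSiteRecord],
    calls_by_sample: Mapping[str, Iterable[VariantCall]],
    samples: pd.DataFrame,
    coverage: Optional[pd.DataFrame] = None,
    thresholds: ThresholdSet = ThresholdSet(),
) -> EditingMatrix:
    """Assemble the editing matrix for the union of high-confidence sites.

    Per (site, sample): a passing call supplies its counts; otherwise a
    coverage table showing depth >= ``thresholds.min_depth`` makes the cell
    covered-but-unedited (level 0); otherwise the cell is missing. Samples on
    the sheet without calls or coverage get an all-missing column (warned).
    """
    site_ids = [s.site_id for s in sites]
    pos_index = {(s.chrom, s.pos): i for i, s in enumerate(sites)}
    sample_ids = samples["sample_id"].tolist()
    S, N = len(site_ids), len(sample_ids)
    ref = np.zeros((S, N), dtype=int)
    alt = np.zeros((S, N), dtype=int)
    covered = np.zeros((S, N), dtype=bool)

    cov_lookup = None
    if coverage is not None:
        cov_lookup = coverage.copy()
        if "site_id" in cov_lookup.columns:
            cov_lookup = cov_lookup.set_index("site_id")
        # match coverage rows by (chrom, pos) parsed from the site_id index
        parsed = {}
        for sid_cov in cov_lookup.index:
            chrom, p = str(sid_cov).split(":")[:2]
            parsed[(chrom, int(p))] = sid_cov
    for j, sample_id in enumerate(sample_ids):
        calls = calls_by_sample.get(sample_id)
        has_cov = cov_lookup is not None and sample_id in cov_lookup.columns
        if calls is None and not has_cov:
            logger.warning("sample %s has no calls and no coverage; column is missing", sample_id)
            continue
        if calls is not None:
            for c in apply_call_thresholds(calls, thresholds):
                i = pos_index.get((c.chrom, c.pos))
                if i is None:
                    continue
                ref[i, j] = c.ref_count
                alt[i, j] = c.alt_count
                covered[i, j] = True
        if has_cov:
            for i, s in enumerate(sites):
                if covered[i, j]:
                    continue
                key = parsed.get((s.chrom, s.pos))
                if key is None:
                    continue
                depth = int(cov_lookup.at[key, sample_id])
                if depth >= thresholds.min_depth:
                    ref[i, j] = depth
                    alt[i, j] = 0
                    covered[i, j] = True
    from .site_discovery import sites_to_frame

    sites_df = sites_to_frame(sites).set_index("site_id")
    idx = pd.Index(site_ids, name="site_id")
    return EditingMatrix(
        sites=sites_df,
        samples=samples.reset_index(drop=True),
        ref=pd.DataFrame(ref, index=idx, columns=sample_ids),
        alt=pd.DataFrame(alt, index=idx, columns=sample_ids),
        covered=pd.DataFrame(covered, index=idx, columns=sample_ids),
    )


def matrix_from_long(
    long_df: pd.DataFrame,
    samples: pd.DataFrame,
    sites: Optional[pd.DataFrame] = None,
) -> EditingMatrix:
    """Rebuild an :class:`EditingMatrix` from its long-format TSV
    (site_id, sample_id, ref_count, alt_count, level).

    ``sites`` optionally supplies per-site annotation (site_id plus e.g.
    gene_id); otherwise a minimal site table is derived from the ids.
    """
    sample_ids = samples["sample_id"].tolist()
    ref = long_df.pivot(index="site_id", columns="sample_id", values="ref_count")
    alt = long_df.pivot(index="site_id", columns="sample_id", values="alt_count")
    covered = ref.notna()
    ref = ref.reindex(columns=sample_ids).fillna(0).astype(int)
    alt = alt.reindex(columns=sample_ids).fillna(0).astype(int)
    covered = covered.reindex(columns=sample_ids).fillna(False)
    ref.columns.name = None
    if sites is not None:
        sites_df = sites.set_index("site_id").reindex(ref.index)
    else:
        parts = [str(s).split(":") for s in ref.index]
        sites_df = pd.DataFrame(
            {
                "chrom": [p[0] for p in parts],
                "pos": [int(p[1]) for p in parts],
                "strand": [p[2] if len(p) > 2 else "+" for p in parts],
                "gene_id": None,
            },
            index=ref.index,
        )
    return EditingMatrix(
        sites=sites_df, samples=samples.reset_index(drop=True),
        ref=ref, alt=alt, covered=covered,
    )


def sample_average_editing(
    matrix: EditingMatrix,
    min_sites: int = 1,
    complete_sites_only: bool = False,
) -> pd.DataFrame:
    """Per-sample transcriptome-wide average editing level.

    Unweighted mean over non-missing site levels; with
    ``complete_sites_only`` the mean is restricted to sites covered in every
    sample. Samples with fewer than ``min_sites`` contributing sites are
    flagged ``ok=False`` and should be excluded from group tests.
    """
    lv = matrix.levels
    if complete_sites_only:
        lv = lv.dropna(axis=0, how="any")
    n = lv.notna().sum(axis=0)
    means = lv.mean(axis=0)
    out = matrix.samples.set_index("sample_id").copy()
    out["n_sites"] = n
    out["mean_level"] = means
    out["ok"] = n >= min_sites
    return out.reset_index()
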