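"""Reading and writing per-sample VCFs of RNA-seq variant calls.

The pipeline consumes VarScan-style single-sample VCFs: one biallelic SNV per
record with FORMAT fields ``DP`` (depth), ``AD`` (ref,alt allele depths) and
``BQ`` (mean base quality of the alternative allele). Reading goes through
:mod:`pysam`; writing emits plain VCF 4.2 text with a contig-complete header
so the files round-trip.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Optional

import pandas as pd

logger = logging.getLogger(__name__)


class VcfFormatError(ValueError):
    """A VCF record is missing a required field; the message names it."""


@dataclass(frozen=True)
class VariantCall:
    """One called single-nucleotide variant in one sample.

    ``alt_count / depth`` is the alternative allele frequency (AAF), which at
    an A-to-G site equals the editing level G/(A+G).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    mean_base_quality: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(f"negative allele count at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def aaf(self) -> float:
        """Alternative allele frequency; 0.0 at zero depth."""
        d = self.depth
        return self.alt_count / d if d > 0 else 0.0


def read_variant_calls(
    path: str | os.PathLike,
    sample_id: Optional[str] = None,
    multiallelic: str = "drop",
) -> List[VariantCall]:
    """Read one sample's biallelic SNV calls from a VCF.

    Parameters
    ----------
    path
        VCF 4.x file with FORMAT ``AD`` (Number=R) and ``BQ``; ``DP`` is
        cross-checked when present.
    sample_id
        Sample column to read; defaults to the first (and usually only) one.
    multiallelic
        ``"drop"`` (default; dropped records are logged) or ``"split"``
        (each ALT becomes its own biallelic call sharing the REF depth).
    """
    import pysam

    if multiallelic not in ("drop", "split"):
        raise ValueError(f"multiallelic policy must be 'drop' or 'split', got {multiallelic!r}")
    calls: List[VariantCall] = []
    n_multi = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise VcfFormatError(f"{path}: no sample columns")
        name = sample_id if sample_id is not None else samples[0]
        if name not in samples:
            raise VcfFormatError(f"{path}: sample {name!r} not in VCF")
        for rec in vf:
            alts = rec.alts or ()
            ref = rec.ref or ""
            if len(alts) == 0:
                continue
            snv_alts = [a for a in alts if len(a) == 1]
            if len(ref) != 1 or len(snv_alts) != len(alts):
                continue  # indel / non-SNV
            fmt = rec.samples[name]
            ad = fmt.get("AD")
            if ad is None or ad[0] is None:
                raise VcfFormatError(f"{path}: record {rec.chrom}:{rec.pos} lacks FORMAT/AD")
            bq = fmt.get("BQ")
            if bq is None:
                raise VcfFormatError(f"{path}: record {rec.chrom}:{rec.pos} lacks FORMAT/BQ")
            if len(alts) > 1:
                n_multi += 1
                if multiallelic == "drop":
                    continue
            for i, alt in enumerate(alts):
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                        ref_count=int(ad[0]),
                        alt_count=int(ad[i + 1]),
                        mean_base_quality=float(bq if not isinstance(bq, tuple) else bq[0]),
                        sample_id=name,
                    )
                )
                if multiallelic == "drop":
                    break
    if n_multi:
        logger.info("%s: %d multi-allelic records (%s)", path, n_multi, multiallelic)
    return calls


def write_sample_vcf(
    path: str | os.PathLike,
    sample_id: str,
    calls: pd.DataFrame,
    contigs: Dict[str, int],
) -> None:
    """Write one sample's calls (columns chrom, pos, ref, alt, ref_count,
    alt_count, mean_base_quality) as a VCF 4.2 file."""
    cols = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count", "mean_base_quality"]
    df = calls[cols].sort_values(["chrom", "pos"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=editome-synthdata\n")
        for chrom in sorted(contigs):
            fh.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(
            '##FORMAT=<ID=BQ,Number=1,Type=Float,'
            'Description="Mean base quality of the alternative allele">\n'
        )
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for r in df.itertuples(index=False):
            dp = int(r.ref_count) + int(r.alt_count)
            fh.write(
                f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\tDP={dp}\t"
                f"GT:DP:AD:BQ\t0/1:{dp}:{int(r.ref_count)},{int(r.alt_count)}:"
                f"{float(r.mean_base_quality):.2f}\n"
            )


def calls_to_frame(calls: List[VariantCall]) -> pd.DataFrame:
    """Tabulate VariantCall objects (adds depth and AAF columns)."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos for c in calls],
            "ref": [c.ref for c in calls],
            "alt": [c.alt for c in calls],
            "ref_count": [c.ref_count for c in calls],
            "alt_count": [c.alt_count for c in calls],
            "mean_base_quality": [c.mean_base_quality for c in calls],
            "sample_id": [c.sample_id for c in calls],
            "depth": [c.depth for c in calls],
            "aaf": [c.aaf for c in calls],
        }
    )
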