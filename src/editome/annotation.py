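"""Genomic annotation containers: gene models, repeat track, known-site catalog.

Coordinate conventions (enforced by round-trip tests):

* GFF3 and the catalog are 1-based inclusive,
* BED is 0-based half-open,
* all in-memory positions are 1-based.

Gene models are loaded from GFF3 through :mod:`gffutils`; interval queries go
through :mod:`intervaltree`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: Precedence of functional categories when a site overlaps several features.
CATEGORY_PRECEDENCE = ("CDS", "3'UTR", "5'UTR", "noncoding_exon", "intron", "intergenic")

_GFF_KIND = {
    "five_prime_UTR": "5'UTR",
    "CDS": "CDS",
    "three_prime_UTR": "3'UTR",
    "exon": "exon",
}
_KIND_GFF = {v: k for k, v in _GFF_KIND.items()}


@dataclass
class GeneModels:
    """Gene and feature intervals with strand, plus derived interval trees.

    ``genes``: gene_id, chrom, start, end, strand, biotype (1-based inclusive).
    ``features``: gene_id, chrom, start, end, kind in {5'UTR, CDS, 3'UTR, exon}.
    Introns are implicit: inside a gene span but in no exon of that gene.
    """

    genes: pd.DataFrame
    features: pd.DataFrame
    _gene_trees: Dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _feature_trees: Dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _junctions: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._biotype = dict(zip(self.genes["gene_id"], self.genes["biotype"]))
        self._strand = dict(zip(self.genes["gene_id"], self.genes["strand"]))
        for _, g in self.genes.iterrows():
            # interval tree is half-open; store [start, end + 1)
            self._gene_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end + 1, (g.gene_id, g.strand, g.biotype)
            )
        for _, f in self.features.iterrows():
            self._feature_trees.setdefault(f.chrom, IntervalTree()).addi(
                f.start, f.end + 1, (f.gene_id, f.kind)
            )
        self._build_junctions()

    def _build_junctions(self) -> None:
        ex = self.features[self.features["kind"] == "exon"]
        juncs: Dict[str, List[int]] = {}
        for gene_id, sub in ex.groupby("gene_id"):
            sub = sub.sort_values("start")
            chrom = sub["chrom"].iloc[0]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            for i in range(len(sub) - 1):
                # internal boundary: last base of exon i, first base of exon i+1
                juncs.setdefault(chrom, []).extend((int(ends[i]), int(starts[i + 1])))
        self._junctions = {c: np.unique(np.asarray(v)) for c, v in juncs.items()}

    # -- queries ----------------------------------------------------------

    def genes_at(self, chrom: str, pos: int) -> List[Tuple[str, str]]:
        """Genes overlapping ``pos`` as (gene_id, strand) pairs."""
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data[0], iv.data[1]) for iv in tree.at(pos))

    def strand_at(self, chrom: str, pos: int) -> Optional[str]:
        """'+', '-', 'ambiguous' (genes on both strands) or None (intergenic)."""
        strands = {s for _, s in self.genes_at(chrom, pos)}
        if not strands:
            return None
        if len(strands) > 1:
            return "ambiguous"
        return strands.pop()

    def functional_category(self, chrom: str, pos: int) -> str:
        """Functional category at a position, by fixed precedence.

        CDS > 3'UTR > 5'UTR > noncoding_exon > intron > intergenic.
        """
        genes = self.genes_at(chrom, pos)
        if not genes:
            return "intergenic"
        found = set()
        tree = self._feature_trees.get(chrom)
        exonic_genes = set()
        if tree is not None:
            for iv in tree.at(pos):
                gene_id, kind = iv.data
                if kind == "exon":
                    exonic_genes.add(gene_id)
                    if self._biotype.get(gene_id) != "protein_coding":
                        found.add("noncoding_exon")
                else:
                    found.add(kind)
                    exonic_genes.add(gene_id)
        if any(g not in exonic_genes for g, _ in genes):
            found.add("intron")
        for cat in CATEGORY_PRECEDENCE:
            if cat in found:
                return cat
        return "intron"

    def host_gene(self, chrom: str, pos: int, strand: Optional[str] = None) -> Optional[str]:
        """Gene id hosting the position (restricted to ``strand`` if given)."""
        genes = self.genes_at(chrom, pos)
        if strand is not None:
            genes = [g for g in genes if g[1] == strand]
        return genes[0][0] if genes else None

    def near_splice_junction(self, chrom: str, pos: int, window: int = 4) -> bool:
        """True if ``pos`` is within ``window`` nt of an internal exon boundary."""
        j = self._junctions.get(chrom)
        if j is None or len(j) == 0:
            return False
        i = int(np.searchsorted(j, pos))
        for k in (i - 1, i):
            if 0 <= k < len(j) and abs(int(j[k]) - pos) <= window:
                return True
        return False

    # -- GFF3 round trip --------------------------------------------------

    def to_gff3(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, g in self.genes.sort_values(["chrom", "start"]).iterrows():
                fh.write(
                    f"{g.chrom}\teditome\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id};biotype={g.biotype}\n"
                )
                sub = self.features[self.features["gene_id"] == g.gene_id]
                for _, f in sub.sort_values("start").iterrows():
                    kind = _KIND_GFF[f.kind] if f.kind in _KIND_GFF else f.kind
                    fh.write(
                        f"{f.chrom}\teditome\t{kind}\t{f.start}\t{f.end}\t.\t{g.strand}\t"
                        f"{'0' if kind == 'CDS' else '.'}\tParent={g.gene_id}\n"
                    )

    @classmethod
    def from_gff3(cls, path: str | os.PathLike) -> "GeneModels":
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes, features = [], []
        for g in db.features_of_type("gene"):
            biotype = g.attributes.get("biotype", ["protein_coding"])[0]
            genes.append((g.id, g.seqid, g.start, g.end, g.strand, biotype))
        for kind_gff, kind in _GFF_KIND.items():
            for f in db.features_of_type(kind_gff):
                parent = f.attributes.get("Parent", [None])[0]
                features.append((parent, f.seqid, f.start, f.end, kind))
        genes_df = pd.DataFrame(
            genes, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
        )
        feat_df = pd.DataFrame(
            features, columns=["gene_id", "chrom", "start", "end", "kind"]
        )
        return cls(genes_df, feat_df)


@dataclass
class RepeatTrack:
    """Repeat intervals (Alu vs other) with BED round trip.

    ``intervals``: chrom, start (0-based), end (half-open), name. Any interval
    whose name starts with "Alu" counts as Alu; other names are other_repeat.
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        self._trees: Dict[str, IntervalTree] = {}
        for _, r in self.intervals.iterrows():
            if r.end > r.start:
                self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r["name"])

    def repeat_class(self, chrom: str, pos: int) -> str:
        """Repeat class at a 1-based position: Alu, other_repeat or none."""
        tree = self._trees.get(chrom)
        if tree is None:
            return "none"
        hits = tree.at(pos - 1)  # BED is 0-based
        if not hits:
            return "none"
        if any(str(iv.data).startswith("Alu") for iv in hits):
            return "Alu"
        return "other_repeat"

    def to_bed(self, path: str | os.PathLike) -> None:
        self.intervals.sort_values(["chrom", "start"]).to_csv(
            path, sep="\t", header=False, index=False,
            columns=["chrom", "start", "end", "name"],
        )

    @classmethod
    def from_bed(cls, path: str | os.PathLike) -> "RepeatTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name"],
            usecols=[0, 1, 2, 3], dtype={0: str, 3: str},
        )
        return cls(df)


def read_position_bed(path: str | os.PathLike) -> Dict[str, IntervalTree]:
    """Read a BED file of excluded intervals (e.g. SNPs) into interval trees.

    Returns 0-based half-open trees keyed by chromosome; query 1-based
    positions with ``trees[chrom].at(pos - 1)``.
    """
    trees: Dict[str, IntervalTree] = {}
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2], dtype={0: str},
    )
    for _, r in df.iterrows():
        if r.end > r.start:
            trees.setdefault(r.chrom, IntervalTree()).addi(int(r.start), int(r.end))
    return trees


@dataclass(frozen=True)
class KnownSiteCatalog:
    """Known editing-site catalog keyed by exact (chrom, pos, strand)."""

    sites: frozenset

    @classmethod
    def from_records(cls, records: Iterable[Tuple[str, int, str]]) -> "KnownSiteCatalog":
        return cls(frozenset((c, int(p), s) for c, p, s in records))

    def __contains__(self, key: Tuple[str, int, str]) -> bool:
        chrom, pos, strand = key
        return (chrom, int(pos), strand) in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    def strand_of(self, chrom: str, pos: int) -> Optional[str]:
        """Catalog strand at (chrom, pos), or None if absent."""
        for s in ("+", "-"):
            if (chrom, int(pos), s) in self.sites:
                return s
        return None

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(sorted(self.sites), columns=["chrom", "pos", "strand"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "KnownSiteCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "strand": str})
        return cls.from_records(df.itertuples(index=False))


# -- reference genome helpers ---------------------------------------------

def write_fasta(genome: Dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    import pysam

    with pysam.FastaFile(str(path)) as fa:
        return {name: fa.fetch(name) for name in fa.references}


def homopolymer_run_length(seq: str, pos: int) -> int:
    """Length of the homopolymer run containing the 1-based position ``pos``."""
    i = pos - 1
    base = seq[i]
    left = i
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = i
    while right + 1 < len(seq) and seq[right + 1] == base:
        right += 1
    return right - left + 1
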