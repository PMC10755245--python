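"""SNP-to-gene mapping and hypergeometric over-representation analysis.

Gene intervals come from a local BED file (0-based, half-open); SNP
positions are 1-based (VCF convention) and the conversion happens in one
place (:func:`snp_to_bed_coord`). A SNP maps to every gene whose —
optionally flanked — interval contains it. Over-representation of a query
gene list against GMT gene sets uses the hypergeometric upper tail
P(X >= k) with BH adjustment across the tested terms; the universe
defaults to all genes in the interval file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree
from gseapy.parser import read_gmt
from scipy import stats

from .association import bh_fdr


@dataclass
class GeneSetCollection:
    """Named gene sets with a source tag (GO-BP/CC/MF, KEGG, custom)."""

    sets: dict
    source: str = "custom"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    @classmethod
    def from_gmt(cls, path, source: str = "custom") -> "GeneSetCollection":
        return cls(sets=read_gmt(str(path)), source=source)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                fh.write("\t".join([name, self.source, *genes]) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (chrom, start, end, name), validating
    each line; malformed lines raise with their 1-based line number."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line {lineno}: fewer than 4 fields")
            chrom, start, end, name = parts[:4]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ValueError(f"BED line {lineno}: non-integer coordinates")
            if s < 0 or e <= s:
                raise ValueError(f"BED line {lineno}: invalid interval [{s}, {e})")
            rows.append((chrom, s, e, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def snp_to_bed_coord(pos_1based: int) -> int:
    """Convert a 1-based SNP position to the 0-based BED coordinate system."""
    return int(pos_1based) - 1


def map_snps_to_genes(
    snps: pd.DataFrame, gene_intervals: pd.DataFrame, flank_kb: float = 0.0
) -> list[str]:
    """Map SNPs (columns ``chr``/``pos``, 1-based) to genes whose flanked
    BED interval contains them; returns the sorted unique gene list."""
    flank = int(round(flank_kb * 1000))
    trees: dict[str, IntervalTree] = {}
    for row in gene_intervals.itertuples():
        start = max(row.start - flank, 0)
        end = row.end + flank
        trees.setdefault(str(row.chrom), IntervalTree()).addi(start, end, row.gene)
    hits = set()
    for row in snps.itertuples():
        tree = trees.get(str(row.chr))
        if tree is None:
            continue
        for iv in tree.at(snp_to_bed_coord(row.pos)):
            hits.add(iv.data)
    return sorted(hits)


def ora(
    query: list[str], sets: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    For a term with K universe genes of which k are in the n query genes
    (universe size N): p = P(X >= k), X ~ Hypergeom(N, K, n). Terms with
    K = 0 are skipped; q is BH across the tested terms. Query genes outside
    the universe are dropped with a warning.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    outside = q - uni
    if outside:
        warnings.warn(f"{len(outside)} query genes outside universe; dropped")
        q &= uni
    N, n = len(uni), len(q)
    rows = []
    for term, genes in sets.sets.items():
        term_genes = set(genes) & uni
        K = len(term_genes)
        if K == 0:
            continue
        k = len(q & term_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["q", "p", "term"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        out["q"] = pd.Series(dtype=float)
    return out
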