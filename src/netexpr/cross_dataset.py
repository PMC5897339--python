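"""Replication across datasets and species: set overlaps and fold-change concordance.

Two network-biased gene sets drawn from a shared measured universe are
compared with the exact upper-tail hypergeometric probability of observing at
least the attained overlap. Gene-wise log2 fold changes from two datasets are
compared with Pearson correlation over the shared genes. Universe convention:
within one dataset, the measured gene universe of that dataset; across
datasets, the intersection of measured universes — echoed in every report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Hypergeometric overlap of two gene sets in a finite universe."""

    k: int  # observed overlap
    K: int  # |set A|
    n: int  # |set B|
    N: int  # universe size
    expected: float
    p_hyper: float  # P(X >= k), X ~ Hypergeometric(N, K, n)

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("overlap exceeds set sizes")
        if max(self.K, self.n) > self.N:
            raise ValueError("set sizes exceed universe")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); includes the observed k."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """Exact upper-tail hypergeometric test of two gene sets' overlap.

    Sets are intersected with the universe first; dropped genes are logged.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    dropped = len(a - universe) + len(b - universe)
    if dropped:
        logger.info("overlap_test: %d genes outside the universe dropped", dropped)
    a &= universe
    b &= universe
    k, K, n, N = len(a & b), len(a), len(b), len(universe)
    return OverlapResult(
        k=k,
        K=K,
        n=n,
        N=N,
        expected=K * n / N,
        p_hyper=hypergeom_upper_tail(k, K, n, N),
    )


@dataclass
class ConcordanceResult:
    """Pearson concordance of gene-wise log2 fold changes across datasets."""

    r: float
    p: float
    n_genes_shared: int


def foldchange_concordance(fc_a, fc_b) -> ConcordanceResult:
    """Correlate two gene -> log2FC maps over their shared genes."""
    sa = pd.Series(fc_a, dtype=float)
    sb = pd.Series(fc_b, dtype=float)
    shared = sa.index.intersection(sb.index)
    va, vb = sa.loc[shared], sb.loc[shared]
    ok = va.notna() & vb.notna()
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared genes with fold changes")
    r, p = stats.pearsonr(va[ok], vb[ok])
    return ConcordanceResult(r=float(r), p=float(p), n_genes_shared=int(ok.sum()))


def replicated_set(
    sets: list, universe=None, report: bool = False
) -> tuple[set, list[OverlapResult]]:
    """Intersection of gene sets, optionally with pairwise overlap tests."""
    if len(sets) < 2:
        raise ValueError("need >= 2 gene sets")
    sets = [set(s) for s in sets]
    intersection = reduce(lambda x, y: x & y, sets)
    overlaps: list[OverlapResult] = []
    if report:
        if universe is None:
            raise ValueError("a universe is required for the overlap report")
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlaps.append(overlap_test(sets[i], sets[j], universe))
    return intersection, overlaps


def read_gene_list(path) -> set[str]:
    """Read a newline-delimited gene list (blank lines and '#' comments skipped)."""
    with open(path) as fh:
        return {
            line.strip() for line in fh if line.strip() and not line.lstrip().startswith("#")
        }


def read_foldchange_tsv(path) -> pd.Series:
    """Read a two-column TSV ``gene<TAB>log2FC`` into a gene -> log2FC Series."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "log2FC" not in df.columns:
        raise ValueError("fold-change TSV needs columns 'gene' and 'log2FC'")
    return df.set_index("gene")["log2FC"].astype(float)
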