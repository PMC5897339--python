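"""Region x region gene co-expression and correspondence with fcMRI.

Co-expression matrices are built per donor as Spearman rank correlations of
mean-normalized expression between regions (across a chosen gene subset),
then averaged across donors on the Fisher-z scale: r values are atanh
transformed, averaged over the donors in which the pair was measured, and
tanh transformed back. Functional-connectivity matrices enter as precomputed
Pearson matrices. Correspondence between a genetic and a functional matrix is
the Pearson correlation of their vectorized unique off-diagonal pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix, ValueScale

logger = logging.getLogger(__name__)

_ATANH_CAP = 0.999999


@dataclass
class CorrelationMatrix:
    """Region x region correlations (square symmetric, or rectangular).

    ``region_ids`` index the rows; ``col_region_ids`` defaults to
    ``region_ids`` (square). NaN marks pairs measured in no donor. For square
    matrices the diagonal is 1 (or NaN where a region is absent).
    """

    values: np.ndarray
    region_ids: list[str]
    method: str = "spearman_gene_expression"
    n_donors_averaged: int = 1
    region_to_network: dict[str, str] | None = None
    col_region_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.col_region_ids is None:
            self.col_region_ids = list(self.region_ids)
        if self.values.shape != (len(self.region_ids), len(self.col_region_ids)):
            raise ValueError("values shape does not match region id lists")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.is_square:
            asym = np.nanmax(np.abs(self.values - self.values.T), initial=0.0)
            if asym > 1e-12:
                raise ValueError(f"square correlation matrix not symmetric (max dev {asym:g})")

    @property
    def is_square(self) -> bool:
        return list(self.region_ids) == list(self.col_region_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.col_region_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "CorrelationMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            list(frame.index.astype(str)),
            col_region_ids=list(frame.columns.astype(str)),
            **kwargs,
        )


@dataclass
class SeedProfile:
    """Fisher-averaged correlation of a seed-region set to every other region."""

    seed_regions: list[str]
    target_region_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.target_region_ids):
            raise ValueError("profile length must match target regions")
        if set(self.seed_regions) & set(self.target_region_ids):
            raise ValueError("seed regions must be excluded from targets")


def read_correlation_tsv(path, **kwargs) -> CorrelationMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return CorrelationMatrix.from_frame(frame, **kwargs)


def write_correlation_tsv(matrix: CorrelationMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="region")


def _fisher_mean(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """atanh -> nanmean -> tanh, with |r| capped below 1.

    Entries whose available values are all equal bypass the cap so that
    averaging identical correlations (including +-1) is an exact identity.
    """
    values = np.asarray(values, dtype=float)
    capped = np.clip(values, -_ATANH_CAP, _ATANH_CAP)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        z = np.arctanh(capped)
        mean_z = np.nanmean(z, axis=axis)
        out = np.tanh(mean_z)
        vmin = np.nanmin(values, axis=axis)
        vmax = np.nanmax(values, axis=axis)
    return np.where(vmin == vmax, vmin, out)


def region_means_by_donor(
    matrix: ExpressionMatrix,
    region_of_sample: dict[str, str],
    manifest: pd.DataFrame,
    gene_subset=None,
    min_donors_per_region: int = 2,
) -> dict[str, pd.DataFrame]:
    """Per-donor region x gene mean-expression tables.

    Regions sampled by fewer than ``min_donors_per_region`` donors are dropped
    globally (from every donor), mirroring the "samples from at least two
    donors" inclusion rule.
    """
    donor_of_sample = manifest.set_index("sample_id")["donor_id"]
    samples = [s for s in matrix.sample_ids if s in region_of_sample]
    if not samples:
        raise ValueError("no matrix samples have region labels")
    frame = matrix.values[samples].T
    if gene_subset is not None:
        genes = [g for g in gene_subset if g in frame.columns]
        if not genes:
            raise ValueError("gene subset is disjoint from the expression matrix")
        frame = frame[genes]
    frame = frame.copy()
    frame["__region"] = [region_of_sample[s] for s in samples]
    frame["__donor"] = donor_of_sample.loc[samples].to_numpy()
    donors_per_region = frame.groupby("__region")["__donor"].nunique()
    keep_regions = set(donors_per_region[donors_per_region >= min_donors_per_region].index)
    n_drop = len(donors_per_region) - len(keep_regions)
    if n_drop:
        logger.info(
            "dropping %d regions sampled in < %d donors", n_drop, min_donors_per_region
        )
    frame = frame[frame["__region"].isin(keep_regions)]
    if frame.empty:
        raise ValueError("no regions pass the minimum-donor filter")
    out = {}
    for donor, sub in frame.groupby("__donor"):
        out[str(donor)] = sub.drop(columns="__donor").groupby("__region").mean()
    return out


def region_correlation_matrix(
    matrix: ExpressionMatrix,
    region_of_sample: dict[str, str],
    manifest: pd.DataFrame,
    gene_subset=None,
    min_donors_per_region: int = 2,
    region_to_network: dict[str, str] | None = None,
) -> list[CorrelationMatrix]:
    """Per-donor region-to-region Spearman co-expression matrices.

    Expression is averaged within regions per donor, then every region pair is
    rank-correlated across the gene subset. All donors' matrices share the
    same (globally filtered) region set, with NaN rows/columns for regions a
    given donor did not sample.
    """
    if matrix.value_scale is not ValueScale.LOG2_MEAN_NORMALIZED:
        raise ValueError("co-expression expects log2 mean-normalized values")
    per_donor = region_means_by_donor(
        matrix, region_of_sample, manifest, gene_subset, min_donors_per_region
    )
    n_genes = next(iter(per_donor.values())).shape[1]
    if n_genes < 3:
        raise ValueError("need >= 3 genes for rank correlations")
    all_regions = sorted({r for df in per_donor.values() for r in df.index})
    if len(all_regions) < 2:
        raise ValueError("need >= 2 regions after filtering")
    out = []
    for donor in sorted(per_donor):
        df = per_donor[donor]
        corr = df.T.corr(method="spearman")  # regions x regions, pairwise-complete
        full = corr.reindex(index=all_regions, columns=all_regions)
        out.append(
            CorrelationMatrix(
                full.to_numpy(),
                all_regions,
                method="spearman_gene_expression",
                n_donors_averaged=1,
                region_to_network=region_to_network,
            )
        )
    return out


def fisher_average(matrices: list[CorrelationMatrix]) -> CorrelationMatrix:
    """Average correlation matrices across donors on the Fisher-z scale."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if list(m.region_ids) != list(first.region_ids) or list(m.col_region_ids) != list(
            first.col_region_ids
        ):
            raise ValueError("matrices must share identical region ids and ordering")
    stack = np.stack([m.values for m in matrices])
    avg = _fisher_mean(stack, axis=0)
    if first.is_square:
        avg = (avg + avg.T) / 2.0  # enforce exact symmetry against fp jitter
    return CorrelationMatrix(
        avg,
        list(first.region_ids),
        method=first.method,
        n_donors_averaged=sum(m.n_donors_averaged for m in matrices),
        region_to_network=first.region_to_network,
        col_region_ids=list(first.col_region_ids),
    )


@dataclass
class CorrespondenceResult:
    r: float
    p: float
    n_pairs: int


def matrix_correspondence(a, b) -> CorrespondenceResult:
    """Pearson correlation between two matrices' unique off-diagonal pairs.

    Square matrices are intersected on their common region set (mismatches
    logged), aligned, and vectorized over the upper triangle; rectangular
    matrices and seed profiles are aligned cell-by-cell. Accepts
    :class:`CorrelationMatrix` or :class:`SeedProfile` arguments.
    """
    va, vb = _aligned_vectors(a, b)
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 common finite pairs")
    r, p = stats.pearsonr(va[ok], vb[ok])
    return CorrespondenceResult(r=float(r), p=float(p), n_pairs=int(ok.sum()))


def _aligned_vectors(a, b) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, SeedProfile) and isinstance(b, SeedProfile):
        common = [r for r in a.target_region_ids if r in set(b.target_region_ids)]
        if len(common) < len(a.target_region_ids) or len(common) < len(b.target_region_ids):
            logger.info("seed profiles intersected to %d common regions", len(common))
        ia = {r: i for i, r in enumerate(a.target_region_ids)}
        ib = {r: i for i, r in enumerate(b.target_region_ids)}
        return (
            np.array([a.values[ia[r]] for r in common]),
            np.array([b.values[ib[r]] for r in common]),
        )
    if not (isinstance(a, CorrelationMatrix) and isinstance(b, CorrelationMatrix)):
        raise TypeError("matrix_correspondence takes two CorrelationMatrix or two SeedProfile")
    if a.is_square and b.is_square:
        common = [r for r in a.region_ids if r in set(b.region_ids)]
        if len(common) < 3:
            raise ValueError("fewer than 3 common regions")
        if len(common) < max(len(a.region_ids), len(b.region_ids)):
            logger.info("matrices intersected to %d common regions", len(common))
        fa = a.to_frame().loc[common, common].to_numpy()
        fb = b.to_frame().loc[common, common].to_numpy()
        iu = np.triu_indices(len(common), k=1)
        return fa[iu], fb[iu]
    # rectangular: align both axes and compare every cell
    rows = [r for r in a.region_ids if r in set(b.region_ids)]
    cols = [c for c in a.col_region_ids if c in set(b.col_region_ids)]
    if not rows or not cols:
        raise ValueError("no common regions between rectangular matrices")
    fa = a.to_frame().loc[rows, cols].to_numpy()
    fb = b.to_frame().loc[rows, cols].to_numpy()
    return fa.ravel(), fb.ravel()


def seed_profile(matrix: CorrelationMatrix, seeds) -> SeedProfile:
    """Fisher-averaged correlation of a seed set to every non-seed region."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("empty seed set")
    missing = set(seeds) - set(matrix.region_ids)
    if missing:
        raise ValueError(f"seed regions not in matrix: {sorted(missing)}")
    frame = matrix.to_frame()
    targets = [r for r in matrix.col_region_ids if r not in set(seeds)]
    block = frame.loc[seeds, targets].to_numpy()
    values = _fisher_mean(block, axis=0)
    return SeedProfile(seed_regions=seeds, target_region_ids=targets, values=values)


def within_between_summary(matrix: CorrelationMatrix) -> pd.DataFrame:
    """Mean co-expression within each network and between network pairs.

    Returns a network x network DataFrame whose diagonal holds the
    Fisher-averaged mean over unique within-network pairs (NaN for
    single-region networks) and whose off-diagonal cells hold the mean over
    the corresponding cross-network block.
    """
    if not matrix.is_square:
        raise ValueError("within/between summary requires a square matrix")
    if matrix.region_to_network is None:
        raise ValueError("region_to_network mapping required")
    missing = [r for r in matrix.region_ids if r not in matrix.region_to_network]
    if missing:
        raise ValueError(f"regions without network labels: {missing[:5]}")
    nets = sorted({matrix.region_to_network[r] for r in matrix.region_ids})
    idx_of_net = {
        n: [i for i, r in enumerate(matrix.region_ids) if matrix.region_to_network[r] == n]
        for n in nets
    }
    out = pd.DataFrame(np.nan, index=nets, columns=nets)
    vals = matrix.values
    for i, na in enumerate(nets):
        ia = idx_of_net[na]
        if len(ia) >= 2:
            block = vals[np.ix_(ia, ia)]
            iu = np.triu_indices(len(ia), k=1)
            out.loc[na, na] = float(_fisher_mean(block[iu]))
        for nb in nets[i + 1 :]:
            ib = idx_of_net[nb]
            block = vals[np.ix_(ia, ib)].ravel()
            m = float(_fisher_mean(block))
            out.loc[na, nb] = m
            out.loc[nb, na] = m
    return out


def striatal_cortical_profile(
    striatal_expr: dict[str, pd.DataFrame],
    cortical_expr: dict[str, pd.DataFrame],
    gene_subset=None,
) -> CorrelationMatrix:
    """Rectangular striatal-region x cortical-region co-expression profile.

    Inputs are per-donor region x gene mean-expression tables (as produced by
    :func:`region_means_by_donor`, with cortex and striatum mean-normalized
    separately beforehand). Per donor, every striatal/cortical region pair is
    Spearman-correlated across the gene subset; donor matrices are then
    Fisher-averaged.
    """
    donors = sorted(set(striatal_expr) & set(cortical_expr))
    if not donors:
        raise ValueError("no donors shared between striatal and cortical tables")
    striatal_regions = sorted({r for d in donors for r in striatal_expr[d].index})
    cortical_regions = sorted({r for d in donors for r in cortical_expr[d].index})
    per_donor = []
    for donor in donors:
        s_df, c_df = striatal_expr[donor], cortical_expr[donor]
        genes = s_df.columns.intersection(c_df.columns)
        if gene_subset is not None:
            genes = genes.intersection(pd.Index(gene_subset))
        if len(genes) < 3:
            raise ValueError(f"donor {donor}: fewer than 3 shared genes")
        combined = pd.concat([s_df[genes], c_df[genes]], keys=["s", "c"])
        corr = combined.T.corr(method="spearman")
        block = corr.loc["s", "c"]
        block = block.reindex(index=striatal_regions, columns=cortical_regions)
        per_donor.append(
            CorrelationMatrix(
                block.to_numpy(),
                striatal_regions,
                method="spearman_gene_expression",
                col_region_ids=cortical_regions,
            )
        )
    return fisher_average(per_donor)
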