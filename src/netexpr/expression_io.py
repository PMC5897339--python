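"""Expression-matrix handling: probe collapsing, log2 transform, compartment-wise
mean normalization, and homolog mapping.

The in-memory container is :class:`ExpressionMatrix`, a genes (or probes) x
samples table with an explicit value-scale state machine:

    linear -> log2 -> log2_mean_normalized

Microarray and RNA-seq inputs arrive probe-level; :func:`collapse_probes`
reduces them to one row per gene using the connectivity criterion (for genes
with three or more probes, keep the probe with the largest summed pairwise
Pearson correlation to its sibling probes) and the max-mean rule otherwise.
Because global transcription differs markedly between cortex and striatum,
:func:`mean_normalize` centers each gene separately within each compartment.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("cortex", "striatum")


class ValueScale(str, enum.Enum):
    """Where a matrix sits in the linear -> log2 -> centered pipeline."""

    LINEAR = "linear"
    LOG2 = "log2"
    LOG2_MEAN_NORMALIZED = "log2_mean_normalized"


_SCALE_ORDER = {
    ValueScale.LINEAR: 0,
    ValueScale.LOG2: 1,
    ValueScale.LOG2_MEAN_NORMALIZED: 2,
}


@dataclass
class ExpressionMatrix:
    """Genes (or probes) x samples expression values.

    Parameters
    ----------
    values
        DataFrame with row ids (genes or probes) as index and sample ids as
        columns. NaN marks missing measurements; infinities are rejected.
    value_scale
        Current scale of ``values``.
    """

    values: pd.DataFrame
    value_scale: ValueScale = ValueScale.LINEAR

    def __post_init__(self) -> None:
        self.value_scale = ValueScale(self.value_scale)
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite (NaN allowed for missing)")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def _advanced(self, new_scale: ValueScale) -> None:
        if _SCALE_ORDER[new_scale] <= _SCALE_ORDER[self.value_scale]:
            raise ValueError(
                f"value_scale may only advance linear->log2->log2_mean_normalized; "
                f"got {self.value_scale.value} -> {new_scale.value}"
            )


def read_expression_tsv(path, value_scale: ValueScale | str = ValueScale.LOG2) -> ExpressionMatrix:
    """Read a TSV whose first column holds row ids and remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, ValueScale(value_scale))


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="row_id")


def read_probe_map(path) -> pd.DataFrame:
    """Read a probe->gene TSV with columns ``probe_id`` and ``gene_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_probe_map(df)


def validate_probe_map(probe_map: pd.DataFrame) -> pd.DataFrame:
    missing = {"probe_id", "gene_id"} - set(probe_map.columns)
    if missing:
        raise ValueError(f"probe map missing columns: {sorted(missing)}")
    if probe_map["probe_id"].duplicated().any():
        dups = probe_map.loc[probe_map["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe ids in probe map: {dups[:5]}")
    return probe_map


def collapse_probes(matrix: ExpressionMatrix, probe_map: pd.DataFrame) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene.

    For genes with >= 3 probes the probe with the maximum summed adjacency is
    retained, where adjacency of a probe is the sum of its pairwise Pearson
    correlations (across samples, pairwise-complete) with the gene's other
    probes; a zero-variance probe contributes adjacency 0. For genes with one
    or two probes the probe with the highest mean expression is kept. Ties are
    broken toward the lexicographically smallest probe id, which also makes the
    selection invariant to probe row order.
    """
    if matrix.n_samples < 2:
        raise ValueError("collapse_probes requires at least 2 samples")
    probe_map = validate_probe_map(probe_map)
    mapped = probe_map.set_index("probe_id")["gene_id"]
    present = [p for p in matrix.row_ids if p in mapped.index]
    absent = set(matrix.row_ids) - set(present)
    if absent:
        raise ValueError(
            f"{len(absent)} matrix probes missing from probe map, e.g. {sorted(absent)[:5]}"
        )

    chosen: dict[str, str] = {}
    dropped = 0
    for gene, group in mapped.loc[present].groupby(mapped.loc[present]):
        probes = sorted(group.index)
        if len(probes) == 0:
            dropped += 1
            continue
        if len(probes) <= 2:
            means = matrix.values.loc[probes].mean(axis=1, skipna=True)
            best = means.sort_index().idxmax()  # ties -> lexicographically smallest
        else:
            sub = matrix.values.loc[probes]
            corr = sub.T.corr(method="pearson")  # pairwise-complete
            corr = corr.fillna(0.0)  # constant probes: adjacency terms 0
            np.fill_diagonal(corr.values, 0.0)
            adjacency = corr.sum(axis=1)
            best = adjacency.sort_index().idxmax()
        chosen[gene] = best
    if dropped:
        logger.warning("collapse_probes: dropped %d genes with zero probes", dropped)
    genes = sorted(chosen)
    out = matrix.values.loc[[chosen[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene_id")
    return ExpressionMatrix(out, matrix.value_scale)


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount) on a linear-scale matrix."""
    if matrix.value_scale is not ValueScale.LINEAR:
        raise ValueError(f"log2_transform requires linear scale, got {matrix.value_scale.value}")
    arr = matrix.values.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("log2_transform requires nonnegative values")
    out = np.log2(arr + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        ValueScale.LOG2,
    )


def mean_normalize(
    matrix: ExpressionMatrix,
    manifest: pd.DataFrame,
    method: str = "center_log2",
) -> ExpressionMatrix:
    """Mean-normalize each gene separately within each compartment.

    The default (and recommended) method subtracts the per-gene mean over each
    compartment's samples on the log2 scale, so per-gene per-compartment means
    of the output are exactly 0. ``method="divide_linear"`` instead divides by
    the per-gene compartment mean of the linearized values and returns
    log2 of the ratio.
    """
    if matrix.value_scale is not ValueScale.LOG2:
        raise ValueError(f"mean_normalize requires log2 scale, got {matrix.value_scale.value}")
    comp = manifest.set_index("sample_id")["compartment"]
    missing = [s for s in matrix.sample_ids if s not in comp.index]
    if missing:
        raise ValueError(f"samples missing from manifest: {missing[:5]}")
    out = matrix.values.copy()
    for compartment in pd.unique(comp.loc[matrix.sample_ids]):
        cols = [s for s in matrix.sample_ids if comp[s] == compartment]
        if not cols:
            continue
        block = out[cols]
        if method == "center_log2":
            out[cols] = block.sub(block.mean(axis=1, skipna=True), axis=0)
        elif method == "divide_linear":
            lin = np.power(2.0, block)
            out[cols] = np.log2(lin.div(lin.mean(axis=1, skipna=True), axis=0))
        else:
            raise ValueError(f"unknown mean_normalize method: {method!r}")
    return ExpressionMatrix(out, ValueScale.LOG2_MEAN_NORMALIZED)


def read_homolog_table(path) -> pd.DataFrame:
    """Read a two-column homolog TSV (``gene_a``, ``gene_b``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_homolog_table(df)


def validate_homolog_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = {"gene_a", "gene_b"} - set(table.columns)
    if missing:
        raise ValueError(f"homolog table missing columns: {sorted(missing)}")
    for col in ("gene_a", "gene_b"):
        if table[col].duplicated().any():
            dups = table.loc[table[col].duplicated(), col].tolist()
            raise ValueError(f"homolog table not one-to-one in {col}: {dups[:5]}")
    return table


def map_homologs(
    matrix: ExpressionMatrix, table: pd.DataFrame, direction: str = "a_to_b"
) -> ExpressionMatrix:
    """Restrict rows to mapped genes and rename them to the other species' ids.

    ``direction`` is ``"a_to_b"`` (row ids are gene_a, renamed to gene_b) or
    ``"b_to_a"``. Unmapped rows are dropped with a logged count; an empty
    intersection is an error rather than an empty matrix.
    """
    table = validate_homolog_table(table)
    if direction == "a_to_b":
        mapping = table.set_index("gene_a")["gene_b"]
    elif direction == "b_to_a":
        mapping = table.set_index("gene_b")["gene_a"]
    else:
        raise ValueError(f"direction must be 'a_to_b' or 'b_to_a', got {direction!r}")
    keep = [g for g in matrix.row_ids if g in mapping.index]
    if not keep:
        raise ValueError("no matrix genes found in the homolog table")
    n_dropped = matrix.n_rows - len(keep)
    if n_dropped:
        logger.info("map_homologs: dropped %d unmapped genes", n_dropped)
    out = matrix.values.loc[keep].copy()
    new_ids = mapping.loc[keep]
    if new_ids.duplicated().any():
        raise ValueError("duplicate target gene ids after homolog mapping")
    out.index = pd.Index(new_ids.to_numpy(), name="gene_id")
    return ExpressionMatrix(out, matrix.value_scale)
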