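"""Cell-type enrichment, annotation enrichment, and laminar contrasts.

A gene is called enriched in a cell type when its expression in the
top-ranked cell type exceeds the second-ranked one by more than a log2
fold-change threshold (default 1.5), the rule used to score network-biased
genes against cortical single-cell profiles. Annotation gene-set enrichment
is the standard hypergeometric overlap with BH correction across sets.
Laminar contrasts compare superficial (layers 2/3) with deep (layers 5/6)
cortical expression through the same moderated one-vs-rest machinery used for
networks, flagging deep-biased genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import network_de
from .cross_dataset import overlap_test
from .expression_io import ExpressionMatrix
from .network_de import BlockingSpec, NetworkExpression, bh_adjust, fit_network_ovr

logger = logging.getLogger(__name__)

SUPERFICIAL_LAYERS = (2, 3)
DEEP_LAYERS = (5, 6)


def validate_celltype_profile(profile: pd.DataFrame) -> pd.DataFrame:
    """Genes x cell-types matrix of nonnegative linear-scale expression."""
    if profile.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    arr = profile.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("cell-type expression must be nonnegative (linear scale)")
    if profile.index.has_duplicates:
        raise ValueError("duplicate gene ids in cell-type profile")
    return profile


@dataclass
class CellTypeEnrichment:
    calls: pd.DataFrame  # gene, enriched_cell_type (None), log2_fc_top_vs_second, all_zero
    counts: pd.Series  # genes enriched per cell type
    fraction_enriched: float


def celltype_enrichment(
    profile: pd.DataFrame, threshold: float = 1.5, pseudocount: float = 0.01
) -> CellTypeEnrichment:
    """Call per-gene cell-type enrichment by the top-vs-second ratio rule.

    Per gene the two highest-expressing cell types are compared:
    log2((top + pseudocount) / (second + pseudocount)). The top type is called
    iff the ratio strictly exceeds ``threshold``; ties give ratio 0 and no
    call, as do all-zero genes (flagged).
    """
    profile = validate_celltype_profile(profile)
    arr = profile.to_numpy(dtype=float)
    order = np.argsort(arr, axis=1)
    top_idx = order[:, -1]
    rows = np.arange(arr.shape[0])
    top = arr[rows, top_idx]
    second = arr[rows, order[:, -2]]
    log2fc = np.log2((top + pseudocount) / (second + pseudocount))
    all_zero = np.nanmax(arr, axis=1) == 0
    enriched = (log2fc > threshold) & ~all_zero
    cell_types = np.asarray(profile.columns)
    calls = pd.DataFrame(
        {
            "gene": profile.index,
            "enriched_cell_type": np.where(enriched, cell_types[top_idx], None),
            "log2_fc_top_vs_second": log2fc,
            "all_zero": all_zero,
        }
    )
    counts = (
        calls.dropna(subset=["enriched_cell_type"])["enriched_cell_type"]
        .value_counts()
        .reindex(profile.columns, fill_value=0)
    )
    return CellTypeEnrichment(
        calls=calls,
        counts=counts,
        fraction_enriched=float(enriched.mean()),
    )


def read_gmt(path) -> dict[str, set[str]]:
    """Read annotation gene sets from a GMT file."""
    from gseapy.parser import read_gmt as _read_gmt

    return {name: set(genes) for name, genes in _read_gmt(str(path)).items()}


def annotate_enrichment(
    query, annotations: dict[str, set], universe
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query set against named annotation sets.

    One overlap test per annotation set, BH-corrected across sets; rows sorted
    by p (ties keep the annotation-name order stable).
    """
    if not annotations:
        raise ValueError("empty annotation collection")
    universe = set(universe)
    rows = []
    for name in sorted(annotations):
        res = overlap_test(annotations[name], query, universe)
        rows.append(
            {
                "set": name,
                "k": res.k,
                "K": res.K,
                "n": res.n,
                "N": res.N,
                "p": res.p_hyper,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


@dataclass
class LaminarResult:
    de_table: pd.DataFrame  # moderated DE, deep (5/6) vs superficial (2/3)
    deep_biased: set  # genes of the query set biased toward deep layers
    gene_means: pd.DataFrame  # per-gene mean expression by layer group


def laminar_contrast(
    layer_expr: ExpressionMatrix,
    layer_of_sample: dict[str, int],
    manifest: pd.DataFrame,
    gene_set=None,
    q_max: float = 0.05,
    blocking: BlockingSpec | None = None,
) -> LaminarResult:
    """Deep (5/6) vs superficial (2/3) laminar differential expression.

    Samples are grouped by layer into superficial (2, 3) and deep (5, 6)
    pseudo-networks, averaged per donor and group, and contrasted with the
    moderated one-vs-rest fit (target = deep, so positive log2FC means
    deep-biased). ``gene_set`` restricts the reported deep-biased genes.
    """
    group_of = {}
    for s, layer in layer_of_sample.items():
        if layer in SUPERFICIAL_LAYERS:
            group_of[s] = "superficial"
        elif layer in DEEP_LAYERS:
            group_of[s] = "deep"
        else:
            raise ValueError(f"sample {s}: layer {layer} not in {{2,3,5,6}}")
    samples = [s for s in layer_expr.sample_ids if s in group_of]
    if not samples:
        raise ValueError("no matrix samples have layer labels")
    groups = pd.Series({s: group_of[s] for s in samples})
    for grp in ("superficial", "deep"):
        if (groups == grp).sum() < 2:
            raise ValueError(f"need >= 2 samples in the {grp} layer group")
    donor_of = manifest.set_index("sample_id")["donor_id"]
    frame = layer_expr.values[samples].T
    frame.index = pd.MultiIndex.from_arrays(
        [donor_of.loc[samples].to_numpy(), groups.loc[samples].to_numpy()],
        names=["donor", "network"],
    )
    means = frame.groupby(level=["donor", "network"]).mean()
    counts = (
        means.reset_index().groupby(["donor", "network"]).size().unstack(fill_value=0)
    )
    nexpr = NetworkExpression(means, counts)
    de = fit_network_ovr(nexpr, target="deep", blocking=blocking or BlockingSpec())
    if gene_set is not None:
        in_set = de["gene"].isin(set(gene_set))
        if not in_set.any():
            raise ValueError("gene set is disjoint from the expression matrix")
    else:
        in_set = pd.Series(True, index=de.index)
    deep = set(de.loc[in_set & (de["q"] <= q_max) & (de["log2FC"] > 0), "gene"])
    gene_means = means.groupby(level="network").mean().T
    return LaminarResult(de_table=de, deep_biased=deep, gene_means=gene_means)
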