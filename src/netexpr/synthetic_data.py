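"""Synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a
small volumetric label atlas of rectangular parcels grouped into functional
networks; multi-donor log2 expression in which a planted subset of genes is
shifted upward within one network (and compartment), donors carry
gene-specific random effects inducing intra-donor correlation, and the
striatal compartment sits at a global offset from cortex; optional redundant
probes per gene; and block-structured functional-connectivity matrices
sampled from a compound-symmetric population correlation.

Default parameters mirror the study conditions the pipeline is designed for:
6 donors, 2000 genes, a planted log2 effect of 1.0 against residual SD 0.5
and donor SD 0.25, and 10% of genes planted per network. All draws come from
a single seeded generator, so a fixed seed reproduces every output bit for
bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas_assignment import ParcellationAtlas
from .coexpression import CorrelationMatrix
from .expression_io import ExpressionMatrix, ValueScale

logger = logging.getLogger(__name__)

CORTICAL_NETWORKS = (
    "control",
    "default",
    "dorsal_attention",
    "limbic",
    "somato_motor",
    "ventral_attention",
    "visual",
)
# visual and dorsal attention are minimally represented in striatum
STRIATAL_NETWORKS = ("control", "default", "limbic", "somato_motor", "ventral_attention")


@dataclass
class NetworkSpec:
    """One functional network: how many parcels and samples per parcel."""

    name: str
    n_parcels: int = 3
    samples_per_parcel: int = 2


def _coerce_networks(specs) -> list[NetworkSpec]:
    out = []
    for s in specs:
        out.append(s if isinstance(s, NetworkSpec) else NetworkSpec(*s))
    return out


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    ``planted_fraction`` is the fraction of genes planted per network (drawn
    disjointly within a compartment); ``effect_size_log2`` the planted shift;
    ``shared_planted_fraction`` forces that share of each striatal network's
    planted genes to coincide with the same cortical network's planted genes
    (emulating genes biased in both compartments of a network).
    ``probe_multiplicity`` maps probe counts to probabilities (None disables
    probe expansion). ``fc_within_rho``/``fc_between_rho`` set the population
    correlation blocks of the simulated functional-connectivity matrix.
    """

    n_genes: int = 2000
    n_donors: int = 6
    networks: list = field(
        default_factory=lambda: [NetworkSpec(n, 3, 2) for n in CORTICAL_NETWORKS]
    )
    striatal_networks: list = field(
        default_factory=lambda: [NetworkSpec(n, 2, 2) for n in STRIATAL_NETWORKS]
    )
    planted_fraction: float = 0.10
    effect_size_log2: float = 1.0
    donor_sd: float = 0.25
    residual_sd: float = 0.5
    compartment_shift: float = 5.0
    baseline_log2: float = 8.0
    shared_planted_fraction: float = 0.0
    probe_multiplicity: dict[int, float] | None = None
    probe_noise_sd: float = 0.1
    fc_within_rho: float = 0.6
    fc_between_rho: float = 0.1
    fc_n_subjects: int = 1000
    volume_shape: tuple[int, int, int] = (40, 40, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        self.networks = _coerce_networks(self.networks)
        self.striatal_networks = _coerce_networks(self.striatal_networks)
        if self.n_genes <= 0 or self.n_donors <= 0:
            raise ValueError("need at least one gene and one donor")
        for sd in (self.donor_sd, self.residual_sd, self.probe_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for frac in (self.planted_fraction, self.shared_planted_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for rho in (self.fc_within_rho, self.fc_between_rho):
            if not abs(rho) < 1:
                raise ValueError("|rho| must be < 1")
        for nets in (self.networks, self.striatal_networks):
            if len(nets) * self.planted_fraction > 1 + 1e-9:
                raise ValueError("planted fractions exceed the gene universe")

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def donors(self) -> list[str]:
        return [f"donor{i + 1}" for i in range(self.n_donors)]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic data."""

    planted: dict[tuple[str, str], set[str]]  # (compartment, network) -> genes
    sample_labels: pd.DataFrame  # sample_id, compartment, network, parcel
    probe_map: pd.DataFrame | None = None

    def planted_for(self, compartment: str, network: str) -> set[str]:
        return self.planted.get((compartment, network), set())


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

_PARCEL_SIDE = 3
_PARCEL_SPACING = 6


def make_atlas(
    config: SimulationConfig, compartment: str = "cortex"
) -> tuple[ParcellationAtlas, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Build a label volume of disjoint rectangular parcels (identity affine).

    Parcels are 3-voxel cubes laid out on a grid with 6-voxel spacing, labeled
    1..P in network order; background is 0. Returns the atlas plus the true
    parcel geometry as inclusive (lo, hi) voxel bounds per parcel.
    """
    nets = config.networks if compartment == "cortex" else config.striatal_networks
    shape = tuple(config.volume_shape)
    slots_per_axis = max((min(shape) - 1) // _PARCEL_SPACING, 1)
    n_parcels = sum(n.n_parcels for n in nets)
    if n_parcels > slots_per_axis**3:
        raise ValueError(
            f"{n_parcels} parcels do not fit a {shape} volume at spacing {_PARCEL_SPACING}"
        )
    volume = np.zeros(shape, dtype=np.int32)
    label_to_parcel: dict[int, str] = {}
    parcel_to_network: dict[str, str] = {}
    geometry: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    label = 0
    slot = 0
    for net in nets:
        for j in range(net.n_parcels):
            label += 1
            parcel = f"{net.name}_p{j + 1}"
            i0 = slot % slots_per_axis
            i1 = (slot // slots_per_axis) % slots_per_axis
            i2 = slot // slots_per_axis**2
            lo = np.array([i0, i1, i2]) * _PARCEL_SPACING + 1
            hi = lo + _PARCEL_SIDE - 1
            volume[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = label
            label_to_parcel[label] = parcel
            parcel_to_network[parcel] = net.name
            geometry[parcel] = (lo, hi)
            slot += 1
    atlas = ParcellationAtlas(volume, np.eye(4), label_to_parcel, parcel_to_network)
    return atlas, geometry


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def _plant_gene_sets(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[tuple[str, str], set[str]]:
    genes = np.array(config.genes)
    n_per_net = int(round(config.planted_fraction * config.n_genes))
    planted: dict[tuple[str, str], set[str]] = {}

    # cortex: disjoint consecutive chunks of a shuffled gene order
    shuffled = rng.permutation(genes)
    pos = 0
    for net in config.networks:
        planted[("cortex", net.name)] = set(shuffled[pos : pos + n_per_net])
        pos += n_per_net

    # striatum: independently drawn, optionally sharing genes with the same
    # cortical network to emulate cross-compartment network-biased genes
    available = list(rng.permutation(genes))
    used: set[str] = set()
    for net in config.striatal_networks:
        n_shared = int(round(config.shared_planted_fraction * n_per_net))
        chosen: set[str] = set()
        cortical = sorted(planted.get(("cortex", net.name), set()) - used)
        if n_shared and cortical:
            take = min(n_shared, len(cortical))
            chosen.update(rng.choice(cortical, size=take, replace=False))
        for g in available:
            if len(chosen) >= n_per_net:
                break
            if g not in used and g not in chosen:
                chosen.add(g)
        planted[("striatum", net.name)] = chosen
        used |= chosen
    return planted


def make_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate the multi-donor expression matrix, manifest and ground truth.

    Each log2 value is baseline + effect_size * planted(gene; network,
    compartment) + donor effect (gene-specific, SD donor_sd) +
    compartment_shift (striatum only) + Normal(0, residual_sd). Samples are
    positioned at voxels inside their parcel's geometry so the atlas
    round-trips through the assignment stage. If ``probe_multiplicity`` is
    set, genes are expanded into 1-4 probes with per-probe bias and noise and
    the returned matrix is probe-level (gene truth in ``truth.probe_map``).
    """
    rng = np.random.default_rng(config.seed)
    planted = _plant_gene_sets(config, rng)
    genes = config.genes
    gene_index = {g: i for i, g in enumerate(genes)}

    geometries = {
        "cortex": make_atlas(config, "cortex")[1],
        "striatum": make_atlas(config, "striatum")[1],
    }
    network_lists = {"cortex": config.networks, "striatum": config.striatal_networks}

    records = []
    for donor in config.donors:
        for compartment in ("cortex", "striatum"):
            for net in network_lists[compartment]:
                for j in range(net.n_parcels):
                    parcel = f"{net.name}_p{j + 1}"
                    lo, hi = geometries[compartment][parcel]
                    for k in range(net.samples_per_parcel):
                        voxel = rng.integers(lo, hi + 1)
                        records.append(
                            {
                                "sample_id": f"{donor}_{compartment[:3]}_{parcel}_s{k + 1}",
                                "donor_id": donor,
                                "compartment": compartment,
                                "network": net.name,
                                "parcel": parcel,
                                "mni_x": float(voxel[0]),
                                "mni_y": float(voxel[1]),
                                "mni_z": float(voxel[2]),
                            }
                        )
    labels = pd.DataFrame(records)
    n_samples = len(labels)

    donor_effects = rng.normal(0.0, config.donor_sd, size=(config.n_donors, config.n_genes))
    donor_idx = {d: i for i, d in enumerate(config.donors)}

    values = np.full((config.n_genes, n_samples), config.baseline_log2)
    for col, rec in enumerate(labels.itertuples(index=False)):
        values[:, col] += donor_effects[donor_idx[rec.donor_id]]
        if rec.compartment == "striatum":
            values[:, col] += config.compartment_shift
        planted_here = planted.get((rec.compartment, rec.network), set())
        if planted_here:
            idx = [gene_index[g] for g in planted_here]
            values[idx, col] += config.effect_size_log2
    values += rng.normal(0.0, config.residual_sd, size=values.shape)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=labels["sample_id"]), ValueScale.LOG2
    )
    manifest = labels[["sample_id", "donor_id", "compartment", "mni_x", "mni_y", "mni_z"]].copy()
    truth = SyntheticTruth(
        planted=planted,
        sample_labels=labels[["sample_id", "compartment", "network", "parcel"]].copy(),
    )

    if config.probe_multiplicity:
        matrix, probe_map = _expand_probes(matrix, config, rng)
        truth.probe_map = probe_map
    return matrix, manifest, truth


def _expand_probes(
    matrix: ExpressionMatrix, config: SimulationConfig, rng: np.random.Generator
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    counts = sorted(config.probe_multiplicity)
    probs = np.array([config.probe_multiplicity[c] for c in counts], dtype=float)
    probs /= probs.sum()
    rows = []
    index = []
    mapping = []
    for gene in matrix.row_ids:
        k = int(rng.choice(counts, p=probs))
        base = matrix.values.loc[gene].to_numpy()
        for j in range(k):
            probe = f"{gene}_pr{j + 1}"
            bias = rng.normal(0.0, 0.2)
            noise = rng.normal(0.0, config.probe_noise_sd, size=base.shape)
            rows.append(base + bias + noise)
            index.append(probe)
            mapping.append({"probe_id": probe, "gene_id": gene})
    probe_values = pd.DataFrame(np.vstack(rows), index=index, columns=matrix.sample_ids)
    return (
        ExpressionMatrix(probe_values, matrix.value_scale),
        pd.DataFrame(mapping),
    )


# ---------------------------------------------------------------------------
# Functional connectivity
# ---------------------------------------------------------------------------


def make_fc_matrix(
    config: SimulationConfig,
    regions: list[str],
    network_of_region: dict[str, str],
) -> CorrelationMatrix:
    """Sample a block-structured functional-connectivity matrix.

    The population correlation is ``fc_within_rho`` between regions of the
    same network and ``fc_between_rho`` otherwise; the output is the sample
    Pearson correlation over ``fc_n_subjects`` simulated region signals, so it
    is positive semidefinite by construction.
    """
    if abs(config.fc_between_rho) > abs(config.fc_within_rho):
        raise ValueError("|fc_between_rho| must not exceed |fc_within_rho|")
    nets = np.array([network_of_region[r] for r in regions])
    same = nets[:, None] == nets[None, :]
    sigma = np.where(same, config.fc_within_rho, config.fc_between_rho)
    np.fill_diagonal(sigma, 1.0)
    eigmin = float(np.linalg.eigvalsh(sigma).min())
    if eigmin < -1e-10:
        raise ValueError(f"population correlation matrix is not PSD (min eig {eigmin:g})")
    rng = np.random.default_rng([config.seed, 202])
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(len(regions)))
    signals = rng.standard_normal((config.fc_n_subjects, len(regions))) @ chol.T
    corr = np.corrcoef(signals, rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(
        corr,
        list(regions),
        method="pearson_fcmri",
        n_donors_averaged=1,
        region_to_network=dict(network_of_region),
    )


# ---------------------------------------------------------------------------
# Truth scoring
# ---------------------------------------------------------------------------


def truth_report(
    truth: SyntheticTruth,
    de_sets: dict[str, set],
    compartment: str = "cortex",
    universe=None,
) -> pd.DataFrame:
    """Confusion-matrix summary of recovered gene sets against planted truth.

    Per network: sensitivity = TP / planted, specificity = TN / not-planted,
    observed FDR = FP / called (0 when nothing is called).
    """
    if universe is None:
        universe = set().union(*truth.planted.values()) if truth.planted else set()
        universe = set(universe) | {g for s in de_sets.values() for g in s}
    universe = set(universe)
    rows = []
    for network, called in sorted(de_sets.items()):
        called = set(called) & universe
        planted = truth.planted_for(compartment, network) & universe
        tp = len(called & planted)
        fp = len(called - planted)
        fn = len(planted - called)
        tn = len(universe) - tp - fp - fn
        rows.append(
            {
                "network": network,
                "n_called": len(called),
                "n_planted": len(planted),
                "sensitivity": tp / len(planted) if planted else np.nan,
                "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
                "fdr": fp / len(called) if called else 0.0,
            }
        )
    return pd.DataFrame(rows)
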