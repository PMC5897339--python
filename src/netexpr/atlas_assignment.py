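"""Assign post-mortem tissue samples to functional parcellations.

Each tissue sample carries an MNI coordinate (mm). Assignment proceeds by the
expanding-ROI rule: a 1-voxel region of interest at the coordinate is tested
first; if it lies on atlas background, the ROI is grown to a 2-voxel and then a
3-voxel cube, and the functional network with the most overlapping labeled
voxels in the first non-empty cube wins. Samples whose 3-voxel cube is still
all background are omitted from further analysis.

Cube placement (the atlases are nominally 1 mm isotropic, so cube sides are in
voxels): the side-1 ROI is the voxel containing the continuous coordinate; the
side-2 cube is the 2x2x2 block of voxels nearest the continuous coordinate
(extending toward the coordinate's octant, ties toward negative indices); the
side-3 cube is centered on the side-1 voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("sample_id", "donor_id", "compartment", "mni_x", "mni_y", "mni_z")


@dataclass
class ParcellationAtlas:
    """Integer label volume in MNI space plus label -> parcel -> network maps.

    ``label_volume`` uses 0 for background. ``affine`` maps voxel indices
    (i, j, k, 1) to MNI mm (voxel centers). Every nonzero label present in the
    volume must appear in ``label_to_parcel`` and every parcel must map to
    exactly one network.
    """

    label_volume: np.ndarray
    affine: np.ndarray
    label_to_parcel: dict[int, str]
    parcel_to_network: dict[str, str]

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            as_int = self.label_volume.astype(np.int64)
            if not np.array_equal(as_int, self.label_volume):
                raise ValueError("label volume must contain integers")
            self.label_volume = as_int
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        present = set(np.unique(self.label_volume).tolist()) - {0}
        unmapped = present - set(self.label_to_parcel)
        if unmapped:
            raise ValueError(f"volume labels missing from mapping: {sorted(unmapped)}")
        for label, parcel in self.label_to_parcel.items():
            if parcel not in self.parcel_to_network:
                raise ValueError(f"parcel {parcel!r} (label {label}) has no network")

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        sizes = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        return tuple(float(s) for s in sizes)

    @property
    def label_to_network(self) -> dict[int, str]:
        return {lab: self.parcel_to_network[p] for lab, p in self.label_to_parcel.items()}

    def mni_to_voxel(self, coord) -> np.ndarray:
        """Continuous voxel coordinate of an MNI mm coordinate."""
        xyz1 = np.append(np.asarray(coord, dtype=float), 1.0)
        return (np.linalg.inv(self.affine) @ xyz1)[:3]


@dataclass
class NetworkAssignment:
    """Outcome of the expanding-ROI rule for one sample.

    ``parcel``/``network``/``roi_side_mm`` are all None for omitted samples;
    for assigned samples ``overlap_voxels`` counts the winning network's voxels
    in the deciding cube.
    """

    sample_id: str
    parcel: str | None
    network: str | None
    roi_side_mm: int | None
    overlap_voxels: int

    @property
    def assigned(self) -> bool:
        return self.network is not None


def load_label_atlas(volume_path, mapping_path) -> ParcellationAtlas:
    """Load a NIfTI label volume and a label/parcel/network TSV mapping."""
    img = nib.load(str(volume_path))
    data = np.asanyarray(img.dataobj)
    mapping = pd.read_csv(mapping_path, sep="\t")
    missing = {"label", "parcel", "network"} - set(mapping.columns)
    if missing:
        raise ValueError(f"label mapping missing columns: {sorted(missing)}")
    if mapping["label"].duplicated().any():
        dups = mapping.loc[mapping["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate labels in mapping: {dups[:5]}")
    label_to_parcel = dict(zip(mapping["label"].astype(int), mapping["parcel"].astype(str)))
    parcel_to_network: dict[str, str] = {}
    for parcel, network in zip(mapping["parcel"].astype(str), mapping["network"].astype(str)):
        if parcel in parcel_to_network and parcel_to_network[parcel] != network:
            raise ValueError(f"parcel {parcel!r} maps to more than one network")
        parcel_to_network[parcel] = network
    return ParcellationAtlas(data, img.affine, label_to_parcel, parcel_to_network)


def load_manifest(path) -> pd.DataFrame:
    """Read and validate a sample manifest TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    return validate_manifest(df)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest["sample_id"].duplicated().any():
        dups = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in manifest: {dups[:5]}")
    bad = ~manifest["compartment"].isin(["cortex", "striatum"])
    if bad.any():
        raise ValueError(
            f"unknown compartments: {manifest.loc[bad, 'compartment'].unique().tolist()}"
        )
    coords = manifest[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("manifest coordinates must be finite")
    return manifest


def _cube_bounds(continuous: np.ndarray, center: np.ndarray, side: int) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive (lo, hi) voxel-index bounds of the ROI cube for one side."""
    if side == 1:
        return center, center
    if side == 2:
        # 2x2x2 block of voxels nearest the continuous coordinate; at exact
        # midpoints (integer coordinate) extend toward negative indices
        lo = np.ceil(continuous).astype(int) - 1
        return lo, lo + 1
    if side == 3:
        return center - 1, center + 1
    raise ValueError(f"cube side must be 1, 2 or 3, got {side}")


def assign_sample(
    atlas: ParcellationAtlas, coord, max_side_mm: int = 3, sample_id: str = ""
) -> NetworkAssignment:
    """Apply the expanding-ROI rule to one MNI coordinate.

    Cubes of side 1, 2 and 3 voxels are evaluated in order, stopping at the
    first cube containing at least one labeled voxel; the network with the most
    overlapping voxels in that cube is assigned (ties go to the network holding
    the lowest tied label, and are logged). A coordinate whose side-3 cube is
    all background — or which falls outside the volume — yields an unassigned
    (omitted) record.
    """
    if max_side_mm not in (1, 2, 3):
        raise ValueError("max_side_mm must be in {1, 2, 3}")
    continuous = atlas.mni_to_voxel(coord)
    center = np.floor(continuous + 0.5).astype(int)  # voxel containing the coordinate
    shape = np.asarray(atlas.label_volume.shape)
    if (center < 0).any() or (center >= shape).any():
        logger.warning("sample %s: coordinate %s maps outside the volume", sample_id, coord)
        return NetworkAssignment(sample_id, None, None, None, 0)
    label_to_network = atlas.label_to_network
    for side in range(1, max_side_mm + 1):
        lo, hi = _cube_bounds(continuous, center, side)
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, shape - 1)
        cube = atlas.label_volume[
            lo_c[0] : hi_c[0] + 1, lo_c[1] : hi_c[1] + 1, lo_c[2] : hi_c[2] + 1
        ]
        labels, counts = np.unique(cube[cube != 0], return_counts=True)
        if labels.size == 0:
            continue
        per_network: dict[str, int] = {}
        min_label: dict[str, int] = {}
        label_counts: dict[str, dict[int, int]] = {}
        for lab, cnt in zip(labels.tolist(), counts.tolist()):
            net = label_to_network[lab]
            per_network[net] = per_network.get(net, 0) + cnt
            min_label[net] = min(min_label.get(net, lab), lab)
            label_counts.setdefault(net, {})[lab] = cnt
        best = max(per_network.values())
        tied = [n for n, c in per_network.items() if c == best]
        if len(tied) > 1:
            logger.warning(
                "sample %s: tie between networks %s at side %d; choosing lowest label",
                sample_id,
                sorted(tied),
                side,
            )
        winner = min(tied, key=lambda n: min_label[n])
        # parcel: most-overlapping label of the winning network, ties -> lowest
        lab_counts = label_counts[winner]
        top = max(lab_counts.values())
        parcel_label = min(lab for lab, c in lab_counts.items() if c == top)
        return NetworkAssignment(
            sample_id, atlas.label_to_parcel[parcel_label], winner, side, int(best)
        )
    return NetworkAssignment(sample_id, None, None, None, 0)


@dataclass
class AssignmentResult:
    """Per-sample assignments plus network / donor x network count summaries."""

    table: pd.DataFrame
    network_counts: pd.Series
    donor_network_counts: pd.DataFrame
    n_unassigned: int
    n_excluded: int


def assignment_table(
    atlas: ParcellationAtlas,
    manifest: pd.DataFrame,
    max_side_mm: int = 3,
    strict_cortex: bool = False,
    exclude_networks: list[str] | None = None,
) -> AssignmentResult:
    """Assign every manifest sample and summarize counts.

    ``strict_cortex`` restricts cortical samples to a side-1 ROI ("fell
    within"), leaving the expansion for striatal samples only.
    ``exclude_networks`` drops assignments to the named networks (e.g. visual
    and dorsal attention in striatum) with a logged count.
    """
    manifest = validate_manifest(manifest)
    if manifest.empty:
        raise ValueError("manifest is empty")
    rows = []
    for rec in manifest.itertuples(index=False):
        side = 1 if (strict_cortex and rec.compartment == "cortex") else max_side_mm
        a = assign_sample(
            atlas, (rec.mni_x, rec.mni_y, rec.mni_z), max_side_mm=side, sample_id=rec.sample_id
        )
        rows.append(
            {
                "sample_id": rec.sample_id,
                "donor_id": rec.donor_id,
                "compartment": rec.compartment,
                "parcel": a.parcel,
                "network": a.network,
                "roi_side_mm": a.roi_side_mm,
                "overlap_voxels": a.overlap_voxels,
            }
        )
    table = pd.DataFrame(rows)
    n_excluded = 0
    if exclude_networks:
        drop = table["network"].isin(exclude_networks)
        n_excluded = int(drop.sum())
        if n_excluded:
            logger.info(
                "excluding %d samples assigned to networks %s", n_excluded, exclude_networks
            )
        table = table.loc[~drop].reset_index(drop=True)
    assigned = table.dropna(subset=["network"])
    network_counts = assigned["network"].value_counts().sort_index()
    donor_network_counts = (
        assigned.groupby(["donor_id", "network"]).size().unstack(fill_value=0)
    )
    return AssignmentResult(
        table=table,
        network_counts=network_counts,
        donor_network_counts=donor_network_counts,
        n_unassigned=int(table["network"].isna().sum()),
        n_excluded=n_excluded,
    )
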