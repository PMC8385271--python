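"""Group-level voxel selection: two-sample t-map + cluster-extent filter.

Selection compares the per-subject task beta maps of the two groups with a
pooled-variance two-sample t-test, thresholds the |t| map (default 3.0),
labels connected components among suprathreshold voxels (26-connectivity
by default, positive and negative excursions labelled separately), and
retains only components strictly larger than ``cluster_min`` voxels
(default 5, i.e. size >= 6). The retained voxel coordinates are the
pipeline's feature locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import BetaMap

__all__ = [
    "VoxelSelection",
    "EmptySelectionError",
    "two_sample_t",
    "select_voxels",
]


class EmptySelectionError(RuntimeError):
    """No voxel survived the threshold + cluster-extent filter."""


@dataclass
class VoxelSelection:
    """Selected voxel coordinates with their t-values and cluster labels."""

    coordinates: np.ndarray  # N x 3 integer voxel indices, 0-based
    t_values: np.ndarray  # length N
    cluster_ids: np.ndarray  # length N

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=int))
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int)

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
                "z": self.coordinates[:, 2],
                "t": self.t_values,
                "cluster_id": self.cluster_ids,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# 0-based voxel indices (x, y, z)\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


def two_sample_t(
    betas_group0: list[BetaMap], betas_group1: list[BetaMap]
) -> np.ndarray:
    """Voxelwise pooled-variance t statistic, group1 minus group0.

    Degrees of freedom are n0 + n1 - 2. Voxels with zero pooled variance
    (t undefined) are set to 0.
    """
    if len(betas_group0) < 2 or len(betas_group1) < 2:
        raise ValueError("need at least two subjects per group")
    a0 = np.stack([b.values for b in betas_group0])
    a1 = np.stack([b.values for b in betas_group1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_ind(a1, a0, axis=0, equal_var=True).statistic
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def select_voxels(
    t_map: np.ndarray,
    t_threshold: float = 3.0,
    cluster_min: int = 5,
    connectivity: int = 26,
    two_sided: bool = True,
) -> VoxelSelection:
    """Threshold the t-map and keep clusters strictly larger than ``cluster_min``.

    Positive and negative suprathreshold excursions are labelled as separate
    components so a cluster never mixes signs. Coordinates are returned in
    lexicographic order; cluster ids are renumbered 1..C in that order.
    """
    t_map = np.asarray(t_map, dtype=float)
    if not np.all(np.isfinite(t_map)):
        raise ValueError("t-map contains non-finite values")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = _STRUCTURES[connectivity]

    masks = [t_map > t_threshold]
    if two_sided:
        masks.append(t_map < -t_threshold)

    coords_all, ts_all, cids_all = [], [], []
    next_id = 1
    for mask in masks:
        labels, n_comp = ndimage.label(mask, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for comp in np.flatnonzero(sizes > cluster_min) + 1:
            xyz = np.argwhere(labels == comp)
            coords_all.append(xyz)
            ts_all.append(t_map[tuple(xyz.T)])
            cids_all.append(np.full(len(xyz), next_id))
            next_id += 1
    if not coords_all:
        raise EmptySelectionError(
            f"no cluster of > {cluster_min} voxels exceeds |t| > {t_threshold}; "
            "review t_threshold / cluster_min"
        )
    coords = np.vstack(coords_all)
    ts = np.concatenate(ts_all)
    cids = np.concatenate(cids_all)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    return VoxelSelection(
        coordinates=coords[order], t_values=ts[order], cluster_ids=cids[order]
    )
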