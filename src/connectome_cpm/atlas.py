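"""Node atlases: per-node hemisphere, macroscale region, and label.

An atlas defines the node set of the connectome and, through the canonical
upper-triangle edge ordering (see :mod:`connectome_cpm.connectome`), the
edge-to-vector mapping used everywhere downstream.  Node ids are 0-based in
memory and 1-based in every file read or written.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right", "midline")

#: The ten bilateral macroscale brain regions nodes are assigned to.
MACROSCALE_REGIONS = (
    "prefrontal",
    "motor",
    "insula",
    "parietal",
    "temporal",
    "occipital",
    "limbic",
    "cerebellum",
    "subcortex",
    "brainstem",
)

_COLUMNS = ["node_id", "hemisphere", "macroscale_region", "label"]


class AtlasFormatError(ValueError):
    """Raised when an atlas table violates the atlas contract."""


@dataclass(frozen=True)
class NodeAtlas:
    """An immutable node table: id, hemisphere, macroscale region, label.

    Parameters
    ----------
    table
        DataFrame with columns ``node_id`` (contiguous 0..n-1), ``hemisphere``
        (one of ``left``/``right``/``midline``), ``macroscale_region`` (one of
        the ten region tokens) and free-text ``label``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise AtlasFormatError(f"atlas table lacks columns: {missing}")
        n = len(t)
        if n == 0:
            raise AtlasFormatError("atlas table is empty")
        ids = t["node_id"].to_numpy()
        if len(np.unique(ids)) != n:
            raise AtlasFormatError("duplicate node ids in atlas")
        if not np.array_equal(np.sort(ids), np.arange(n)):
            raise AtlasFormatError("node ids must be contiguous 0..n_nodes-1")
        bad_hemi = set(t["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise AtlasFormatError(f"unknown hemisphere token(s): {sorted(bad_hemi)}")
        bad_reg = set(t["macroscale_region"]) - set(MACROSCALE_REGIONS)
        if bad_reg:
            raise AtlasFormatError(f"unknown macroscale region token(s): {sorted(bad_reg)}")
        # store sorted by node_id so positional indexing == node_id
        object.__setattr__(
            self, "table", t.sort_values("node_id").reset_index(drop=True)[_COLUMNS]
        )

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def regions(self) -> np.ndarray:
        return self.table["macroscale_region"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


def load_atlas(path) -> NodeAtlas:
    """Read an atlas from a tab-separated table with 1-based node ids."""
    t = pd.read_csv(path, sep="\t", dtype={"label": str})
    missing = [c for c in _COLUMNS if c not in t.columns]
    if missing:
        raise AtlasFormatError(f"atlas file lacks columns: {missing}")
    t = t.copy()
    t["node_id"] = t["node_id"].astype(int) - 1  # 1-based on disk
    return NodeAtlas(t)


def save_atlas(atlas: NodeAtlas, path) -> None:
    """Write an atlas as a tab-separated table with 1-based node ids."""
    t = atlas.table.copy()
    t["node_id"] = t["node_id"] + 1
    t.to_csv(path, sep="\t", index=False)


# Per-hemisphere cortical node counts for the default 368-node atlas.  The
# component totals (164 left cortex, 163 right cortex, 7+7 subcortical,
# 13+13 cerebellar, 1 brainstem) match the published parcellation; the split
# of cortical nodes across the seven cortical macroscale regions is a
# SYNTHETIC stand-in, since the per-node assignment table is not distributed
# with this package.
_DEFAULT_CORTICAL_COUNTS = {
    "prefrontal": (38, 38),
    "motor": (21, 21),
    "insula": (7, 7),
    "parietal": (27, 27),
    "temporal": (30, 30),
    "occipital": (25, 24),
    "limbic": (16, 16),
}


def default_atlas() -> NodeAtlas:
    """Build the default 368-node atlas (synthetic region assignment).

    The atlas has 164 left-hemisphere and 163 right-hemisphere cortical
    nodes, 7 subcortical nodes per hemisphere, 13 cerebellar nodes per
    hemisphere, and a single midline brainstem node (368 total).  Cortical
    nodes are assigned to the seven cortical macroscale regions in fixed
    blocks; the assignment is a deterministic synthetic stand-in for the
    real parcellation table and carries no anatomical meaning.
    """
    rows: list[tuple[int, str, str, str]] = []
    node = 0
    for hemi_key, hemi in (("L", "left"), ("R", "right")):
        idx = 0 if hemi == "left" else 1
        for region, counts in _DEFAULT_CORTICAL_COUNTS.items():
            for k in range(counts[idx]):
                rows.append((node, hemi, region, f"{hemi_key}_{region}_{k + 1:02d}"))
                node += 1
    for hemi_key, hemi in (("L", "left"), ("R", "right")):
        for k in range(7):
            rows.append((node, hemi, "subcortex", f"{hemi_key}_subcortex_{k + 1:02d}"))
            node += 1
    for hemi_key, hemi in (("L", "left"), ("R", "right")):
        for k in range(13):
            rows.append((node, hemi, "cerebellum", f"{hemi_key}_cerebellum_{k + 1:02d}"))
            node += 1
    rows.append((node, "midline", "brainstem", "brainstem_01"))
    table = pd.DataFrame(rows, columns=_COLUMNS)
    return NodeAtlas(table)
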