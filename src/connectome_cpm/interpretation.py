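"""Network interpretation: node degrees, hubs, edge classification.

Consensus masks are summarized as machine-readable tables replacing circle
plots and glass brains: a per-node degree table (how many consensus edges
touch each node), the top-degree "hub" nodes, and a per-edge annotation by
hemispheric type and macroscale region pair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .atlas import NodeAtlas
from .connectome import edge_pairs
from .cpm import NetworkMask

logger = logging.getLogger(__name__)

#: Default number of high-degree nodes reported per network sign.
DEFAULT_TOP_K = 2


class InterpretationError(ValueError):
    pass


def _check_dims(mask: NetworkMask, atlas: NodeAtlas) -> None:
    if mask.edges.size != atlas.n_edges:
        raise InterpretationError(
            f"mask has {mask.edges.size} edges; atlas with {atlas.n_nodes} nodes "
            f"implies {atlas.n_edges}"
        )


def node_degrees(mask: NetworkMask, atlas: NodeAtlas) -> pd.DataFrame:
    """Count consensus edges incident to each node.

    Returns a table ``node_id label hemisphere macroscale_region degree``
    ordered by (degree descending, node_id ascending).  The handshake
    identity holds: degrees sum to twice the number of masked edges.
    """
    _check_dims(mask, atlas)
    ii, jj = edge_pairs(atlas.n_nodes)
    deg = np.zeros(atlas.n_nodes, dtype=int)
    np.add.at(deg, ii[mask.edges], 1)
    np.add.at(deg, jj[mask.edges], 1)
    table = atlas.table.copy()
    table["degree"] = deg
    table = table.sort_values(
        ["degree", "node_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return table[["node_id", "label", "hemisphere", "macroscale_region", "degree"]]


def top_nodes(degree_table: pd.DataFrame, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """First k rows of the degree table, expanding ties at rank k.

    All nodes whose degree equals the k-th ranked degree are included, so
    the output may exceed k rows; tie expansion is logged.
    """
    if k < 1:
        raise InterpretationError(f"k must be >= 1, got {k}")
    if len(degree_table) <= k:
        return degree_table.copy()
    cutoff = degree_table["degree"].iloc[k - 1]
    out = degree_table[degree_table["degree"] >= cutoff].copy()
    if len(out) > k:
        logger.info("top_nodes: tie at rank %d expanded selection to %d nodes", k, len(out))
    return out


def classify_edges(mask: NetworkMask, atlas: NodeAtlas) -> pd.DataFrame:
    """Annotate each masked edge by hemisphere pattern and region pair.

    ``hemispheric_type`` is ``inter`` (left-right), ``intra-left``,
    ``intra-right``, or ``midline-involving`` when either endpoint is a
    midline node (hemisphere undefined there).  ``region_a``/``region_b``
    give the unordered macroscale-region pair (sorted alphabetically).
    Node ids in the output are 1-based, matching file conventions.
    """
    _check_dims(mask, atlas)
    hemi = atlas.hemispheres
    regions = atlas.regions
    ii, jj = edge_pairs(atlas.n_nodes)
    rows = []
    for a, b in zip(ii[mask.edges], jj[mask.edges]):
        ha, hb = hemi[a], hemi[b]
        if "midline" in (ha, hb):
            htype = "midline-involving"
        elif ha != hb:
            htype = "inter"
        else:
            htype = f"intra-{ha}"
        ra, rb = sorted((regions[a], regions[b]))
        rows.append((int(a) + 1, int(b) + 1, mask.sign, htype, ra, rb))
    return pd.DataFrame(
        rows,
        columns=["node_a", "node_b", "sign", "hemispheric_type", "region_a", "region_b"],
    )


def edge_summary(annotations: pd.DataFrame) -> dict[str, pd.Series]:
    """Counts by hemispheric type and by macroscale region pair."""
    by_hemi = annotations.groupby("hemispheric_type").size().sort_index()
    by_region = annotations.groupby(["region_a", "region_b"]).size().sort_index()
    return {"by_hemispheric_type": by_hemi, "by_region_pair": by_region}
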