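"""Expansion distance along a map-projected population tree.

Each population's expansion distance is the sum of great-circle distances
between the coordinates of consecutive nodes on the path from the cluster's
core node down to the population's leaf; designated "old" (rear-edge)
populations instead use the direct great-circle distance to the core.
Distances use a spherical Earth of mean radius 6371.0088 km.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088


def haversine(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    for lat, lon in (p1, p2):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(np.radians, (*p1, *p2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


@dataclass
class GeoTree:
    """Rooted population tree plus per-node map coordinates.

    ``coords`` maps node label -> (lat, lon); ``core`` maps cluster name ->
    core node label.  Every population leaf must be reachable from its
    cluster's core node.
    """

    tree: dendropy.Tree
    coords: dict[str, tuple[float, float]]
    core: dict[str, str]

    @classmethod
    def from_files(cls, newick_path: str | Path, coords_path: str | Path,
                   core: dict[str, str]) -> "GeoTree":
        tree = dendropy.Tree.get(path=str(newick_path), schema="newick",
                                 suppress_internal_node_taxa=False,
                                 preserve_underscores=True)
        tab = pd.read_csv(coords_path, sep="\t")
        coords = {str(r["node"]): (float(r["lat"]), float(r["lon"]))
                  for _, r in tab.iterrows()}
        return cls(tree=tree, coords=coords, core=core)

    def _label(self, node: dendropy.Node) -> str | None:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        return node.label

    def path_to_core(self, leaf_label: str, cluster: str) -> list[str]:
        """Node labels from the cluster core down to the leaf (inclusive)."""
        core_label = self.core[cluster]
        target = None
        for leaf in self.tree.leaf_node_iter():
            if self._label(leaf) == leaf_label:
                target = leaf
                break
        if target is None:
            raise KeyError(f"population {leaf_label} not on the tree")
        path = []
        node = target
        while node is not None:
            lab = self._label(node)
            if lab is not None:
                path.append(lab)
            if lab == core_label:
                break
            node = node.parent_node
        else:
            raise KeyError(
                f"core {core_label} is not an ancestor of {leaf_label}")
        return list(reversed(path))

    def path_distance(self, leaf_label: str, cluster: str) -> float:
        """Sum of great-circle legs along the core-to-leaf node path."""
        labels = self.path_to_core(leaf_label, cluster)
        total = 0.0
        for a, b in zip(labels[:-1], labels[1:]):
            total += haversine(self.coords[a], self.coords[b])
        return total

    def direct_distance(self, leaf_label: str, cluster: str) -> float:
        return haversine(self.coords[leaf_label],
                         self.coords[self.core[cluster]])


def expansion_distance(tree: GeoTree, meta: pd.DataFrame) -> pd.DataFrame:
    """Attach expansion distances (km) to the population metadata.

    ``meta`` needs columns pop, cluster, lat, lon and optionally ``is_old``;
    old populations get the direct great-circle distance to their cluster's
    core, all others the along-tree path sum.  The triangle inequality
    (path sum >= direct distance) is asserted for every population.
    """
    out = meta.copy()
    dists = []
    for _, row in out.iterrows():
        pop, cluster = row["pop"], row["cluster"]
        is_old = bool(row.get("is_old", False))
        direct = tree.direct_distance(pop, cluster)
        if is_old:
            dists.append(direct)
        else:
            d = tree.path_distance(pop, cluster)
            if d < direct - 1e-6:
                raise AssertionError(
                    f"path sum {d} km < direct distance {direct} km for {pop}")
            dists.append(d)
    out["expansion_distance"] = dists
    return out


def build_chain_tree(pop_ids: list[str], coords: list[tuple[float, float]],
                     ) -> tuple[str, pd.DataFrame]:
    """Caterpillar Newick tree plus node-coordinate table for a linear
    expansion: internal node ``node_i`` sits at population i's location and
    is the ancestor of all populations founded later.  Returns the Newick
    string and a (node, lat, lon) table; node_0 is the core.
    """
    n = len(pop_ids)
    newick = f"{pop_ids[-1]}"
    for i in range(n - 2, -1, -1):
        newick = f"({pop_ids[i]},{newick})node_{i}"
    newick = newick + ";"
    rows = []
    for i, (pop, (lat, lon)) in enumerate(zip(pop_ids, coords)):
        rows.append((pop, lat, lon))
        if i < n - 1:
            rows.append((f"node_{i}", lat, lon))
    return newick, pd.DataFrame(rows, columns=["node", "lat", "lon"])
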