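"""Weighted co-splicing networks and their third-order tensor stack.

Each RNA-seq dataset yields one weighted network whose nodes are cassette
exons and whose edge weights are correlations between exon inclusion-rate
profiles across the dataset's samples.  A collection of m such networks over
a shared n-exon universe is stacked into an n x n x m tensor whose entry
``a[i, j, k]`` is the weight of edge (i, j) in network k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inclusion import InclusionMatrix

__all__ = [
    "WeightedNetwork",
    "NetworkTensor",
    "correlation_network",
    "assemble_tensor",
    "union_universe",
    "intersection_universe",
    "read_network",
    "write_network",
    "read_tensor_manifest",
    "write_tensor_manifest",
]

_EDGE_HEADER = ("node_a", "node_b", "weight")


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative weighted graph over an ordered node list.

    Weights live in [0, 1] with a zero diagonal; ``dataset_id`` names the
    RNA-seq dataset (or simulation replicate) the network was derived from.
    """

    node_ids: list[str]
    weights: np.ndarray
    dataset_id: str

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weight matrix shape {self.weights.shape} does not match "
                f"{n} node ids"
            )
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node ids in network")
        if not np.allclose(self.weights, self.weights.T, atol=1e-8):
            raise ValueError("weight matrix is not symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        if np.nanmin(self.weights) < -1e-12 or np.nanmax(self.weights) > 1 + 1e-12:
            raise ValueError("edge weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class NetworkTensor:
    """Stack of m symmetric weight matrices over a shared node universe.

    ``weights`` is stored network-major with shape (m, n, n); the
    ``entries`` view exposes the same data as an (n, n, m) array for
    callers that index edge-first.
    """

    node_ids: list[str]
    network_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.network_ids = list(self.network_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        m, n = len(self.network_ids), len(self.node_ids)
        if self.weights.shape != (m, n, n):
            raise ValueError(
                f"tensor shape {self.weights.shape} inconsistent with "
                f"{m} networks x {n} nodes"
            )
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node ids in tensor universe")
        if len(set(self.network_ids)) != m:
            raise ValueError("duplicate network ids in tensor")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_networks(self) -> int:
        return len(self.network_ids)

    @property
    def entries(self) -> np.ndarray:
        """Edge-first (n, n, m) view of the tensor."""
        return np.moveaxis(self.weights, 0, 2)

    def node_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.node_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message detail
            raise KeyError(f"unknown node id {exc.args[0]!r}") from None

    def network_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.network_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover
            raise KeyError(f"unknown network id {exc.args[0]!r}") from None

    def slice(self, network_id: str) -> WeightedNetwork:
        k = self.network_ids.index(network_id)
        return WeightedNetwork(list(self.node_ids), self.weights[k].copy(), network_id)

    def copy(self) -> "NetworkTensor":
        return NetworkTensor(
            list(self.node_ids), list(self.network_ids), self.weights.copy()
        )

    def validate(self) -> None:
        """Check the per-slice invariants (symmetry, zero diagonal, range)."""
        for k, net_id in enumerate(self.network_ids):
            w = self.weights[k]
            if not np.allclose(w, w.T, atol=1e-8):
                raise ValueError(f"slice {net_id!r} is not symmetric")
            if np.any(np.diag(w) != 0):
                raise ValueError(f"slice {net_id!r} has nonzero diagonal")
        if self.weights.size and (
            self.weights.min() < -1e-12 or self.weights.max() > 1 + 1e-12
        ):
            raise ValueError("tensor entries must lie in [0, 1]")


def correlation_network(
    profiles: InclusionMatrix,
    min_overlap: int = 4,
    dataset_id: str = "dataset",
    edge_transform: str = "clamp",
) -> WeightedNetwork:
    """Pearson-correlation network between inclusion-rate profiles.

    Correlations are computed over pairwise-complete samples.  Pairs with
    fewer than ``min_overlap`` shared defined samples, or with a
    zero-variance profile, get weight 0.  Negative correlations are clamped
    to 0 by default (``edge_transform="clamp"``); ``"abs"`` takes absolute
    values instead.  The miner targets positively co-spliced exon sets, so
    clamping is the default.
    """
    if profiles.n_exons < 2:
        raise ValueError("need at least 2 exons to build a network")
    if min_overlap < 2:
        raise ValueError("min_overlap must be >= 2")
    df = profiles.values
    corr = df.T.corr(min_periods=min_overlap).to_numpy()
    corr = np.where(np.isfinite(corr), corr, 0.0)
    if edge_transform == "clamp":
        corr = np.maximum(corr, 0.0)
    elif edge_transform == "abs":
        corr = np.abs(corr)
    else:
        raise ValueError(f"unknown edge_transform {edge_transform!r}")
    corr = np.clip(corr, 0.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 0.0)
    return WeightedNetwork(list(df.index), corr, dataset_id)


def union_universe(networks: Sequence[WeightedNetwork]) -> list[str]:
    """Sorted union of the node sets of a network collection."""
    seen: set[str] = set()
    for net in networks:
        seen.update(net.node_ids)
    return sorted(seen)


def intersection_universe(networks: Sequence[WeightedNetwork]) -> list[str]:
    """Sorted intersection of the node sets of a network collection."""
    if not networks:
        return []
    common = set(networks[0].node_ids)
    for net in networks[1:]:
        common &= set(net.node_ids)
    return sorted(common)


def assemble_tensor(
    networks: Sequence[WeightedNetwork],
    universe: Sequence[str] | None = None,
) -> NetworkTensor:
    """Stack networks onto a shared node universe (default: their union).

    Node pairs absent from a network contribute weight 0 in its slice, so
    every slice stays symmetric with a zero diagonal.
    """
    if not networks:
        raise ValueError("no networks to assemble")
    if universe is None:
        universe = union_universe(networks)
    universe = list(universe)
    if not universe:
        raise ValueError("empty node universe")
    if len(set(universe)) != len(universe):
        raise ValueError("duplicate ids in universe")
    ids = [net.dataset_id for net in networks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset_id among networks")
    pos = {v: i for i, v in enumerate(universe)}
    n, m = len(universe), len(networks)
    tensor = np.zeros((m, n, n))
    for k, net in enumerate(networks):
        idx = np.array([pos[v] for v in net.node_ids if v in pos], dtype=int)
        src = np.array([i for i, v in enumerate(net.node_ids) if v in pos], dtype=int)
        tensor[np.ix_([k], idx, idx)] = net.weights[np.ix_(src, src)]
    return NetworkTensor(universe, ids, tensor)


# ---------------------------------------------------------------------------
# On-disk formats: full matrix TSV (row/col headers) or 3-column edge list.


def write_network(net: WeightedNetwork, path: str | Path, fmt: str = "matrix") -> None:
    path = Path(path)
    if fmt == "matrix":
        pd.DataFrame(net.weights, index=net.node_ids, columns=net.node_ids).to_csv(
            path, sep="\t"
        )
    elif fmt == "edges":
        rows = []
        n = net.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                w = net.weights[i, j]
                if w != 0:
                    rows.append((net.node_ids[i], net.node_ids[j], w))
        pd.DataFrame(rows, columns=list(_EDGE_HEADER)).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(
    path: str | Path,
    dataset_id: str | None = None,
    node_ids: Sequence[str] | None = None,
) -> WeightedNetwork:
    """Read a network from TSV, auto-detecting matrix vs edge-list layout.

    Edge lists need ``node_ids`` (or are restricted to the nodes that occur
    in at least one edge, in sorted order, when omitted).
    """
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    is_edges = tuple(header[:3]) == _EDGE_HEADER
    if not is_edges and len(header) == 3:
        # headerless edge list: third field numeric
        try:
            float(header[2])
            is_edges = True
        except ValueError:
            is_edges = False
    if is_edges:
        names = list(_EDGE_HEADER)
        skip = 1 if tuple(header[:3]) == _EDGE_HEADER else 0
        df = pd.read_csv(path, sep="\t", names=names, skiprows=skip)
        if node_ids is None:
            node_ids = sorted(set(df.node_a.astype(str)) | set(df.node_b.astype(str)))
        node_ids = list(node_ids)
        pos = {v: i for i, v in enumerate(node_ids)}
        w = np.zeros((len(node_ids), len(node_ids)))
        for a, b, weight in df.itertuples(index=False):
            i, j = pos[str(a)], pos[str(b)]
            w[i, j] = w[j, i] = weight
        return WeightedNetwork(node_ids, w, dataset_id)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return WeightedNetwork([str(i) for i in df.index], df.to_numpy(), dataset_id)


def write_tensor_manifest(
    tensor: NetworkTensor, out_dir: str | Path, fmt: str = "matrix"
) -> Path:
    """Persist a tensor as one network file per slice plus a manifest.

    The manifest is plain text, one ``network_id<TAB>relative_path`` line
    per slice; returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "tensor_manifest.tsv"
    with open(manifest, "w") as fh:
        for net_id in tensor.network_ids:
            fname = f"network_{net_id}.tsv"
            write_network(tensor.slice(net_id), out_dir / fname, fmt=fmt)
            fh.write(f"{net_id}\t{fname}\n")
    return manifest


def read_tensor_manifest(
    manifest: str | Path, universe: Sequence[str] | None = None
) -> NetworkTensor:
    manifest = Path(manifest)
    networks = []
    with open(manifest) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            net_id, rel = line.split("\t")
            networks.append(
                read_network(manifest.parent / rel, dataset_id=net_id)
            )
    return assemble_tensor(networks, universe=universe)
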