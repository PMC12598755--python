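"""Intra-/inter-network connectivity features from node-level signals.

A parcellation assigns each node of a whole-brain graph to one resting-state
network (RSN).  Whole-brain functional connectivity is the Pearson correlation
matrix of the node time-series; the upper-triangle entries split into
*intra-network* pairs (both nodes in the same RSN) and *inter-network* pairs
(nodes in different RSNs).  The two pair vectors are the raw feature sets for
connectivity-based brain-age prediction, optionally compressed with PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "DEFAULT_NETWORK_SIZES",
    "DEFAULT_NETWORK_NAMES",
    "Parcellation",
    "PairPartition",
    "PCAReducer",
    "make_parcellation",
    "timeseries_to_connectivity",
    "partition_pairs",
    "extract_pair_vector",
    "insert_pair_vector",
    "fit_pca",
    "transform",
    "components_for_variance",
]

#: Default per-network node counts for the 10-RSN, 167-node parcellation.
#: Chosen so that the number of within-network node pairs is exactly 1539
#: (and hence 12322 between-network pairs out of C(167,2) = 13861).
DEFAULT_NETWORK_SIZES: tuple[int, ...] = (30, 26, 20, 18, 15, 15, 15, 11, 10, 7)

DEFAULT_NETWORK_NAMES: tuple[str, ...] = (
    "visual-fovea",
    "visual-periphery",
    "sensory-motor",
    "auditory",
    "dorsal-attention",
    "ventral-attention",
    "language",
    "fronto-parietal",
    "cingulo-opercular",
    "default-mode",
)


@dataclass(frozen=True)
class Parcellation:
    """Node -> resting-state-network assignment with a fixed node order."""

    node_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.node_ids) != len(self.labels):
            raise ValueError("node_ids and labels must have equal length")
        if len(self.node_ids) == 0:
            raise ValueError("parcellation must contain at least one node")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node ids must be unique")
        if any(not lab for lab in self.labels):
            raise ValueError("network labels must be non-empty")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def networks(self) -> tuple[str, ...]:
        """Network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)


@dataclass(frozen=True)
class PairPartition:
    """Upper-triangle node pairs split into intra- and inter-network sets."""

    intra_pairs: tuple[tuple[int, int], ...]
    inter_pairs: tuple[tuple[int, int], ...]

    @property
    def n_intra(self) -> int:
        return len(self.intra_pairs)

    @property
    def n_inter(self) -> int:
        return len(self.inter_pairs)


def make_parcellation(
    network_sizes: tuple[int, ...] | list[int] = DEFAULT_NETWORK_SIZES,
    network_names: tuple[str, ...] | list[str] | None = None,
) -> Parcellation:
    """Build a parcellation with consecutive blocks of nodes per network.

    Parameters
    ----------
    network_sizes
        Number of nodes in each network; all must be positive.  The default
        is a 10-network, 167-node layout whose within-network pair count is
        1539.
    network_names
        Optional labels, one per network; defaults to the 10 canonical RSN
        names (or ``"network-<k>"`` when a non-default size list is given).
    """
    sizes = list(network_sizes)
    if not sizes:
        raise ValueError("network_sizes must be non-empty")
    if any(int(s) <= 0 or int(s) != s for s in sizes):
        raise ValueError("network sizes must be positive integers")
    sizes = [int(s) for s in sizes]
    if network_names is None:
        if tuple(sizes) == DEFAULT_NETWORK_SIZES:
            names = list(DEFAULT_NETWORK_NAMES)
        else:
            names = [f"network-{k + 1}" for k in range(len(sizes))]
    else:
        names = list(network_names)
        if len(names) != len(sizes):
            raise ValueError("network_names must match network_sizes in length")
    node_ids: list[str] = []
    labels: list[str] = []
    node = 0
    for name, size in zip(names, sizes):
        for _ in range(size):
            node_ids.append(f"node_{node:03d}")
            labels.append(name)
            node += 1
    return Parcellation(node_ids=tuple(node_ids), labels=tuple(labels))


def timeseries_to_connectivity(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of node time-series.

    Parameters
    ----------
    ts
        Array of shape (n_nodes, n_timepoints) with at least two time points.

    Returns
    -------
    Symmetric matrix with unit diagonal and entries in [-1, 1].
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time-series must be a 2-D (nodes x time) array")
    if ts.shape[1] < 2:
        raise ValueError("need at least two time points per node")
    sd = ts.std(axis=1)
    constant = np.flatnonzero(sd == 0.0)
    if constant.size:
        raise ValueError(
            f"constant time-series for node index {int(constant[0])}; "
            "correlation is undefined"
        )
    corr = np.corrcoef(ts)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def partition_pairs(parcellation: Parcellation) -> PairPartition:
    """Split all upper-triangle node pairs into intra- and inter-network sets.

    Intra pairs are ordered by network (first-appearance order), row-major
    within each network; inter pairs are row-major over the upper triangle.
    The ordering is a fixed convention so feature vectors are comparable
    across participants.
    """
    labels = parcellation.labels
    n = parcellation.n_nodes
    intra: list[tuple[int, int]] = []
    for net in parcellation.networks:
        nodes = [i for i, lab in enumerate(labels) if lab == net]
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                intra.append((nodes[a], nodes[b]))
    inter = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if labels[i] != labels[j]
    ]
    return PairPartition(intra_pairs=tuple(intra), inter_pairs=tuple(inter))


def _pairs_for(partition: PairPartition, which: str) -> tuple[tuple[int, int], ...]:
    if which == "intra":
        return partition.intra_pairs
    if which == "inter":
        return partition.inter_pairs
    raise ValueError(f"which must be 'intra' or 'inter', got {which!r}")


def extract_pair_vector(
    matrix: np.ndarray, partition: PairPartition, which: str
) -> np.ndarray:
    """Read the selected off-diagonal cells into an ordered feature vector."""
    matrix = np.asarray(matrix, dtype=float)
    pairs = _pairs_for(partition, which)
    n_needed = 1 + max((max(i, j) for i, j in pairs), default=-1)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if matrix.shape[0] < n_needed:
        raise ValueError(
            f"matrix of size {matrix.shape[0]} does not cover node index "
            f"{n_needed - 1} required by the partition"
        )
    if not pairs:
        return np.empty(0)
    idx = np.asarray(pairs)
    return matrix[idx[:, 0], idx[:, 1]].astype(float)


def insert_pair_vector(
    vector: np.ndarray, partition: PairPartition, which: str, n_nodes: int
) -> np.ndarray:
    """Inverse of :func:`extract_pair_vector`: place values back into a
    symmetric matrix (other cells zero, diagonal zero)."""
    pairs = _pairs_for(partition, which)
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(pairs),):
        raise ValueError("vector length does not match the pair list")
    out = np.zeros((n_nodes, n_nodes))
    for value, (i, j) in zip(vector, pairs):
        out[i, j] = value
        out[j, i] = value
    return out


@dataclass
class PCAReducer:
    """Train-fitted PCA: center vector, orthonormal loadings, variance ratios."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray
    n_components_fit: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_components_fit == 0:
            self.n_components_fit = self.components.shape[0]


def fit_pca(train_vectors: np.ndarray, n_components: int) -> PCAReducer:
    """Fit PCA on training participants only (centering on the training mean).

    ``n_components`` must not exceed min(n_train - 1, n_features).
    """
    X = np.asarray(train_vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("train_vectors must be 2-D (participants x features)")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components={n_components} outside valid range [1, {max_rank}]"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return PCAReducer(
        mean=pca.mean_.copy(),
        components=pca.components_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        explained_variance=pca.explained_variance_.copy(),
        n_components_fit=n_components,
    )


def transform(reducer: PCAReducer, vectors: np.ndarray) -> np.ndarray:
    """Project (possibly held-out) vectors using training center and loadings."""
    X = np.asarray(vectors, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != reducer.mean.shape[0]:
        raise ValueError("feature dimension does not match the fitted reducer")
    scores = (X - reducer.mean) @ reducer.components.T
    return scores[0] if single else scores


def components_for_variance(reducer: PCAReducer, target: float = 0.95) -> int:
    """Smallest component count whose cumulative variance ratio reaches target."""
    if not (0.0 < target <= 1.0):
        raise ValueError("target must be in (0, 1]")
    cum = np.cumsum(reducer.explained_variance_ratio)
    # tiny tolerance so target=1.0 is reachable despite floating-point round-off
    hit = np.flatnonzero(cum >= target - 1e-12)
    if hit.size == 0:
        raise ValueError(
            f"fitted components explain only {cum[-1]:.4f} of variance; "
            f"cannot reach target {target}"
        )
    return int(hit[0]) + 1
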