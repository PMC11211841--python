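"""SE(3)-invariant graph featurization of coarse-grained RNA backbones.

The chain becomes a directed k-nearest-neighbour graph over nucleotides
(distances between C1' atoms).  Node scalars are rotation/translation
invariant: sin/cos of pseudo-dihedrals along the C1' trace and of the two
dihedrals that orient the (C4', C1', N) triad against the adjacent C1'
atoms, plus radial-basis encodings of the two intra-nucleotide bond lengths
and two bond-angle cosines.  Node vectors (unit length) rotate with the
frame: forward and reverse C1' chain directions and the C1'->C4' and
C1'->N1/N9 orientations.  Edge features are the unit inter-C1' direction, a
Gaussian radial basis over the C1' distance, and a sinusoidal encoding of
the signed sequence offset.

Bond-length scalars are included because in a three-atom representation the
glycosidic and ribose bond geometry is the only per-nucleotide information
that unit vectors discard; they are invariant and can be disabled via
:class:`FeatureConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .backbone import CoarseBackbone


class GraphError(ValueError):
    pass


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    k: int = 20
    n_rbf: int = 32
    rbf_min: float = 0.0
    rbf_max: float = 40.0
    n_posenc: int = 16
    offset_clip: int = 64
    bond_scalars: bool = True
    n_bond_rbf: int = 8
    bond_rbf_min: float = 0.8
    bond_rbf_max: float = 3.2

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.rbf_min >= self.rbf_max:
            raise ValueError("rbf_min must be < rbf_max")
        if self.n_rbf < 2:
            raise ValueError("n_rbf must be >= 2")

    @property
    def node_scalar_dim(self) -> int:
        d = 8  # sin/cos of 4 dihedrals
        if self.bond_scalars:
            d += 2 * self.n_bond_rbf + 2
        return d

    @property
    def node_vector_dim(self) -> int:
        return 4

    @property
    def edge_scalar_dim(self) -> int:
        return self.n_rbf + 2 * self.n_posenc


@dataclass
class NucleotideGraph:
    """k-NN graph with scalar/vector features; vectors are stored (n, 3, C)."""

    edges: np.ndarray          # (E, 2) int, rows (i, j): j is a neighbour of i
    node_scalars: np.ndarray   # (N, d_s)
    node_vectors: np.ndarray   # (N, 3, v_n)
    edge_scalars: np.ndarray   # (E, e_s)
    edge_vectors: np.ndarray   # (E, 3, 1)
    n_nodes: int
    k: int

    def __post_init__(self):
        for arr_name in ("node_scalars", "node_vectors", "edge_scalars", "edge_vectors"):
            arr = getattr(self, arr_name)
            if not np.all(np.isfinite(arr)):
                raise FeatureError(f"{arr_name} contains non-finite values")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise GraphError("graph contains self-edges")
        expected = min(self.k, self.n_nodes - 1)
        deg = np.bincount(self.edges[:, 0], minlength=self.n_nodes)
        if not np.all(deg == expected):
            raise GraphError("every node must have out-degree min(k, N-1)")


# ---------------------------------------------------------------------------

def build_knn_graph(backbone: CoarseBackbone, k: int) -> np.ndarray:
    """Edges (i, j) to the k nearest neighbours of i by C1' distance.

    Ties break toward the lower index; with fewer than k other nodes the
    graph is complete (no self loops).
    """
    n = len(backbone)
    if n < 2:
        raise GraphError(f"need at least 2 nucleotides for a graph, got {n}")
    d = cdist(backbone.c1, backbone.c1)
    np.fill_diagonal(d, np.inf)
    kk = min(k, n - 1)
    # round distances so exact geometric ties stay tied under the float
    # jitter of a rigid motion, then break ties toward the lower index
    d = np.round(d, 6)
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d), axis=1)
    neighbours = order[:, :kk]
    src = np.repeat(np.arange(n), kk)
    return np.stack([src, neighbours.ravel()], axis=1).astype(np.intp)


def _dihedral(p0, p1, p2, p3):
    """Signed dihedral angle(s) of the plane (p0,p1,p2) vs (p1,p2,p3), radians."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = (n1 * n2).sum(-1)
    y = (m1 * n2).sum(-1)
    return np.arctan2(y, x)


def _unit(v, what: str):
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm < 1e-9):
        bad = int(np.argmin(norm))
        raise FeatureError(f"degenerate zero-length {what} vector at residue index {bad}")
    return v / norm


def _rbf(d: np.ndarray, n: int, lo: float, hi: float) -> np.ndarray:
    centers = np.linspace(lo, hi, n)
    width = centers[1] - centers[0]
    return np.exp(-((d[..., None] - centers) / width) ** 2)


def node_geometry_features(backbone: CoarseBackbone,
                           config: FeatureConfig | None = None):
    """Per-nucleotide invariant scalars and equivariant unit vectors.

    Terminal positions where a dihedral or chain vector is undefined are
    zero-padded (chains are linear, no wrap-around).
    """
    config = config or FeatureConfig()
    n = len(backbone)
    if n < 2:
        raise FeatureError("need at least 2 nucleotides")
    c1, c4, ng = backbone.c1, backbone.c4, backbone.n_glyc

    dihedrals = np.zeros((n, 4))
    if n >= 4:
        # eta-like: (i-2, i-1, i, i+1); theta-like: (i-1, i, i+1, i+2)
        eta = _dihedral(c1[:-3], c1[1:-2], c1[2:-1], c1[3:])
        dihedrals[2:-1, 0] = eta
        dihedrals[1:-2, 1] = eta
    # triad (N, C4', C1') against the next / previous C1'
    if n >= 2:
        dihedrals[:-1, 2] = _dihedral(ng[:-1], c4[:-1], c1[:-1], c1[1:])
        dihedrals[1:, 3] = _dihedral(ng[1:], c4[1:], c1[1:], c1[:-1])

    # zero-padded positions stay exactly zero in both sin and cos channels
    defined = np.zeros((n, 4), dtype=bool)
    if n >= 4:
        defined[2:-1, 0] = True
        defined[1:-2, 1] = True
    defined[:-1, 2] = True
    defined[1:, 3] = True
    scalars = np.concatenate(
        [np.where(defined, np.sin(dihedrals), 0.0),
         np.where(defined, np.cos(dihedrals), 0.0)], axis=1)

    to_c4 = c4 - c1
    to_n = ng - c1
    fwd = np.zeros((n, 3))
    rev = np.zeros((n, 3))
    fwd[:-1] = _unit(c1[1:] - c1[:-1], "forward chain")
    rev[1:] = _unit(c1[:-1] - c1[1:], "reverse chain")
    u_c4 = _unit(to_c4, "C1'->C4'")
    u_n = _unit(to_n, "C1'->N")

    if config.bond_scalars:
        len_c4 = np.linalg.norm(to_c4, axis=-1)
        len_n = np.linalg.norm(to_n, axis=-1)
        bond = np.concatenate(
            [_rbf(len_c4, config.n_bond_rbf, config.bond_rbf_min, config.bond_rbf_max),
             _rbf(len_n, config.n_bond_rbf, config.bond_rbf_min, config.bond_rbf_max),
             (u_c4 * u_n).sum(-1, keepdims=True),
             (u_c4 * fwd).sum(-1, keepdims=True)], axis=1)
        scalars = np.concatenate([scalars, bond], axis=1)

    vectors = np.stack([fwd, rev, u_c4, u_n], axis=-1)  # (N, 3, 4)
    return scalars, vectors


def edge_geometry_features(backbone: CoarseBackbone, edges: np.ndarray,
                           config: FeatureConfig | None = None):
    """Edge scalars (distance RBF + signed-offset sinusoids) and unit direction."""
    config = config or FeatureConfig()
    c1 = backbone.c1
    i, j = edges[:, 0], edges[:, 1]
    delta = c1[j] - c1[i]
    dist = np.linalg.norm(delta, axis=-1)
    direction = _unit(delta, "edge")

    rbf = _rbf(dist, config.n_rbf, config.rbf_min, config.rbf_max)
    offset = np.clip(j - i, -config.offset_clip, config.offset_clip).astype(np.float64)
    freqs = np.exp(-np.arange(config.n_posenc) * np.log(10000.0) / config.n_posenc)
    phase = offset[:, None] * freqs
    scalars = np.concatenate([rbf, np.sin(phase), np.cos(phase)], axis=1)
    return scalars, direction[:, :, None]


def save_graph(graph: NucleotideGraph, path: str):
    """Cache a featurized graph as a compressed .npz container."""
    np.savez_compressed(path, edges=graph.edges, node_scalars=graph.node_scalars,
                        node_vectors=graph.node_vectors, edge_scalars=graph.edge_scalars,
                        edge_vectors=graph.edge_vectors,
                        meta=np.array([graph.n_nodes, graph.k]))


def load_graph(path: str) -> NucleotideGraph:
    with np.load(path) as npz:
        return NucleotideGraph(edges=npz["edges"], node_scalars=npz["node_scalars"],
                               node_vectors=npz["node_vectors"],
                               edge_scalars=npz["edge_scalars"],
                               edge_vectors=npz["edge_vectors"],
                               n_nodes=int(npz["meta"][0]), k=int(npz["meta"][1]))


def featurize(backbone: CoarseBackbone,
              config: FeatureConfig | None = None) -> NucleotideGraph:
    """Full graph construction: k-NN edges plus node/edge features."""
    config = config or FeatureConfig()
    edges = build_knn_graph(backbone, config.k)
    node_s, node_v = node_geometry_features(backbone, config)
    edge_s, edge_v = edge_geometry_features(backbone, edges, config)
    return NucleotideGraph(edges=edges, node_scalars=node_s, node_vectors=node_v,
                           edge_scalars=edge_s, edge_vectors=edge_v,
                           n_nodes=len(backbone), k=config.k)
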