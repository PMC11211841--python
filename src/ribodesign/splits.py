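"""Cluster-based train/validation/test split construction.

Items (RNA structures) are first clustered on a similarity matrix — average
linkage agglomerative clustering on distance 1 - similarity, cut at the
requested similarity threshold — and whole clusters are then randomly
assigned to partitions, so that no near-duplicate straddles train and test.
Precomputed similarity matrices or cluster files from external tools are
ingested via plain-text formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


class SplitError(ValueError):
    pass


@dataclass
class ClusterAssignment:
    item_ids: list[str]
    labels: np.ndarray
    threshold: float
    similarity_kind: str = "sequence"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.item_ids) != self.labels.size:
            raise SplitError("one label per item required")

    @property
    def n_clusters(self) -> int:
        return np.unique(self.labels).size


@dataclass(frozen=True)
class SplitSpec:
    test_frac: float = 0.15
    valid_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.test_frac <= 0 or self.valid_frac <= 0:
            raise SplitError("fractions must be positive")
        if self.test_frac + self.valid_frac >= 1.0:
            raise SplitError("test_frac + valid_frac must be < 1")


def agglomerative_cluster(similarity: np.ndarray, threshold: float,
                          item_ids: list[str] | None = None,
                          similarity_kind: str = "sequence") -> ClusterAssignment:
    """Average-linkage clustering of a similarity matrix, cut at the threshold.

    Items whose average inter-cluster similarity exceeds ``threshold`` end up
    in the same cluster.
    """
    sim = np.asarray(similarity, dtype=np.float64)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise SplitError(f"similarity matrix must be square, got {sim.shape}")
    if np.max(np.abs(sim - sim.T)) > 1e-8:
        raise SplitError("similarity matrix is not symmetric")
    n = sim.shape[0]
    item_ids = item_ids or [str(i) for i in range(n)]
    if n == 1:
        return ClusterAssignment(item_ids, np.array([1]), threshold, similarity_kind)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=1.0 - threshold, criterion="distance")
    return ClusterAssignment(item_ids, labels, threshold, similarity_kind)


def make_splits(clusters: ClusterAssignment, spec: SplitSpec | None = None,
                rng: np.random.Generator | None = None) -> dict[str, str]:
    """Assign whole clusters to train/valid/test.

    Cluster counts are floor(frac * n_clusters) for test and valid, remainder
    to train; returns item_id -> partition.
    """
    spec = spec or SplitSpec()
    rng = rng or np.random.default_rng(spec.seed)
    unique = np.unique(clusters.labels)
    if unique.size < 3:
        raise SplitError(f"need at least 3 clusters to split, got {unique.size}")
    order = rng.permutation(unique)
    n_test = int(np.floor(spec.test_frac * unique.size))
    n_valid = int(np.floor(spec.valid_frac * unique.size))
    if n_test < 1 or n_valid < 1:
        raise SplitError("too few clusters for the requested fractions")
    partition_of = {}
    for c in order[:n_test]:
        partition_of[c] = "test"
    for c in order[n_test:n_test + n_valid]:
        partition_of[c] = "valid"
    for c in order[n_test + n_valid:]:
        partition_of[c] = "train"
    return {item: partition_of[label]
            for item, label in zip(clusters.item_ids, clusters.labels)}


def make_nonoverlapping_splits(clusters: ClusterAssignment, spec: SplitSpec | None = None,
                               n_splits: int = 4,
                               rng: np.random.Generator | None = None) -> list[dict[str, str]]:
    """Several random splits whose test+valid cluster sets are pairwise disjoint.

    One shuffled cluster order is partitioned into consecutive evaluation
    blocks, so disjointness holds by construction; raises when the requested
    fractions cannot fit ``n_splits`` disjoint evaluation sets.
    """
    spec = spec or SplitSpec()
    rng = rng or np.random.default_rng(spec.seed)
    unique = np.unique(clusters.labels)
    n_test = int(np.floor(spec.test_frac * unique.size))
    n_valid = int(np.floor(spec.valid_frac * unique.size))
    block = n_test + n_valid
    if n_splits * block > unique.size:
        raise SplitError(f"cannot fit {n_splits} disjoint evaluation sets: "
                         f"{n_splits} x {block} > {unique.size} clusters")
    order = rng.permutation(unique)
    splits = []
    for k in range(n_splits):
        eval_block = order[k * block:(k + 1) * block]
        partition_of = {c: "train" for c in unique}
        for c in eval_block[:n_test]:
            partition_of[c] = "test"
        for c in eval_block[n_test:]:
            partition_of[c] = "valid"
        splits.append({item: partition_of[label]
                       for item, label in zip(clusters.item_ids, clusters.labels)})
    return splits


def check_disjoint(splits: list[dict[str, str]],
                   partitions: tuple[str, ...] = ("test", "valid")) -> list[str]:
    """Item ids appearing in the evaluation partitions of more than one split."""
    seen: dict[str, int] = {}
    overlaps = []
    for k, split in enumerate(splits):
        for item, part in split.items():
            if part in partitions:
                if item in seen and seen[item] != k:
                    overlaps.append(item)
                seen.setdefault(item, k)
    return sorted(set(overlaps))


# ---------------------------------------------------------------------------
# plain-text interchange with external clustering tools
# ---------------------------------------------------------------------------

def read_cluster_file(text: str, threshold: float = 0.0,
                      similarity_kind: str = "sequence") -> ClusterAssignment:
    """Two-column whitespace text: item_id cluster_id."""
    ids, labels = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SplitError(f"line {lineno}: expected 'item_id cluster_id'")
        ids.append(parts[0])
        labels.append(parts[1])
    uniq = {lab: i for i, lab in enumerate(dict.fromkeys(labels))}
    return ClusterAssignment(ids, np.asarray([uniq[lab] for lab in labels]),
                             threshold, similarity_kind)


def read_similarity_matrix(text: str) -> tuple[list[str], np.ndarray]:
    """Labeled square matrix: header row of ids, then 'id v1 v2 ...' rows."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise SplitError("empty similarity matrix")
    header = lines[0].split()
    n = len(header)
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise SplitError(f"matrix row has {len(parts) - 1} values, expected {n}")
        rows.append([float(x) for x in parts[1:]])
    if len(rows) != n:
        raise SplitError(f"matrix has {len(rows)} rows, expected {n}")
    return header, np.asarray(rows)


def write_splits(split: dict[str, str]) -> str:
    return "".join(f"{item}\t{part}\n" for item, part in sorted(split.items()))
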