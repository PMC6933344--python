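"""Tumour clustering: cosine distance, Ward agglomeration, silhouette-chosen k.

Tumour samples are compared by the cosine distance between their expression
profiles over the module-member genes, agglomerated with Ward linkage
(Ward.D2 convention: each merge minimizes the increase in within-cluster sum
of squared distances), and the number of clusters k is the one maximizing the
mean silhouette width over a bounded sweep, ties broken toward smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .exceptions import ZeroVectorError


@dataclass
class Dendrogram:
    """Merge history over named samples (scipy linkage encoding)."""

    sample_ids: list[str]
    merges: np.ndarray  # (n-1, 4) linkage matrix

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class ClusterAssignment:
    """sample -> cluster index in 1..k; indices ordered by first-appearing sample."""

    labels: pd.Series
    k: int

    def __post_init__(self) -> None:
        observed = set(self.labels)
        if observed != set(range(1, self.k + 1)):
            raise ValueError(f"cluster labels must be exactly 1..{self.k}, got {sorted(observed)}")

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def write(self, path) -> None:
        self.labels.rename("cluster").rename_axis("sample").to_csv(path, sep="\t")


def cosine_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine distance ``1 - u.v/(|u||v|)`` between sample rows.

    ``profiles`` is samples x features. On log-ratio features, which can be
    negative, the distance can exceed 1 (range [0, 2]); that is allowed.
    A zero-norm sample vector is an error naming the sample.
    """
    values = profiles.to_numpy(dtype=float)
    norms = np.linalg.norm(values, axis=1)
    dead = np.flatnonzero(norms == 0.0)
    if dead.size:
        names = [str(profiles.index[i]) for i in dead[:5]]
        raise ZeroVectorError(f"zero-norm expression vector for sample(s) {names}")
    d = squareform(pdist(values, metric="cosine"))
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def ward_tree(d: pd.DataFrame) -> Dendrogram:
    """Ward (D2) agglomeration of a precomputed distance matrix."""
    if d.shape[0] < 2:
        raise ValueError("need at least 2 samples to build a dendrogram")
    if d.shape[0] != d.shape[1] or not np.allclose(d.to_numpy(), d.to_numpy().T):
        raise ValueError("distance matrix must be square and symmetric")
    condensed = squareform(d.to_numpy(), checks=False)
    merges = linkage(condensed, method="ward")
    return Dendrogram(sample_ids=list(d.index), merges=merges)


def cut_clusters(tree: Dendrogram, k: int) -> ClusterAssignment:
    """Partition induced by removing the k-1 highest merges."""
    if not (1 <= k <= tree.n):
        raise ValueError(f"k must be in 1..{tree.n}, got {k}")
    raw = fcluster(tree.merges, t=k, criterion="maxclust")
    # renumber clusters by first-appearing sample
    remap: dict[int, int] = {}
    for label in raw:
        if label not in remap:
            remap[label] = len(remap) + 1
    labels = pd.Series(
        [remap[v] for v in raw], index=pd.Index(tree.sample_ids, name="sample")
    )
    return ClusterAssignment(labels=labels, k=len(remap))


def mean_silhouette(d: pd.DataFrame, labels: pd.Series) -> float:
    """Mean silhouette width over all samples from a precomputed distance matrix."""
    return float(silhouette_score(d.to_numpy(), labels.to_numpy(), metric="precomputed"))


def find_k(d: pd.DataFrame, tree: Dendrogram, k_max: int | None = None):
    """Choose k in 2..k_max maximizing mean silhouette width; ties go to smaller k.

    Returns ``(k, sweep)`` where ``sweep`` is a Series of mean silhouette
    widths indexed by candidate k (NaN when the cut degenerates to fewer
    groups than requested).
    """
    n = tree.n
    if k_max is None:
        k_max = min(20, n - 1)
    if not (2 <= k_max <= n - 1):
        raise ValueError(f"k_max must be in 2..{n - 1}, got {k_max}")
    if np.allclose(d.to_numpy(), 0.0):
        raise ValueError("all samples are identical; silhouette is undefined")
    scores: dict[int, float] = {}
    best_k, best_score = None, -np.inf
    for k in range(2, k_max + 1):
        assignment = cut_clusters(tree, k)
        if assignment.k < 2 or assignment.k < k:
            scores[k] = float("nan")
            continue
        score = mean_silhouette(d, assignment.labels)
        scores[k] = score
        if score > best_score:  # strict: ties keep the smaller k
            best_k, best_score = k, score
    if best_k is None:
        raise ValueError("no candidate k produced a valid partition")
    return best_k, pd.Series(scores, name="mean_silhouette").rename_axis("k")


def to_newick(tree: Dendrogram) -> str:
    """Render the dendrogram as a Newick string with merge heights as branch lengths."""
    n = tree.n
    heights = {i: 0.0 for i in range(n)}
    texts = {i: str(tree.sample_ids[i]) for i in range(n)}
    for idx, (left, right, height, _) in enumerate(tree.merges):
        left, right = int(left), int(right)
        node = n + idx
        lt = f"{texts[left]}:{height - heights[left]:.6g}"
        rt = f"{texts[right]}:{height - heights[right]:.6g}"
        texts[node] = f"({lt},{rt})"
        heights[node] = float(height)
    return texts[n + len(tree.merges) - 1] + ";"
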