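"""Species ordination over 59-codon usage profiles.

Each species is a row of 59 synonymous-codon relative frequencies (codon count
over total SC count) or RSCU values. Two complementary views are produced:

* hierarchical clustering with average linkage on the correlation distance
  d(i, j) = 1 - Pearson r(row_i, row_j), exportable as newick;
* covariance PCA (column-centred; a correlation-PCA flag standardises columns)
  reporting per-species scores on the first principal components and the
  explained-variance fractions.

PC signs are fixed so the loading of largest magnitude on each component is
positive, making score plots reproducible; any claim about species separation
should nevertheless be phrased sign-invariantly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .codon_metrics import SC_CODONS, ScubProfile


def species_matrix(profiles: dict[str, ScubProfile],
                   mode: str = "frequency") -> pd.DataFrame:
    """Assemble the species x 59-codon matrix from SCUB profiles.

    ``mode='frequency'`` uses each SC's share of the total SC count (rows sum
    to 1); ``mode='rscu'`` uses RSCU values. Codon columns are sorted
    lexicographically.
    """
    codons = sorted(SC_CODONS)
    rows = {}
    for name, prof in profiles.items():
        if mode == "frequency":
            total = sum(prof.per_codon_freq.values())
            rows[name] = [prof.per_codon_freq[c] / total for c in codons]
        elif mode == "rscu":
            if any(prof.rscu[c] is None for c in codons):
                raise ValueError(f"{name}: RSCU undefined for some family")
            rows[name] = [prof.rscu[c] for c in codons]
        else:
            raise ValueError(f"unknown matrix mode {mode!r}")
    return pd.DataFrame.from_dict(rows, orient="index", columns=codons)


def correlation_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson r between species rows; zero diagonal."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least two species")
    values = matrix.to_numpy(dtype=float)
    if (values.std(axis=1) == 0).any():
        bad = matrix.index[values.std(axis=1) == 0][0]
        raise ValueError(f"zero-variance row: {bad}")
    dist = 1.0 - np.corrcoef(values)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


class Dendrogram:
    """Average-linkage merge tree over a correlation-distance matrix."""

    def __init__(self, linkage_matrix: np.ndarray, labels: list[str]):
        self.linkage_matrix = linkage_matrix
        self.labels = list(labels)

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster membership (labels -> 1-based cluster id)."""
        assignment = hierarchy.fcluster(
            self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree)


def average_linkage(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA-style agglomeration of a symmetric distance matrix.

    Deterministic: scipy merges the lowest-index closest pair first.
    """
    arr = dist.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix is not symmetric")
    condensed = squareform(arr, checks=False)
    linkage_matrix = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage_matrix, list(dist.index))


def pca_scores(
    matrix: pd.DataFrame, n_components: int = 3, standardize: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal component scores per species plus explained-variance fractions.

    Column-centred PCA via SVD; ``standardize`` divides columns by their
    standard deviation first (correlation PCA). If the requested number of
    components exceeds the matrix rank the output is truncated with a warning.
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA needs at least three species rows")
    values = matrix.to_numpy(dtype=float)
    centred = values - values.mean(axis=0)
    if standardize:
        sd = centred.std(axis=0, ddof=1)
        centred = centred / np.where(sd == 0, 1.0, sd)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2)
        n_components = rank
    # sign convention: largest-magnitude loading positive on each component
    for j in range(n_components):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :n_components] * s[:n_components]
    variances = s ** 2 / (matrix.shape[0] - 1)
    explained = variances[:n_components] / variances.sum()
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), explained
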