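"""Earth Mover's Distance matrices and tree clustering of MMS distributions.

The similarity between two participants' micro-movement spike
distributions is the first-order Wasserstein (Earth Mover's) distance
between the empirical distributions; in one dimension this equals the
integrated absolute difference of the empirical CDFs.  Pairwise matrices
over (participant, region) keys are clustered with agglomerative
hierarchical clustering (average linkage) on the precomputed distances,
and the dendrogram is cut into the requested number of subtypes, each
reported with its group composition.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import wasserstein_distance

from facemms import errors


@dataclasses.dataclass
class EMDMatrix:
    labels: list
    matrix: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise errors.DomainError("matrix/label shape mismatch")
        if not np.allclose(m, m.T):
            raise errors.DomainError("EMD matrix must be symmetric")
        if np.any(np.diag(m) != 0) or np.any(m < 0):
            raise errors.DomainError("EMD matrix must be a distance matrix")

    def to_frame(self) -> pd.DataFrame:
        names = ["|".join(map(str, l)) if isinstance(l, tuple) else str(l)
                 for l in self.labels]
        df = pd.DataFrame(self.matrix, index=names, columns=names)
        df.index.name = "key"
        return df


@dataclasses.dataclass
class ClusterReport:
    k: int
    labels: list
    leaf_assignment: np.ndarray  # leaf id per row, 1..k
    composition: dict[int, dict[str, float]]  # leaf -> group -> percent
    linkage: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        names = ["|".join(map(str, l)) if isinstance(l, tuple) else str(l)
                 for l in self.labels]
        return pd.DataFrame({"key": names, "leaf": self.leaf_assignment})


def emd_1d(samples_a: np.ndarray, samples_b: np.ndarray) -> float:
    """1-D Earth Mover's Distance between two empirical distributions.

    Equal weight per sample; equals the L1 distance between empirical CDFs.
    """
    samples_a = np.asarray(samples_a, dtype=float)
    samples_b = np.asarray(samples_b, dtype=float)
    if samples_a.size == 0 or samples_b.size == 0:
        raise errors.DomainError("EMD requires non-empty sample sets")
    return float(wasserstein_distance(samples_a, samples_b))


def pairwise_emd(
    cohort: dict, normalize: bool = False
) -> EMDMatrix:
    """Symmetric EMD matrix over MMS peak sets keyed by (participant, ..., region).

    Keys with empty peak sets are excluded with a warning.  With
    ``normalize``, entries are divided by the maximum off-diagonal
    distance, mapping the matrix into [0, 1].
    """
    keys = []
    for key in cohort:
        if np.asarray(cohort[key]).size == 0:
            warnings.warn(f"excluding empty MMS peak set {key}")
            continue
        keys.append(key)
    if len(keys) < 2:
        raise errors.InsufficientDataError("need >= 2 non-empty peak sets")
    n = len(keys)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = emd_1d(cohort[keys[i]], cohort[keys[j]])
    if normalize:
        top = m.max()
        if top > 0:
            m = m / top
    return EMDMatrix(labels=keys, matrix=m, normalized=normalize)


def tree_cluster(
    matrix: EMDMatrix, k: int, labels: list[str]
) -> ClusterReport:
    """Cut an average-linkage tree of the EMD matrix into k subtype leaves.

    ``labels`` gives the group label of each matrix row; the report lists,
    per leaf, the percentage of rows from each group.
    """
    n = matrix.matrix.shape[0]
    if k < 2 or k > n:
        raise errors.DomainError(f"k={k} outside [2, {n}]")
    if len(labels) != n:
        raise errors.DomainError("one group label per matrix row required")
    condensed = squareform(matrix.matrix, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    assignment = hierarchy.fcluster(link, t=k, criterion="maxclust")
    composition: dict[int, dict[str, float]] = {}
    for leaf in np.unique(assignment):
        members = [labels[i] for i in np.flatnonzero(assignment == leaf)]
        counts = pd.Series(members).value_counts()
        composition[int(leaf)] = {
            str(g): 100.0 * c / len(members) for g, c in counts.items()
        }
    return ClusterReport(
        k=k,
        labels=list(matrix.labels),
        leaf_assignment=assignment,
        composition=composition,
        linkage=link,
    )
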