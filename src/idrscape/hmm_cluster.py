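"""Average-linkage clustering of protein families from HMM-HMM probabilities.

Profile-HMM versus profile-HMM comparison tools report, for each ordered pair
of families (i, j), the probability p_ij that the two are homologous.  The
matrix of those probabilities is converted to a dissimilarity matrix
D_ij = -ln p_ij, with probabilities below a floor of 0.001 raised to the
floor so that the logarithm stays finite, directed entries symmetrized by
their arithmetic mean, and the diagonal forced to zero.  The families are
then agglomerated by average linkage (UPGMA-style: repeatedly merge the
cluster pair with the smallest mean pairwise dissimilarity, the merge height
being that mean) and the resulting dendrogram can be exported as Newick or a
plain merge table.

The log base is natural; any other base rescales all heights uniformly and
cannot change the topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: Probabilities below this are raised to it before taking the log.
PROBABILITY_FLOOR = 0.001


@dataclass
class ProbabilityMatrix:
    """Square matrix of pairwise match probabilities in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"probability matrix must be square, got {self.values.shape}")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class DissimilarityMatrix:
    """Symmetric non-negative matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        # NaN entries are tolerated here and rejected at clustering time
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("dissimilarity matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("dissimilarity diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if (v < 0).any():
                raise ValueError("dissimilarities must be non-negative")


@dataclass
class Dendrogram:
    """Binary merge tree in SciPy linkage form, with leaf labels.

    ``Z`` rows are (left, right, height, size); indices < n are leaves.
    """

    labels: list[str]
    Z: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def merge_members(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """Per merge step, the two clusters (as label sets) and the height."""
        n = self.n_leaves
        members: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        for step, (a, b, h, _) in enumerate(self.Z):
            left, right = members[int(a)], members[int(b)]
            out.append((left, right, float(h)))
            members[n + step] = left | right
        return out

    def merge_table(self) -> pd.DataFrame:
        rows = [
            {"step": i, "members": ",".join(sorted(l | r)), "height": h}
            for i, (l, r, h) in enumerate(self.merge_members())
        ]
        return pd.DataFrame(rows)

    def cut(self, height: float) -> dict[str, int]:
        """Flat cluster assignment cutting all links above ``height``."""
        flat = fcluster(self.Z, t=height, criterion="distance")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def cophenetic(self) -> DissimilarityMatrix:
        """Cophenetic distances (height of the lowest common ancestor)."""
        coph = squareform(cophenet(self.Z))
        return DissimilarityMatrix(self.labels, coph)


def read_probability_matrix(path: str | Path) -> ProbabilityMatrix:
    """Read a square labelled TSV/CSV probability matrix.

    Values greater than 1 anywhere are taken to be percentages and the whole
    matrix is rescaled by 1/100 (logged).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy(dtype=float)
    if (values > 1).any():
        logger.info("matrix values exceed 1; interpreting as percentages (/100)")
        values = values / 100.0
    return ProbabilityMatrix([str(c) for c in df.columns], values)


def to_dissimilarity(P: ProbabilityMatrix, *,
                     floor: float = PROBABILITY_FLOOR,
                     floor_mode: Literal["all", "zeros_only"] = "all",
                     symmetrize: Literal["mean", "max"] = "mean"
                     ) -> DissimilarityMatrix:
    """Convert match probabilities to -log dissimilarities.

    ``floor_mode="all"`` raises every probability below the floor to the
    floor, keeping D monotone in p; ``"zeros_only"`` substitutes the floor
    only for exact zeros.  Directed entries are symmetrized by their mean
    (or elementwise max probability-dissimilarity-wise min with ``"max"``);
    the diagonal is forced to zero.
    """
    p = P.values.copy()
    if floor_mode == "all":
        p = np.maximum(p, floor)
    elif floor_mode == "zeros_only":
        p[p == 0.0] = floor
    else:
        raise ValueError(f"unknown floor_mode {floor_mode!r}")
    D = -np.log(p)
    if symmetrize == "mean":
        D = 0.5 * (D + D.T)
    elif symmetrize == "max":
        # keep the stronger (higher-probability, lower-D) directed evidence
        D = np.minimum(D, D.T)
    else:
        raise ValueError(f"unknown symmetrize mode {symmetrize!r}")
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(P.labels, D)


def average_linkage(D: DissimilarityMatrix) -> Dendrogram:
    """UPGMA-style agglomeration on a dissimilarity matrix.

    At each step the pair of clusters with the minimal mean pairwise
    dissimilarity is merged, the merge height being that mean.  Merge heights
    are non-decreasing in merge order (average linkage cannot invert).
    """
    if len(D.labels) < 2:
        raise ValueError("need at least two items to cluster")
    if np.isnan(D.values).any():
        raise ValueError("dissimilarity matrix contains NaN")
    Z = linkage(squareform(D.values, checks=False), method="average")
    return Dendrogram(list(D.labels), Z)


def to_newick(tree: Dendrogram, decimals: int = 6) -> str:
    """Newick export: branch length = parent height - child height; leaves at 0."""
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for step, (_, _, h, _) in enumerate(tree.Z):
        heights[n + step] = float(h)

    def render(node: int, parent_height: float) -> str:
        bl = parent_height - heights[node]
        if node < n:
            return f"{tree.labels[node]}:{bl:.{decimals}g}"
        a, b = int(tree.Z[node - n, 0]), int(tree.Z[node - n, 1])
        h = heights[node]
        return f"({render(a, h)},{render(b, h)}):{bl:.{decimals}g}"

    root = n + len(tree.Z) - 1
    a, b = int(tree.Z[-1, 0]), int(tree.Z[-1, 1])
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"


def cluster_probabilities(P: ProbabilityMatrix, **kwargs) -> Dendrogram:
    """Convenience: probability matrix -> dissimilarity -> dendrogram."""
    return average_linkage(to_dissimilarity(P, **kwargs))
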