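"""Ordination (PCoA) and average-linkage (UPGMA) views of a distance matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .panel import DistanceMatrix


@dataclass
class PCoAResult:
    """Principal-coordinate axes ordered by eigenvalue.

    ``coordinates`` contains one column per positive-eigenvalue axis;
    ``eigenvalues`` reports the full spectrum including negative values
    (which arise from non-Euclidean distances and are not silently dropped);
    ``pct_variance`` is λᵢ / Σλ⁺ over the positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    pct_variance: np.ndarray

    def to_csv(self, path) -> None:
        out = self.coordinates.copy()
        header = ", ".join(
            f"Axis{i + 1} {v:.2f}%" for i, v in enumerate(self.pct_variance))
        with open(path, "w") as fh:
            fh.write(f"# % variance per axis: {header}\n")
            out.to_csv(fh)


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Classical multidimensional scaling via Gower double-centering.

    Requires a complete symmetric matrix; undefined entries must first be
    resolved by an imputation or pairwise-deletion policy upstream.
    """
    d = dist.d
    if np.isnan(d).any():
        raise ValueError(
            "distance matrix has undefined entries; impute or drop samples "
            "(pairs with zero co-called loci) before ordination")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pct = 100 * eigvals[pos] / eigvals[pos].sum()
    frame = pd.DataFrame(
        coords, index=dist.ids,
        columns=[f"Axis{i + 1}" for i in range(int(pos.sum()))])
    return PCoAResult(coordinates=frame, eigenvalues=eigvals, pct_variance=pct)


def upgma_linkage(dist: DistanceMatrix) -> np.ndarray:
    """Average-linkage merge table for the distance matrix (scipy format)."""
    d = dist.d
    if np.isnan(d).any():
        raise ValueError("distance matrix has undefined entries")
    if d.shape[0] < 2:
        raise ValueError("UPGMA needs at least 2 samples")
    return linkage(squareform(d, checks=False), method="average")


def upgma_newick(dist: DistanceMatrix) -> str:
    """Ultrametric UPGMA tree in newick with branch lengths.

    A node created at merge height h sits at ultrametric depth h/2, so every
    root-to-leaf path has the same length.  Input order determines the
    deterministic tie-break, making the output byte-stable for a fixed
    matrix.
    """
    z = upgma_linkage(dist)
    ids = list(dist.ids)
    n = len(ids)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: ids[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        node = n + k
        depth = h / 2.0
        la = depth - heights[a]
        lb = depth - heights[b]
        newick[node] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        heights[node] = depth
    return newick[n + len(z) - 1] + ";"
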