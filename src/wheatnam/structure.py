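"""Population structure: marker skimming and principal coordinate
analysis (classical metric multidimensional scaling)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .core import GenotypeMatrix


def skim_markers(
    dosages: pd.DataFrame,
    r_abs_threshold: float = 0.8,
    marker_order: list[str] | None = None,
) -> list[str]:
    """Prune one member of every marker pair with |r| >= threshold.

    Greedy left-to-right scan in map order (``marker_order``; defaults
    to column order): a marker is kept iff its absolute Pearson
    correlation with every already-retained marker is below the
    threshold, so the first-seen member of each correlated pair wins.
    The retained set has all pairwise |r| < threshold.
    """
    if not 0 < r_abs_threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = marker_order if marker_order is not None else list(dosages.columns)
    X = dosages[order].to_numpy(dtype=float)
    # mean-fill so the scan tolerates missing calls
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X = X - X.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))
    retained: list[int] = []
    for j in range(X.shape[1]):
        if norms[j] == 0:
            retained.append(j)  # constant marker correlates with nothing
            continue
        if retained:
            prev = np.array([k for k in retained if norms[k] > 0], dtype=int)
            if len(prev):
                r = (X[:, prev].T @ X[:, j]) / (norms[prev] * norms[j])
                if np.any(np.abs(r) >= r_abs_threshold - 1e-12):
                    continue
        retained.append(j)
    return [order[j] for j in retained]


def pcoa(
    data: GenotypeMatrix | pd.DataFrame,
    n_axes: int = 10,
    metric: str = "euclidean",
):
    """Classical PCoA of genotypes from dosages or a distance matrix.

    ``data`` may be a genotype matrix (distances computed on dosages;
    ``metric`` is ``euclidean`` or ``matching`` for simple mismatch
    proportion) or a precomputed square symmetric distance DataFrame.
    Negative eigenvalues are truncated to zero for the
    percent-variance denominator. Returns the skbio ``OrdinationResults``
    with ``samples`` (coordinates), ``eigvals`` and
    ``proportion_explained``.
    """
    if isinstance(data, GenotypeMatrix):
        data = data.dosages
    arr = data.to_numpy(dtype=float)
    if arr.shape[0] == arr.shape[1] and np.allclose(np.diag(arr), 0) and data.index.equals(
        data.columns
    ):
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        dm = DistanceMatrix(arr, ids=[str(i) for i in data.index])
    else:
        if arr.shape[0] < 2:
            raise ValueError("need >= 2 genotypes")
        filled = arr.copy()
        mu = np.nanmean(filled, axis=0)
        inds = np.where(np.isnan(filled))
        filled[inds] = np.take(mu, inds[1])
        if metric == "euclidean":
            d = pdist(filled, metric="euclidean")
        elif metric == "matching":
            d = pdist(filled, metric="hamming")
        else:
            raise ValueError(f"unknown metric {metric!r}")
        dm = DistanceMatrix(squareform(d), ids=[str(i) for i in data.index])
    res = _skbio_pcoa(dm, number_of_dimensions=min(n_axes, len(dm.ids) - 1))
    return res


def d_subgenome_markers(mmap: pd.DataFrame) -> list[str]:
    """Markers placed on the D sub-genome (chromosomes 1D..7D)."""
    placed = mmap[mmap["chrom"].notna()]
    return placed.index[placed["chrom"].astype(str).str.endswith("D")].tolist()
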