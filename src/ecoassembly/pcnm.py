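"""Spatial eigenfunctions by principal coordinates of neighbor matrices (PCNM).

PCNM variables are the positive-eigenvalue eigenvectors of the
double-centered (Gower) matrix of a truncated geographic distance matrix:
distances above a truncation threshold are replaced by four times the
threshold, so that eigenvectors describe spatial structure at scales from
the full extent (PCNM1) down to the neighborhood scale. The classical
truncation threshold is the longest edge of the Euclidean minimum spanning
tree of the plots, the smallest value keeping the neighbor graph connected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from ecoassembly.data import PlotCoordinates, ValidationError

#: eigenvalues below this fraction of the largest are treated as numerically zero
DEFAULT_TOLERANCE = 1e-9


@dataclass(frozen=True)
class SpatialEigenfunctions:
    """Retained PCNM variables, ordered by descending eigenvalue.

    ``eigenvectors`` has one unit-norm column per retained (positive)
    eigenvalue, named PCNM1, PCNM2, ... The sign of each column is fixed so
    that its largest-magnitude loading is positive, making results
    reproducible across linear-algebra backends.
    """

    plot_ids: tuple
    eigenvalues: np.ndarray
    eigenvectors: pd.DataFrame
    truncation_distance: float

    @property
    def n_retained(self) -> int:
        return len(self.eigenvalues)

    def to_frame(self) -> pd.DataFrame:
        return self.eigenvectors


def truncation_distance(coords: PlotCoordinates) -> float:
    """Longest edge of the Euclidean minimum spanning tree of the plots."""
    if coords.n_plots < 3:
        raise ValidationError("need at least 3 plots")
    d = squareform(pdist(coords.as_array()))
    if d.max() == 0:
        raise ValidationError("all plots coincide; truncation distance undefined")
    mst = minimum_spanning_tree(d)
    return float(mst.toarray().max())


def build_pcnm(
    coords: PlotCoordinates,
    truncation: float | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> SpatialEigenfunctions:
    """Construct PCNM spatial variables from plot coordinates.

    Distances greater than ``truncation`` (default: longest MST edge) are
    replaced by ``4 * truncation``; the truncated matrix is double-centered
    and eigendecomposed; eigenvectors with eigenvalue greater than
    ``tolerance`` times the largest eigenvalue are retained. The construction
    is deterministic: no randomness, fixed sign convention.
    """
    n = coords.n_plots
    if n < 3:
        raise ValidationError("need at least 3 plots")
    d = squareform(pdist(coords.as_array()))
    max_mst_edge = truncation_distance(coords)
    if truncation is None:
        truncation = max_mst_edge
    elif truncation < max_mst_edge:
        import warnings

        warnings.warn(
            f"truncation {truncation:g} m is below the longest MST edge "
            f"({max_mst_edge:g} m); the neighbor graph is disconnected",
            stacklevel=2,
        )
    dt = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(dt, 0.0)
    # Gower double-centering of -0.5 * D^2
    a = -0.5 * dt**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > tolerance * eigval[0]
    if not keep.any() or eigval[0] <= 0:
        raise ValidationError("no positive eigenvalues; degenerate configuration")
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    # sign convention: largest-magnitude loading positive (ties -> first index)
    for k in range(eigvec.shape[1]):
        j = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    names = [f"PCNM{i + 1}" for i in range(eigvec.shape[1])]
    frame = pd.DataFrame(eigvec, index=list(coords.plot_ids), columns=names)
    return SpatialEigenfunctions(
        plot_ids=tuple(coords.plot_ids),
        eigenvalues=eigval,
        eigenvectors=frame,
        truncation_distance=float(truncation),
    )


def write_pcnm_table(sef: SpatialEigenfunctions, path, delimiter: str = ",") -> None:
    sef.eigenvectors.to_csv(path, sep=delimiter, index_label="plot")
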