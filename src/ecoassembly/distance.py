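"""Distance matrices: Bray-Curtis community dissimilarity and Euclidean
environmental / geographical distances."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ecoassembly.data import CommunityMatrix, PlotCoordinates, ValidationError

KINDS = ("bray_curtis", "euclidean", "deviation")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric plot x plot dissimilarity matrix.

    ``kind`` records the metric: ``bray_curtis`` (community dissimilarity in
    [0, 1]), ``euclidean`` (environmental or geographic distance), or
    ``deviation`` (per-pair standardized turnover deviation, which may be
    negative and may contain NaN for pairs with a degenerate null SD).
    """

    plot_ids: tuple
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "plot_ids", tuple(self.plot_ids))
        if self.kind not in KINDS:
            raise ValidationError(f"unknown distance kind {self.kind!r}")
        n = len(self.plot_ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.T)) if n else 0.0
        if asym > 1e-12:
            raise ValidationError(f"distance matrix asymmetric by {asym:g}")
        if self.kind == "bray_curtis":
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValidationError("Bray-Curtis entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.plot_ids)

    @property
    def condensed(self) -> np.ndarray:
        return condensed_form(self)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.plot_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


def bray_curtis(comm: CommunityMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between plots.

    BC(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik); 0 for identical
    plots, 1 for plots sharing no abundance. Invariant to multiplying all
    abundances by a positive constant.
    """
    x = comm.counts.to_numpy(dtype=float)
    if np.any(x.sum(axis=1) == 0):
        raise ValidationError("Bray-Curtis undefined for all-zero plot rows")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(tuple(comm.plot_ids), d, "bray_curtis")


def euclidean_distance(table, plot_ids: Sequence | None = None) -> DistanceMatrix:
    """Euclidean distance between rows of a plot x variable table.

    Accepts a pandas DataFrame (plot ids taken from the index), a
    :class:`PlotCoordinates`, or a bare array plus explicit ``plot_ids``.
    """
    if isinstance(table, PlotCoordinates):
        ids = table.plot_ids
        x = table.as_array()
    elif isinstance(table, pd.DataFrame):
        ids = tuple(table.index)
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        ids = tuple(plot_ids) if plot_ids is not None else tuple(range(x.shape[0]))
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(ids, d, "euclidean")


def condensed_form(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Upper-triangle (row-major) vector of length n(n-1)/2."""
    v = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def from_condensed(vec: np.ndarray, plot_ids: Sequence, kind: str) -> DistanceMatrix:
    """Inverse of :func:`condensed_form`."""
    n = len(plot_ids)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n * (n - 1) // 2,):
        raise ValidationError(f"condensed length {vec.shape[0]} != n(n-1)/2 for n={n}")
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return DistanceMatrix(tuple(plot_ids), out, kind)


def write_distance_matrix(d: DistanceMatrix, path, delimiter: str = ",") -> None:
    d.to_frame().to_csv(path, sep=delimiter, index_label="plot")


def read_distance_matrix(path, kind: str, delimiter: str | None = None) -> DistanceMatrix:
    kwargs = {"index_col": 0}
    if delimiter is None:
        kwargs.update(sep=None, engine="python")
    else:
        kwargs.update(sep=delimiter)
    frame = pd.read_csv(path, **kwargs)
    return DistanceMatrix(tuple(frame.index), frame.to_numpy(dtype=float), kind)
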