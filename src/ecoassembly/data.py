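"""Community, environment and coordinate tables: reading, validation, pooling
and the standard pre-analysis transforms.

All tabular inputs are delimited text (CSV/TSV) with a header row and plot
identifiers in the first column. Community tables hold non-negative integer
abundances (individuals); environment tables hold real-valued measurements in
mixed units; coordinate tables hold either planar meters or lon/lat degrees
(converted to planar meters on read).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Iterable, what: str) -> None:
    ids = list(ids)
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class CommunityMatrix:
    """Plot x species abundance matrix of individual counts.

    ``counts`` is a pandas DataFrame with plot identifiers as the index and
    species identifiers as the columns; entries are non-negative integers.
    Column sums are the regional species-pool abundances; row sums are the
    per-plot individual totals.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        _check_unique(c.index, "plot")
        _check_unique(c.columns, "species")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("abundances must be integers (individual counts)")
            object.__setattr__(self, "counts", c.astype(np.int64))
            values = self.counts.to_numpy()
        neg = np.argwhere(values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative abundance at plot {c.index[i]!r}, species {c.columns[j]!r}"
            )
        empty_plots = np.flatnonzero(values.sum(axis=1) == 0)
        if empty_plots.size:
            raise ValidationError(
                f"plot {c.index[empty_plots[0]]!r} has no individuals; "
                "all-zero plot rows are rejected"
            )

    @property
    def plot_ids(self) -> list:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def plot_totals(self) -> np.ndarray:
        """Total individuals per plot (N_j, row sums)."""
        return self.counts.to_numpy().sum(axis=1)

    @property
    def species_totals(self) -> np.ndarray:
        """Regional-pool abundance per species (column sums)."""
        return self.counts.to_numpy().sum(axis=0)

    @property
    def n_plots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    def drop_absent_species(self) -> "CommunityMatrix":
        """Remove species with zero total abundance (undefined under the pool)."""
        totals = self.counts.sum(axis=0)
        absent = totals.index[totals == 0]
        if len(absent):
            logger.warning(
                "dropping %d species absent from all plots: %s",
                len(absent),
                ", ".join(map(str, absent[:10])),
            )
            return CommunityMatrix(self.counts.drop(columns=absent))
        return self


@dataclass(frozen=True)
class EnvironmentTable:
    """Plot x variable table of real-valued environmental measurements."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "plot")
        _check_unique(self.values.columns, "variable")
        v = self.values
        if v.isna().any().any():
            col = v.columns[v.isna().any().to_numpy()][0]
            raise ValidationError(f"missing values in variable {col!r}; imputation is not supported")
        object.__setattr__(self, "values", v.astype(float))

    @property
    def plot_ids(self) -> list:
        return list(self.values.index)

    @property
    def variable_names(self) -> list:
        return list(self.values.columns)


@dataclass(frozen=True)
class PlotCoordinates:
    """Planar plot coordinates in meters."""

    plot_ids: tuple
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.plot_ids, "plot")
        object.__setattr__(self, "plot_ids", tuple(self.plot_ids))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValidationError("non-finite coordinates")
        if len(self.plot_ids) != len(self.x) or len(self.x) != len(self.y):
            raise ValidationError("coordinate arrays and plot ids differ in length")

    @classmethod
    def from_lonlat(cls, plot_ids, lon, lat) -> "PlotCoordinates":
        """Project lon/lat degrees to planar meters.

        Uses an equirectangular projection at the mean latitude; the error is
        negligible at the tens-of-kilometers extents this package targets.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lat0 = math.radians(float(np.mean(lat)))
        x = np.radians(lon) * EARTH_RADIUS_M * math.cos(lat0)
        y = np.radians(lat) * EARTH_RADIUS_M
        return cls(tuple(plot_ids), x - x.min(), y - y.min())

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)


@dataclass(frozen=True)
class SubplotMap:
    """Assignment of subplot identifiers to the plot they belong to."""

    assignment: Mapping

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))

    def plot_of(self, subplot_id):
        try:
            return self.assignment[subplot_id]
        except KeyError:
            raise ValidationError(f"subplot {subplot_id!r} is not mapped to any plot") from None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_delimited(path, delimiter: str | None) -> pd.DataFrame:
    kwargs = {"index_col": 0}
    if delimiter is None:
        kwargs.update(sep=None, engine="python")
    else:
        kwargs.update(sep=delimiter)
    frame = pd.read_csv(path, **kwargs)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"duplicate plot identifier: {dup!r}")
    return frame


def read_community_table(path, delimiter: str | None = None) -> CommunityMatrix:
    """Read a plot x species abundance table.

    Species columns whose total abundance is zero are dropped with a logged
    warning: they carry no information and are undefined under the
    species-pool null model.
    """
    frame = _read_delimited(path, delimiter)
    return CommunityMatrix(frame).drop_absent_species()


def write_community_table(comm: CommunityMatrix, path, delimiter: str = ",") -> None:
    comm.counts.to_csv(path, sep=delimiter, index_label="plot")


def read_environment_table(path, delimiter: str | None = None) -> EnvironmentTable:
    return EnvironmentTable(_read_delimited(path, delimiter))


def write_environment_table(env: EnvironmentTable, path, delimiter: str = ",") -> None:
    env.values.to_csv(path, sep=delimiter, index_label="plot")


def read_coordinates(path, delimiter: str | None = None, lonlat: bool = False) -> PlotCoordinates:
    """Read plot coordinates; columns x,y (meters) or lon,lat (degrees)."""
    frame = _read_delimited(path, delimiter)
    cols = [c.lower() for c in frame.columns]
    if lonlat:
        lon = frame.iloc[:, cols.index("lon")] if "lon" in cols else frame.iloc[:, 0]
        lat = frame.iloc[:, cols.index("lat")] if "lat" in cols else frame.iloc[:, 1]
        return PlotCoordinates.from_lonlat(frame.index, lon.to_numpy(), lat.to_numpy())
    x = frame.iloc[:, cols.index("x")] if "x" in cols else frame.iloc[:, 0]
    y = frame.iloc[:, cols.index("y")] if "y" in cols else frame.iloc[:, 1]
    return PlotCoordinates(tuple(frame.index), x.to_numpy(), y.to_numpy())


def write_coordinates(coords: PlotCoordinates, path, delimiter: str = ",") -> None:
    pd.DataFrame({"x": coords.x, "y": coords.y}, index=list(coords.plot_ids)).to_csv(
        path, sep=delimiter, index_label="plot"
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def pool_subplots(subplots: CommunityMatrix, mapping: SubplotMap) -> CommunityMatrix:
    """Sum subplot rows into plot rows; total abundance is conserved exactly."""
    plots = [mapping.plot_of(s) for s in subplots.plot_ids]
    pooled = subplots.counts.groupby(pd.Index(plots, name="plot"), sort=False).sum()
    return CommunityMatrix(pooled)


def circularize_aspect(aspect_degrees) -> tuple[np.ndarray, np.ndarray]:
    """Split a circular aspect variable (degrees in [0, 360)) into sin and cos.

    Slope aspect is circular (0 == 360), so it enters linear models as the
    pair sin(aspect), cos(aspect).
    """
    a = np.asarray(aspect_degrees, dtype=float)
    if np.any((a < 0) | (a >= 360)):
        bad = a[(a < 0) | (a >= 360)][0]
        raise ValidationError(f"aspect {bad} outside [0, 360)")
    rad = np.radians(a)
    return np.sin(rad), np.cos(rad)


def zscore_standardize(env: EnvironmentTable) -> EnvironmentTable:
    """Center each variable to mean 0 and scale to sample SD 1 (divisor n-1)."""
    v = env.values
    sd = v.std(axis=0, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        raise ValidationError(f"variable {constant[0]!r} is constant; cannot standardize")
    return EnvironmentTable((v - v.mean(axis=0)) / sd)


def hellinger_transform(comm: CommunityMatrix) -> pd.DataFrame:
    """Square root of per-plot relative abundance.

    Each output row has unit sum of squares; Euclidean distances on the
    transformed matrix correspond to Hellinger distances, making the matrix
    suitable as the response in RDA.
    """
    counts = comm.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValidationError("all-zero plot row; Hellinger transform undefined")
    return pd.DataFrame(
        np.sqrt(counts / totals), index=comm.counts.index, columns=comm.counts.columns
    )


def collinearity_filter(
    env: EnvironmentTable, r_threshold: float = 0.80
) -> tuple[EnvironmentTable, list[tuple[str, str, float]]]:
    """Greedily remove variables until no pair has |Pearson r| > ``r_threshold``.

    At each pass the variable with the largest mean absolute correlation to
    all remaining variables, among those involved in a violating pair, is
    dropped (ties broken by column order). Returns the filtered table and a
    list of ``(dropped, partner, r)`` records, where ``partner`` is the
    remaining variable it was most strongly correlated with.
    """
    frame = env.values.copy()
    if frame.shape[1] < 2 or frame.shape[0] < 3:
        raise ValidationError("collinearity filter needs >=2 variables and >=3 plots")
    dropped: list[tuple[str, str, float]] = []
    while True:
        corr = frame.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        viol = np.abs(corr) > r_threshold
        if not viol.any():
            break
        involved = np.flatnonzero(viol.any(axis=0))
        mean_abs = np.abs(corr).mean(axis=0)
        # first index attaining the max among involved -> deterministic tie-break
        worst = involved[int(np.argmax(mean_abs[involved]))]
        partner = int(np.argmax(np.abs(corr[worst])))
        dropped.append(
            (str(frame.columns[worst]), str(frame.columns[partner]), float(corr[worst, partner]))
        )
        frame = frame.drop(columns=frame.columns[worst])
        if frame.shape[1] < 2:
            break
    return EnvironmentTable(frame), dropped


def align(
    comm: CommunityMatrix,
    env: EnvironmentTable | None = None,
    coords: PlotCoordinates | None = None,
):
    """Check that environment and coordinates cover the community's plots, and
    reindex them to the community's plot order. Returns the aligned objects."""
    ids = comm.plot_ids
    out = [comm]
    if env is not None:
        missing = set(ids) - set(env.plot_ids)
        if missing:
            raise ValidationError(f"environment table missing plots: {sorted(missing)[:5]}")
        out.append(EnvironmentTable(env.values.loc[ids]))
    if coords is not None:
        missing = set(ids) - set(coords.plot_ids)
        if missing:
            raise ValidationError(f"coordinates missing plots: {sorted(missing)[:5]}")
        order = [coords.plot_ids.index(i) for i in ids]
        out.append(PlotCoordinates(tuple(ids), coords.x[order], coords.y[order]))
    return tuple(out)
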