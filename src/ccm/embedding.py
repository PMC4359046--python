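"""Time-delay embedding: shadow manifolds reconstructed from single time series.

A scalar time series sampled from a deterministic dynamical system can be
unfolded into a point cloud of lagged-coordinate vectors ("shadow manifold").
By Takens' theorem this reconstruction is, generically, diffeomorphic to the
attractor of the full system, so geometry in the shadow (who is near whom)
carries information about the true underlying states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "TimeSeries",
    "EmbeddingParams",
    "ShadowManifold",
    "DistanceTable",
    "embed",
    "pairwise_distances",
    "thin",
    "min_series_length",
]


@dataclass(frozen=True)
class TimeSeries:
    """A named, equally spaced sequence of real observations.

    Parameters
    ----------
    values : array-like of float
        Ordered observations. Must be finite and of length >= 2.
    name : str
        Variable label used in direction labels and output tables.
    step : float
        Sampling interval in the user's time units. Informational only:
        all lags are expressed in index units.
    """

    values: np.ndarray
    name: str = "x"
    step: float = 1.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if vals.size < 2:
            raise ValueError("TimeSeries needs at least 2 observations")
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                f"TimeSeries {self.name!r} contains missing or non-finite "
                "values; interpolate or filter upstream before loading"
            )
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension E, coordinate lag tau, and causal delay tau_p.

    ``E`` is the number of lagged coordinates per manifold point. ``tau``
    is the lag between successive coordinates (index units, default 1).
    ``tau_p`` is the assumed delay of the causal effect: the manifold
    point at time ``t`` is used to predict the opposing series at
    ``t - tau_p``, so a positive ``tau_p`` means the cause precedes the
    effect.
    """

    E: int
    tau: int = 1
    tau_p: int = 0

    def __post_init__(self) -> None:
        if int(self.E) != self.E or self.E < 2:
            raise ValueError("embedding dimension E must be an integer >= 2")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError("coordinate lag tau must be an integer >= 1")
        if int(self.tau_p) != self.tau_p or self.tau_p < 0:
            raise ValueError("causal delay tau_p must be an integer >= 0")
        object.__setattr__(self, "E", int(self.E))
        object.__setattr__(self, "tau", int(self.tau))
        object.__setattr__(self, "tau_p", int(self.tau_p))


def min_series_length(params: EmbeddingParams) -> int:
    """Minimum series length producing a non-empty embedding."""
    return (params.E - 1) * params.tau + 1


@dataclass(frozen=True)
class ShadowManifold:
    """Lagged-coordinate point cloud with per-point source time indices.

    ``points[i]`` is ``(X(t), X(t - tau), ..., X(t - (E-1) tau))`` where
    ``t = time_index[i]`` is the 0-based index of the point's leading
    (most recent) coordinate in the source series.
    """

    points: np.ndarray
    time_index: np.ndarray
    params: EmbeddingParams
    series_name: str = "x"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        idx = np.asarray(self.time_index, dtype=int)
        if pts.ndim != 2 or pts.shape[0] != idx.size:
            raise ValueError("points and time_index are inconsistent")
        pts.flags.writeable = False
        idx.flags.writeable = False
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "time_index", idx)

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class DistanceTable:
    """Symmetric matrix of pairwise Euclidean distances between manifold points."""

    values: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("distance table must be square")
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)


def embed(series: TimeSeries, params: EmbeddingParams) -> ShadowManifold:
    """Reconstruct the shadow manifold of ``series`` by lagged coordinates.

    The point for time ``t`` is ``(X(t), X(t-tau), ..., X(t-(E-1)tau))``;
    the first valid ``t`` is ``(E-1)*tau`` (0-based), giving
    ``N - (E-1)*tau`` points in increasing time order.

    Examples
    --------
    >>> m = embed(TimeSeries([1, 2, 3, 4]), EmbeddingParams(E=2, tau=1))
    >>> m.points.tolist()
    [[2.0, 1.0], [3.0, 2.0], [4.0, 3.0]]
    """
    n = len(series)
    need = min_series_length(params)
    if n < need:
        raise ValueError(
            f"insufficient length: series {series.name!r} has {n} points but "
            f"E={params.E}, tau={params.tau} requires at least {need}"
        )
    offset = (params.E - 1) * params.tau
    t = np.arange(offset, n)
    # column j holds X(t - j*tau): leading coordinate first
    lags = t[:, None] - params.tau * np.arange(params.E)[None, :]
    return ShadowManifold(
        points=series.values[lags],
        time_index=t,
        params=params,
        series_name=series.name,
    )


def pairwise_distances(manifold: ShadowManifold) -> DistanceTable:
    """All pairwise Euclidean distances between manifold points.

    Computed once per ``(E, tau)`` and reused across library windows and
    causal delays.
    """
    if len(manifold) < 2:
        raise ValueError("need at least 2 manifold points for distances")
    return DistanceTable(values=squareform(pdist(manifold.points, metric="euclidean")))


def thin(series: TimeSeries, k: int) -> TimeSeries:
    """Keep every ``k``-th observation starting from the first.

    The result has ``ceil(N / k)`` points; ``k=1`` is the identity. Used to
    probe how predictive skill degrades as a record is subsampled.
    """
    if int(k) != k or k < 1:
        raise ValueError("thinning factor k must be a positive integer")
    return TimeSeries(
        values=series.values[::k], name=series.name, step=series.step * k
    )
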