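"""Selection of the embedding dimension E and causal delay tau_p.

Both tuning parameters are chosen to maximize cross-validated predictive
skill: the objective for a cell (E, tau_p) is the maximum over the library
grid of the windowed mean rho_ccm (the plateau of the convergence curve).
Cyclic coordinate descent over the two axes is the fast path; exhaustive
evaluation of the full (E, tau_p) surface is the audit path and the input
to the sensitivity heatmaps. The optimal E additionally bounds the
dimensionality of the true causal system through Whitney's embedding
theorem.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .crossmap import min_library_size, window_sweep
from .embedding import EmbeddingParams, TimeSeries, embed, pairwise_distances

__all__ = [
    "ParamGrid",
    "ParamSurface",
    "default_grid",
    "default_lib_sizes",
    "coordinate_descent",
    "full_surface",
    "whitney_bounds",
]

MIN_RECOMMENDED_LENGTH = 25
MIN_LENGTH = 10
MAX_CYCLES = 10


@dataclass(frozen=True)
class ParamGrid:
    """Candidate E and tau_p values plus the library-size policy.

    ``lib_sizes`` may be an explicit ascending list applied (clipped) to
    every cell, or None to generate ~``n_lib_sizes`` sizes per cell, evenly
    spaced from the cell's minimum feasible library up to the full usable
    point count.
    """

    e_values: tuple[int, ...]
    tau_p_values: tuple[int, ...]
    lib_sizes: tuple[int, ...] | None = None
    n_lib_sizes: int = 8

    def __post_init__(self) -> None:
        e = tuple(int(v) for v in self.e_values)
        tp = tuple(int(v) for v in self.tau_p_values)
        if not e or not tp:
            raise ValueError("parameter grid must be non-empty")
        if min(e) < 2 or list(e) != sorted(set(e)):
            raise ValueError("E values must be ascending integers >= 2")
        if min(tp) < 0 or list(tp) != sorted(set(tp)):
            raise ValueError("tau_p values must be ascending integers >= 0")
        object.__setattr__(self, "e_values", e)
        object.__setattr__(self, "tau_p_values", tp)
        if self.lib_sizes is not None:
            object.__setattr__(
                self, "lib_sizes", tuple(sorted(set(int(v) for v in self.lib_sizes)))
            )

    def lib_sizes_for(self, n: int, E: int, tau: int, tau_p: int) -> np.ndarray:
        """Library sizes for one cell, empty if the cell is infeasible."""
        n_points = n - (E - 1) * tau
        usable = n_points - max(0, tau_p - (E - 1) * tau)
        L_lo = max(min_library_size(E), 10)
        if usable < L_lo:
            return np.array([], dtype=int)
        if self.lib_sizes is not None:
            sizes = np.asarray(self.lib_sizes, dtype=int)
            return sizes[(sizes >= min_library_size(E)) & (sizes <= usable)]
        return default_lib_sizes(L_lo, usable, self.n_lib_sizes)


def default_lib_sizes(L_min: int, L_max: int, n: int = 8) -> np.ndarray:
    """~n library sizes spaced evenly from L_min to L_max inclusive."""
    if L_max < L_min:
        return np.array([], dtype=int)
    return np.unique(np.linspace(L_min, L_max, num=n).round().astype(int))


def default_grid(n: int, lib_sizes=None, n_lib_sizes: int = 8) -> ParamGrid:
    """Intelligent default search grid for a series of length ``n``.

    E ranges over 2..min(10, floor(sqrt(n))) and tau_p over
    0..min(10, floor(n/5)); library sizes span each cell's feasible range.
    Records shorter than 25 points draw a warning (the method wants >= ~25
    observations); shorter than 10 are refused outright.
    """
    if n < MIN_LENGTH:
        raise ValueError(
            f"series of length {n} is too short: CCM needs at least "
            f"{MIN_RECOMMENDED_LENGTH} points for reliable inference "
            f"(hard floor {MIN_LENGTH})"
        )
    if n < MIN_RECOMMENDED_LENGTH:
        warnings.warn(
            f"series of length {n} is below the recommended minimum of "
            f"{MIN_RECOMMENDED_LENGTH} points; results will be unreliable",
            UserWarning,
            stacklevel=2,
        )
    e_hi = min(10, math.isqrt(n))
    tp_hi = min(10, n // 5)
    return ParamGrid(
        e_values=tuple(range(2, max(e_hi, 2) + 1)),
        tau_p_values=tuple(range(0, tp_hi + 1)),
        lib_sizes=lib_sizes,
        n_lib_sizes=n_lib_sizes,
    )


@dataclass
class ParamSurface:
    """Max-over-L predictive skill across the (E, tau_p) grid.

    ``values[i, j]`` is the objective at ``(e_values[i], tau_p_values[j])``;
    infeasible or unevaluated cells are NaN (missing, never zero). The
    optimum attains the maximum over all evaluated cells, ties broken
    toward smaller E then smaller tau_p; ``trajectory`` records the
    coordinate-descent path when that was the search strategy.
    """

    direction: str
    e_values: np.ndarray
    tau_p_values: np.ndarray
    values: np.ndarray
    best_E: int
    best_tau_p: int
    best_value: float
    trajectory: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.e_values = np.asarray(self.e_values, dtype=int)
        self.tau_p_values = np.asarray(self.tau_p_values, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("surface values must lie in [-1, 1]")


def whitney_bounds(e_star: int) -> tuple[int, int]:
    """Bounds on the true system dimensionality implied by the optimal E.

    If ``e_star`` is the best embedding dimension, the dimensionality of
    the full causal system lies generically between ``ceil((e_star - 1)/2)``
    and ``e_star`` inclusive.
    """
    if e_star < 2:
        raise ValueError("optimal embedding dimension must be >= 2")
    return (math.ceil((e_star - 1) / 2), int(e_star))


class _Objective:
    """Cached objective(E, tau_p) = max over L of mean windowed rho_ccm.

    Pairwise distance tables depend only on (E, tau), so they are computed
    once per E and shared across all tau_p values.
    """

    def __init__(self, X, Y, grid, tau=1, exclusion_window=0):
        self.X, self.Y, self.grid = X, Y, grid
        self.tau = tau
        self.exclusion_window = exclusion_window
        self._cache: dict[tuple[int, int], float] = {}
        self._dist_cache: dict[int, object] = {}

    def _distances(self, E: int):
        if E not in self._dist_cache:
            m = embed(self.Y, EmbeddingParams(E=E, tau=self.tau))
            self._dist_cache[E] = pairwise_distances(m)
        return self._dist_cache[E]

    def __call__(self, E: int, tau_p: int) -> float:
        key = (E, tau_p)
        if key in self._cache:
            return self._cache[key]
        sizes = self.grid.lib_sizes_for(len(self.X), E, self.tau, tau_p)
        if sizes.size == 0:
            value = -np.inf  # infeasible cell
        else:
            try:
                result = window_sweep(
                    self.X,
                    self.Y,
                    EmbeddingParams(E=E, tau=self.tau, tau_p=tau_p),
                    sizes,
                    exclusion_window=self.exclusion_window,
                    distances=self._distances(E),
                )
                value = result.max_rho
            except ValueError:
                value = -np.inf
        self._cache[key] = value
        return value


def _surface_from_cache(direction, grid, cache, best, trajectory=None):
    e_vals = np.asarray(grid.e_values)
    tp_vals = np.asarray(grid.tau_p_values)
    values = np.full((e_vals.size, tp_vals.size), np.nan)
    for (E, tp), v in cache.items():
        if np.isfinite(v):
            values[int(np.searchsorted(e_vals, E)), int(np.searchsorted(tp_vals, tp))] = v
    return ParamSurface(
        direction=direction,
        e_values=e_vals,
        tau_p_values=tp_vals,
        values=values,
        best_E=best[0],
        best_tau_p=best[1],
        best_value=best[2],
        trajectory=list(trajectory or []),
    )


def _line_argmax(values: list[float]) -> int:
    """Index of the maximum, smallest index on ties (prefers simpler models)."""
    best_i, best_v = 0, -np.inf
    for i, v in enumerate(values):
        if v > best_v:
            best_i, best_v = i, v
    return best_i


def _cyclic_descent(
    objective,
    e_values,
    tau_p_values,
    max_cycles: int = MAX_CYCLES,
    start: tuple[int, int] | None = None,
    scan_e_first: bool = True,
):
    """Alternating full line scans of the E and tau_p axes from one start.

    ``objective(E, tau_p)`` may return -inf for infeasible cells. Returns
    the final ``(E, tau_p)`` and the trajectory of ``(E, tau_p, value)``
    after each cycle. Stops when a full cycle leaves the position
    unchanged, or after ``max_cycles``.
    """
    E, tp = start if start is not None else (e_values[0], tau_p_values[0])
    e_pos = {e: i for i, e in enumerate(e_values)}
    tp_pos = {t: j for j, t in enumerate(tau_p_values)}
    trajectory = [(E, tp, objective(E, tp))]
    for _ in range(max_cycles):
        prev = (E, tp)
        if scan_e_first:
            E = e_values[_line_argmax([objective(e, tp) for e in e_values])]
            tp = tau_p_values[_line_argmax([objective(E, t) for t in tau_p_values])]
        else:
            tp = tau_p_values[_line_argmax([objective(E, t) for t in tau_p_values])]
            E = e_values[_line_argmax([objective(e, tp) for e in e_values])]
        if (E, tp) == prev:
            # stalled on a coordinate-wise maximum; skill surfaces often
            # carry a diagonal ridge (larger E trades against longer
            # tau_p), so probe the diagonal neighbors before stopping
            here = objective(E, tp)
            i, j = e_pos[E], tp_pos[tp]
            for di, dj in ((1, 1), (-1, -1), (1, -1), (-1, 1)):
                if 0 <= i + di < len(e_values) and 0 <= j + dj < len(tau_p_values):
                    cand = (e_values[i + di], tau_p_values[j + dj])
                    if objective(*cand) > here:
                        E, tp = cand
                        break
        trajectory.append((E, tp, objective(E, tp)))
        if (E, tp) == prev:
            break
    return E, tp, trajectory


def _multi_start_descent(objective, e_values, tau_p_values):
    """Cyclic coordinate descent from a deterministic portfolio of starts.

    Cross-map skill surfaces often carry a diagonal ridge — in a
    deterministic system a larger embedding can trade off against a longer
    causal delay — on which a single-start cyclic descent can stall at a
    coordinate-wise local maximum. Three corner starts with alternating
    scan orders cover both ridge orientations while evaluating far fewer
    cells than the exhaustive surface (the objective caches, so repeated
    cells are free). The best terminal wins; ties prefer smaller E, then
    smaller tau_p.
    """
    starts = [
        ((e_values[0], tau_p_values[0]), True),
        ((e_values[-1], tau_p_values[0]), False),
        ((e_values[0], tau_p_values[-1]), True),
    ]
    outcomes = []
    best_trajectory = None
    for start, e_first in starts:
        E, tp, traj = _cyclic_descent(
            objective, e_values, tau_p_values, start=start, scan_e_first=e_first
        )
        outcomes.append((-objective(E, tp), E, tp, traj))
    outcomes.sort(key=lambda o: o[:3])
    _, E, tp, best_trajectory = outcomes[0]
    return E, tp, best_trajectory


def coordinate_descent(
    X: TimeSeries,
    Y: TimeSeries,
    grid: ParamGrid,
    tau: int = 1,
    exclusion_window: int = 0,
) -> ParamSurface:
    """Optimize (E, tau_p) by cyclic coordinate descent on held-out skill.

    The search alternates full line scans of the E axis (tau_p fixed) and
    the tau_p axis (E fixed), always moving to the scan's maximum (ties
    toward smaller values), stopping when a full cycle leaves the position
    unchanged or after 10 cycles; it is repeated from three deterministic
    corner starts to avoid stalling on diagonal ridges (see
    :func:`_multi_start_descent`), and the best terminal wins. The
    returned surface holds NaN at cells the descent never visited.
    """
    objective = _Objective(X, Y, grid, tau, exclusion_window)
    E, tp, trajectory = _multi_start_descent(
        objective, grid.e_values, grid.tau_p_values
    )
    best_value = objective(E, tp)
    if not np.isfinite(best_value):
        raise ValueError(
            "every (E, tau_p) cell is infeasible for this series length"
        )
    return _surface_from_cache(
        f"{Y.name} xmap {X.name}", grid, objective._cache, (E, tp, best_value), trajectory
    )


def full_surface(
    X: TimeSeries,
    Y: TimeSeries,
    grid: ParamGrid,
    tau: int = 1,
    exclusion_window: int = 0,
) -> ParamSurface:
    """Exhaustively evaluate the (E, tau_p) sensitivity surface.

    Every cell is computed (infeasible cells stay NaN) and the optimum is
    the exact argmax, ties toward smaller E then smaller tau_p. This is the
    audit path for :func:`coordinate_descent` and the data behind the
    sensitivity heatmaps.
    """
    objective = _Objective(X, Y, grid, tau, exclusion_window)
    best = (None, None, -np.inf)
    for E in grid.e_values:
        for tp in grid.tau_p_values:
            v = objective(E, tp)
            if v > best[2]:
                best = (E, tp, v)
    if best[0] is None:
        raise ValueError(
            "every (E, tau_p) cell is infeasible for this series length"
        )
    return _surface_from_cache(
        f"{Y.name} xmap {X.name}", grid, objective._cache, best
    )
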