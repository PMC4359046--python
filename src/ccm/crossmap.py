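"""Cross-map prediction and convergent predictive skill.

To test whether X causes Y, CCM asks the *effect*'s shadow manifold M_y to
locate, for each held-out target, its nearest reconstructed states; the
corresponding observations of X are then combined by simplex projection
(an exponentially weighted average over the E+1 nearest neighbors) into a
prediction of X. Predictive skill rho_ccm is the Pearson correlation
between held-out and predicted values. If X truly drives Y, its states are
encoded in M_y, so skill rises ("converges") as the library of available
neighbor points grows — the convergence, not the absolute correlation, is
the causal signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .embedding import (
    DistanceTable,
    EmbeddingParams,
    ShadowManifold,
    TimeSeries,
    embed,
    pairwise_distances,
)

__all__ = [
    "Library",
    "Prediction",
    "CrossMapResult",
    "ConvergenceSummary",
    "neighbor_rank",
    "exp_weights",
    "crossmap_point",
    "skill",
    "window_sweep",
    "assess_convergence",
    "min_library_size",
]


def min_library_size(E: int) -> int:
    # E+1 simplex neighbors plus the held-out target itself
    return E + 2


@dataclass(frozen=True)
class Library:
    """A contiguous window of manifold points used as the prediction basis."""

    start: int
    size: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("library start must be >= 0")
        if self.size < 1:
            raise ValueError("library size must be >= 1")

    @property
    def stop(self) -> int:
        return self.start + self.size

    def validate(self, manifold: ShadowManifold) -> None:
        if self.stop > len(manifold):
            raise ValueError(
                f"library [{self.start}, {self.stop}) exceeds the "
                f"{len(manifold)}-point manifold"
            )
        E = manifold.params.E
        if self.size < min_library_size(E):
            raise ValueError(
                f"library size {self.size} < minimum {min_library_size(E)} "
                f"for E={E} (E+1 neighbors plus a target)"
            )


@dataclass(frozen=True)
class Prediction:
    """One cross-mapped point: observation, estimate and the neighbors used."""

    target_time: int
    observed: float
    predicted: float
    neighbor_times: np.ndarray
    weights: np.ndarray
    skipped: bool = False
    reason: str = ""


@dataclass(frozen=True)
class ConvergenceSummary:
    """Change in skill from the smallest to the largest library size."""

    delta_rho: float
    relative_delta: float
    rho_at_min_L: float
    rho_at_max_L: float
    converged: bool


@dataclass
class CrossMapResult:
    """Predictive skill as a function of library size for one direction.

    ``direction`` reads "Y xmap X": manifold built from Y, predicting X,
    which tests the hypothesis that X causes Y. ``rho_mean[i]`` is the
    mean over all sliding windows of size ``lib_sizes[i]`` of the
    within-window leave-one-out Pearson skill; ``rho_windows[i]`` keeps
    the per-window values.
    """

    direction: str
    lib_sizes: np.ndarray
    rho_mean: np.ndarray
    rho_windows: list[np.ndarray]
    params: EmbeddingParams
    n_skipped: int = 0
    n_zero_variance_windows: int = 0

    def __post_init__(self) -> None:
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=int)
        self.rho_mean = np.asarray(self.rho_mean, dtype=float)
        if self.lib_sizes.size != self.rho_mean.size:
            raise ValueError("lib_sizes and rho_mean must align")
        if self.lib_sizes.size and np.any(np.diff(self.lib_sizes) <= 0):
            raise ValueError("library sizes must be strictly increasing")

    @property
    def max_rho(self) -> float:
        return float(np.max(self.rho_mean))


def neighbor_rank(
    distances: DistanceTable,
    target: int,
    lib: Library,
    k: int,
    exclusion_window: int = 0,
) -> list[tuple[int, float]]:
    """The ``k`` nearest library points to ``target``, nearest first.

    The target itself — and, with a Theiler exclusion window ``w > 0``, any
    point within ``w`` manifold positions of it — is never a neighbor.
    Distance ties are broken toward the earlier time index.

    Returns a list of ``(point_index, distance)`` pairs.
    """
    d = distances.values
    candidates = np.arange(lib.start, lib.stop)
    if lib.start <= target < lib.stop:
        candidates = candidates[np.abs(candidates - target) > exclusion_window]
    if candidates.size < k:
        raise ValueError(
            f"cannot find {k} neighbors in a library of {lib.size} points "
            f"(minimum library size is {k + 1} with the target excluded)"
        )
    row = d[target, candidates]
    order = np.argsort(row, kind="stable")[:k]  # stable: earlier index wins ties
    chosen = candidates[order]
    return [(int(i), float(d[target, i])) for i in chosen]


def exp_weights(distances: np.ndarray) -> np.ndarray:
    """Simplex-projection weights from ascending neighbor distances.

    ``u_i = exp(-d_i / d_1)`` with ``d_1`` the nearest distance, normalized
    to sum to one. If the nearest distance is exactly zero the weights are
    uniform over all zero-distance neighbors and zero elsewhere.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one neighbor distance")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be sorted ascending")
    if d[0] == 0.0:
        u = (d == 0.0).astype(float)
    else:
        with np.errstate(over="ignore"):  # huge ratios underflow exp to 0
            u = np.exp(-d / d[0])
    return u / u.sum()


def skill(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Predictive skill rho_ccm: Pearson correlation of held-out vs predicted.

    A zero-variance side yields 0.0 with a warning (rather than NaN) so that
    parameter optimization remains well-defined; fewer than 3 pairs is an
    error.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 3:
        raise ValueError("skill is undefined for fewer than 3 pairs")
    rho = _pearson(obs, pred)
    if rho is None:
        warnings.warn(
            "zero variance in observed or predicted values; rho_ccm set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return rho


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson r, or None when either side has (numerically) zero variance."""
    a = a - a.mean()
    b = b - b.mean()
    sa = float(a @ a)
    sb = float(b @ b)
    if sa <= 0.0 or sb <= 0.0:
        return None
    return float(np.clip((a @ b) / np.sqrt(sa * sb), -1.0, 1.0))


def crossmap_point(
    manifold: ShadowManifold,
    target_series: TimeSeries,
    lib: Library,
    t: int,
    tau_p: int | None = None,
    distances: DistanceTable | None = None,
    exclusion_window: int = 0,
) -> Prediction:
    """Cross-map a single held-out observation of ``target_series``.

    The manifold point at time ``t`` (which must lie inside ``lib``) is the
    held-out target; its ``E+1`` nearest library neighbors (leave-one-out)
    supply exponential weights, and the prediction is
    ``sum_i w_i * X(t_i - tau_p)`` for the opposing series ``X``. A ``tau_p``
    that pushes any required index out of range marks the prediction as
    skipped rather than silently dropping it.
    """
    params = manifold.params
    if tau_p is None:
        tau_p = params.tau_p
    lib.validate(manifold)
    where = np.flatnonzero(manifold.time_index == t)
    if where.size != 1:
        raise ValueError(f"time {t} is not a manifold time")
    tgt = int(where[0])
    if not (lib.start <= tgt < lib.stop):
        raise ValueError(f"target time {t} lies outside the library span")
    if distances is None:
        distances = pairwise_distances(manifold)
    k = params.E + 1
    neighbors = neighbor_rank(distances, tgt, lib, k, exclusion_window)
    idx = np.array([i for i, _ in neighbors])
    nbr_times = manifold.time_index[idx]
    required = np.append(nbr_times, t) - tau_p
    if required.min() < 0 or required.max() >= len(target_series):
        return Prediction(
            target_time=t,
            observed=np.nan,
            predicted=np.nan,
            neighbor_times=nbr_times,
            weights=np.array([]),
            skipped=True,
            reason=f"tau_p={tau_p} pushes an index out of range",
        )
    w = exp_weights(np.array([d for _, d in neighbors]))
    predicted = float(w @ target_series.values[nbr_times - tau_p])
    return Prediction(
        target_time=t,
        observed=float(target_series.values[t - tau_p]),
        predicted=predicted,
        neighbor_times=nbr_times,
        weights=w,
    )


def window_sweep(
    X: TimeSeries,
    Y: TimeSeries,
    params: EmbeddingParams,
    lib_sizes,
    exclusion_window: int = 0,
    distances: DistanceTable | None = None,
) -> CrossMapResult:
    """Sweep library sizes, averaging skill across sliding windows.

    Builds M_y from ``Y`` and cross-maps ``X`` (direction "Y xmap X",
    testing X -> Y). For each library size ``L`` every window of ``L``
    consecutive manifold points (stride 1) yields one leave-one-out Pearson
    skill; the mean across windows is the reported rho_ccm for that ``L``.
    Manifold points whose ``tau_p``-shifted index would fall before the
    start of the record are clipped from the sweep up front, so all
    predictions are valid by construction.

    ``distances`` may carry a precomputed table for M_y (it depends only on
    ``(E, tau)``), allowing reuse across ``tau_p`` values and library grids.
    """
    manifold = embed(Y, params)
    if distances is None:
        distances = pairwise_distances(manifold)
    E, tau_p = params.E, params.tau_p
    k = E + 1
    if len(X) != len(Y):
        raise ValueError("X and Y must have equal length")

    times = manifold.time_index
    clip = int(np.searchsorted(times, tau_p))  # first point with t >= tau_p
    P = len(manifold) - clip
    L_min = min_library_size(E)
    if P < L_min:
        raise ValueError(
            f"only {P} usable manifold points for E={E}, tau_p={tau_p}; "
            f"need at least {L_min}"
        )
    requested = np.unique(np.asarray(lib_sizes, dtype=int))
    sizes = requested[(requested >= L_min) & (requested <= P)]
    if sizes.size == 0:
        raise ValueError(
            f"no usable library sizes in {list(requested)}: valid range is "
            f"[{L_min}, {P}]"
        )

    D = distances.values[clip:, clip:]
    # value each manifold point predicts: X(t - tau_p)
    xv = X.values[times[clip:] - tau_p]

    rho_mean = np.empty(sizes.size)
    rho_windows: list[np.ndarray] = []
    n_zero_var = 0
    for si, L in enumerate(sizes):
        n_win = P - L + 1
        rhos = np.empty(n_win)
        for s in range(n_win):
            sub = D[s : s + L, s : s + L].copy()
            _mask_self(sub, exclusion_window)
            order = _k_nearest_rows(sub, k)
            d = np.take_along_axis(sub, order, axis=1)
            w = _exp_weights_rows(d)
            xw = xv[s : s + L]
            pred = np.einsum("ij,ij->i", w, xw[order])
            r = _pearson(xw, pred)
            if r is None:
                n_zero_var += 1
                r = 0.0
            rhos[s] = r
        rho_windows.append(rhos)
        rho_mean[si] = rhos.mean()

    return CrossMapResult(
        direction=f"{Y.name} xmap {X.name}",
        lib_sizes=sizes,
        rho_mean=rho_mean,
        rho_windows=rho_windows,
        params=params,
        n_zero_variance_windows=n_zero_var,
    )


def _k_nearest_rows(sub: np.ndarray, k: int) -> np.ndarray:
    """Per-row indices of the k smallest entries, nearest first.

    Distance ties among the selected k are broken toward the smaller
    (earlier-time) index, matching :func:`neighbor_rank`.
    """
    cand = np.argpartition(sub, k - 1, axis=1)[:, :k]
    d = np.take_along_axis(sub, cand, axis=1)
    order = np.lexsort((cand, d), axis=1)
    return np.take_along_axis(cand, order, axis=1)


def _mask_self(sub: np.ndarray, exclusion_window: int) -> None:
    """Exclude each target and its Theiler neighborhood from its own row."""
    L = sub.shape[0]
    if exclusion_window <= 0:
        np.fill_diagonal(sub, np.inf)
        return
    i, j = np.indices((L, L), sparse=True)
    sub[np.abs(i - j) <= exclusion_window] = np.inf


def _exp_weights_rows(d: np.ndarray) -> np.ndarray:
    """Row-wise exponential simplex weights for ascending distance rows."""
    d1 = d[:, :1]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(d1 > 0.0, np.exp(-d / np.where(d1 > 0.0, d1, 1.0)), d == 0.0)
    return u / u.sum(axis=1, keepdims=True)


def assess_convergence(
    result: CrossMapResult,
    delta_rho_min: float = 0.1,
    rho_min: float = 0.2,
    eps: float = 1e-6,
) -> ConvergenceSummary:
    """Convergence of skill with library size: the causality criterion.

    A systematic rise of rho_ccm from the smallest to the largest library —
    ``delta_rho >= delta_rho_min`` together with a non-trivial terminal
    skill ``rho(L_max) >= rho_min`` — is taken as evidence of causal
    coupling. Flat curves, however high, do not qualify. Thresholds are
    configurable defaults; the criterion is inherently qualitative.
    """
    if result.lib_sizes.size < 2:
        raise ValueError("convergence needs at least 2 library sizes")
    rho_lo = float(result.rho_mean[0])
    rho_hi = float(result.rho_mean[-1])
    delta = rho_hi - rho_lo
    rel = delta / max(abs(rho_hi), eps)
    return ConvergenceSummary(
        delta_rho=delta,
        relative_delta=rel,
        rho_at_min_L=rho_lo,
        rho_at_max_L=rho_hi,
        converged=bool(delta >= delta_rho_min and rho_hi >= rho_min),
    )
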