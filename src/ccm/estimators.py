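"""Scikit-learn style estimators wrapping the cross-mapping pipeline.

``CCM`` evaluates one causal hypothesis ("does X cause y?") at fixed
embedding parameters; ``CCMOptimizer`` additionally searches the
(E, tau_p) grid. Both follow the sklearn estimator contract — constructor
parameters mirror attributes, ``fit`` returns ``self``, fitted results
carry a trailing underscore — so they compose with ``clone``,
``get_params``/``set_params`` and friends.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .crossmap import (
    ConvergenceSummary,
    CrossMapResult,
    assess_convergence,
    min_library_size,
    window_sweep,
)
from .embedding import EmbeddingParams, TimeSeries
from .optimize import (
    ParamGrid,
    ParamSurface,
    coordinate_descent,
    default_grid,
    default_lib_sizes,
    full_surface,
    whitney_bounds,
)

__all__ = ["CCM", "CCMOptimizer"]


def _as_series(values, name) -> TimeSeries:
    if isinstance(values, TimeSeries):
        return values
    arr = np.asarray(values, dtype=float).ravel()
    return TimeSeries(arr, name=name)


class CCM(BaseEstimator):
    """Convergent cross mapping of a single causal direction.

    ``fit(X, y)`` tests the hypothesis *X causes y*: the shadow manifold is
    reconstructed from the putative **effect** ``y``, and held-out values of
    the putative **cause** ``X`` are predicted from it by simplex projection
    (an exponentially weighted average over the ``E + 1`` nearest manifold
    neighbors). Skill is the Pearson correlation between held-out and
    predicted values, averaged across all sliding windows of each library
    size; a systematic rise of skill with library size is the causal
    signature.

    Parameters
    ----------
    E : int
        Embedding dimension (number of lagged coordinates), >= 2.
    tau : int
        Lag between embedding coordinates, in index units.
    tau_p : int
        Assumed delay of the causal effect: the manifold point at time
        ``t`` predicts the cause at ``t - tau_p``.
    lib_sizes : sequence of int, optional
        Ascending library sizes; by default ~8 sizes spanning the feasible
        range.
    exclusion_window : int
        Theiler window: neighbors within this many time steps of the
        target are excluded (0 excludes only the target itself).
    delta_rho_min, rho_min : float
        Convergence verdict thresholds: the skill gain from the smallest
        to the largest library must reach ``delta_rho_min`` and terminal
        skill must reach ``rho_min``.

    Attributes
    ----------
    result_ : CrossMapResult
        Per-library-size skill curve with per-window detail.
    lib_sizes_ : ndarray of int
        Library sizes actually evaluated (after clipping).
    rho_ : ndarray of float
        Mean windowed skill per library size.
    convergence_ : ConvergenceSummary
        Delta-rho convergence assessment.
    converged_ : bool
        The causal verdict under the configured thresholds.

    Examples
    --------
    >>> from ccm.synthetic import CoupledLogisticSpec, coupled_logistic
    >>> x, y = coupled_logistic(CoupledLogisticSpec(n=200, seed=3))
    >>> est = CCM(E=2).fit(x, y)   # doctest: +SKIP
    >>> est.converged_             # doctest: +SKIP
    True
    """

    def __init__(
        self,
        E: int = 2,
        tau: int = 1,
        tau_p: int = 0,
        lib_sizes=None,
        exclusion_window: int = 0,
        delta_rho_min: float = 0.1,
        rho_min: float = 0.2,
    ):
        self.E = E
        self.tau = tau
        self.tau_p = tau_p
        self.lib_sizes = lib_sizes
        self.exclusion_window = exclusion_window
        self.delta_rho_min = delta_rho_min
        self.rho_min = rho_min

    def fit(self, X, y):
        """Cross-map ``X`` from the shadow manifold of ``y``.

        Parameters
        ----------
        X : 1-D array-like or TimeSeries
            The putative cause.
        y : 1-D array-like or TimeSeries
            The putative effect, from which the manifold is built.
        """
        cause = _as_series(X, "X")
        effect = _as_series(y, "Y")
        params = EmbeddingParams(E=self.E, tau=self.tau, tau_p=self.tau_p)
        sizes = self.lib_sizes
        if sizes is None:
            n_points = len(effect) - (self.E - 1) * self.tau
            usable = n_points - max(0, self.tau_p - (self.E - 1) * self.tau)
            sizes = default_lib_sizes(
                min(max(min_library_size(self.E), 10), usable), usable
            )
        self.result_ = window_sweep(
            cause, effect, params, sizes, exclusion_window=self.exclusion_window
        )
        self.lib_sizes_ = self.result_.lib_sizes
        self.rho_ = self.result_.rho_mean
        self.convergence_ = assess_convergence(
            self.result_, delta_rho_min=self.delta_rho_min, rho_min=self.rho_min
        )
        self.converged_ = self.convergence_.converged
        return self

    def score(self, X=None, y=None) -> float:
        """Skill at the largest library size (the plateau of the curve)."""
        if not hasattr(self, "result_"):
            raise AttributeError("CCM instance is not fitted yet")
        return float(self.result_.rho_mean[-1])


class CCMOptimizer(BaseEstimator):
    """Cross mapping with (E, tau_p) selection by cyclic coordinate descent.

    ``fit(X, y)`` tests *X causes y* while tuning the embedding dimension
    and causal delay to maximize cross-validated predictive skill (the max
    over the library grid of the windowed mean rho). With
    ``search="exhaustive"`` every grid cell is evaluated — the audit path,
    and the data behind sensitivity heatmaps; with ``search="descent"``
    (default) cyclic coordinate descent visits only the cells it needs.

    Attributes
    ----------
    best_E_, best_tau_p_ : int
        The selected embedding dimension and causal delay.
    best_score_ : float
        Objective value at the optimum.
    surface_ : ParamSurface
        Evaluated cells (NaN where unevaluated/infeasible) and the descent
        trajectory if applicable.
    whitney_bounds_ : tuple of int
        Implied (lower, upper) bounds on the true system dimensionality.
    result_ : CrossMapResult
        Convergence curve re-evaluated at the optimum.
    converged_ : bool
        Convergence verdict at the optimum.
    """

    def __init__(
        self,
        e_values=None,
        tau_p_values=None,
        tau: int = 1,
        lib_sizes=None,
        exclusion_window: int = 0,
        search: str = "descent",
        delta_rho_min: float = 0.1,
        rho_min: float = 0.2,
    ):
        self.e_values = e_values
        self.tau_p_values = tau_p_values
        self.tau = tau
        self.lib_sizes = lib_sizes
        self.exclusion_window = exclusion_window
        self.search = search
        self.delta_rho_min = delta_rho_min
        self.rho_min = rho_min

    def _grid(self, n: int) -> ParamGrid:
        if self.e_values is None and self.tau_p_values is None:
            return default_grid(n, lib_sizes=self.lib_sizes)
        base = default_grid(n, lib_sizes=self.lib_sizes)
        return ParamGrid(
            e_values=tuple(self.e_values) if self.e_values else base.e_values,
            tau_p_values=(
                tuple(self.tau_p_values) if self.tau_p_values else base.tau_p_values
            ),
            lib_sizes=tuple(self.lib_sizes) if self.lib_sizes else None,
        )

    def fit(self, X, y):
        cause = _as_series(X, "X")
        effect = _as_series(y, "Y")
        if len(cause) != len(effect):
            raise ValueError("X and y must have equal length")
        grid = self._grid(len(cause))
        if self.search == "exhaustive":
            surface = full_surface(
                cause, effect, grid, tau=self.tau,
                exclusion_window=self.exclusion_window,
            )
        elif self.search == "descent":
            surface = coordinate_descent(
                cause, effect, grid, tau=self.tau,
                exclusion_window=self.exclusion_window,
            )
        else:
            raise ValueError("search must be 'descent' or 'exhaustive'")
        self.grid_ = grid
        self.surface_ = surface
        self.best_E_ = int(surface.best_E)
        self.best_tau_p_ = int(surface.best_tau_p)
        self.best_score_ = float(surface.best_value)
        self.whitney_bounds_ = whitney_bounds(self.best_E_)

        best = CCM(
            E=self.best_E_,
            tau=self.tau,
            tau_p=self.best_tau_p_,
            lib_sizes=self.lib_sizes,
            exclusion_window=self.exclusion_window,
            delta_rho_min=self.delta_rho_min,
            rho_min=self.rho_min,
        ).fit(cause, effect)
        self.result_ = best.result_
        self.convergence_ = best.convergence_
        self.converged_ = best.converged_
        return self

    def score(self, X=None, y=None) -> float:
        if not hasattr(self, "best_score_"):
            raise AttributeError("CCMOptimizer instance is not fitted yet")
        return self.best_score_
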