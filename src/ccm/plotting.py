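"""Convergence-curve and (E, tau_p) sensitivity-surface figures.

Direction labels always state both the mapping and the causal hypothesis
it tests ("Y xmap X (tests X -> Y)"), because the inversion — the effect's
manifold predicts the cause — is the single most common reading error with
this method.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .crossmap import CrossMapResult
from .optimize import ParamSurface

__all__ = ["direction_caption", "plot_convergence", "plot_surface"]


def direction_caption(direction: str) -> str:
    """Expand "Y xmap X" into "Y xmap X (tests X -> Y)"."""
    parts = direction.split(" xmap ")
    if len(parts) != 2:
        return direction
    effect, cause = parts
    return f"{direction} (tests {cause} → {effect})"


def plot_convergence(
    results: list[CrossMapResult],
    path,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """Skill versus library size, one line per direction.

    Writes one file per requested format next to ``path`` (its suffix is
    replaced) and returns the written paths.
    """
    results = [r for r in results if r is not None]
    if not results or any(r.lib_sizes.size < 2 for r in results):
        raise ValueError("need at least 2 library sizes per direction to plot")
    fig, ax = plt.subplots(figsize=(6, 4))
    shades = ["0.15", "0.55", "0.35", "0.75"]
    for res, shade in zip(results, shades):
        ax.plot(
            res.lib_sizes,
            res.rho_mean,
            marker="o",
            color=shade,
            label=direction_caption(res.direction),
        )
    ax.set_xlabel("library size L")
    ax.set_ylabel(r"cross-map skill $\rho_{ccm}$")
    ax.set_ylim(-0.1, 1.05)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    written = _save(fig, Path(path), formats)
    plt.close(fig)
    return written


def plot_surface(
    surfaces: list[ParamSurface],
    path,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """One heatmap per direction: max skill over (E, tau_p).

    Infeasible or unevaluated cells render as missing (not zero); the
    optimum cell is outlined.
    """
    surfaces = [s for s in surfaces if s is not None]
    if not surfaces:
        raise ValueError("no surfaces to plot")
    fig, axes = plt.subplots(
        1, len(surfaces), figsize=(5 * len(surfaces), 4), squeeze=False
    )
    vals = np.concatenate([s.values[np.isfinite(s.values)] for s in surfaces])
    vmin = float(vals.min()) if vals.size else 0.0
    vmax = float(vals.max()) if vals.size else 1.0
    for ax, surf in zip(axes[0], surfaces):
        masked = np.ma.masked_invalid(surf.values)
        im = ax.pcolormesh(
            np.arange(surf.tau_p_values.size + 1),
            np.arange(surf.e_values.size + 1),
            masked,
            vmin=vmin,
            vmax=vmax,
            cmap="viridis",
        )
        ax.set_xticks(np.arange(surf.tau_p_values.size) + 0.5)
        ax.set_xticklabels(surf.tau_p_values)
        ax.set_yticks(np.arange(surf.e_values.size) + 0.5)
        ax.set_yticklabels(surf.e_values)
        ax.set_xlabel(r"causal delay $\tau_p$")
        ax.set_ylabel("embedding dimension E")
        ax.set_title(direction_caption(surf.direction), fontsize=9)
        i = int(np.searchsorted(surf.e_values, surf.best_E))
        j = int(np.searchsorted(surf.tau_p_values, surf.best_tau_p))
        ax.add_patch(
            plt.Rectangle((j, i), 1, 1, fill=False, edgecolor="red", linewidth=2)
        )
        fig.colorbar(im, ax=ax, label=r"max $\rho_{ccm}$")
    fig.tight_layout()
    written = _save(fig, Path(path), formats)
    plt.close(fig)
    return written


def _save(fig, path: Path, formats) -> list[Path]:
    written = []
    for fmt in formats:
        target = path.with_suffix(f".{fmt}")
        fig.savefig(target, dpi=150)
        written.append(target)
    return written
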