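"""Optional figure set: access-effect caterpillar plots and
occupancy-versus-access response curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.special import expit

from .model import AREAS
from .sampler import PosteriorDraws
from .summaries import _eqtail


def caterpillar_access_effects(draws: PosteriorDraws, path,
                               levels=(0.66, 0.85)) -> Path:
    """Per-species access-slope posteriors with nested credible bars."""
    beta1 = draws.stacked("beta1")  # (N, K, 2)
    sp = draws.species_index
    K = len(sp)
    fig, axes = plt.subplots(1, len(AREAS), figsize=(9, 0.28 * K + 1.5),
                             sharey=True)
    ypos = np.arange(K)
    for a, (ax, area) in enumerate(zip(np.atleast_1d(axes), AREAS)):
        b = beta1[:, :, a]
        mean = b.mean(axis=0)
        for level, lw in zip(sorted(levels, reverse=True), (1.0, 2.5)):
            lo, hi = _eqtail(b, level)
            ax.hlines(ypos, lo, hi, lw=lw, color="steelblue")
        ax.plot(mean, ypos, "o", ms=3, color="black")
        ax.axvline(0, color="grey", ls=":")
        ax.set_title(area)
        ax.set_xlabel("access slope (per SD walking hours)")
    np.atleast_1d(axes)[0].set_yticks(ypos, sp)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def occupancy_vs_access_curves(draws: PosteriorDraws, path,
                               species=None, level: float = 0.85) -> Path:
    """Posterior occupancy response to walking-hours access per area."""
    std = draws.meta["standardization"]
    i_access = list(std.names).index("access")
    ranges = draws.meta["cov_range_std"]
    beta0 = draws.stacked("beta0")
    beta1 = draws.stacked("beta1")
    sp_index = draws.species_index
    species = species or sp_index[: min(4, len(sp_index))]
    fig, axes = plt.subplots(len(species), len(AREAS),
                             figsize=(8, 2.2 * len(species)), squeeze=False)
    for r, sp in enumerate(species):
        k = sp_index.index(sp)
        for a, area in enumerate(AREAS):
            rng_std = np.asarray(ranges.get(area, ranges["pooled"]))[0]
            grid = np.linspace(rng_std[0], rng_std[1], 50)
            lp = beta0[:, k, a][:, None] + beta1[:, k, a][:, None] * grid
            psi = expit(lp)
            lo, hi = _eqtail(psi, level)
            hours = std.invert("access", grid)
            ax = axes[r][a]
            ax.fill_between(hours, lo, hi, alpha=0.3, color="steelblue")
            ax.plot(hours, psi.mean(axis=0), color="steelblue")
            ax.set_ylim(0, 1)
            ax.set_title(f"{sp} — {area}", fontsize=9)
            if r == len(species) - 1:
                ax.set_xlabel("access (walking hours)")
            if a == 0:
                ax.set_ylabel(r"$\psi$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
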