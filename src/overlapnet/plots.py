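"""Static diagnostic figures: scale-free fit, cutoff scan, CV curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .association import LassoFit
from .network import BetaSelection, CutoffScan


def plot_scale_free_fit(selection: BetaSelection, path: str | Path) -> Path:
    path = Path(path)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    betas = [f.beta for f in selection.scan]
    r2s = [f.r_squared for f in selection.scan]
    ax1.plot(betas, r2s, "o-")
    ax1.axhline(0.8, color="grey", ls="--", lw=0.8)
    ax1.axvline(selection.beta, color="red", ls=":", lw=0.8)
    ax1.set_xlabel(r"$\beta$")
    ax1.set_ylabel(r"scale-free fit $R^2$")
    fit = selection.fit
    ax2.plot(fit.bin_centers, fit.bin_frequencies, "o")
    ax2.set_xlabel(r"$\log_{10} k$")
    ax2.set_ylabel(r"$\log_{10} p(k)$")
    ax2.set_title(f"beta={selection.beta}, R²={fit.r_squared:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_cutoff_scan(scan: CutoffScan, cutoff: float, path: str | Path) -> Path:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(scan.thresholds, scan.densities, "o-", label="density")
    ax.axvline(cutoff, color="red", ls=":", lw=0.8, label=f"cutoff={cutoff:g}")
    ax.set_xlabel("cutoff")
    ax.set_ylabel("network density")
    ax2 = ax.twinx()
    ax2.plot(scan.thresholds, scan.node_counts, "s--", color="grey", label="nodes")
    ax2.set_ylabel("non-isolated nodes")
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_cv_curves(fits: list[LassoFit], path: str | Path) -> Path:
    path = Path(path)
    fig, axes = plt.subplots(1, max(len(fits), 1), figsize=(4 * max(len(fits), 1), 3.5), squeeze=False)
    for ax, fit in zip(axes[0], fits):
        ax.errorbar(fit.lambda_grid, fit.cv_mse_mean, yerr=fit.cv_mse_se, fmt=".", ms=3, lw=0.6)
        ax.axvline(fit.chosen_lambda, color="red", ls=":", lw=0.8)
        ax.set_xscale("log")
        ax.set_xlabel(r"$\lambda$")
        ax.set_ylabel("CV MSE")
        ax.set_title(fit.trait_name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
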