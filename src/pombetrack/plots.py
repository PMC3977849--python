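"""Optional figure output for growth statistics.

Histograms of the six cycle parameters, shift-aligned scatter of a
parameter versus absolute division time (colored by the fraction of the
cycle after the shift, with moving mean ± SD), and sister-pair scatter
colored by the mother's division length.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .growth import PARAMETERS, align_to_shift  # noqa: E402

__all__ = ["plot_histograms", "plot_shift_scatter", "plot_sister_scatter"]

_UNITS = {
    "birth_length": "µm", "division_length": "µm", "fission_length": "µm",
    "elongation_time": "min", "septation_time": "min", "doubling_time": "min",
    "elongation_rate": "µm/min",
}


def plot_histograms(records: pd.DataFrame, path: str | Path) -> Path:
    fig, axes = plt.subplots(2, 4, figsize=(14, 6))
    for ax, par in zip(axes.ravel(), PARAMETERS):
        ax.hist(records[par], bins=30, color="steelblue")
        ax.set_xlabel(f"{par} ({_UNITS[par]})")
        ax.set_ylabel("cells")
    axes.ravel()[-1].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_shift_scatter(records: pd.DataFrame, t_shift: float, path: str | Path,
                       parameter: str = "doubling_time",
                       window: float = 30.0) -> Path:
    aligned = align_to_shift(records, t_shift, window=window)
    moving = aligned.attrs["moving"]
    fig, ax = plt.subplots(figsize=(8, 5))
    sc = ax.scatter(aligned["division_time_abs"], aligned[parameter], s=8,
                    c=aligned["fraction_of_cycle_after_shift"],
                    cmap="coolwarm", vmin=0, vmax=1)
    if len(moving):
        ax.plot(moving["t_center"], moving[f"{parameter}_mean"], "k-", lw=2)
        ax.plot(moving["t_center"],
                moving[f"{parameter}_mean"] + moving[f"{parameter}_sd"], "r-", lw=1)
        ax.plot(moving["t_center"],
                moving[f"{parameter}_mean"] - moving[f"{parameter}_sd"], "r-", lw=1)
    ax.axvline(t_shift, ls="--", color="gray")
    ax.set_xlabel("division time (min)")
    ax.set_ylabel(f"{parameter} ({_UNITS[parameter]})")
    fig.colorbar(sc, label="fraction of cycle after shift")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_sister_scatter(sister_pairs: pd.DataFrame, path: str | Path,
                        parameter: str = "doubling_time") -> Path:
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(sister_pairs[f"{parameter}_a"], sister_pairs[f"{parameter}_b"],
                    s=14, c=sister_pairs["mother_division_length"], cmap="viridis")
    lo = min(ax.get_xlim()[0], ax.get_ylim()[0])
    hi = max(ax.get_xlim()[1], ax.get_ylim()[1])
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel(f"sister A {parameter} ({_UNITS[parameter]})")
    ax.set_ylabel(f"sister B {parameter} ({_UNITS[parameter]})")
    fig.colorbar(sc, label="mother division length (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
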