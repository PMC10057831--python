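"""Figure generation from run directories and in-memory results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clot import FREE_SPECIES, LysisResult
from .systemic import SystemicTrajectory

__all__ = ["plot_systemic", "plot_clot_map", "plot_comparison", "plot_results"]


def plot_systemic(traj: SystemicTrajectory, path: Path) -> Path:
    """Central-compartment drug and protein concentration profiles."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    tmin = traj.times / 60.0
    ax1.plot(tmin, traj.Cc, label="central")
    ax1.plot(tmin, traj.Cp, label="peripheral", ls="--")
    ax1.set_xlabel("time [min]")
    ax1.set_ylabel(f"{traj.drug} [μM]")
    ax1.legend(frameon=False)
    for sp in ("PLG", "FBG", "AP", "PAI"):
        ax2.semilogy(tmin, np.maximum(traj.protein(sp), 1e-12), label=sp)
    ax2.set_xlabel("time [min]")
    ax2.set_ylabel("concentration [μM]")
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_clot_map(result: LysisResult, species: str, path: Path) -> Path:
    """Space-time heat map of one species (or ``n_total``) in the clot."""
    if species == "n_total":
        Z = result.ntot
        label = "binding sites [μM]"
    else:
        Z = result.C[:, FREE_SPECIES.index(species), :]
        label = f"{species} [μM]"
    fig, ax = plt.subplots(figsize=(5.5, 3.8))
    pcm = ax.pcolormesh(result.x * 1e3, result.times / 60.0, Z,
                        shading="nearest", cmap="viridis")
    fig.colorbar(pcm, ax=ax, label=label)
    ax.set_xlabel("x [mm]")
    ax.set_ylabel("time [min]")
    ax.set_title(result.drug)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_comparison(table, path: Path) -> Path:
    """Bar chart of the headline metrics across drugs."""
    cols = ["lysis_time", "activation_time", "fbg_nadir_fraction"]
    fig, axes = plt.subplots(1, len(cols), figsize=(10, 3.2))
    for ax, col in zip(axes, cols):
        vals = table[col]
        if col.endswith("time"):
            vals = vals / 60.0
            unit = " [min]"
        else:
            unit = ""
        ax.bar(vals.index, vals.to_numpy())
        ax.set_ylabel(col + unit)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_results(rundir: Path) -> list[Path]:
    """Render the standard figure set from a run directory's CSV outputs.

    Produces the systemic profile, binding-site map, free-drug map and local
    fibrinogen map under ``<rundir>/figures/``.
    """
    import pandas as pd

    from .parameters import builtin_clot_config

    rundir = Path(rundir)
    sysc = rundir / "systemic.csv"
    clotc = rundir / "clot.csv"
    if not sysc.exists() or not clotc.exists():
        raise FileNotFoundError(
            f"run directory {rundir} is missing systemic.csv/clot.csv outputs")
    sdf = pd.read_csv(sysc)
    drug = [s for s in sdf.species.unique()
            if s not in ("PLG", "PLS", "AP", "MG", "FBG", "PAI")][0]
    traj = SystemicTrajectory.from_frame(sdf, drug)

    cdf = pd.read_csv(clotc)
    times = np.sort(cdf.time.unique())
    xs = np.sort(cdf.x.unique())

    def grid(species):
        sub = cdf[cdf.species == species].pivot(index="time", columns="x",
                                                values="value")
        return sub.loc[times, xs].to_numpy()

    cfg = builtin_clot_config()
    ntot = grid("n_total")
    result = LysisResult(
        drug=drug, x=xs, clot_mask=np.ones(len(xs), bool), times=times,
        ntot=ntot,
        C=np.stack([grid(sp) for sp in FREE_SPECIES], axis=1),
        nb=np.zeros((len(times), 3, len(xs))),
        U=np.zeros(len(times)), ntot_init=ntot[0], dissolved=False,
        config=cfg)

    figdir = rundir / "figures"
    figdir.mkdir(exist_ok=True)
    out = [
        plot_systemic(traj, figdir / "systemic.png"),
        plot_clot_map(result, "n_total", figdir / "binding_sites.png"),
        plot_clot_map(result, "drug", figdir / "drug.png"),
        plot_clot_map(result, "FBG", figdir / "fbg.png"),
    ]
    return out
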