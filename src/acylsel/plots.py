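"""Optional figure output for analysis reports.

Quick-look figures mirroring the standard presentation of this analysis:
D1 distributions per system, joined (D2, αBD) density contours with their
modes, and the normalised selectivity-profile bars. Matplotlib is imported
lazily so headless pipeline runs pay nothing for it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["plot_report"]


def plot_report(report: dict, outdir: str | Path) -> list[Path]:
    """Write PNG figures for a :func:`acylsel.pipeline.run_analysis` report."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    systems = report["systems"]
    if not systems:
        return written

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, res in systems.items():
        ax.hist(res["series"].d1, bins=40, histtype="step", density=True,
                label=label)
    ax.set_xlabel("D1 (Å)")
    ax.set_ylabel("probability density")
    ax.legend(fontsize=7)
    p = outdir / "d1_distributions.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(4.5, 3.6))
    for label, res in systems.items():
        dens = res["density2d"]
        d2c = 0.5 * (dens.d2_edges[:-1] + dens.d2_edges[1:])
        abdc = 0.5 * (dens.abd_edges[:-1] + dens.abd_edges[1:])
        if dens.counts.max() > 0:
            ax.contour(d2c, abdc, dens.counts.T,
                       levels=np.array([0.5, 0.8]) * dens.counts.max())
        mode = dens.mode
        ax.plot(*mode, "o", ms=4, label=label)
    ax.axvline(6.0, ls="--", lw=0.8, color="k")
    ax.axhline(90.0, ls="--", lw=0.8, color="k")
    ax.set_xlabel("D2 (Å)")
    ax.set_ylabel("Bürgi–Dunitz angle (°)")
    ax.legend(fontsize=7)
    p = outdir / "d2_abd_density.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    profile = report.get("selectivity_profile")
    if profile is not None:
        fig, ax = plt.subplots(figsize=(4.2, 3.0))
        x = np.arange(len(profile))
        ax.bar(x - 0.2, profile["normalized_reactive_pct"], width=0.4,
               label="reactive (αBD > 90°)", color="c")
        if "normalized_improper_pct" in profile:
            ax.bar(x + 0.2, profile["normalized_improper_pct"], width=0.4,
                   label="improper (αBD < 90°)", color="0.6")
        ax.set_xticks(x, profile.index)
        ax.set_ylabel("normalised fraction (%)")
        ax.legend(fontsize=7)
        p = outdir / "selectivity_profile.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
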