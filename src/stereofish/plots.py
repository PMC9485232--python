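"""Optional figures for the distribution comparison (q-q, overlaid histograms).

Matplotlib is imported lazily so headless pipelines that never plot do
not pay for it.
"""

from __future__ import annotations

from pathlib import Path

from .popstats import DistributionComparison

__all__ = ["plot_comparison"]


def plot_comparison(result: DistributionComparison, outdir: str | Path) -> list[Path]:
    """Write q-q and 1-cm-histogram figures for a comparison; returns the paths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    qx, qy = zip(*result.qq)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(qx, qy, s=12, alpha=0.7)
    lims = [min(min(qx), min(qy)), max(max(qx), max(qy))]
    ax.plot(lims, lims, "k--", lw=1, label="identity")
    ax.set_xlabel("sampled quantiles")
    ax.set_ylabel("estimated quantiles")
    ax.legend()
    path = outdir / "qq.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(6, 4))
    for hist, label in (
        (result.histogram_sampled, f"sampled (n={result.n_sampled})"),
        (result.histogram_estimated, f"estimated (n={result.n_estimated})"),
    ):
        bins = sorted(hist)
        ax.bar(bins, [hist[b] for b in bins], width=0.9, alpha=0.5, align="edge", label=label)
    ax.set_xlabel("1-cm size class")
    ax.set_ylabel("count")
    ax.legend()
    path = outdir / "histogram.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
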