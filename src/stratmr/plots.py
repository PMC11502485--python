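"""Optional rendering of funnel and dosage diagnostics.

Separated from plot-data computation (:func:`stratmr.pipeline.diagnostic_plot_data`)
so analyses remain testable without a graphics stack; matplotlib is imported
lazily.
"""

from __future__ import annotations

from pathlib import Path

from .pipeline import PlotData


def render_funnel(data: PlotData, path: str | Path, title: str = "") -> Path:
    """Wald ratio vs precision scatter with per-method reference lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(data.funnel_points["ratio"], data.funnel_points["precision"], s=12, alpha=0.7)
    for row in data.funnel_lines.itertuples(index=False):
        ax.axvline(row.estimate, linestyle="--", linewidth=1, label=row.method)
    ax.set_xlabel("per-SNP causal estimate (Wald ratio)")
    ax.set_ylabel("precision (1 / se)")
    if title:
        ax.set_title(title)
    if len(data.funnel_lines):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def render_dosage(data: PlotData, path: str | Path, title: str = "") -> Path:
    """SNP–exposure vs SNP–outcome scatter with fitted model lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        data.dosage_points["beta_x"],
        data.dosage_points["beta_y"],
        yerr=data.dosage_points["se_y"],
        fmt="o",
        markersize=3,
        alpha=0.6,
        linestyle="none",
    )
    if len(data.dosage_points):
        xs = np.linspace(0, float(data.dosage_points["beta_x"].max()) * 1.05, 50)
        for row in data.dosage_lines.itertuples(index=False):
            ax.plot(xs, row.intercept + row.slope * xs, linewidth=1, label=row.method)
        ax.legend(fontsize=8)
    ax.set_xlabel("SNP–exposure effect")
    ax.set_ylabel("SNP–outcome effect")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
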