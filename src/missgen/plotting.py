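"""Static summary plots for study reports."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def violin_report(report: pd.DataFrame, path: str | Path) -> None:
    """Violin plots of per-variable imputation accuracy by method and regime."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = sorted(report["metric"].unique())
    regimes = sorted(report["regime"].unique())
    fig, axes = plt.subplots(
        len(metrics), len(regimes),
        figsize=(1.2 * report["method"].nunique() * len(regimes) + 2, 4 * len(metrics)),
        squeeze=False,
    )
    for i, metric in enumerate(metrics):
        for j, regime in enumerate(regimes):
            ax = axes[i][j]
            sub = report[(report["metric"] == metric) & (report["regime"] == regime)]
            methods = sorted(sub["method"].unique())
            data = [sub.loc[sub["method"] == m, "value"].to_numpy() for m in methods]
            if data:
                ax.violinplot(data, showmedians=True)
                ax.set_xticks(range(1, len(methods) + 1))
                ax.set_xticklabels(methods, rotation=60, ha="right", fontsize=7)
            ax.set_title(f"{metric} — {regime}")
            ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
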