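"""Figure helpers. Kept separate so headless pipelines need not import them."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import seaborn as sns

from .prediction import PredictionReport


def prediction_delta_heatmap(report: PredictionReport, path) -> None:
    """Heatmap of d_pred - d_ctrl per (receptor, odorant), red = model beats control."""
    pivot = report.entries.pivot(index="odorant_id", columns="heldout_id", values="delta")
    lim = float(abs(pivot.to_numpy()).max()) or 1.0
    fig, ax = plt.subplots(figsize=(0.5 * pivot.shape[1] + 3, 0.35 * pivot.shape[0] + 2))
    sns.heatmap(pivot, cmap="RdBu", center=0.0, vmin=-lim, vmax=lim, ax=ax,
                cbar_kws={"label": "d_pred - d_ctrl (spikes)"})
    ax.set_xlabel("held-out receptor")
    ax.set_ylabel("odorant")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
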