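"""Small matplotlib report figures (never a gate in any analysis)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["abbreviation_curve", "score_scatter"]


def abbreviation_curve(summary: pd.DataFrame, path) -> None:
    """Mean subset-full correlation vs subset size, with +-1 SD band."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(
        summary["subset_size"], summary["mean_r"], yerr=summary["sd_r"],
        marker="o", capsize=3,
    )
    ax.set_xlabel("number of randomly selected items")
    ax.set_ylabel("correlation with full scale")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def score_scatter(x, y, xlabel: str, ylabel: str, path) -> None:
    """Scatter of two log discounting scores (e.g. novel scale vs MCQ)."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=12, alpha=0.7)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
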