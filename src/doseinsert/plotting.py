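"""Convenience plots: operating characteristics against the MTC threshold."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_oc_vs_lambda"]


def plot_oc_vs_lambda(df: pd.DataFrame, out_path: str) -> None:
    """One panel per scenario: PCS/PAS/PSS/PTS and insertion rate vs lambda."""
    scenarios = list(dict.fromkeys(df["scenario"]))
    fig, axes = plt.subplots(1, len(scenarios), figsize=(4 * len(scenarios), 3.5),
                             squeeze=False, sharey=True)
    series = [("PCS (%)", "tab:green"), ("PAS (%)", "tab:blue"),
              ("PSS (%)", "tab:orange"), ("PTS (%)", "tab:red"),
              ("Insertions (%)", "tab:cyan")]
    for ax, scen in zip(axes[0], scenarios):
        sub = df[df["scenario"] == scen].sort_values("lambda")
        for col, color in series:
            ax.plot(sub["lambda"], sub[col], marker="o", ms=3, color=color,
                    label=col)
        ax.set_title(f"Scenario {scen}")
        ax.set_xlabel("MTC threshold")
        ax.set_ylim(0, 100)
    axes[0][0].set_ylabel("%")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
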