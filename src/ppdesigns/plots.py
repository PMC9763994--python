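"""Accuracy and efficiency planes for candidate designs (vector output)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .calibration import OCRecord

__all__ = ["plot_accuracy", "plot_efficiency"]


def _split(records: list[OCRecord], optimal: OCRecord | None):
    def is_opt(r):
        return optimal is not None and (r.theta, r.theta_star) == (
            optimal.theta,
            optimal.theta_star,
        )

    rest = [r for r in records if not is_opt(r)]
    opt = [r for r in records if is_opt(r)]
    return rest, opt


def plot_accuracy(
    records: list[OCRecord], optimal: OCRecord | None = None, path: str | Path | None = None
):
    """Type I error versus power, one point per threshold combination."""
    rest, opt = _split(records, optimal)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        [r.calibration_type1 for r in rest],
        [r.calibration_power for r in rest],
        s=18, color="#4477aa", alpha=0.8, label="candidate designs",
    )
    if opt:
        ax.scatter(
            [r.calibration_type1 for r in opt],
            [r.calibration_power for r in opt],
            s=90, color="#ee7733", marker="D", label="optimal efficiency",
        )
    ax.axvspan(0.05, 0.1, color="grey", alpha=0.12)
    ax.axhline(0.8, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("type I error")
    ax.set_ylabel("power")
    ax.set_title(f"{records[0].design} design: accuracy")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_efficiency(
    records: list[OCRecord], optimal: OCRecord | None = None, path: str | Path | None = None
):
    """Average total sample size under the null versus under the alternative."""
    rest, opt = _split(records, optimal)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        [r.avg_n_null for r in rest],
        [r.avg_n_alt for r in rest],
        s=18, color="#4477aa", alpha=0.8, label="candidate designs",
    )
    if opt:
        ax.scatter(
            [r.avg_n_null for r in opt],
            [r.avg_n_alt for r in opt],
            s=90, color="#ee7733", marker="D", label="optimal efficiency",
        )
    ax.set_xlabel("average total N under the null")
    ax.set_ylabel("average total N under the alternative")
    ax.set_title(f"{records[0].design} design: efficiency")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
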