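"""Diagnostic figures: Bland-Altman agreement plot and ROC curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import AgreementResult, RocResult

__all__ = ["plot_bland_altman", "plot_roc"]


def plot_bland_altman(est, ref, result: AgreementResult, path: str | Path) -> None:
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    mean = (est + ref) / 2.0
    diff = est - ref
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=4, alpha=0.4)
    for yv, style, label in (
        (result.bias_mmhg, "-", f"bias {result.bias_mmhg:.2f}"),
        (result.loa_low_mmhg, "--", f"LoA {result.loa_low_mmhg:.2f}"),
        (result.loa_high_mmhg, "--", f"LoA {result.loa_high_mmhg:.2f}"),
    ):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
        ax.annotate(label, (0.99, yv), xycoords=("axes fraction", "data"), ha="right", fontsize=8)
    ax.set_xlabel("mean of nICP and invasive ICP (mmHg)")
    ax.set_ylabel("nICP − invasive ICP (mmHg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(roc: RocResult, path: str | Path) -> None:
    fpr = [p[0] for p in roc.curve]
    tpr = [p[1] for p in roc.curve]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k:", linewidth=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
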