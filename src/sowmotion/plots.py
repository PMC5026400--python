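"""Plot helpers for behaviour profiles (matplotlib, non-interactive)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .behaviour_profiles import BehaviourProfile
from .transition_features import FEATURE_NAMES

__all__ = ["plot_ecdf_grid", "plot_transition_frequency"]


def plot_ecdf_grid(profiles: dict, out_path) -> None:
    """Per-feature ECDFs of every animal against the pooled baseline."""
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, name in zip(axes.ravel(), FEATURE_NAMES):
        baseline = None
        for prof in profiles.values():
            if name not in prof.ecdf_per_feature:
                continue
            own, base = prof.ecdf_per_feature[name]
            xs = own.values
            ax.step(xs, np.arange(1, own.n + 1) / own.n, where="post", lw=0.8,
                    label=prof.animal_id)
            baseline = base
        if baseline is not None:
            xs = baseline.values
            ax.step(xs, np.arange(1, baseline.n + 1) / baseline.n, where="post",
                    lw=2.0, color="navy", label="baseline")
        ax.set_title(name)
        ax.set_ylim(0, 1.02)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_transition_frequency(prof: BehaviourProfile, out_path) -> None:
    """Transition count per 2-h window against window-centre time."""
    fig, ax = plt.subplots(figsize=(9, 3))
    tf = prof.transition_frequency
    ax.plot(tf["window_center_s"] / 3600.0, tf["count"], lw=1.2)
    ax.set_xlabel("time [h]")
    ax.set_ylabel("transitions / 2 h")
    ax.set_title(prof.animal_id)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
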