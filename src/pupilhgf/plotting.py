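"""Basic figures: belief trajectories and group beta weights."""

from __future__ import annotations

import numpy as np

from .hgf import HGFTrajectory


def plot_trajectory(traj: HGFTrajectory, y=None, ax=None):
    """Inputs, responses, posterior belief and learning rate over trials."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    trials = np.arange(1, len(traj) + 1)
    ax.plot(trials, traj.mu1hat, color="tab:red", label=r"$\hat\mu_1$ (belief)")
    ax.plot(trials, traj.alpha_lr / traj.alpha_lr.max(), color="black", lw=0.8,
            label=r"$\alpha$ (scaled)")
    ax.scatter(trials, traj.u, s=8, color="tab:green", label="inputs u", zorder=3)
    if y is not None:
        ax.scatter(trials, np.asarray(y) * 1.05 - 0.025, s=8, color="tab:cyan",
                   label="responses y", zorder=3)
    ax.set(xlabel="trial", ylabel="p(normal)", ylim=(-0.1, 1.15))
    ax.legend(loc="center right", fontsize=8)
    return ax


def plot_betas(betas, ax=None):
    """Per-participant beta weights by predictor and source."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    order = sorted(betas["predictor"].unique())
    for i, source in enumerate(sorted(betas["source"].unique())):
        sub = betas[betas["source"] == source]
        means = [sub[sub["predictor"] == p]["beta"].mean() for p in order]
        pos = np.arange(len(order)) + 0.35 * i
        ax.bar(pos, means, width=0.3, label=source)
        for j, p in enumerate(order):
            vals = sub[sub["predictor"] == p]["beta"].dropna()
            ax.scatter(np.full(len(vals), pos[j]), vals, s=6, color="k", alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xticks(np.arange(len(order)) + 0.175, order)
    ax.set(ylabel=r"$\beta$ (SD pupil / SD predictor)")
    ax.legend()
    return ax
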