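"""Optional plots: tracking-accuracy bars with chance line, TRF curves with
significance shading."""
from __future__ import annotations

import numpy as np


def plot_tracking_bars(tracking_df, out_path, chance: float | None = None):
    """Grouped bars of mean tracking r per band x group with a chance line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = tracking_df.groupby(["band", "group"]).r.mean().unstack()
    ax = summary.plot.bar(rot=0, figsize=(6, 4))
    if chance is not None and np.isfinite(chance):
        ax.axhline(chance, ls=":", color="k", label="chance")
    ax.set_ylabel("prediction accuracy (Pearson r)")
    ax.legend(frameon=False)
    ax.figure.tight_layout()
    ax.figure.savefig(out_path, dpi=150)
    plt.close(ax.figure)


def plot_trf_curves(lags_ms, curves_by_group, out_path, sig_mask=None):
    """Group-mean TRF time courses with a shaded significant-lag region."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curves in curves_by_group.items():
        curves = np.atleast_2d(np.asarray(curves))
        ax.plot(lags_ms, curves.mean(axis=0), label=label)
    if sig_mask is not None and np.any(sig_mask):
        ylim = ax.get_ylim()
        ax.fill_between(lags_ms, *ylim, where=sig_mask, alpha=0.15, color="gray")
        ax.set_ylim(ylim)
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("beta weight")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
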