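"""Diagnostic plotting helpers (matplotlib; figures only, no statistics)."""

from __future__ import annotations

import numpy as np


def heatmap_cross_temporal(matrix, ax=None, cmap="RdBu_r"):
    """Plot a cross-temporal correlation matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = matrix.time_axis
    im = ax.imshow(
        matrix.values, origin="lower", cmap=cmap, vmin=-1, vmax=1,
        extent=[t[0], t[-1] + matrix.bin_width, t[0], t[-1] + matrix.bin_width],
    )
    ax.set_xlabel("observation time (ms)")
    ax.set_ylabel("execution time (ms)")
    ax.figure.colorbar(im, ax=ax, label="r")
    return ax


def population_heatmap(tensor, ax=None, cmap="RdBu_r"):
    """Neurons x time heatmap of (normalized) population rates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vmax = np.nanmax(np.abs(tensor.values)) or 1.0
    t = tensor.time_axis
    im = ax.imshow(
        tensor.values, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax,
        extent=[t[0], t[-1] + tensor.bin_width, tensor.values.shape[0], 0],
    )
    for name, tc in tensor.canonical_events.items():
        ax.axvline(tc, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron")
    ax.figure.colorbar(im, ax=ax)
    return ax


def trajectory_2d(traj, ax=None, **kwargs):
    """First two principal components of a projected trajectory."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj[:, 0], traj[:, 1], **kwargs)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    return ax
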