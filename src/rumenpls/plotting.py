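"""Optional score-plot helper (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .pls import PlsModel, fit_pls


def plot_scores(model: PlsModel, X, y, path=None, ax=None):
    """Scatter the first two latent-component scores, coloured by class
    (discriminant) or response value (regression).

    With a one-component model a second component is fitted for display
    only.  Returns the matplotlib axes; writes ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if model.n_components >= 2:
        T = model.T[:, :2]
    else:
        # refit with two components purely for visualisation
        X2 = np.asarray(X, dtype=float)
        h2 = min(2, X2.shape[1], X2.shape[0] - 1)
        T = fit_pls(X2, y, h=h2).T
        if T.shape[1] < 2:
            T = np.column_stack([T[:, 0], np.zeros(len(T))])

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    yarr = np.asarray(y)
    if model.mode == "discriminant":
        for cls, marker in zip(np.unique(yarr), "os"):
            m = yarr == cls
            ax.scatter(T[m, 0], T[m, 1], label=str(cls), marker=marker)
        ax.legend(title="class")
    else:
        sc = ax.scatter(T[:, 0], T[:, 1], c=yarr.astype(float))
        ax.figure.colorbar(sc, ax=ax, label="response")
    ax.set_xlabel("component 1 score")
    ax.set_ylabel("component 2 score")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
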