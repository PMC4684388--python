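"""Report figures: method-comparison bars and fit diagnostics."""

from __future__ import annotations

import numpy as np

from .allometry import COMPONENTS

__all__ = ["plot_rmse_rc", "plot_fit"]


def plot_rmse_rc(ci_frame, ax=None):
    """Grouped bar chart of RMSE_rc (%) by component with bootstrap CIs.

    ``ci_frame`` is the tidy frame from
    :func:`allocarbon.carbon.bootstrap_rmse_rc`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    series = list(COMPONENTS) + ["total"]
    methods = sorted(ci_frame["method"].unique())
    width = 0.8 / len(methods)
    for k, method in enumerate(methods):
        sl = ci_frame[ci_frame["method"] == method].set_index("component").loc[series]
        pos = np.arange(len(series)) + (k - (len(methods) - 1) / 2) * width
        err = np.vstack(
            [sl["rmse_rc"] - sl["ci_lower"], sl["ci_upper"] - sl["rmse_rc"]]
        )
        ax.bar(pos, sl["rmse_rc"], width=width, yerr=err, capsize=2, label=f"Method {method}")
    ax.set_xticks(np.arange(len(series)))
    ax.set_xticklabels(series)
    ax.set_ylabel("RMSE$_{rc}$ (%)")
    ax.legend(frameon=False)
    return ax


def plot_fit(results, ax=None):
    """Observed vs fitted component masses against the predictor."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = results.model.x
    order = np.argsort(x)
    for j, name in enumerate(COMPONENTS):
        pts = ax.plot(x, results.model.endog[:, j], ".", ms=4, alpha=0.6, label=name)
        ax.plot(x[order], results.fittedvalues[order, j], "-", color=pts[0].get_color(), lw=1)
    ax.set_xlabel(f"predictor {results.model.spec.predictor.value}")
    ax.set_ylabel(results.model.spec.response.value + " (kg)")
    ax.legend(frameon=False)
    return ax
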