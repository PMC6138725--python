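"""Basic plots for combination-index results."""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError


def ci_heatmap(ci_table: pd.DataFrame, cell_line: str, method: str = "bliss", ax=None):
    """Heat map of combination indices over the dose grid of one cell line.

    ``ci_table`` is the output of :func:`coopsyn.synergy.grid_ci`. Values
    below 1 (cooperative) render blue, above 1 red. Returns the axes.
    """
    import matplotlib.pyplot as plt  # deferred: headless use never imports it

    sub = ci_table[(ci_table["cell_line"] == cell_line) & (ci_table["method"] == method)]
    if sub.empty:
        raise ValidationError(f"no CI rows for cell line {cell_line!r} / method {method!r}")
    grid = sub.pivot(index="dose_opc", columns="dose_cur", values="ci").sort_index(ascending=False)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.6 * grid.shape[1], 1.0 + 0.5 * grid.shape[0]))
    im = ax.imshow(grid.to_numpy(), cmap="coolwarm", vmin=0.0, vmax=2.0, aspect="auto")
    ax.set_xticks(range(grid.shape[1]), [f"{d:g}" for d in grid.columns])
    ax.set_yticks(range(grid.shape[0]), [f"{d:g}" for d in grid.index])
    ax.set_xlabel("curcumin dose (ng/ul)")
    ax.set_ylabel("OPCs dose (ng/ul)")
    ax.set_title(f"{cell_line}: {method.upper()} combination index")
    ax.figure.colorbar(im, ax=ax, label="CI (<1 cooperative)")
    return ax
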