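"""Diagnostic plots: Hanes-Woolf and integrated-equation views of a dataset.

Optional output only; nothing in the analysis depends on these figures.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import Measurement
from .estimators import FitResult, RateEstimate


def hanes_woolf_plot(rates: Sequence[RateEstimate], fit: Optional[FitResult] = None, ax=None):
    """s0/v against s0; curvature upward signals [P]/t bias at high conversion."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s0 = np.array([r.s0 for r in rates])
    v = np.array([r.v_hat for r in rates])
    ax.plot(s0, s0 / v, "o", color="k", label="data")
    if fit is not None:
        xs = np.linspace(0, 1.05 * s0.max(), 100)
        ax.plot(xs, (fit.Km_hat + xs) / fit.V_hat, "-", color="tab:blue",
                label=f"fit: V={fit.V_hat:.3g}, Km={fit.Km_hat:.3g}")
        ax.legend()
    ax.set_xlabel("[S]0")
    ax.set_ylabel("[S]0 / v")
    return ax


def integrated_plot(measurements: Sequence[Measurement], fit: Optional[FitResult] = None, ax=None):
    """[P]/t against (1/t) ln(s0/(s0-p)); linear with intercept V, slope -Km."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ms = [m for m in measurements if m.p > 0 and m.t > 0]
    s0 = np.array([m.s0 for m in ms])
    t = np.array([m.t for m in ms])
    p = np.array([m.p for m in ms])
    x = np.log(s0 / (s0 - p)) / t
    ax.plot(x, p / t, "o", color="k", label="data")
    if fit is not None:
        xs = np.linspace(0, 1.05 * x.max(), 50)
        ax.plot(xs, fit.V_hat - fit.Km_hat * xs, "-", color="tab:red",
                label=f"fit: V={fit.V_hat:.3g}, Km={fit.Km_hat:.3g}")
        ax.legend()
    ax.set_xlabel("(1/t) ln([S]0/([S]0-[P]))")
    ax.set_ylabel("[P]/t")
    return ax
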