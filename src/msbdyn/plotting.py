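"""Optional plots of pair dynamics (integrated densities and DiffIndex trend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .dynamics import PairDynamics  # noqa: E402

__all__ = ["plot_pair_dynamics"]


def plot_pair_dynamics(pair: PairDynamics, path=None):
    """Two-panel figure: head integrated densities over time, and the
    DiffIndex series with its fitted linear trend. Saves to ``path`` when
    given, otherwise returns the figure."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3), constrained_layout=True)
    ax1.plot(pair.times, pair.intden_dom, "o-", label="dominant")
    ax1.plot(pair.times, pair.intden_nondom, "s-", label="nondominant")
    ax1.set_xlabel("time (h)")
    ax1.set_ylabel("integrated density (a.u.)")
    ax1.legend(frameon=False)
    ax2.plot(pair.times, pair.diff_index, "o", color="k")
    import numpy as np
    valid = ~np.isnan(pair.diff_index)
    t0, t1 = pair.times[0], pair.times[-1]
    tm = pair.times[valid].mean()
    ym = pair.diff_index[valid].mean()
    # OLS trend passes through the (mean time, mean DiffIndex) point
    ax2.plot([t0, t1],
             [ym + pair.dominance_rate * (t0 - tm),
              ym + pair.dominance_rate * (t1 - tm)],
             "r-", label=f"rate {pair.dominance_rate:.3f}/h, R² {pair.r_squared:.2f}")
    ax2.set_xlabel("time (h)")
    ax2.set_ylabel("DiffIndex")
    ax2.set_ylim(-1.05, 1.05)
    ax2.legend(frameon=False)
    fig.suptitle(f"pair {pair.pair_id} ({pair.pair_class})")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return str(path)
    return fig
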