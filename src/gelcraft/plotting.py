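"""Quick-look plots for gelation kinetics and pore-size distributions."""

from __future__ import annotations

import numpy as np

from .integrator import KineticsLog
from .structure_analysis import PoreSizeDistribution, normalize_kinetics


def plot_kinetics(log: KineticsLog, ax=None, normalized: bool = True, **kwargs):
    """Plot the interaction count (optionally I/I_max) against stage time."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    t = np.asarray(log.time_ps) / 1e3
    if normalized:
        ax.plot(t, normalize_kinetics(log), **kwargs)
        ax.set_ylabel(r"$I/I_{\max}$")
    else:
        ax.plot(t, log.interactions, **kwargs)
        ax.set_ylabel("intermolecular interactions $I$")
    ax.set_xlabel("time / ns")
    return ax


def plot_psd(psd: PoreSizeDistribution, ax=None, **kwargs):
    """Bar plot of the incremental pore volume per discretization window."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    lo = psd.window_edges_nm[:-1]
    hi = psd.window_edges_nm[1:]
    ax.bar((lo + hi) / 2, psd.incremental_volumes_nm3, width=hi - lo,
           edgecolor="k", **kwargs)
    ax.set_xlabel(r"pore width $d_{P}$ / nm")
    ax.set_ylabel(r"incremental pore volume / nm$^3$")
    return ax
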