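"""Optional monitoring-figure conveniences (all acceptance surfaces are the
tabular outputs; these are visual aids only)."""

from __future__ import annotations

import numpy as np

from .control_charts import alarm_sparks


def plot_monitoring(result, path) -> None:
    """Four control-chart panels with alarm spark rows, plus the patient's
    raw signals over the reference trajectory band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    signals = list(result.trajectory_map.mean)
    n_sig = len(signals)
    fig, axes = plt.subplots(n_sig + 4, 1, figsize=(10, 2 * (n_sig + 4)),
                             sharex=True)
    tmap = result.trajectory_map
    for ax, sig in zip(axes[:n_sig], signals):
        m, s = tmap.mean[sig], tmap.sd[sig]
        ax.fill_between(tmap.minutes, m - s, m + s, alpha=0.3, lw=0,
                        label="reference +/- 1 SD")
        ax.plot(tmap.minutes, m, lw=1, label="reference mean")
        tr = result.record.traces[sig]
        ax.plot(tr.minutes, tr.value, lw=0.6, color="0.25", label="patient")
        ax.set_ylabel(sig)
    axes[0].legend(loc="upper right", fontsize=7)
    for ax, (name, chart) in zip(axes[n_sig:], result.charts.items()):
        ax.plot(chart.minutes, chart.statistic, lw=0.6)
        ax.fill_between(chart.minutes, 0, chart.limit, alpha=0.25, lw=0)
        top = np.nanmax(chart.statistic) if np.isfinite(chart.statistic).any() else 1.0
        for a, b in alarm_sparks(chart):
            ax.plot([a, b], [top * 1.05] * 2, lw=3, color="crimson",
                    solid_capstyle="butt")
        ax.set_ylabel(name)
        ax.set_yscale("symlog")
    axes[-1].set_xlabel("minutes since operation end")
    fig.suptitle(f"patient {result.patient_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
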