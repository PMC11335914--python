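"""Quick-look matplotlib figures for fits and recovery studies."""

from __future__ import annotations

import numpy as np

from .assess import RecoveryReport, defective_cdf_percentiles

__all__ = [
    "plot_defective_cdfs",
    "plot_inhibition_function",
    "plot_recovery",
]


def plot_defective_cdfs(table, predicted=None, ax=None):
    """Defective cumulative RT distributions per response, with the
    response probability as the upper asymptote; optionally overlays
    posterior predictive percentile clouds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n = len(table)
    for resp, style in (("blue", "-"), ("orange", "--")):
        rts = np.sort(
            table.loc[table.response == resp, "rt"].dropna().to_numpy()
        )
        if rts.size == 0:
            continue
        ax.step(rts, np.arange(1, rts.size + 1) / n, style, label=resp)
        pct = defective_cdf_percentiles(
            table.rt.to_numpy(), table.response.to_numpy()
        ).set_index("response")
        if resp in pct.index:
            prop = pct.at[resp, "proportion"]
            xs = [pct.at[resp, f"p{p}"] for p in (10, 30, 50, 70, 90)]
            ax.plot(xs, [prop * p / 100 for p in (10, 30, 50, 70, 90)], "o",
                    mfc="none", color=f"C{0 if resp == 'blue' else 1}")
    if predicted is not None:
        for rep in predicted:
            for resp in ("blue", "orange"):
                rts = np.sort(rep.loc[rep.response == resp, "rt"].dropna().to_numpy())
                if rts.size:
                    ax.step(rts, np.arange(1, rts.size + 1) / len(rep),
                            color="grey", alpha=0.15, lw=0.5)
    ax.set_xlabel("RT (s)")
    ax.set_ylabel("defective CDF")
    ax.legend()
    return ax


def plot_inhibition_function(observed, predicted=None, ax=None):
    """Probability of responding on stop trials by SSD bin, observed
    (open circles) vs predicted (points with 95% intervals)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(observed.mean_ssd, observed.p_respond, "o-", mfc="none",
            label="observed")
    if predicted is not None:
        grouped = predicted.groupby("bin")
        mean = grouped[["mean_ssd", "p_respond"]].mean()
        lo = grouped["p_respond"].quantile(0.025)
        hi = grouped["p_respond"].quantile(0.975)
        ax.errorbar(mean.mean_ssd, mean.p_respond,
                    yerr=[mean.p_respond - lo, hi - mean.p_respond],
                    fmt="s", label="predicted")
    ax.set_xlabel("SSD (s)")
    ax.set_ylabel("p(respond)")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_recovery(report: RecoveryReport, types=("B", "v", "t0"), axes=None):
    """True vs replicate-averaged estimated values per parameter type,
    with the identity line."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, len(types), figsize=(4 * len(types), 4))
    avg = report.averaged_means
    corr = report.correlation_by_type()
    for ax, ptype in zip(np.atleast_1d(axes), types):
        idx = [j for j, lab in enumerate(report.labels)
               if lab.split(".")[0] == ptype]
        x = report.truths[:, idx].ravel()
        y = avg[:, idx].ravel()
        ax.plot(x, y, "o", alpha=0.6)
        lims = [min(x.min(), np.nanmin(y)), max(x.max(), np.nanmax(y))]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_title(f"{ptype} (r = {corr.get(ptype, float('nan')):.2f})")
        ax.set_xlabel("true")
        ax.set_ylabel("estimated")
    return axes
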