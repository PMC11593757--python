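"""Observed-versus-expected trajectory plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_observed_vs_band(monthly: pd.DataFrame, path, max_panels: int = 12) -> None:
    """Plot observed monthly rates against the composite expectation band.

    One panel per factor (overall series only when the frame is
    stratified: the first stratum is shown).  ``monthly`` must carry
    ``factor``, ``month``, ``observed``, ``L`` and ``U``.
    """
    factors = list(pd.unique(monthly["factor"]))[:max_panels]
    ncols = 3 if len(factors) > 4 else min(2, len(factors))
    ncols = max(ncols, 1)
    nrows = -(-len(factors) // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.2 * ncols, 2.8 * nrows), squeeze=False
    )
    for ax in axes.flat[len(factors):]:
        ax.set_visible(False)
    for ax, factor in zip(axes.flat, factors):
        sub = monthly[monthly["factor"] == factor]
        strata = [c for c in sub.columns if c in
                  ("age_band", "sex", "ethnicity", "imd_quintile")]
        if strata:
            first = sub[strata[0]].iloc[0]
            sub = sub[sub[strata[0]] == first]
        x = [pd.Period(m, freq="M").to_timestamp() for m in sub["month"]]
        ax.fill_between(x, sub["L"], sub["U"], alpha=0.3, color="tab:blue",
                        label="expectation band")
        ax.plot(x, sub["observed"], color="black", lw=1.0, label="observed")
        ax.set_title(factor, fontsize=9)
        ax.tick_params(labelsize=7)
    axes.flat[0].legend(fontsize=7)
    fig.suptitle("Monthly measurements per 1,000 individuals", fontsize=11)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
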