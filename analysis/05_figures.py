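#!/usr/bin/env python
"""Growth and learning-curve figures from the simulated cohorts.

Plots group-mean body-weight trajectories and water-maze latency /
success-rate curves per age group into results/figures/.  Requires
matplotlib (the package's optional 'plot' extra).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import rfcohort.calibration as cal
from rfcohort.cohort import read_table_csv
from rfcohort.endpoints import mwm_daily_summary, summarize_weights

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "figures"
STYLE = {"control": dict(color="tab:blue", marker="o"),
         "exposed": dict(color="tab:red", marker="s")}


def main() -> None:
    cohorts = BASE / "cohorts"
    animals = pd.concat([read_table_csv(p) for p in sorted(cohorts.glob("animals_*.csv"))],
                        ignore_index=True)
    trials = pd.concat([read_table_csv(p) for p in sorted(cohorts.glob("trials_*.csv"))],
                       ignore_index=True)
    OUT.mkdir(parents=True, exist_ok=True)

    weights = summarize_weights(animals).data
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=False)
    for ax, age in zip(axes, cal.AGE_GROUPS):
        for arm in cal.ARMS:
            sub = weights[(weights["age_group"] == age) & (weights["arm"] == arm)]
            ax.errorbar(range(len(sub)), sub["mean"], yerr=sub["dispersion"],
                        label=arm, capsize=3, **STYLE[arm])
        ax.set_title(f"{age} rats")
        ax.set_xticks(range(len(cal.WEIGHT_TIMEPOINTS)),
                      cal.WEIGHT_TIMEPOINTS, rotation=45)
        ax.set_ylabel("body weight [g]")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(OUT / "growth_curves.png", dpi=150)

    mwm = mwm_daily_summary(trials)
    fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True)
    for col, age in enumerate(cal.AGE_GROUPS):
        for arm in cal.ARMS:
            sub = mwm[(mwm["age_group"] == age) & (mwm["arm"] == arm)]
            axes[0, col].errorbar(sub["day"], sub["mean_successful_latency_s"],
                                  yerr=sub["dispersion_s"], label=arm,
                                  capsize=3, **STYLE[arm])
            axes[1, col].plot(sub["day"], sub["percent_successful"],
                              label=arm, **STYLE[arm])
        axes[0, col].set_title(f"{age} rats")
        axes[1, col].set_xlabel("testing day")
    axes[0, 0].set_ylabel("successful latency [s]")
    axes[1, 0].set_ylabel("successful swims [%]")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(OUT / "learning_curves.png", dpi=150)

    print(f"wrote growth_curves.png and learning_curves.png to {OUT}")


if __name__ == "__main__":
    main()
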