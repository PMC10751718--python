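"""Convenience figures for Fano test results (matplotlib, lazily imported)."""

from __future__ import annotations

import numpy as np


def plot_region_deviations(result, ax=None):
    """Relative deviation per region with error bars (percent)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = result.testable
    ax.errorbar(t["region_id"], 100 * t["delta_rel"],
                yerr=100 * 2 * t["sigma_rel"], fmt="o", capsize=3,
                label="simulated (2 sigma bars)")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.axhline(0.1, color="r", ls="--", lw=0.8, label="0.1 % pass band")
    ax.axhline(-0.1, color="r", ls="--", lw=0.8)
    ax.set_xticks(t["region_id"])
    ax.set_xticklabels(t["name"], rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("dose deviation from Fano value [%]")
    md = result.metadata
    ax.set_title(f"E0={md.get('energy')} MeV  |B|={np.linalg.norm(md.get('b_field', (0,)*3)):g} T  "
                 f"EM ESTEPE={md.get('em_estepe')}")
    ax.legend(fontsize=8)
    ax.figure.tight_layout()
    return ax


def plot_deviation_vs_em_estepe(report_frame, region_label="sensitive volume",
                                ax=None):
    """Max |deviation| per cell against the magnetic step-size fraction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for (energy, b), grp in report_frame.groupby(["energy_mev", "b_tesla"]):
        grp = grp.sort_values("em_estepe")
        ax.plot(grp["em_estepe"], 100 * grp["max_abs_delta"], "o-",
                label=f"{energy:g} MeV, {b:g} T")
    ax.axhline(0.1, color="r", ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("EM ESTEPE (fraction of gyroradius)")
    ax.set_ylabel(f"max |dose deviation| [%] ({region_label})")
    ax.legend(fontsize=8)
    ax.figure.tight_layout()
    return ax
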