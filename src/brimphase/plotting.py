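"""Convenience plots: spectrum fit overlay and cohort violin plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .brillouin import BrillouinResult, BrillouinSpectrum, lorentzian


def plot_spectrum_fit(spectrum: BrillouinSpectrum, result: BrillouinResult,
                      ax: plt.Axes | None = None) -> plt.Axes:
    """Overlay the fitted Stokes/anti-Stokes Lorentzians on the data."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    f = spectrum.frequency_ghz
    ax.plot(f, spectrum.counts, ".", ms=2, color="0.5", label="data")
    for pk, name in ((result.stokes, "Stokes"), (result.antistokes, "anti-Stokes")):
        ff = np.linspace(pk.center_ghz - 3 * pk.fwhm_ghz,
                         pk.center_ghz + 3 * pk.fwhm_ghz, 200)
        ax.plot(ff, lorentzian(ff, pk.amplitude, pk.center_ghz, pk.fwhm_ghz,
                               pk.offset), label=name)
    ax.set_xlabel("frequency (GHz)")
    ax.set_ylabel("counts")
    ax.set_title(f"ν_B = {result.nu_b_ghz:.3f} GHz, "
                 f"Γ_B = {result.gamma_b_ghz:.3f} GHz")
    ax.legend(fontsize=8)
    return ax


def violin(table: pd.DataFrame, parameter: str,
           ax: plt.Axes | None = None) -> plt.Axes:
    """Violin plot of one parameter across conditions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    conditions = list(table["condition"].unique())
    data = [table.loc[table["condition"] == c, parameter].dropna()
            for c in conditions]
    ax.violinplot(data, showmeans=True)
    ax.set_xticks(range(1, len(conditions) + 1), conditions)
    ax.set_ylabel(parameter)
    return ax
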