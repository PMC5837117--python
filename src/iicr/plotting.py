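"""PSMC-style step plots of IICR curves (side-effect only, never mutates data)."""

from __future__ import annotations

import numpy as np

from .curves import IICRCurve

__all__ = ["plot_curve"]


def plot_curve(curve: IICRCurve, ax=None, label: str | None = None,
               diploid: bool = False, **kwargs):
    """Draw a curve as a log-time step plot in the style of PSMC output.

    ``diploid=True`` divides displayed sizes by two (diploid individuals
    instead of haploid genes) and labels the axis accordingly; the curve
    object itself is never modified.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = curve.defined() & (curve.times > 0)
    values = curve.values[ok] / (2.0 if diploid else 1.0)
    kwargs.setdefault("drawstyle", "steps-post")
    ax.plot(curve.times[ok], values, label=label, **kwargs)
    ax.set_xscale("log")
    ax.set_yscale("log")
    unit = {"coalescent": "N_ref generations",
            "generations": "generations", "years": "years"}[curve.time_unit]
    ax.set_xlabel(f"time ({unit})")
    size = "N_ref multiples" if curve.size_unit == "N_ref" else "haploid genes"
    if diploid:
        size = size.replace("haploid genes", "diploid individuals")
    ax.set_ylabel(f"IICR ({size})")
    if label:
        ax.legend()
    return ax
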