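"""Unit conversion between coalescent-scaled and physical curves.

Internally every curve lives on the coalescent scale: time in units of
``N_ref`` generations, IICR in multiples of ``N_ref``.  For comparison with
sequence-based inferences (PSMC-style plots) times can be expressed in
generations or years and sizes in haploid gene counts.  Defaults follow the
scaling commonly used for human data: deme size ``N_ref = 500`` haploid
genes, 25 years per generation, and a per-site per-generation mutation rate
of 2.5e-8 (carried as metadata only — no sequence simulation happens here).
"""

from __future__ import annotations

from dataclasses import dataclass

from .curves import IICRCurve

__all__ = ["ScalingConfig", "scale_curve"]


@dataclass(frozen=True)
class ScalingConfig:
    """Physical constants used to scale coalescent units."""

    N_ref: float = 500.0
    generation_time: float = 25.0
    mutation_rate: float = 2.5e-8

    def __post_init__(self):
        if not (self.N_ref > 0 and self.generation_time > 0 and self.mutation_rate > 0):
            raise ValueError("all scaling constants must be positive")


def _time_factor(unit: str, config: ScalingConfig) -> float:
    if unit == "coalescent":
        return 1.0
    if unit == "generations":
        return config.N_ref
    if unit == "years":
        return config.N_ref * config.generation_time
    raise ValueError(f"unknown time unit {unit!r}")


def _size_factor(unit: str, config: ScalingConfig) -> float:
    if unit == "N_ref":
        return 1.0
    if unit == "haploid_genes":
        return config.N_ref
    raise ValueError(f"unknown size unit {unit!r}")


def scale_curve(
    curve: IICRCurve,
    config: ScalingConfig,
    time_unit: str = "years",
    size_unit: str = "haploid_genes",
) -> IICRCurve:
    """Re-express a curve in the requested units (exactly invertible).

    Times are multiplied by ``N_ref`` to give generations and additionally by
    ``generation_time`` to give years; IICR values are multiplied by
    ``N_ref`` to give haploid gene counts.  The coalescent-scale arrays ride
    along on the ``base`` attribute, so scaling followed by descaling
    restores the original curve bit-for-bit.
    """
    if curve.base is not None:
        base_t, base_v = curve.base
    elif curve.time_unit == "coalescent" and curve.size_unit == "N_ref":
        base_t, base_v = curve.times, curve.values
    else:
        base_t = curve.times / _time_factor(curve.time_unit, config)
        base_v = curve.values / _size_factor(curve.size_unit, config)
    tf = _time_factor(time_unit, config)
    sf = _size_factor(size_unit, config)
    return curve.with_(
        times=base_t if tf == 1.0 else base_t * tf,
        values=base_v if sf == 1.0 else base_v * sf,
        time_unit=time_unit,
        size_unit=size_unit,
        base=(base_t, base_v),
    )
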