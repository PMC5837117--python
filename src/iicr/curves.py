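"""The IICR curve container and its plain-text interchange format.

A curve is a strictly increasing time grid with one IICR value per point,
tagged with its units (coalescent / generations / years on the time axis,
multiples of ``N_ref`` or haploid gene counts on the size axis), how it was
obtained (``exact`` or ``estimated``), the sampling scheme and a short model
hash.  Estimated curves may contain NaN entries for grid bins with no
observed coalescence times; NaN and ``inf`` survive file round-trips.

File format: tab-separated ``time<TAB>iicr`` with ``#``-prefixed header
lines carrying the metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import IO

import numpy as np

__all__ = ["IICRCurve", "write_curve", "read_curve", "CurveParseError"]

TIME_UNITS = ("coalescent", "generations", "years")
SIZE_UNITS = ("N_ref", "haploid_genes")


class CurveParseError(ValueError):
    """Raised on a malformed curve file, naming the offending line."""


@dataclass(frozen=True)
class IICRCurve:
    """Time grid + IICR values + unit/provenance metadata."""

    times: np.ndarray
    values: np.ndarray
    time_unit: str = "coalescent"
    size_unit: str = "N_ref"
    provenance: str = "exact"
    sampling: tuple[int, int] | None = None
    model_hash: str | None = None
    bin_counts: np.ndarray | None = None
    #: coalescent-scale (times, values) retained by unit scaling so that
    #: descaling restores the original arrays bit-for-bit
    base: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        finite = v[np.isfinite(v)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("IICR values must be positive where defined")
        if self.time_unit not in TIME_UNITS:
            raise ValueError(f"unknown time unit {self.time_unit!r}")
        if self.size_unit not in SIZE_UNITS:
            raise ValueError(f"unknown size unit {self.size_unit!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def defined(self) -> np.ndarray:
        """Boolean mask of grid points with a finite IICR value."""
        return np.isfinite(self.values)

    def with_(self, **changes) -> "IICRCurve":
        return replace(self, **changes)

    def equals(self, other: "IICRCurve") -> bool:
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values, equal_nan=True)
            and self.time_unit == other.time_unit
            and self.size_unit == other.size_unit
            and self.provenance == other.provenance
            and self.sampling == other.sampling
            and self.model_hash == other.model_hash
        )


def write_curve(curve: IICRCurve, path: str | os.PathLike | IO[str]) -> None:
    """Write a curve as TSV with ``#`` metadata headers."""
    own = not hasattr(path, "write")
    fh = open(path, "w") if own else path
    try:
        fh.write("# iicr-curve v1\n")
        fh.write(f"# time_unit: {curve.time_unit}\n")
        fh.write(f"# size_unit: {curve.size_unit}\n")
        fh.write(f"# provenance: {curve.provenance}\n")
        if curve.sampling is not None:
            fh.write(f"# sampling: {curve.sampling[0]} {curve.sampling[1]}\n")
        if curve.model_hash is not None:
            fh.write(f"# model_hash: {curve.model_hash}\n")
        fh.write("time\tiicr\n")
        for t, v in zip(curve.times, curve.values):
            fh.write(f"{float(t)!r}\t{float(v)!r}\n")
    finally:
        if own:
            fh.close()


def read_curve(path: str | os.PathLike | IO[str]) -> IICRCurve:
    """Parse a curve TSV; round-trips :func:`write_curve` exactly."""
    own = not hasattr(path, "read")
    fh = open(path) if own else path
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    meta: dict[str, str] = {}
    times, values = [], []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        if line.startswith("time"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CurveParseError(f"line {lineno}: expected 'time<TAB>iicr'")
        try:
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError as exc:
            raise CurveParseError(f"line {lineno}: {exc}") from exc
    if "time_unit" not in meta or "size_unit" not in meta:
        raise CurveParseError("missing unit metadata header (# time_unit / # size_unit)")
    sampling = None
    if "sampling" in meta:
        a, b = meta["sampling"].split()
        sampling = (int(a), int(b))
    return IICRCurve(
        times=np.array(times),
        values=np.array(values),
        time_unit=meta["time_unit"],
        size_unit=meta["size_unit"],
        provenance=meta.get("provenance", "exact"),
        sampling=sampling,
        model_hash=meta.get("model_hash"),
    )
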