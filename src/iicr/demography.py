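"""Structured demographic models with piecewise-constant parameters.

A :class:`DemographicModel` is an ordered sequence of :class:`Epoch` objects,
each holding relative deme sizes and a scaled migration matrix, valid from its
``start_time`` (backward in time, in units of ``N_ref`` generations) until the
next epoch begins.  Deme counts may change between epochs only through a
*remap* applied, backward in time, at the instant the new epoch starts: every
lineage in deme ``d`` moves to deme ``remap[d]`` (with probability ``p`` for
admixture pulses, 1 for clean splits).

Migration follows the classical island-model convention ``M = 2Nm``: entry
``M[i][j]`` is the scaled rate at which a lineage currently in deme ``i``
traces its ancestry back to deme ``j`` (equivalently, the expected number of
haploid immigrant genes deme ``i`` receives from deme ``j`` per generation).
In the coalescent time scale used throughout (one unit = ``N_ref``
generations) a single lineage in deme ``i`` jumps to deme ``j`` at rate
``M[i][j] / 2``, and two lineages in a deme of relative size ``s`` coalesce at
rate ``1 / s``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Epoch",
    "Remap",
    "DemographicModel",
    "SamplingScheme",
    "make_n_island",
    "make_stepping_stone",
    "make_continent_island",
    "make_asymmetric_model",
    "make_custom_model",
    "add_population_split",
    "model_to_json",
    "model_from_json",
]


class ModelValidationError(ValueError):
    """Raised when a demographic model violates a structural invariant."""


@dataclass(frozen=True)
class Remap:
    """Lineage relocation applied at the start (backward in time) of an epoch.

    ``mapping`` sends deme indices of the *previous* epoch to deme indices of
    the epoch carrying the remap; demes absent from the mapping keep their
    index.  ``p`` is the per-lineage move probability: 1.0 is a deterministic
    merge (population split seen backward in time), values below 1 model an
    admixture pulse in which each lineage moves independently.  ``p`` may be a
    single float or a per-source-deme mapping.
    """

    mapping: Mapping[int, int]
    p: float | Mapping[int, float] = 1.0

    def move_probability(self, deme: int) -> float:
        if isinstance(self.p, Mapping):
            return float(self.p.get(deme, 1.0))
        return float(self.p)

    def target(self, deme: int) -> int:
        return int(self.mapping.get(deme, deme))


@dataclass(frozen=True)
class Epoch:
    """One piecewise-constant slice of a structured model.

    Parameters
    ----------
    start_time
        Epoch start, backward in time, in units of ``N_ref`` generations.
    deme_sizes
        Relative haploid deme sizes ``s_i`` (absolute size ``s_i * N_ref``).
    migration
        Square matrix of scaled rates in the ``M = 2Nm`` convention; the
        diagonal is ignored.
    remap_at_start
        Optional lineage relocation applied when this epoch begins.
    """

    start_time: float
    deme_sizes: tuple[float, ...]
    migration: tuple[tuple[float, ...], ...]
    remap_at_start: Remap | None = None

    @property
    def n_demes(self) -> int:
        return len(self.deme_sizes)

    def migration_matrix(self) -> np.ndarray:
        m = np.asarray(self.migration, dtype=float).copy()
        if m.size == 0:
            m = m.reshape(self.n_demes, self.n_demes)
        np.fill_diagonal(m, 0.0)
        return m


@dataclass(frozen=True)
class SamplingScheme:
    """Deme locations of the two sampled lineages at time 0."""

    deme_a: int
    deme_b: int

    @property
    def same_deme(self) -> bool:
        return self.deme_a == self.deme_b

    def as_pair(self) -> tuple[int, int]:
        return (min(self.deme_a, self.deme_b), max(self.deme_a, self.deme_b))


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant structured demography (epochs ordered in time)."""

    epochs: tuple[Epoch, ...]
    N_ref: float = 1.0
    label: str = ""

    @property
    def n_demes(self) -> int:
        """Number of demes in the most recent epoch (where sampling happens)."""
        return self.epochs[0].n_demes

    def epoch_starts(self) -> np.ndarray:
        return np.array([e.start_time for e in self.epochs], dtype=float)

    def hash(self) -> str:
        """Stable short hash of the JSON form, used to tag output files."""
        payload = model_to_json(self, indent=None)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def validate_sampling(self, sampling: SamplingScheme) -> None:
        n = self.epochs[0].n_demes
        for d in (sampling.deme_a, sampling.deme_b):
            if not (0 <= d < n):
                raise ModelValidationError(
                    f"sampled deme {d} not in the first epoch (n_demes={n})"
                )


def _validate_epoch(epoch: Epoch, index: int, prev: Epoch | None) -> None:
    n = epoch.n_demes
    if n < 1:
        raise ModelValidationError(f"epoch {index}: needs at least one deme")
    if any(not (s > 0) or not math.isfinite(s) for s in epoch.deme_sizes):
        raise ModelValidationError(f"epoch {index}: deme sizes must be positive")
    m = np.asarray(epoch.migration, dtype=float)
    if m.shape != (n, n):
        raise ModelValidationError(
            f"epoch {index}: migration matrix shape {m.shape} != ({n}, {n})"
        )
    off = m[~np.eye(n, dtype=bool)]
    if off.size and (np.any(off < 0) or not np.all(np.isfinite(off))):
        raise ModelValidationError(f"epoch {index}: negative migration rate")
    if index == 0:
        if epoch.start_time != 0:
            raise ModelValidationError("first epoch must start at time 0")
        if epoch.remap_at_start is not None:
            raise ModelValidationError("first epoch cannot carry a remap")
    else:
        assert prev is not None
        if not epoch.start_time > prev.start_time:
            raise ModelValidationError(
                f"epoch {index}: start_time must exceed the previous epoch's"
            )
        remap = epoch.remap_at_start
        n_prev = prev.n_demes
        if remap is None:
            if n != n_prev:
                raise ModelValidationError(
                    f"epoch {index}: deme count changed without a remap"
                )
        else:
            for src in remap.mapping:
                if not (0 <= src < n_prev):
                    raise ModelValidationError(
                        f"epoch {index}: remap source deme {src} invalid"
                    )
            for src in range(n_prev):
                tgt = remap.target(src)
                if not (0 <= tgt < n):
                    raise ModelValidationError(
                        f"epoch {index}: remap target deme {tgt} invalid"
                    )
                p = remap.move_probability(src)
                if not (0.0 <= p <= 1.0):
                    raise ModelValidationError(
                        f"epoch {index}: move probability {p} outside [0, 1]"
                    )
                if p < 1.0 and src >= n:
                    raise ModelValidationError(
                        f"epoch {index}: deme {src} may stay (p<1) but does "
                        "not exist in the new epoch"
                    )


def make_custom_model(
    epochs: Sequence[Epoch], N_ref: float = 1.0, label: str = ""
) -> DemographicModel:
    """Validate a list of epochs and assemble a :class:`DemographicModel`.

    All preset builders funnel through this function, so re-validating any
    builder output is a no-op.
    """
    if not epochs:
        raise ModelValidationError("model needs at least one epoch")
    if not (N_ref > 0):
        raise ModelValidationError("N_ref must be positive")
    prev = None
    for i, e in enumerate(epochs):
        _validate_epoch(e, i, prev)
        prev = e
    return DemographicModel(epochs=tuple(epochs), N_ref=float(N_ref), label=label)


def _epoch(sizes, migration, start_time=0.0, remap=None) -> Epoch:
    sizes = tuple(float(s) for s in sizes)
    m = np.asarray(migration, dtype=float).reshape(len(sizes), len(sizes))
    np.fill_diagonal(m, 0.0)
    return Epoch(
        start_time=float(start_time),
        deme_sizes=sizes,
        migration=tuple(tuple(row) for row in m),
        remap_at_start=remap,
    )


def make_n_island(n: int, M: float, N_ref: float = 1.0) -> DemographicModel:
    """Symmetric n-island model: ``n`` demes of size 1, total scaled
    immigration ``M`` per deme split evenly over the ``n - 1`` others."""
    if n < 1:
        raise ModelValidationError("n must be >= 1")
    if M < 0:
        raise ModelValidationError("M must be >= 0")
    if n == 1 and M > 0:
        raise ModelValidationError("a single deme cannot receive migrants")
    m = np.zeros((n, n))
    if n > 1:
        m[:] = M / (n - 1)
        np.fill_diagonal(m, 0.0)
    return make_custom_model(
        [_epoch([1.0] * n, m)], N_ref=N_ref, label=f"n-island(n={n}, M={M})"
    )


def make_stepping_stone(
    dims: Sequence[int],
    M: float,
    circular: bool = False,
    rate_mode: str = "total",
    N_ref: float = 1.0,
) -> DemographicModel:
    """1D or 2D stepping-stone model on a bounded (default) or wrapped lattice.

    Demes are indexed row-major.  In the default ``rate_mode="total"`` each
    deme's total scaled emigration ``M`` is split equally among its nearest
    neighbours, which keeps the per-deme immigrant count comparable with an
    n-island model of the same ``M``.  ``rate_mode="per_link"`` instead puts
    rate ``M`` on every lattice edge.
    """
    dims = tuple(int(d) for d in dims)
    if not dims or len(dims) > 2 or any(d < 1 for d in dims):
        raise ModelValidationError("dims must be a 1- or 2-tuple of counts >= 1")
    if M < 0:
        raise ModelValidationError("M must be >= 0")
    if rate_mode not in ("total", "per_link"):
        raise ModelValidationError(f"unknown rate_mode {rate_mode!r}")
    if len(dims) == 1:
        dims = (dims[0], 1)
    nr, nc = dims
    n = nr * nc
    if n == 1 and M > 0:
        raise ModelValidationError("a single deme cannot exchange migrants")

    def neighbours(r: int, c: int) -> list[int]:
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if circular:
                # wrap only along axes longer than 2 demes to avoid double edges
                if nr > 2 or (nr == 2 and dr != 0 and 0 <= rr < nr):
                    rr %= nr
                if nc > 2 or (nc == 2 and dc != 0 and 0 <= cc < nc):
                    cc %= nc
            if 0 <= rr < nr and 0 <= cc < nc and (rr, cc) != (r, c):
                out.append(rr * nc + cc)
        return sorted(set(out))

    m = np.zeros((n, n))
    for r in range(nr):
        for c in range(nc):
            i = r * nc + c
            nb = neighbours(r, c)
            for j in nb:
                m[i, j] += M if rate_mode == "per_link" else M / len(nb)
    shape = f"{nr}" if nc == 1 else f"{nr}x{nc}"
    kind = "circular" if circular else "bounded"
    return make_custom_model(
        [_epoch([1.0] * n, m)],
        N_ref=N_ref,
        label=f"stepping-stone({shape}, M={M}, {kind})",
    )


def make_continent_island(
    size_ratio: float, M: float, symmetric: bool = False, N_ref: float = 1.0
) -> DemographicModel:
    """Continent-island model: deme 0 is the continent (relative size
    ``size_ratio``), deme 1 the island (size 1).

    The island's scaled immigration is ``M``.  By default the exchange is
    conservative — the continent's scaled immigration is ``M / size_ratio``,
    so the expected number of migrant genes is the same in both directions.
    ``symmetric=True`` sets both scaled rates to ``M`` instead.
    """
    if size_ratio < 1:
        raise ModelValidationError("size_ratio must be >= 1")
    if M < 0:
        raise ModelValidationError("M must be >= 0")
    m_cont = M if symmetric else M / size_ratio
    m = np.array([[0.0, m_cont], [M, 0.0]])
    return make_custom_model(
        [_epoch([float(size_ratio), 1.0], m)],
        N_ref=N_ref,
        label=f"continent-island(ratio={size_ratio}, M={M})",
    )


def make_asymmetric_model(
    migration: Sequence[Sequence[float]],
    sizes: Sequence[float] | None = None,
    N_ref: float = 1.0,
) -> DemographicModel:
    """Island model with an arbitrary (possibly asymmetric) migration matrix.

    ``migration[i][j]`` is the scaled rate ``M_ij`` at which deme ``i``
    receives genes from deme ``j`` — all off-diagonal rates are exposed
    explicitly, with no symmetry assumption.
    """
    m = np.asarray(migration, dtype=float)
    n = m.shape[0]
    if sizes is None:
        sizes = [1.0] * n
    return make_custom_model(
        [_epoch(sizes, m)], N_ref=N_ref, label=f"asymmetric({n} demes)"
    )


def add_population_split(
    model: DemographicModel,
    T: float,
    derived: Sequence[int],
    ancestral_size: float,
    ancestral_M: float = 0.0,
) -> DemographicModel:
    """Merge a set of demes into one ancestral deme at time ``T`` (backward).

    Appends an epoch starting at ``T`` whose remap sends every deme in
    ``derived`` to a single new ancestral deme of relative size
    ``ancestral_size``.  Demes not listed keep their mutual migration rates;
    the ancestral deme exchanges with each surviving deme at scaled rate
    ``ancestral_M`` (both directions).
    """
    last = model.epochs[-1]
    if not T > last.start_time:
        raise ModelValidationError(
            f"split time {T} must exceed the last epoch start {last.start_time}"
        )
    derived = sorted(set(int(d) for d in derived))
    n_old = last.n_demes
    if len(derived) < 1:
        raise ModelValidationError("derived deme list is empty")
    for d in derived:
        if not (0 <= d < n_old):
            raise ModelValidationError(f"unknown deme index {d}")
    keep = [d for d in range(n_old) if d not in derived]
    n_new = len(keep) + 1
    anc = n_new - 1
    mapping = {d: i for i, d in enumerate(keep)}
    mapping.update({d: anc for d in derived})
    m_old = last.migration_matrix()
    m_new = np.zeros((n_new, n_new))
    for a, da in enumerate(keep):
        for b, db in enumerate(keep):
            m_new[a, b] = m_old[da, db]
    m_new[anc, :anc] = ancestral_M
    m_new[:anc, anc] = ancestral_M
    sizes_new = [last.deme_sizes[d] for d in keep] + [float(ancestral_size)]
    new_epoch = _epoch(
        sizes_new, m_new, start_time=T, remap=Remap(mapping=mapping, p=1.0)
    )
    label = model.label + f" + split(T={T}, derived={derived})"
    return make_custom_model(
        list(model.epochs) + [new_epoch], N_ref=model.N_ref, label=label
    )


# --------------------------------------------------------------------------
# JSON interchange
# --------------------------------------------------------------------------

def model_to_json(model: DemographicModel, indent: int | None = 2) -> str:
    """Serialise a model to the JSON interchange form (times in units of
    ``N_ref`` generations, rates in the ``M = 2Nm`` convention)."""
    epochs = []
    for e in model.epochs:
        remap = None
        if e.remap_at_start is not None:
            r = e.remap_at_start
            p = dict(r.p) if isinstance(r.p, Mapping) else r.p
            if isinstance(p, dict):
                p = {str(k): float(v) for k, v in p.items()}
            remap = {"map": {str(k): int(v) for k, v in r.mapping.items()}, "p": p}
        epochs.append(
            {
                "start_time": e.start_time,
                "deme_sizes": list(e.deme_sizes),
                "migration": [list(row) for row in e.migration],
                "remap": remap,
            }
        )
    doc = {"N_ref": model.N_ref, "epochs": epochs, "label": model.label}
    return json.dumps(doc, indent=indent, sort_keys=True)


def model_from_json(text: str) -> DemographicModel:
    """Parse the JSON interchange form and validate the resulting model."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"malformed model JSON: {exc}") from exc
    epochs = []
    for spec in doc.get("epochs", []):
        remap = None
        rspec = spec.get("remap")
        if rspec is not None:
            p = rspec.get("p", 1.0)
            if isinstance(p, dict):
                p = {int(k): float(v) for k, v in p.items()}
            remap = Remap(
                mapping={int(k): int(v) for k, v in rspec["map"].items()}, p=p
            )
        epochs.append(
            _epoch(
                spec["deme_sizes"],
                spec["migration"],
                start_time=spec.get("start_time", 0.0),
                remap=remap,
            )
        )
    return make_custom_model(
        epochs, N_ref=doc.get("N_ref", 1.0), label=doc.get("label", "")
    )
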