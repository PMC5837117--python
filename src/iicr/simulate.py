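"""Native coalescent simulation of pairwise coalescence times.

``simulate_t2`` draws i.i.d. ``T2`` values by simulating the absorbing
two-lineage location chain directly: exponential waiting times from the
current state's total exit rate, with exact truncate-and-resample handling of
epoch boundaries (valid for piecewise-constant rates), and lineage remaps
sampled at each boundary.  All replicates advance in lock-step, grouped by
(epoch, state), which keeps million-replicate runs fast without changing the
stochastic process.

``emit_ms_command`` renders an equivalent command line for Hudson's ``ms``
program for external cross-validation.  Unit conversion: ``ms`` measures time
in units of ``4*N0`` generations and migration as ``4*N0*m`` with ``N0`` the
diploid deme size; identifying the haploid deme size ``N = 2*N0`` gives
``ms_time = t / 2`` and leaves the scaled migration entries ``M_ij = 2*N*m``
numerically unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DemographicModel, ModelValidationError, SamplingScheme
from .exact import _check_reachability, build_pair_generator, build_remap_matrix

__all__ = ["T2Sample", "simulate_t2", "emit_ms_command", "write_t2", "read_t2"]


@dataclass(frozen=True)
class T2Sample:
    """A seeded batch of independent pairwise coalescence times.

    Values are in units of ``N_ref`` generations (coalescent scale).
    """

    values: np.ndarray
    seed: int
    model_hash: str
    sampling: tuple[int, int]

    @property
    def n_rep(self) -> int:
        return self.values.size


class _EpochSampler:
    """Pre-computed jump tables for one epoch of the pair chain."""

    def __init__(self, gen):
        Q = gen.Q
        k = gen.space.n_transient
        self.exit_rate = -np.diag(Q)[:k]
        self.dests = []
        self.cumprobs = []
        for s in range(k):
            row = Q[s].copy()
            row[s] = 0.0
            nz = np.nonzero(row > 0)[0]
            self.dests.append(nz)
            if nz.size:
                p = row[nz] / row[nz].sum()
                self.cumprobs.append(np.cumsum(p))
            else:
                self.cumprobs.append(np.array([]))
        self.absorbing = gen.space.absorbing
        self.space = gen.space


def _remap_tables(R: np.ndarray):
    """Per-old-state destination/cumulative-probability tables of a remap."""
    dests, cumprobs = [], []
    for s in range(R.shape[0]):
        nz = np.nonzero(R[s] > 0)[0]
        dests.append(nz)
        cumprobs.append(np.cumsum(R[s, nz] / R[s, nz].sum()))
    return dests, cumprobs


def simulate_t2(
    model: DemographicModel,
    sampling: SamplingScheme,
    n_rep: int,
    seed: int,
    allow_infinite: bool = False,
) -> T2Sample:
    """Draw ``n_rep`` independent coalescence times for the sampled pair.

    Identical ``(model, sampling, n_rep, seed)`` always produces a
    bit-identical sample.  Raises unless the lineages are guaranteed to
    coalesce (set ``allow_infinite=True`` to record ``inf`` for lineages
    trapped in disconnected demes).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    model.validate_sampling(sampling)
    if not allow_infinite:
        _check_reachability(model, sampling)
    rng = np.random.default_rng(seed)
    gens = [build_pair_generator(e) for e in model.epochs]
    samplers = [_EpochSampler(g) for g in gens]
    starts = [e.start_time for e in model.epochs]
    bounds = starts[1:] + [np.inf]
    remaps = [
        _remap_tables(
            build_remap_matrix(gens[i].space, gens[i + 1].space, model.epochs[i + 1])
        )
        for i in range(len(gens) - 1)
    ]

    n_epochs = len(gens)
    state = np.full(n_rep, samplers[0].space.index(*sampling.as_pair()), dtype=np.int64)
    epoch = np.zeros(n_rep, dtype=np.int64)
    t = np.zeros(n_rep)
    out = np.full(n_rep, np.nan)
    active = np.arange(n_rep)

    while active.size:
        # draw one waiting time per active replicate, grouped by (epoch, state)
        key = epoch[active] * 10_000 + state[active]
        order = np.argsort(key, kind="stable")
        active = active[order]
        key = key[order]
        groups = np.flatnonzero(np.r_[True, key[1:] != key[:-1]])
        drop = np.zeros(active.size, dtype=bool)
        for gi, gstart in enumerate(groups):
            gend = groups[gi + 1] if gi + 1 < groups.size else active.size
            idx = active[gstart:gend]
            e = int(epoch[idx[0]])
            s = int(state[idx[0]])
            sampler = samplers[e]
            rate = sampler.exit_rate[s]
            if rate > 0:
                t_new = t[idx] + rng.exponential(1.0 / rate, size=idx.size)
            else:
                t_new = np.full(idx.size, np.inf)
            crossed = t_new >= bounds[e] if e + 1 < n_epochs else np.zeros(idx.size, bool)
            # replicates crossing the boundary: truncate, remap, resample later
            cross_idx = idx[crossed]
            if cross_idx.size:
                t[cross_idx] = bounds[e]
                rdests, rcum = remaps[e]
                if rdests[s].size == 1:
                    state[cross_idx] = rdests[s][0]
                else:
                    u = rng.random(cross_idx.size)
                    state[cross_idx] = rdests[s][np.searchsorted(rcum[s], u)]
                epoch[cross_idx] += 1
            stay_idx = idx[~crossed]
            if stay_idx.size:
                tt = t_new[~crossed]
                t[stay_idx] = tt
                if rate > 0:
                    dests, cum = sampler.dests[s], sampler.cumprobs[s]
                    u = rng.random(stay_idx.size)
                    nxt = dests[np.searchsorted(cum, u)]
                    state[stay_idx] = nxt
                    done = nxt == sampler.absorbing
                else:
                    done = np.ones(stay_idx.size, bool)  # trapped forever
                fin = stay_idx[done]
                out[fin] = t[fin]
                local = np.arange(gstart, gend)[~crossed]
                drop[local[done]] = True
        active = active[~drop]

    return T2Sample(
        values=out,
        seed=int(seed),
        model_hash=model.hash(),
        sampling=(sampling.deme_a, sampling.deme_b),
    )


# --------------------------------------------------------------------------
# ms command emission (cross-validation aid)
# --------------------------------------------------------------------------


class MsNotRepresentableError(ModelValidationError):
    """Model uses features that do not map onto ms command-line flags."""


def emit_ms_command(
    model: DemographicModel, sampling: SamplingScheme, n_rep: int
) -> str:
    """Render an ``ms`` command drawing ``n_rep`` genealogies of 2 lineages.

    Only deterministic merge remaps (population splits) are representable;
    admixture pulses (``p < 1``) raise :class:`MsNotRepresentableError`.
    Header comments document the unit conversion applied.
    """
    model.validate_sampling(sampling)
    n0 = model.epochs[0].n_demes
    lines = [
        "# ms command (Hudson's ms); time in units of 4*N0 generations with",
        "# N0 = N_ref/2 diploids, i.e. ms_time = t_model / 2; migration matrix",
        "# entries are 4*N0*m = 2*N_ref*m = M_ij, numerically unchanged.",
    ]
    parts = ["ms", "2", str(int(n_rep)), "-T"]
    if n0 > 1 or len(model.epochs) > 1:
        counts = [0] * n0
        counts[sampling.deme_a] += 1
        counts[sampling.deme_b] += 1
        parts += ["-I", str(n0)] + [str(c) for c in counts]
        for i, s in enumerate(model.epochs[0].deme_sizes):
            if s != 1.0:
                parts += ["-n", str(i + 1), _fmt(s)]
        parts += ["-ma"] + _ma_entries(model.epochs[0].migration_matrix())
    # ms keeps the deme count fixed; track which ms label each model deme maps to
    label_of = list(range(n0))  # model deme (current epoch) -> ms pop (0-based)
    for e_idx in range(1, len(model.epochs)):
        epoch = model.epochs[e_idx]
        t_ms = epoch.start_time / 2.0
        remap = epoch.remap_at_start
        if remap is not None:
            n_prev = model.epochs[e_idx - 1].n_demes
            for src in range(n_prev):
                if remap.move_probability(src) not in (0.0, 1.0):
                    raise MsNotRepresentableError(
                        "probabilistic remaps (admixture pulses) have no ms form"
                    )
            new_labels = [-1] * epoch.n_demes
            merged = []
            for src in range(n_prev):
                tgt = remap.target(src)
                if new_labels[tgt] == -1:
                    new_labels[tgt] = label_of[src]
                else:
                    merged.append((label_of[src], new_labels[tgt]))
            if any(l == -1 for l in new_labels):
                raise MsNotRepresentableError(
                    "remap creates a deme with no ancestor population"
                )
            for src_label, dst_label in merged:
                parts += ["-ej", _fmt(t_ms), str(src_label + 1), str(dst_label + 1)]
            label_of = new_labels
        for i, s in enumerate(epoch.deme_sizes):
            parts += ["-en", _fmt(t_ms), str(label_of[i] + 1), _fmt(s)]
        m_small = epoch.migration_matrix()
        m_full = np.zeros((n0, n0))
        for i in range(epoch.n_demes):
            for j in range(epoch.n_demes):
                m_full[label_of[i], label_of[j]] = m_small[i, j]
        if n0 > 1:
            parts += ["-ema", _fmt(t_ms), str(n0)] + _ma_entries(m_full)
    lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"


def _fmt(x: float) -> str:
    return f"{float(x):g}"


def _ma_entries(m: np.ndarray) -> list[str]:
    out = []
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            out.append("x" if i == j else _fmt(m[i, j]))
    return out


# --------------------------------------------------------------------------
# plain-text sample files
# --------------------------------------------------------------------------


def write_t2(sample: T2Sample, path) -> None:
    """One value per line, ``#`` header with seed/model hash/sampling."""
    with open(path, "w") as fh:
        fh.write("# t2-sample v1\n")
        fh.write(f"# seed: {sample.seed}\n")
        fh.write(f"# model_hash: {sample.model_hash}\n")
        fh.write(f"# sampling: {sample.sampling[0]} {sample.sampling[1]}\n")
        fh.write(f"# n_rep: {sample.n_rep}\n")
        for v in sample.values:
            fh.write(f"{float(v)!r}\n")


def read_t2(path) -> T2Sample:
    meta: dict[str, str] = {}
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, _, v = body.partition(":")
                    meta[k.strip()] = v.strip()
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: not a number: {line!r}") from exc
    sampling = (0, 0)
    if "sampling" in meta:
        a, b = meta["sampling"].split()
        sampling = (int(a), int(b))
    return T2Sample(
        values=np.array(values),
        seed=int(meta.get("seed", -1)),
        model_hash=meta.get("model_hash", ""),
        sampling=sampling,
    )
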