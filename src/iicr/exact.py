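"""Exact IICR curves via the phase-type structured coalescent.

For a sample of two lineages the structured coalescent reduces to an
absorbing continuous-time Markov chain over the unordered pairs of deme
locations.  The pairwise coalescence time ``T2`` is the absorption time of
that chain, hence (piecewise) phase-type: its survival function and density
are matrix exponentials of the per-epoch transient generator, and

    IICR(t) = P(T2 > t) / f_T2(t)

is computed exactly on any time grid.  Time is measured in units of ``N_ref``
generations; a lineage in deme ``i`` migrates to deme ``j`` at rate
``M_ij / 2`` and two lineages in a deme of relative size ``s`` coalesce at
rate ``1 / s``.  Under this scaling the large-``t`` plateau of the n-island
model is ``N / beta`` with ``beta`` the smallest-magnitude eigenvalue of the
lumped (same-deme / different-deme) chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .curves import IICRCurve
from .demography import (
    DemographicModel,
    Epoch,
    ModelValidationError,
    SamplingScheme,
)

__all__ = [
    "PairStateSpace",
    "PairGenerator",
    "build_pair_generator",
    "build_remap_matrix",
    "survival_and_density",
    "survival_function",
    "exact_iicr",
    "nisland_iicr_closed_form",
    "beta_asymptote",
    "alpha_companion",
    "nei_takahata_ne",
    "small_m_plateau",
]

# relative tolerance at which the eigendecomposition fast path must agree
# with scipy's Pade/scaling-and-squaring expm before it is trusted
_EIG_CHECK_RTOL = 1e-11


class UnreachableCoalescenceError(ModelValidationError):
    """Sampled lineages can never coalesce (disconnected demes)."""


@dataclass(frozen=True)
class PairStateSpace:
    """Unordered two-lineage location states for one epoch.

    States are the pairs ``{i, j}`` with ``i <= j`` in lexicographic order,
    followed by a single absorbing "coalesced" state, giving
    ``n(n+1)/2 + 1`` states for ``n`` demes.
    """

    n_demes: int
    pairs: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self):
        n = self.n_demes
        object.__setattr__(
            self,
            "pairs",
            tuple((i, j) for i in range(n) for j in range(i, n)),
        )

    @property
    def n_transient(self) -> int:
        return len(self.pairs)

    @property
    def n_states(self) -> int:
        return self.n_transient + 1

    @property
    def absorbing(self) -> int:
        return self.n_transient

    def index(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        # offset of row i in the upper-triangular enumeration
        n = self.n_demes
        return i * n - i * (i - 1) // 2 + (j - i)


@dataclass(frozen=True)
class PairGenerator:
    """Absorbing CTMC rate matrix over a :class:`PairStateSpace`."""

    space: PairStateSpace
    Q: np.ndarray
    epoch: Epoch

    @property
    def transient(self) -> np.ndarray:
        """Transient-to-transient block of ``Q``."""
        k = self.space.n_transient
        return self.Q[:k, :k]

    @property
    def absorption_rates(self) -> np.ndarray:
        """Per-transient-state absorption (coalescence) rate vector."""
        k = self.space.n_transient
        return self.Q[:k, k]


def build_pair_generator(epoch: Epoch) -> PairGenerator:
    """Assemble the two-lineage rate matrix for one epoch.

    From ``{i, i}``: coalescence to the absorbing state at rate ``1/s_i`` and
    each of the two lineages migrates ``i -> k`` at rate ``M_ik / 2``.  From
    ``{i, j}`` with ``i != j`` each lineage migrates at its own deme's rates.
    """
    space = PairStateSpace(epoch.n_demes)
    m = epoch.migration_matrix()
    k = space.n_transient
    Q = np.zeros((k + 1, k + 1))
    for idx, (i, j) in enumerate(space.pairs):
        if i == j:
            Q[idx, space.absorbing] += 1.0 / epoch.deme_sizes[i]
        # each lineage moves independently at half its deme's scaled rate
        for mover, other in ((i, j), (j, i)):
            for dest in range(epoch.n_demes):
                if dest == mover or m[mover, dest] == 0.0:
                    continue
                Q[idx, space.index(dest, other)] += m[mover, dest] / 2.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return PairGenerator(space=space, Q=Q, epoch=epoch)


def build_remap_matrix(
    old: PairStateSpace, new: PairStateSpace, epoch: Epoch
) -> np.ndarray:
    """Stochastic matrix sending old-epoch pair states to new-epoch states.

    Each lineage is relocated independently according to the new epoch's
    ``remap_at_start`` (move to the mapped deme with probability ``p``, stay
    otherwise).  Returns the transient-to-transient block; remaps never
    absorb, so rows sum to 1.
    """
    remap = epoch.remap_at_start
    R = np.zeros((old.n_transient, new.n_transient))
    for idx, (i, j) in enumerate(old.pairs):
        outcomes_i = _lineage_outcomes(i, remap)
        outcomes_j = _lineage_outcomes(j, remap)
        for di, pi in outcomes_i:
            for dj, pj in outcomes_j:
                R[idx, new.index(di, dj)] += pi * pj
    return R


def _lineage_outcomes(deme: int, remap) -> list[tuple[int, float]]:
    if remap is None:
        return [(deme, 1.0)]
    p = remap.move_probability(deme)
    tgt = remap.target(deme)
    if p >= 1.0 or tgt == deme:
        return [(tgt, 1.0)]
    if p <= 0.0:
        return [(deme, 1.0)]
    return [(tgt, p), (deme, 1.0 - p)]


# --------------------------------------------------------------------------
# piecewise propagation
# --------------------------------------------------------------------------


class _EpochSegment:
    """Transient dynamics of one epoch with the entering state distribution."""

    def __init__(self, gen: PairGenerator, p_start: np.ndarray, t_start: float):
        self.gen = gen
        self.p_start = p_start
        self.t_start = t_start
        self.T = gen.transient
        self.a = gen.absorption_rates
        self._eig = self._try_eig()

    def _try_eig(self):
        T = self.T
        if T.shape[0] == 1:
            return (T.ravel().astype(complex), np.ones((1, 1), complex),
                    np.ones((1, 1), complex))
        try:
            w, V = np.linalg.eig(T)
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            return None
        # trust the spectral path only if it reproduces expm at a probe time
        t_probe = 1.0 / max(1.0, np.abs(w.real).max())
        approx = (V * np.exp(w * t_probe)) @ Vinv
        exact = scipy.linalg.expm(T * t_probe)
        scale = max(1.0, np.abs(exact).max())
        if np.abs(approx - exact).max() > _EIG_CHECK_RTOL * scale:
            return None
        return (w, V, Vinv)

    def distribution(self, dt: float | np.ndarray) -> np.ndarray:
        """Transient distribution(s) after time ``dt`` inside this epoch."""
        dt = np.atleast_1d(np.asarray(dt, dtype=float))
        if self._eig is not None:
            w, V, Vinv = self._eig
            left = self.p_start.astype(complex) @ V  # (k,)
            # p(t) = (left * e^{w t}) @ Vinv, vectorised over t
            out = np.real((left[None, :] * np.exp(np.outer(dt, w))) @ Vinv)
        else:
            out = np.empty((dt.size, self.T.shape[0]))
            for i, d in enumerate(dt):
                out[i] = self.p_start @ scipy.linalg.expm(self.T * d)
        return np.clip(out, 0.0, None)

    def survival_density(self, dt) -> tuple[np.ndarray, np.ndarray]:
        p = self.distribution(dt)
        # spectral roundoff can push the total mass past the entering mass
        S = np.minimum(p.sum(axis=1), self.p_start.sum())
        return S, p @ self.a


def _build_segments(
    model: DemographicModel,
    sampling: SamplingScheme,
    allow_infinite: bool = False,
) -> list[_EpochSegment]:
    model.validate_sampling(sampling)
    if not allow_infinite:
        _check_reachability(model, sampling)
    gens = [build_pair_generator(e) for e in model.epochs]
    i0 = gens[0].space.index(*sampling.as_pair())
    p = np.zeros(gens[0].space.n_transient)
    p[i0] = 1.0
    segments = []
    for e_idx, gen in enumerate(gens):
        seg = _EpochSegment(gen, p, model.epochs[e_idx].start_time)
        segments.append(seg)
        if e_idx + 1 < len(gens):
            dt = model.epochs[e_idx + 1].start_time - model.epochs[e_idx].start_time
            p_end = seg.distribution(dt)[0]
            R = build_remap_matrix(
                gen.space, gens[e_idx + 1].space, model.epochs[e_idx + 1]
            )
            p = p_end @ R
    return segments


def _check_reachability(model: DemographicModel, sampling: SamplingScheme) -> None:
    """Raise unless absorption is certain from the sampled configuration."""
    gens = [build_pair_generator(e) for e in model.epochs]
    reach = {gens[0].space.index(*sampling.as_pair())}
    for e_idx, gen in enumerate(gens):
        T = gen.transient
        # close the reachable set under within-epoch transitions
        frontier = set(reach)
        while frontier:
            s = frontier.pop()
            for d in np.nonzero(T[s] > 0)[0]:
                if d != s and d not in reach:
                    reach.add(int(d))
                    frontier.add(int(d))
        if e_idx + 1 < len(gens):
            R = build_remap_matrix(
                gen.space, gens[e_idx + 1].space, model.epochs[e_idx + 1]
            )
            reach = {int(d) for s in reach for d in np.nonzero(R[s] > 0)[0]}
    # in the final (infinite) epoch every reachable state must reach absorption
    gen = gens[-1]
    T, a = gen.transient, gen.absorption_rates
    can_absorb = set(np.nonzero(a > 0)[0].astype(int))
    changed = True
    while changed:
        changed = False
        for s in range(T.shape[0]):
            if s in can_absorb:
                continue
            dests = np.nonzero(T[s] > 0)[0]
            if any(int(d) in can_absorb for d in dests if d != s):
                can_absorb.add(s)
                changed = True
    if not reach <= can_absorb:
        raise UnreachableCoalescenceError(
            "the sampled lineages can never coalesce under this model; "
            "pass allow_infinite=True to compute the conditional curve"
        )


def survival_function(
    model: DemographicModel,
    sampling: SamplingScheme,
    allow_infinite: bool = False,
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorised exact survival function ``t -> P(T2 > t)``.

    Useful as a reference CDF (``F = 1 - S``) for goodness-of-fit tests
    against simulated coalescence times.
    """
    segments = _build_segments(model, sampling, allow_infinite)
    starts = np.array([s.t_start for s in segments])

    def S(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        e_idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
        for e in np.unique(e_idx):
            mask = e_idx == e
            seg = segments[e]
            out[mask] = seg.survival_density(t[mask] - seg.t_start)[0]
        return out

    return S


def survival_and_density(
    model: DemographicModel,
    sampling: SamplingScheme,
    t: float | np.ndarray,
    allow_infinite: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact ``(P(T2 > t), f_T2(t))`` at the requested time(s).

    The density is the instantaneous absorption flux of the transient
    distribution; both quantities are left-continuous at epoch boundaries
    (the remap applies at the boundary instant, before the new epoch's
    generator acts).
    """
    segments = _build_segments(model, sampling, allow_infinite)
    starts = np.array([s.t_start for s in segments])
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("times must be >= 0")
    S = np.empty_like(t_arr)
    f = np.empty_like(t_arr)
    e_idx = np.clip(np.searchsorted(starts, t_arr, side="right") - 1, 0, None)
    for e in np.unique(e_idx):
        mask = e_idx == e
        seg = segments[e]
        S[mask], f[mask] = seg.survival_density(t_arr[mask] - seg.t_start)
    if np.isscalar(t) or np.ndim(t) == 0:
        return S[0], f[0]
    return S, f


def exact_iicr(
    model: DemographicModel,
    sampling: SamplingScheme,
    times: Sequence[float] | np.ndarray,
    allow_infinite: bool = False,
) -> IICRCurve:
    """Exact IICR curve ``S(t)/f(t)`` on a strictly increasing time grid.

    ``t = 0`` is reported as the analytic limit: the sampled deme's relative
    size for same-deme sampling, ``+inf`` for different-deme sampling.  A
    vanishing density at an interior grid point yields ``+inf`` with a
    warning rather than an error.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a 1-D grid")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("times must be >= 0")
    S, f = survival_and_density(model, sampling, times, allow_infinite)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = S / f
    if times[0] == 0.0:
        values[0] = (
            model.epochs[0].deme_sizes[sampling.deme_a]
            if sampling.same_deme
            else np.inf
        )
    interior_zero = (f == 0.0) & (times > 0) & (S > 0)
    if np.any(interior_zero):
        warnings.warn(
            "density vanished at interior grid points; IICR recorded as +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        values[interior_zero] = np.inf
    return IICRCurve(
        times=times.copy(),
        values=values,
        time_unit="coalescent",
        size_unit="N_ref",
        provenance="exact",
        sampling=(sampling.deme_a, sampling.deme_b),
        model_hash=model.hash(),
    )


# --------------------------------------------------------------------------
# n-island closed forms
# --------------------------------------------------------------------------


def _nisland_rates(n: int, M: float) -> tuple[float, float, float, float]:
    """Eigenvalues (alpha, beta) and helpers of the lumped n-island chain.

    Lumping the pair chain by "same deme" vs "different demes" gives the
    2-state transient generator  [[-(1+M), M], [gamma, -gamma]]  with
    ``gamma = M/(n-1)``; alpha and beta are the negated eigenvalues, roots of
    ``x^2 - a x + gamma = 0`` with ``a = 1 + n M / (n - 1)``.
    """
    gamma = M / (n - 1)
    a = 1.0 + n * M / (n - 1)
    disc = np.sqrt(a * a - 4.0 * gamma)
    beta = 0.5 * (a - disc)
    alpha = 0.5 * (a + disc)
    return alpha, beta, gamma, a


def beta_asymptote(n: int, M: float) -> float:
    """Dominant decay rate ``beta`` of the n-island pair chain.

    ``N / beta`` is the ancient plateau of the IICR; ``beta`` lies in
    ``(0, 1)``, tends to ``M/(n-1)`` as ``M -> 0`` and to ``1/n`` as
    ``M -> inf``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not M > 0:
        raise ValueError("M must be > 0")
    return _nisland_rates(n, M)[1]


def alpha_companion(n: int, M: float) -> float:
    """Companion (fast) decay rate of the same characteristic polynomial."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not M > 0:
        raise ValueError("M must be > 0")
    return _nisland_rates(n, M)[0]


def nisland_iicr_closed_form(
    n: int,
    M: float,
    scheme: str,
    times: Sequence[float] | np.ndarray,
) -> IICRCurve:
    """Two-exponential closed-form IICR of the symmetric n-island model.

    ``scheme`` is ``"same"`` or ``"different"``.  The survival function and
    density are explicit mixtures of ``exp(-beta t)`` and ``exp(-alpha t)``
    obtained by spectral decomposition of the lumped 2-state chain, so this
    never touches a matrix exponential and serves as an independent oracle
    for :func:`exact_iicr` on n-island models.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not M > 0:
        raise ValueError("M must be > 0")
    if scheme not in ("same", "different"):
        raise ValueError("scheme must be 'same' or 'different'")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise ValueError("times must be non-negative and strictly increasing")
    alpha, beta, gamma, _ = _nisland_rates(n, M)
    d = alpha - beta
    eb = np.exp(-beta * times)
    ea = np.exp(-alpha * times)
    if scheme == "same":
        # p_s(0)=1, p_s'(0)=-(1+M);  p_d(0)=0, p_d'(0)=M
        A = (alpha - (1.0 + M)) / d
        B = ((1.0 + M) - beta) / d
        ps = A * eb + B * ea
        pd = (M / d) * (eb - ea)
    else:
        # p_s(0)=0, p_s'(0)=gamma;  p_d(0)=1, p_d'(0)=-gamma
        ps = (gamma / d) * (eb - ea)
        pd = ((alpha - gamma) / d) * eb + ((gamma - beta) / d) * ea
    S = ps + pd
    f = ps  # coalescence flux: rate 1 from the same-deme state (deme size 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = S / f
    if times.size and times[0] == 0.0:
        values[0] = 1.0 if scheme == "same" else np.inf
    sampling = (0, 0) if scheme == "same" else (0, 1)
    return IICRCurve(
        times=times.copy(),
        values=values,
        time_unit="coalescent",
        size_unit="N_ref",
        provenance="exact",
        sampling=sampling,
        model_hash=None,
    )


def nei_takahata_ne(n: int, N: float, M: float) -> float:
    """Nucleotide-diversity effective size ``N (n + (n-1)^2 / (n M))``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not N > 0:
        raise ValueError("N must be > 0")
    if n == 1:
        return float(N)
    if not M > 0:
        raise ValueError("M must be > 0 for a subdivided population")
    return N * (n + (n - 1) ** 2 / (n * M))


def small_m_plateau(n: int, N: float, M: float) -> float:
    """Low-migration limit ``N (n - 1) / M`` of the ancient plateau ``N/beta``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not M > 0:
        raise ValueError("M must be > 0")
    return N * (n - 1) / M
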