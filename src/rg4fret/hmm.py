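"""Gaussian-emission hidden Markov models for smFRET trace idealization.

A K-state HMM with scalar Gaussian emissions is fit jointly to all accepted
FRET traces of a condition (shared means, s.d.s and transition matrix;
per-trace forward-backward), the number of states is chosen by BIC, and each
trace is idealized to a piecewise-constant state path by Viterbi decoding.
The forward/backward recursions are computed with per-frame scaling so long
traces do not underflow, and are vectorized across traces.

States are always reported in canonical order of ascending emission mean,
matching the folding pathway convention (ssRNA lowest, G4 highest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .traces import FretTrace

__all__ = [
    "GaussianHmm",
    "IdealizedTrace",
    "FitResult",
    "StateCountSelection",
    "forward_log_likelihood",
    "baum_welch_fit",
    "viterbi_decode",
    "select_state_count",
    "idealize",
    "SD_FLOOR",
]

#: lower bound on emission s.d. (FRET units) to prevent variance collapse
SD_FLOOR = 0.01

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianHmm:
    """K-state HMM with Gaussian emissions on the FRET axis."""

    means: np.ndarray
    sds: np.ndarray
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self):
        means = np.atleast_1d(np.asarray(self.means, dtype=float))
        sds = np.atleast_1d(np.asarray(self.sds, dtype=float))
        A = np.atleast_2d(np.asarray(self.transition_matrix, dtype=float))
        pi0 = np.atleast_1d(np.asarray(self.initial_distribution, dtype=float))
        K = means.size
        if sds.size != K or A.shape != (K, K) or pi0.size != K:
            raise ValueError("inconsistent state dimensions in HMM parameters")
        if np.any(sds <= 0):
            raise ValueError("emission s.d.s must be positive")
        if np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-10, rtol=0):
            raise ValueError("transition matrix must be row-stochastic")
        if np.any(pi0 < 0) or abs(pi0.sum() - 1.0) > 1e-10:
            raise ValueError("initial distribution must sum to 1")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "transition_matrix", A)
        object.__setattr__(self, "initial_distribution", pi0)

    @property
    def n_states(self) -> int:
        return self.means.size

    def canonicalized(self) -> "GaussianHmm":
        """States permuted into ascending order of emission mean."""
        order = np.argsort(self.means, kind="stable")
        return GaussianHmm(
            means=self.means[order],
            sds=self.sds[order],
            transition_matrix=self.transition_matrix[np.ix_(order, order)],
            initial_distribution=self.initial_distribution[order],
        )

    def to_dict(self) -> dict:
        return {
            "n_states": int(self.n_states),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianHmm":
        return cls(
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            transition_matrix=np.asarray(d["transition_matrix"]),
            initial_distribution=np.asarray(d["initial_distribution"]),
        )


@dataclass(frozen=True)
class IdealizedTrace:
    """Run-length-encoded Viterbi path of one trace.

    ``segments`` is a list of ``(start_frame, end_frame, state)`` with
    half-open frame ranges that tile the decoded range; consecutive
    segments carry different states.  Dwell times follow as
    ``(end - start) * frame_interval_s``.
    """

    molecule_id: str
    segments: tuple[tuple[int, int, int], ...]
    state_means: np.ndarray
    frame_interval_s: float = 0.1

    def __post_init__(self):
        segs = tuple(tuple(int(v) for v in s) for s in self.segments)
        prev_end, prev_state = None, None
        for s, e, k in segs:
            if e <= s:
                raise ValueError("segments must be non-empty half-open ranges")
            if prev_end is not None and (s != prev_end or k == prev_state):
                raise ValueError("segments must be contiguous with alternating states")
            prev_end, prev_state = e, k
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "state_means", np.asarray(self.state_means, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.segments[-1][1] - self.segments[0][0]

    def state_path(self) -> np.ndarray:
        path = np.empty(self.n_frames, dtype=np.int64)
        off = self.segments[0][0]
        for s, e, k in self.segments:
            path[s - off : e - off] = k
        return path


@dataclass
class FitResult:
    model: GaussianHmm
    log_likelihood: float
    ll_history: np.ndarray
    n_iter: int
    converged: bool
    n_observations: int

    @property
    def n_parameters(self) -> int:
        K = self.model.n_states
        return K * K + 2 * K - 1  # K(K-1) transitions + K-1 initial + K means + K sds

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters * math.log(self.n_observations)


def _pack(observations) -> tuple[np.ndarray, np.ndarray]:
    """Pad a list of 1-D observation arrays to (N, Tmax) plus lengths."""
    obs_list = [np.asarray(o, dtype=float).ravel() for o in observations]
    if not obs_list or any(o.size == 0 for o in obs_list):
        raise ValueError("observations must be a non-empty collection of non-empty arrays")
    lengths = np.array([o.size for o in obs_list])
    packed = np.zeros((len(obs_list), lengths.max()))
    for i, o in enumerate(obs_list):
        packed[i, : o.size] = o
    return packed, lengths


def _log_emission(model: GaussianHmm, obs: np.ndarray) -> np.ndarray:
    """(..., K) Gaussian log densities of observations under each state."""
    z = (obs[..., None] - model.means) / model.sds
    return -0.5 * (z * z) - np.log(model.sds) - 0.5 * _LOG_2PI


def _forward_pass(model: GaussianHmm, obs: np.ndarray, lengths: np.ndarray):
    """Scaled forward recursion, vectorized over traces.

    Returns per-trace log-likelihoods, scaled alpha (N, T, K), shifted
    emission probabilities Bs, per-frame log shifts m, and scales c.
    """
    N, T = obs.shape
    A = model.transition_matrix
    logB = _log_emission(model, obs)
    m = logB.max(axis=2)
    Bs = np.exp(logB - m[..., None])

    alpha = np.empty((N, T, model.n_states))
    scale = np.ones((N, T))
    ll = np.zeros(N)

    a = model.initial_distribution * Bs[:, 0]
    c = np.maximum(a.sum(axis=1), 1e-300)
    a = a / c[:, None]
    alpha[:, 0] = a
    scale[:, 0] = c
    ll += np.log(c) + m[:, 0]

    for t in range(1, T):
        active = lengths > t
        an = (alpha[:, t - 1] @ A) * Bs[:, t]
        c = an.sum(axis=1)
        c_safe = np.where(active & (c > 0), c, 1.0)
        an = an / c_safe[:, None]
        alpha[:, t] = np.where(active[:, None], an, alpha[:, t - 1])
        scale[:, t] = c_safe
        ll += np.where(active, np.log(c_safe) + m[:, t], 0.0)
    return ll, alpha, Bs, m, scale


def forward_log_likelihood(model: GaussianHmm, observations) -> float:
    """Exact log marginal likelihood of one observation sequence."""
    obs, lengths = _pack([observations])
    ll, *_ = _forward_pass(model, obs, lengths)
    return float(ll[0])


def _e_step(model: GaussianHmm, obs: np.ndarray, lengths: np.ndarray):
    """One forward-backward sweep; returns total LL and sufficient stats."""
    N, T = obs.shape
    K = model.n_states
    A = model.transition_matrix
    ll, alpha, Bs, _, scale = _forward_pass(model, obs, lengths)

    frame_mask = np.arange(T) < lengths[:, None]  # (N, T)
    xi_sum = np.zeros((K, K))
    g_sum = np.zeros(K)
    gx_sum = np.zeros(K)
    gxx_sum = np.zeros(K)
    pi_sum = np.zeros(K)

    beta = np.ones((N, K))
    for t in range(T - 1, -1, -1):
        act = frame_mask[:, t]
        gamma = alpha[:, t] * beta
        gm = gamma[act]
        x = obs[act, t]
        g_sum += gm.sum(axis=0)
        gx_sum += (gm * x[:, None]).sum(axis=0)
        gxx_sum += (gm * (x * x)[:, None]).sum(axis=0)
        if t == 0:
            pi_sum = gamma.sum(axis=0)  # every trace has a frame 0
        else:
            tmp = Bs[:, t] * beta / scale[:, t][:, None]
            xi = alpha[:, t - 1][:, :, None] * A[None] * tmp[:, None, :]
            xi_sum += xi[act].sum(axis=0)
            beta_new = tmp @ A.T
            beta = np.where(act[:, None], beta_new, beta)
    return float(ll.sum()), xi_sum, g_sum, gx_sum, gxx_sum, pi_sum


def _default_init(obs_pool: np.ndarray, K: int, self_prob: float = 0.95) -> GaussianHmm:
    """Quantile-spaced means, pooled-s.d. widths, sticky transitions."""
    qs = (np.arange(K) + 0.5) / K
    means = np.quantile(obs_pool, qs)
    means = means + 1e-6 * np.arange(K)  # break exact ties
    sd = max(float(obs_pool.std()) / max(K, 1), SD_FLOOR)
    A = np.full((K, K), (1.0 - self_prob) / max(K - 1, 1))
    np.fill_diagonal(A, self_prob if K > 1 else 1.0)
    pi0 = np.full(K, 1.0 / K)
    return GaussianHmm(means, np.full(K, sd), A, pi0)


def baum_welch_fit(
    observations,
    n_states: int,
    *,
    init: GaussianHmm | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
    n_restarts: int = 10,
    seed: int | np.random.SeedSequence | None = 0,
    sd_floor: float = SD_FLOOR,
) -> FitResult:
    """Maximum-likelihood EM fit of a shared model over all traces.

    Restarts jitter the quantile initialization (seed-controlled); the best
    final likelihood wins.  Each run's log-likelihood sequence is checked to
    be non-decreasing within 1e-8 (the EM guarantee); a violation raises.
    A state whose responsibility mass collapses is re-seeded at a random
    observation, up to a retry limit.

    Returns the canonically ordered model with the per-iteration LL history
    of the winning run.
    """
    obs, lengths = _pack(observations)
    n_total = int(lengths.sum())
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_total < 10 * n_states:
        raise ValueError(f"need >= {10 * n_states} pooled observations for K={n_states}")
    obs_pool = np.concatenate([obs[i, :l] for i, l in enumerate(lengths)])
    rng = np.random.default_rng(seed)

    base = init or _default_init(obs_pool, n_states)
    spread = max(float(obs_pool.std()), 0.05)

    best: FitResult | None = None
    n_runs = 1 if init is not None else max(1, n_restarts)
    for run in range(n_runs):
        model = base
        if run > 0:
            jitter = rng.normal(0.0, 0.25 * spread, n_states)
            means = np.clip(base.means + jitter, obs_pool.min(), obs_pool.max())
            model = replace(base, means=np.sort(means) + 1e-9 * np.arange(n_states))
        result = _em_run(model, obs, lengths, obs_pool, tol, max_iter, sd_floor, rng)
        if result is not None and (best is None or result.log_likelihood > best.log_likelihood):
            best = result
    if best is None:
        raise RuntimeError("all EM restarts failed (state collapse)")
    return best


def _em_run(model, obs, lengths, obs_pool, tol, max_iter, sd_floor, rng, max_collapse_retries=5):
    n_total = int(lengths.sum())
    K = model.n_states
    history: list[float] = []
    collapse_retries = 0
    it = 0
    while it < max_iter:
        ll, xi_sum, g_sum, gx_sum, gxx_sum, pi_sum = _e_step(model, obs, lengths)
        if history and ll < history[-1] - 1e-8 * max(1.0, abs(history[-1])):
            raise RuntimeError(
                f"EM log-likelihood decreased: {history[-1]:.10g} -> {ll:.10g}"
            )
        history.append(ll)

        if np.any(g_sum < 1e-6):
            if collapse_retries >= max_collapse_retries:
                return None
            collapse_retries += 1
            dead = g_sum < 1e-6
            means = model.means.copy()
            means[dead] = rng.choice(obs_pool, size=int(dead.sum()))
            model = replace(model, means=means, sds=np.full(K, max(obs_pool.std(), sd_floor)))
            history.clear()
            it += 1
            continue

        if len(history) > 1 and history[-1] - history[-2] < tol:
            break  # report the model that produced history[-1]

        pi_new = pi_sum / pi_sum.sum()
        if K > 1:
            rows = xi_sum.sum(axis=1, keepdims=True)
            A_new = np.where(rows > 0, xi_sum / np.where(rows > 0, rows, 1.0), 1.0 / K)
            A_new = A_new / A_new.sum(axis=1, keepdims=True)
        else:
            A_new = np.ones((1, 1))
        means_new = gx_sum / g_sum
        var = gxx_sum / g_sum - means_new**2
        sds_new = np.sqrt(np.clip(var, sd_floor**2, None))
        model = GaussianHmm(means_new, sds_new, A_new, pi_new)
        it += 1

    converged = len(history) > 1 and (history[-1] - history[-2]) < tol
    return FitResult(
        model=model.canonicalized(),
        log_likelihood=history[-1],
        ll_history=np.asarray(history),
        n_iter=len(history),
        converged=converged,
        n_observations=n_total,
    )


def viterbi_decode(model: GaussianHmm, observations) -> np.ndarray:
    """Maximum-probability state path; ties break toward lower state index."""
    obs = np.asarray(observations, dtype=float).ravel()
    if obs.size == 0:
        raise ValueError("observations must be non-empty")
    K = model.n_states
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition_matrix)
        logpi = np.log(model.initial_distribution)
    logB = _log_emission(model, obs)

    delta = logpi + logB[0]
    psi = np.zeros((obs.size, K), dtype=np.int64)
    for t in range(1, obs.size):
        scores = delta[:, None] + logA  # (from, to)
        psi[t] = np.argmax(scores, axis=0)  # argmax picks lowest index on ties
        delta = scores[psi[t], np.arange(K)] + logB[t]
    path = np.empty(obs.size, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(obs.size - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


@dataclass
class StateCountSelection:
    n_states: int
    criterion: str
    table: list[dict]
    fits: dict[int, FitResult]


def select_state_count(
    observations,
    k_range=range(1, 6),
    *,
    criterion: str = "bic",
    n_restarts: int = 4,
    seed: int | None = 0,
    **fit_kw,
) -> StateCountSelection:
    """Choose the number of folding states by information criterion.

    Fits each K with restarted Baum-Welch and picks the K minimizing
    BIC = -2 LL + p ln(n) with p = K^2 + 2K - 1 free parameters and n the
    pooled frame count.  Per-K failures are recorded and that K skipped.
    """
    if criterion != "bic":
        raise ValueError("only BIC selection is implemented")
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ks))
    table, fits = [], {}
    for k, child in zip(ks, children):
        try:
            fit = baum_welch_fit(
                observations, k, n_restarts=n_restarts, seed=child, **fit_kw
            )
        except (RuntimeError, ValueError) as exc:
            table.append({"n_states": k, "error": str(exc)})
            continue
        fits[k] = fit
        table.append(
            {
                "n_states": k,
                "log_likelihood": fit.log_likelihood,
                "n_parameters": fit.n_parameters,
                "bic": fit.bic,
            }
        )
    if not fits:
        raise RuntimeError("every candidate state count failed to fit")
    chosen = min(fits, key=lambda k: fits[k].bic)
    return StateCountSelection(n_states=chosen, criterion="bic", table=table, fits=fits)


def idealize(model: GaussianHmm, fret: FretTrace) -> IdealizedTrace:
    """Viterbi-decode an accepted FRET trace into dwell segments.

    Rare invalid frames inside the accepted range are filled from the
    nearest valid frame before decoding so segments stay contiguous.
    """
    if not fret.is_accepted:
        raise ValueError(f"trace {fret.molecule_id} is not accepted for analysis")
    lo, hi = fret.accepted
    eff = fret.efficiency[lo:hi].copy()
    valid = fret.valid[lo:hi]
    if not valid.all():
        idx = np.arange(eff.size)
        eff = np.interp(idx, idx[valid], eff[valid])
    path = viterbi_decode(model, np.clip(eff, 0.0, 1.0))

    boundaries = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [path.size]])
    segments = tuple(
        (int(lo + s), int(lo + e), int(path[s])) for s, e in zip(starts, ends)
    )
    return IdealizedTrace(
        molecule_id=fret.molecule_id,
        segments=segments,
        state_means=model.means,
        frame_interval_s=fret.frame_interval_s,
    )
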