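"""Synthetic smFRET data generation for G-quadruplex folding dynamics.

Real single-molecule recordings of rG4 folding are donor/acceptor intensity
time traces collected at 100 ms per frame from a few hundred surface-tethered
molecules per condition.  This module emulates that experiment: a molecule's
conformation evolves as a discrete-state Markov chain over the folding
pathway ssRNA <-> G-hairpin <-> G-triplex <-> G4 (a birth-death chain:
only adjacent states interconvert), each state emits a FRET efficiency drawn
from a truncated Gaussian around its characteristic value, and the efficiency
is converted to noisy donor/acceptor photon counts with single-step,
irreversible photobleaching in either channel.

K+ stabilizes the quadruplex; the simulator encodes this as a Hill-type
scaling of the folding (forward) transition probabilities so that the
stationary occupancy of the folded state rises monotonically with KCl
concentration.  The quantitative K+ -> rate mapping is a stand-in chosen for
qualitative realism, not a fitted physical model of any real sequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

__all__ = [
    "FoldingModel",
    "PhotophysicsConfig",
    "BleachEvents",
    "SimulatedDataset",
    "stationary_distribution",
    "birth_death_matrix",
    "potassium_transition_matrix",
    "with_potassium",
    "folding_model",
    "atrg3_model",
    "rg4_model",
    "unwinding_model",
    "simulate_state_path",
    "emit_intensities",
    "simulate_dataset",
    "trace_seed_sequence",
    "STATE_LABELS_4",
    "STATE_LABELS_3",
]

#: canonical state labels along the folding pathway
STATE_LABELS_4 = ("ssRNA", "G-hairpin", "G-triplex", "G4")
STATE_LABELS_3 = ("ssRNA", "G-hairpin", "G-triplex")

#: FRET efficiency means of the three ATRG3 states (mutant lacking the
#: fourth G-tract, so it stops at the G-triplex) and of the full
#: three-layer construct including the well-folded G4 state.
ATRG3_MEANS = (0.32, 0.50, 0.74)
RG4_MEANS = (0.32, 0.50, 0.74, 0.92)

_ATOL = 1e-12


def _as_prob_matrix(P, atol: float = _ATOL) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {P.shape}")
    if np.any(P < 0):
        raise ValueError("transition matrix entries must be non-negative")
    rows = P.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=atol, rtol=0.0):
        raise ValueError(f"transition matrix rows must sum to 1, got {rows}")
    return P


@dataclass(frozen=True)
class FoldingModel:
    """Discrete-state folding model with Gaussian FRET emissions.

    ``emission_means`` are strictly increasing: folding compacts the
    molecule, so more folded states sit at higher FRET.
    """

    state_labels: tuple[str, ...]
    emission_means: np.ndarray
    emission_sds: np.ndarray
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self):
        means = np.asarray(self.emission_means, dtype=float)
        sds = np.asarray(self.emission_sds, dtype=float)
        P = _as_prob_matrix(self.transition_matrix)
        pi0 = np.asarray(self.initial_distribution, dtype=float)
        K = len(self.state_labels)
        if not (len(means) == len(sds) == P.shape[0] == len(pi0) == K):
            raise ValueError("inconsistent number of states across model fields")
        if np.any(means < 0) or np.any(means > 1):
            raise ValueError("emission means must lie in [0, 1]")
        if np.any(np.diff(means) <= 0):
            raise ValueError("emission means must be strictly increasing")
        if np.any(sds <= 0):
            raise ValueError("emission s.d.s must be positive")
        if np.any(pi0 < 0) or abs(pi0.sum() - 1.0) > _ATOL:
            raise ValueError("initial distribution must sum to 1")
        object.__setattr__(self, "state_labels", tuple(self.state_labels))
        object.__setattr__(self, "emission_means", means)
        object.__setattr__(self, "emission_sds", sds)
        object.__setattr__(self, "transition_matrix", P)
        object.__setattr__(self, "initial_distribution", pi0)

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def replace(self, **kw) -> "FoldingModel":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "state_labels": list(self.state_labels),
            "emission_means": self.emission_means.tolist(),
            "emission_sds": self.emission_sds.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoldingModel":
        return cls(
            state_labels=tuple(d["state_labels"]),
            emission_means=np.asarray(d["emission_means"]),
            emission_sds=np.asarray(d["emission_sds"]),
            transition_matrix=np.asarray(d["transition_matrix"]),
            initial_distribution=np.asarray(d["initial_distribution"]),
        )


@dataclass(frozen=True)
class PhotophysicsConfig:
    """Detection-channel model: intensities, noise, and photobleaching.

    total_intensity : mean summed donor+acceptor count per frame (a.u.)
    intensity_sd    : additive Gaussian noise s.d. per channel (a.u.)
    frame_interval_s: camera exposure per frame; recordings here use 0.1 s
    donor_bleach_prob, acceptor_bleach_prob : per-frame single-step
        irreversible bleaching probabilities (geometric waiting times)
    background      : per-channel baseline offset (a.u.)
    """

    total_intensity: float = 1000.0
    intensity_sd: float = 30.0
    frame_interval_s: float = 0.1
    donor_bleach_prob: float = 0.002
    acceptor_bleach_prob: float = 0.002
    background: float = 20.0

    def __post_init__(self):
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        for name in ("donor_bleach_prob", "acceptor_bleach_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.intensity_sd < 0 or self.background < 0:
            raise ValueError("intensity_sd and background must be non-negative")


@dataclass(frozen=True)
class BleachEvents:
    """First bleach frame per channel; ``None`` means no bleach occurred."""

    donor_frame: int | None = None
    acceptor_frame: int | None = None

    @property
    def first_frame(self) -> int | None:
        frames = [f for f in (self.donor_frame, self.acceptor_frame) if f is not None]
        return min(frames) if frames else None


def stationary_distribution(P) -> np.ndarray:
    """Stationary distribution pi of a row-stochastic matrix (pi P = pi).

    Raises ``ValueError`` for a non-stochastic matrix and for a reducible
    chain (no unique stationary law), naming the absorbing class.
    """
    P = _as_prob_matrix(P)
    K = P.shape[0]
    n_comp, labels = connected_components(
        csr_matrix(P > 0), directed=True, connection="strong"
    )
    if n_comp > 1:
        # a strongly connected component with no outgoing edge is absorbing
        absorbing = []
        for c in range(n_comp):
            members = np.flatnonzero(labels == c)
            outside = np.setdiff1d(np.arange(K), members)
            if P[np.ix_(members, outside)].sum() == 0:
                absorbing.append(members.tolist())
        raise ValueError(
            f"reducible chain: absorbing class(es) {absorbing}; "
            "stationary distribution is not unique"
        )
    A = np.vstack([P.T - np.eye(K), np.ones(K)])
    b = np.zeros(K + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def birth_death_matrix(p_fold: Sequence[float], p_unfold: Sequence[float]) -> np.ndarray:
    """Row-stochastic matrix of a birth-death chain.

    ``p_fold[i]`` is the per-frame probability of the forward (folding) step
    i -> i+1; ``p_unfold[i]`` that of the backward step i+1 -> i.  Only
    adjacent states interconvert, matching the sequential folding pathway.
    """
    p_fold = np.asarray(p_fold, dtype=float)
    p_unfold = np.asarray(p_unfold, dtype=float)
    if p_fold.shape != p_unfold.shape or p_fold.ndim != 1:
        raise ValueError("p_fold and p_unfold must be 1-D of equal length")
    K = len(p_fold) + 1
    P = np.zeros((K, K))
    for i in range(K - 1):
        P[i, i + 1] = p_fold[i]
        P[i + 1, i] = p_unfold[i]
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    if np.any(np.diag(P) < 0):
        raise ValueError("step probabilities too large: negative self-transition")
    return P


def folding_model(
    means: Sequence[float],
    sd: float | Sequence[float] = 0.06,
    p_fold: float | Sequence[float] = 0.025,
    p_unfold: float | Sequence[float] = 0.025,
    labels: Sequence[str] | None = None,
    initial: Sequence[float] | str = "stationary",
) -> FoldingModel:
    """Build a birth-death :class:`FoldingModel` from state means and rates.

    ``initial="stationary"`` starts molecules at equilibrium (falls back to
    uniform when the chain is reducible, e.g. in unwinding mode).
    """
    means = np.asarray(means, dtype=float)
    K = len(means)
    sds = np.broadcast_to(np.asarray(sd, dtype=float), (K,)).copy()
    pf = np.broadcast_to(np.asarray(p_fold, dtype=float), (K - 1,)).copy()
    pu = np.broadcast_to(np.asarray(p_unfold, dtype=float), (K - 1,)).copy()
    P = birth_death_matrix(pf, pu)
    if labels is None:
        labels = {3: STATE_LABELS_3, 4: STATE_LABELS_4}.get(
            K, tuple(f"state_{i}" for i in range(K))
        )
    if isinstance(initial, str):
        if initial != "stationary":
            raise ValueError(f"unknown initial spec {initial!r}")
        try:
            pi0 = stationary_distribution(P)
        except ValueError:
            pi0 = np.full(K, 1.0 / K)
    else:
        pi0 = np.asarray(initial, dtype=float)
    return FoldingModel(tuple(labels), means, sds, P, pi0)


def potassium_transition_matrix(
    base: FoldingModel,
    kcl_mM: float,
    *,
    k_half_mM: float = 40.0,
    hill_coeff: float = 1.0,
    floor: float = 1e-3,
) -> np.ndarray:
    """Transition matrix of ``base`` with K+-scaled folding steps.

    Forward (folding) probabilities of the base matrix are taken as their
    saturating-K+ values and multiplied by the Hill factor
    ``kcl^h / (kcl^h + k_half^h)``, floored at ``floor`` so the chain stays
    irreducible at 0 mM.  The stationary folded occupancy is therefore
    non-decreasing in KCl, with ssRNA dominant at zero K+.
    """
    if kcl_mM < 0:
        raise ValueError("kcl_mM must be non-negative")
    g = 0.0
    if kcl_mM > 0:
        g = kcl_mM**hill_coeff / (kcl_mM**hill_coeff + k_half_mM**hill_coeff)
    g = max(g, floor)
    P = base.transition_matrix.copy()
    K = P.shape[0]
    for i in range(K - 1):
        P[i, i + 1] = base.transition_matrix[i, i + 1] * g
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    return P


def with_potassium(base: FoldingModel, kcl_mM: float, **kw) -> FoldingModel:
    """``base`` re-equilibrated at the given KCl concentration."""
    P = potassium_transition_matrix(base, kcl_mM, **kw)
    return base.replace(transition_matrix=P, initial_distribution=stationary_distribution(P))


def atrg3_model(sd: float = 0.06, p_fold: float = 0.025, p_unfold: float = 0.025) -> FoldingModel:
    """Three-state model of the ATRG3 mutant (ssRNA / G-hairpin / G-triplex).

    Symmetric sticky transitions (self-probability 0.95 for interior states)
    give roughly balanced occupancy of the three states, as seen for this
    construct at low KCl.
    """
    return folding_model(ATRG3_MEANS, sd=sd, p_fold=p_fold, p_unfold=p_unfold)


def rg4_model(
    sd: float = 0.06,
    p_fold: float = 0.025,
    p_unfold: float = 0.025,
    kcl_mM: float | None = None,
    *,
    p_fold_max: float = 0.03,
    k_half_mM: float = 40.0,
    hill_coeff: float = 1.0,
) -> FoldingModel:
    """Four-state model of a three-layer rG4 (adds the well-folded G4 state).

    With ``kcl_mM=None`` the transitions are symmetric and sticky (uniform
    stationary law).  With a concentration given, folding steps are scaled
    by the Hill factor from ``p_fold_max`` so occupancy shifts toward G4 as
    K+ increases.
    """
    if kcl_mM is None:
        return folding_model(RG4_MEANS, sd=sd, p_fold=p_fold, p_unfold=p_unfold)
    base = folding_model(RG4_MEANS, sd=sd, p_fold=p_fold_max, p_unfold=0.01)
    return with_potassium(base, kcl_mM, k_half_mM=k_half_mM, hill_coeff=hill_coeff)


def unwinding_model(base: FoldingModel, p_unfold: float = 0.05) -> FoldingModel:
    """Helicase-unwinding mode: folding switched off, unfolding active.

    Molecules start from the equilibrium occupancy of ``base`` and can only
    step down the pathway (ATP-driven unwinding overwhelms refolding), so
    the population drains toward ssRNA over the recording.
    """
    K = base.n_states
    pf = np.zeros(K - 1)
    pu = np.full(K - 1, p_unfold)
    P = birth_death_matrix(pf, pu)
    try:
        pi0 = stationary_distribution(base.transition_matrix)
    except ValueError:
        pi0 = base.initial_distribution
    return base.replace(transition_matrix=P, initial_distribution=pi0)


def trace_seed_sequence(seed: int, index: int) -> np.random.SeedSequence:
    """Seed sequence of trace ``index`` under master ``seed``.

    Independent of the number of molecules simulated, so trace i is the same
    whether it is drawn alone or as part of a large dataset.
    """
    return np.random.SeedSequence([int(seed), int(index)])


def simulate_state_path(
    model: FoldingModel,
    n_frames: int,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Markov-chain state index path of length ``n_frames``."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    K = model.n_states
    cum = np.cumsum(model.transition_matrix, axis=1)
    path = np.empty(n_frames, dtype=np.int64)
    u = rng.random(n_frames)
    path[0] = np.searchsorted(np.cumsum(model.initial_distribution), u[0], side="right")
    path[0] = min(path[0], K - 1)
    for t in range(1, n_frames):
        s = np.searchsorted(cum[path[t - 1]], u[t], side="right")
        path[t] = min(s, K - 1)
    return path


def emit_intensities(
    path: np.ndarray,
    model: FoldingModel,
    phys: PhotophysicsConfig,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
):
    """Donor/acceptor intensities for a state path, with photobleaching.

    Per frame the apparent FRET efficiency E* is drawn from a Gaussian
    truncated to [0, 1] around the state's mean; the acceptor channel gets
    ``total * E*`` and the donor ``total * (1 - E*)``, plus background and
    additive noise.  After an acceptor bleach the acceptor falls to
    background and the donor rises to the full intensity; after a donor
    bleach both channels fall to background.  Bleaching is single-step and
    irreversible.

    Returns ``(IntensityTrace, BleachEvents)``.
    """
    from .traces import IntensityTrace  # local import to avoid a cycle

    path = np.asarray(path, dtype=np.int64)
    if path.size == 0:
        raise ValueError("state path must be non-empty")
    rng = np.random.default_rng(seed)
    n = path.size

    e_star = np.empty(n)
    for k in np.unique(path):
        idx = path == k
        mu, sd = model.emission_means[k], model.emission_sds[k]
        a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
        e_star[idx] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=idx.sum(), random_state=rng)

    def _bleach_frame(p: float) -> int | None:
        if p <= 0:
            return None
        f = rng.geometric(p) - 1  # 0-based frame from which the dye is dark
        return int(f) if f < n else None

    donor_b = _bleach_frame(phys.donor_bleach_prob)
    acceptor_b = _bleach_frame(phys.acceptor_bleach_prob)

    acceptor = phys.total_intensity * e_star
    donor = phys.total_intensity * (1.0 - e_star)
    if acceptor_b is not None:
        acceptor[acceptor_b:] = 0.0
        donor[acceptor_b:] = phys.total_intensity
    if donor_b is not None:
        if acceptor_b is None or donor_b < acceptor_b:
            acceptor[donor_b:] = 0.0
        donor[donor_b:] = 0.0
    donor = donor + phys.background + rng.normal(0.0, phys.intensity_sd, n)
    acceptor = acceptor + phys.background + rng.normal(0.0, phys.intensity_sd, n)

    trace = IntensityTrace(
        molecule_id="sim", donor=donor, acceptor=acceptor, frame_interval_s=phys.frame_interval_s
    )
    return trace, BleachEvents(donor_frame=donor_b, acceptor_frame=acceptor_b)


@dataclass
class SimulatedDataset:
    """A simulated smFRET experiment with full ground truth."""

    traces: list  # list[IntensityTrace]
    truth_paths: list[np.ndarray]
    bleach_events: list[BleachEvents]
    truth_model: FoldingModel
    phys: PhotophysicsConfig
    condition: str
    seed: int

    def __post_init__(self):
        if len(self.traces) != len(self.truth_paths):
            raise ValueError("traces and truth_paths must have equal count")
        for tr, p in zip(self.traces, self.truth_paths):
            if len(tr.donor) != len(p):
                raise ValueError("trace and truth path lengths differ")

    @property
    def n_molecules(self) -> int:
        return len(self.traces)


def simulate_dataset(
    model: FoldingModel,
    phys: PhotophysicsConfig | None = None,
    n_molecules: int = 300,
    n_frames: int = 500,
    condition: str = "",
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate ``n_molecules`` independent traces under one condition.

    Per-trace randomness is derived from ``(seed, molecule index)`` so the
    i-th trace does not depend on how many molecules are requested.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    phys = phys or PhotophysicsConfig()
    traces, paths, bleaches = [], [], []
    for i in range(n_molecules):
        rng = np.random.default_rng(trace_seed_sequence(seed, i))
        path = simulate_state_path(model, n_frames, rng)
        trace, bleach = emit_intensities(path, model, phys, rng)
        trace = dataclasses.replace(trace, molecule_id=f"mol{i:04d}")
        traces.append(trace)
        paths.append(path)
        bleaches.append(bleach)
    return SimulatedDataset(
        traces=traces,
        truth_paths=paths,
        bleach_events=bleaches,
        truth_model=model,
        phys=phys,
        condition=condition,
        seed=int(seed),
    )
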