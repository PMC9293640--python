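"""Transition density plots and transition-count matrices.

Every boundary between consecutive dwell segments of an idealized trace
contributes one (FRET before, FRET after) pair, placed at the fitted state
means so transitions cluster crisply.  The 2-D density of these pairs shows
which folding states interconvert; for a birth-death folding pathway only
adjacent-state clusters should be populated.  At equilibrium the counts are
time-reversible: i->j and j->i occur equally often up to sampling noise,
quantified here by per-pair asymmetry z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .hmm import IdealizedTrace

__all__ = [
    "TransitionSet",
    "TransitionDensity",
    "extract_transitions",
    "transition_density",
    "transition_counts",
    "detailed_balance_score",
]


@dataclass(frozen=True)
class TransitionSet:
    """All detected transitions, one (E_before, E_after) pair each."""

    e_before: np.ndarray
    e_after: np.ndarray
    state_before: np.ndarray
    state_after: np.ndarray
    molecule_id: np.ndarray
    frame: np.ndarray  # first frame of the post-transition segment

    def __post_init__(self):
        n = self.e_before.size
        for name in ("e_after", "state_before", "state_after", "molecule_id", "frame"):
            if getattr(self, name).size != n:
                raise ValueError("all TransitionSet fields must have equal length")

    def __len__(self) -> int:
        return self.e_before.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "molecule_id": self.molecule_id,
                "frame": self.frame,
                "e_before": self.e_before,
                "e_after": self.e_after,
                "state_before": self.state_before,
                "state_after": self.state_after,
            }
        )


def extract_transitions(idealized: Sequence[IdealizedTrace]) -> TransitionSet:
    """Segment boundaries of idealized traces as FRET-mean pairs.

    Traces with a single segment contribute nothing; the total pair count
    equals the total segment count minus the trace count.
    """
    eb, ea, sb, sa, mid, fr = [], [], [], [], [], []
    for tr in idealized:
        means = tr.state_means
        for (s0, e0, k0), (s1, e1, k1) in zip(tr.segments[:-1], tr.segments[1:]):
            eb.append(means[k0])
            ea.append(means[k1])
            sb.append(k0)
            sa.append(k1)
            mid.append(tr.molecule_id)
            fr.append(s1)
    return TransitionSet(
        e_before=np.asarray(eb, dtype=float),
        e_after=np.asarray(ea, dtype=float),
        state_before=np.asarray(sb, dtype=np.int64),
        state_after=np.asarray(sa, dtype=np.int64),
        molecule_id=np.asarray(mid, dtype=object),
        frame=np.asarray(fr, dtype=np.int64),
    )


@dataclass(frozen=True)
class TransitionDensity:
    """2-D histogram/density of transition pairs on [0, 1]^2."""

    grid_edges: np.ndarray
    density: np.ndarray
    total_transitions: int
    normalized: bool

    def __post_init__(self):
        n = self.grid_edges.size - 1
        if self.density.shape != (n, n):
            raise ValueError("density shape must match the grid")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def integral(self) -> float:
        area = np.diff(self.grid_edges)[:, None] * np.diff(self.grid_edges)[None, :]
        return float(np.sum(self.density * area))


def transition_density(
    transitions: TransitionSet,
    n_bins: int = 50,
    smoothing_bandwidth: float | None = 0.02,
    normalize: bool = False,
) -> TransitionDensity:
    """2-D transition histogram with optional Gaussian kernel smoothing.

    Axes are (E before, E after) on [0, 1]; ``smoothing_bandwidth`` is the
    kernel s.d. in FRET units (``None`` disables smoothing).  When
    ``normalize`` is set the output integrates to 1 over the unit square.
    """
    if len(transitions) == 0:
        raise ValueError("no transitions to bin")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    H, _, _ = np.histogram2d(
        np.clip(transitions.e_before, 0, 1),
        np.clip(transitions.e_after, 0, 1),
        bins=[edges, edges],
    )
    if smoothing_bandwidth:
        sigma_bins = smoothing_bandwidth * n_bins  # bandwidth / bin width
        H = ndimage.gaussian_filter(H, sigma=sigma_bins, mode="constant")
    if normalize:
        bin_area = (1.0 / n_bins) ** 2
        H = H / (H.sum() * bin_area)
    return TransitionDensity(
        grid_edges=edges,
        density=H,
        total_transitions=len(transitions),
        normalized=normalize,
    )


def transition_counts(idealized: Sequence[IdealizedTrace], n_states: int) -> np.ndarray:
    """K x K matrix of i->j segment-boundary counts (zero diagonal)."""
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    for tr in idealized:
        states = [k for _, _, k in tr.segments]
        for k0, k1 in zip(states[:-1], states[1:]):
            if not (0 <= k0 < n_states and 0 <= k1 < n_states):
                raise ValueError(
                    f"state index out of range for K={n_states}: {k0}->{k1}"
                )
            counts[k0, k1] += 1
    return counts


def detailed_balance_score(counts: np.ndarray) -> np.ndarray:
    """Pairwise asymmetry z-scores z_ij = (n_ij - n_ji) / sqrt(n_ij + n_ji).

    At equilibrium the folding chain is time-reversible, so every populated
    pair should satisfy |z| <~ 3.  Unpopulated pairs are NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != counts.shape[1] or counts.shape[0] < 2:
        raise ValueError("counts must be a square matrix with K >= 2")
    total = counts + counts.T
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(total > 0, (counts - counts.T) / np.sqrt(total), np.nan)
    np.fill_diagonal(z, np.nan)
    return z
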