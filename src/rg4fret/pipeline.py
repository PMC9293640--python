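"""End-to-end analysis of one condition: QC -> HMM -> histogram -> TDP.

This is the library-level orchestration behind the command line: intensity
traces are QC-filtered into FRET traces, a shared Gaussian-emission HMM is
fit (state count fixed or BIC-selected), traces are idealized, the
transition density assembled, and the pooled 30-50-frame histogram
decomposed into Gaussian peaks whose areas give the state fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import hmm as hmm_mod
from . import population, tdp
from .traces import FretTrace, IntensityTrace, QcConfig, process_trace, qc_report, select_histogram_frames

__all__ = ["ConditionAnalysis", "analyze_condition"]


@dataclass
class ConditionAnalysis:
    """Everything computed for one experimental condition."""

    condition: str
    qc: dict
    fret_traces: list[FretTrace]
    hmm_fit: hmm_mod.FitResult
    state_selection: hmm_mod.StateCountSelection | None
    idealized: list[hmm_mod.IdealizedTrace]
    transitions: tdp.TransitionSet
    transition_count_matrix: np.ndarray
    histogram: population.FretHistogram
    condition_fit: population.ConditionFit

    @property
    def decomposition(self) -> population.HistogramDecomposition:
        return self.condition_fit.decomposition

    @property
    def fractions(self) -> dict[str, float]:
        return population.state_fractions(self.decomposition)


def analyze_condition(
    traces: Sequence[IntensityTrace],
    *,
    n_states: int | None = None,
    k_range=range(1, 6),
    condition: str = "",
    seed: int = 0,
    qc_config: QcConfig | None = None,
    hmm_restarts: int = 5,
    mixture_restarts: int = 5,
    anchor_mixture_to_hmm: bool = True,
    hist_frames: tuple[int, int] = (30, 50),
    bin_width: float = 0.02,
) -> ConditionAnalysis:
    """Run the full single-condition pipeline.

    ``n_states=None`` selects the state count by BIC over ``k_range``.
    When ``anchor_mixture_to_hmm`` is set, the Gaussian mixture centers are
    constrained near the HMM state means, which stabilizes decompositions
    with sparsely occupied states.
    """
    qc_config = qc_config or QcConfig()
    fret_traces = [process_trace(tr, qc_config) for tr in traces]
    accepted = [ft for ft in fret_traces if ft.is_accepted]
    if not accepted:
        raise ValueError(f"no traces passed QC for condition {condition!r}")
    report = qc_report(fret_traces)

    observations = [ft.accepted_values() for ft in accepted]
    ss = np.random.SeedSequence(seed)
    hmm_seed, mix_seed = ss.spawn(2)

    selection = None
    if n_states is None:
        selection = hmm_mod.select_state_count(
            observations, k_range, n_restarts=max(2, hmm_restarts // 2), seed=hmm_seed
        )
        n_states = selection.n_states
        fit = selection.fits[n_states]
    else:
        fit = hmm_mod.baum_welch_fit(
            observations, n_states, n_restarts=hmm_restarts, seed=hmm_seed
        )

    idealized = [hmm_mod.idealize(fit.model, ft) for ft in accepted]
    transitions = tdp.extract_transitions(idealized)
    counts = tdp.transition_counts(idealized, n_states)

    n_min, n_max = hist_frames
    molecule_samples = []
    for ft in accepted:
        sel = select_histogram_frames(ft, n_min=n_min, n_max=n_max)
        if sel is not None:
            molecule_samples.append(sel)
    if not molecule_samples:
        raise ValueError(f"no molecule passed the histogram frame rule for {condition!r}")

    anchors = fit.model.means if anchor_mixture_to_hmm else None
    condition_fit = population.fit_condition(
        molecule_samples,
        n_states,
        label=condition,
        seed=mix_seed,
        n_restarts=mixture_restarts,
        center_anchors=anchors,
    )
    histogram = population.build_histogram(
        condition_fit.pooled, bin_width=bin_width, n_molecules=len(molecule_samples)
    )
    return ConditionAnalysis(
        condition=condition,
        qc=report,
        fret_traces=fret_traces,
        hmm_fit=fit,
        state_selection=selection,
        idealized=idealized,
        transitions=transitions,
        transition_count_matrix=counts,
        histogram=histogram,
        condition_fit=condition_fit,
    )
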