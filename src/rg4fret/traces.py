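"""QC and conversion of donor/acceptor intensity traces to FRET traces.

The raw observable is a pair of intensity time series per molecule.  The
proximity ratio E = I_A / (I_D + I_A) is computed per frame, single-step
photobleaching events are located by a change-point scan, traces are
truncated at the first bleach, and molecules contribute 30-50 of their
earliest usable frames to population histograms so that no molecule
dominates.  No gamma / donor-leakage correction is applied: the analysis
works on the raw proximity ratio throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "IntensityTrace",
    "FretTrace",
    "BleachPoint",
    "QcConfig",
    "compute_fret",
    "detect_bleach",
    "truncate_and_filter",
    "select_histogram_frames",
    "process_trace",
    "qc_report",
]


@dataclass(frozen=True)
class IntensityTrace:
    """Per-molecule donor (Cy3) and acceptor (Cy5) intensities, a.u."""

    molecule_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval_s: float = 0.1

    def __post_init__(self):
        d = np.asarray(self.donor, dtype=float)
        a = np.asarray(self.acceptor, dtype=float)
        if d.ndim != 1 or a.shape != d.shape or d.size < 1:
            raise ValueError("donor and acceptor must be equal-length 1-D arrays")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        object.__setattr__(self, "donor", d)
        object.__setattr__(self, "acceptor", a)

    def __len__(self) -> int:
        return self.donor.size


@dataclass(frozen=True)
class FretTrace:
    """Per-frame FRET efficiency with validity mask and QC state.

    ``accepted`` is the half-open frame range retained for analysis, or
    ``None`` when the trace has not been through ``truncate_and_filter`` /
    was rejected.  Rejections carry machine-readable ``rejected:<reason>``
    flags.
    """

    molecule_id: str
    efficiency: np.ndarray
    valid: np.ndarray
    frame_interval_s: float = 0.1
    accepted: tuple[int, int] | None = None
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self):
        e = np.asarray(self.efficiency, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if e.shape != v.shape or e.ndim != 1:
            raise ValueError("efficiency and valid must be equal-length 1-D arrays")
        finite = e[v]
        if finite.size and (np.any(finite < 0) or np.any(finite > 1)):
            raise ValueError("valid efficiencies must lie in [0, 1]")
        if self.accepted is not None:
            lo, hi = self.accepted
            if not (0 <= lo <= hi <= e.size):
                raise ValueError("accepted range out of bounds")
        object.__setattr__(self, "efficiency", e)
        object.__setattr__(self, "valid", v)
        object.__setattr__(self, "qc_flags", tuple(self.qc_flags))

    @property
    def is_accepted(self) -> bool:
        return self.accepted is not None and not any(
            f.startswith("rejected:") for f in self.qc_flags
        )

    def accepted_values(self) -> np.ndarray:
        """Valid efficiencies within the accepted frame range."""
        if self.accepted is None:
            raise ValueError("trace has no accepted frame range")
        lo, hi = self.accepted
        sl = slice(lo, hi)
        return self.efficiency[sl][self.valid[sl]]

    def __len__(self) -> int:
        return self.efficiency.size


@dataclass(frozen=True)
class BleachPoint:
    frame: int
    channel: str  # "donor" | "acceptor" | "unknown"
    z: float


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for trace QC.

    ``intensity_floor`` marks frames with total intensity below it invalid
    (default 10% of the nominal total count of the simulator defaults);
    ``min_frames`` is the minimum usable length of an accepted trace,
    matching the 30-frame histogram selection rule.  ``background`` is the
    per-channel baseline subtracted before computing E; when a trace shows
    a donor bleach, the median of the post-bleach segment is used instead
    (both channels are dark there, so it measures the baseline directly).
    """

    intensity_floor: float = 100.0
    min_frames: int = 30
    bleach_window: int = 5
    bleach_z: float = 5.0
    background: float = 20.0
    # molecules whose acceptor is dark for most of the trace carry no active
    # FRET pair (acceptor absent or bleached before the recording window)
    e_dark: float = 0.15
    max_dark_fraction: float = 0.5


def compute_fret(
    trace: IntensityTrace, floor: float = 100.0, background: float = 0.0
) -> FretTrace:
    """Proximity ratio E = I_A / (I_D + I_A) per frame.

    ``background`` is subtracted from both channels first (an uncorrected
    baseline compresses the ratio toward 0.5); channels are then clamped at
    zero before dividing, so E is always in [0, 1].  Frames whose summed
    intensity falls below ``floor`` (e.g. after donor bleach) are marked
    invalid instead of divided; a trace with no valid frame gets a
    ``rejected:all_invalid`` flag rather than an exception.
    """
    d = np.clip(trace.donor - background, 0.0, None)
    a = np.clip(trace.acceptor - background, 0.0, None)
    total = d + a
    valid = total >= floor
    eff = np.full(trace.donor.shape, np.nan)
    np.divide(a, total, out=eff, where=valid)
    eff = np.clip(eff, 0.0, 1.0)
    flags = () if valid.any() else ("rejected:all_invalid",)
    return FretTrace(
        molecule_id=trace.molecule_id,
        efficiency=eff,
        valid=valid,
        frame_interval_s=trace.frame_interval_s,
        qc_flags=flags,
    )


def _robust_noise_sd(x: np.ndarray) -> float:
    # s.d. from the median absolute successive difference; insensitive to steps
    d = np.abs(np.diff(x))
    return float(np.median(d)) / 0.9539  # sqrt(2) * Phi^-1(0.75)


def _step_z(x: np.ndarray, window: int, sd: float) -> np.ndarray:
    """z-score of mean(after) - mean(before) at each interior frame.

    Entry i corresponds to a candidate change point at frame ``i + window``
    (first frame of the 'after' window).
    """
    w = window
    c = np.convolve(x, np.ones(w) / w, mode="valid")  # c[i] = mean x[i:i+w]
    step = c[w:] - c[:-w]
    se = max(sd, 1e-12) * np.sqrt(2.0 / w)
    return step / se


def _scan_channel(x: np.ndarray, window: int, z_thr: float, sd: float) -> list[int]:
    """Binary-segmentation scan for change points in one channel."""
    points: list[int] = []

    def recurse(lo: int, hi: int):
        if hi - lo < 2 * window + 1:
            return
        z = _step_z(x[lo:hi], window, sd)
        i = int(np.argmax(np.abs(z)))
        if abs(z[i]) < z_thr:
            return
        t = lo + i + window
        points.append(t)
        recurse(lo, t)
        recurse(t, hi)

    recurse(0, x.size)
    return sorted(points)


def detect_bleach(
    trace: IntensityTrace,
    window: int = 5,
    z_threshold: float = 5.0,
    *,
    e_dark_threshold: float = 0.15,
    total_drop_fraction: float = 0.5,
) -> list[BleachPoint]:
    """Locate single-step photobleaching events with channel attribution.

    Genuine conformational transitions move intensity between the channels
    while conserving their sum, so they must not be reported here.  The two
    bleach signatures used instead are:

    * donor bleach — the summed intensity collapses: a downward step in
      I_D + I_A exceeding ``z_threshold`` noise s.e. that loses more than
      ``total_drop_fraction`` of the pre-step level;
    * acceptor bleach — the apparent efficiency collapses: a downward step
      in the acceptor channel after which the proximity ratio falls below
      ``e_dark_threshold`` (all folding states sit well above it), while
      the summed intensity is conserved.

    Traces shorter than ``2 * window + 1`` frames return an empty list.
    """
    n = len(trace)
    if n < 2 * window + 1:
        return []
    total = np.clip(trace.donor, 0, None) + np.clip(trace.acceptor, 0, None)
    sd_tot = _robust_noise_sd(total)
    sd_a = _robust_noise_sd(trace.acceptor)

    events: list[BleachPoint] = []

    def _window_means(x: np.ndarray, t: int) -> tuple[float, float]:
        return float(x[max(0, t - window) : t].mean()), float(x[t : t + window].mean())

    for t in _scan_channel(total, window, z_threshold, sd_tot):
        before, after = _window_means(total, t)
        if after < before * (1.0 - total_drop_fraction):
            z = (after - before) / (max(sd_tot, 1e-12) * np.sqrt(2.0 / window))
            events.append(BleachPoint(t, "donor", z))

    donor_frames = [bp.frame for bp in events]
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = np.where(total > 0, np.clip(trace.acceptor, 0, None) / total, np.nan)
    for t in _scan_channel(trace.acceptor, window, z_threshold, sd_a):
        if any(abs(t - f) <= window for f in donor_frames):
            continue
        e_before, e_after = _window_means(eff, t)
        tot_before, tot_after = _window_means(total, t)
        if (
            np.isfinite(e_after)
            and e_after < e_dark_threshold
            and (not np.isfinite(e_before) or e_before >= e_dark_threshold)
            and tot_after >= tot_before * (1.0 - total_drop_fraction)
        ):
            z = (trace.acceptor[t : t + window].mean() - trace.acceptor[max(0, t - window) : t].mean()) / (
                max(sd_a, 1e-12) * np.sqrt(2.0 / window)
            )
            events.append(BleachPoint(t, "acceptor", float(z)))

    return sorted(events, key=lambda bp: bp.frame)


def truncate_and_filter(
    fret: FretTrace,
    bleach_points: Sequence[BleachPoint],
    config: QcConfig | None = None,
) -> FretTrace:
    """Truncate at the first bleach and apply acceptance rules.

    A trace is rejected when more than one bleach step is seen in a single
    channel (multiple fluorophores), when fewer than ``min_frames`` usable
    frames remain before the first bleach, or when the acceptor is dark
    (E below ``e_dark``) for most of the retained frames — the signature of
    a molecule without an active FRET pair, e.g. an acceptor that bleached
    before the recording started and so shows no detectable bleach step.
    """
    config = config or QcConfig()
    flags = list(fret.qc_flags)
    if "rejected:all_invalid" in flags:
        return replace(fret, accepted=None)

    per_channel = {"donor": 0, "acceptor": 0}
    for bp in bleach_points:
        if bp.channel in per_channel:
            per_channel[bp.channel] += 1
            flags.append(f"{bp.channel}_bleach_at:{bp.frame}")
    if max(per_channel.values()) > 1:
        flags.append("rejected:multistep_bleach")
        return replace(fret, accepted=None, qc_flags=tuple(flags))

    first = min((bp.frame for bp in bleach_points), default=len(fret))
    usable = int(fret.valid[:first].sum())
    if usable < config.min_frames:
        flags.append("rejected:too_short")
        return replace(fret, accepted=None, qc_flags=tuple(flags))
    kept = fret.efficiency[:first][fret.valid[:first]]
    if (kept < config.e_dark).mean() > config.max_dark_fraction:
        flags.append("rejected:dark_acceptor")
        return replace(fret, accepted=None, qc_flags=tuple(flags))
    return replace(fret, accepted=(0, first), qc_flags=tuple(flags))


def select_histogram_frames(
    fret: FretTrace, n_min: int = 30, n_max: int = 50
) -> np.ndarray | None:
    """Earliest usable frames for the population histogram.

    Returns the first ``min(n_max, usable)`` valid efficiencies of the
    accepted range, or ``None`` when fewer than ``n_min`` are available —
    capping per-molecule contribution so no single molecule dominates the
    histogram.
    """
    if not fret.is_accepted:
        return None
    values = fret.accepted_values()
    if values.size < n_min:
        return None
    return values[:n_max].copy()


def estimate_background(
    trace: IntensityTrace,
    bleach_points: Sequence[BleachPoint],
    default: float = 0.0,
    min_segment: int = 5,
) -> float:
    """Per-trace baseline from the post-donor-bleach segment.

    After a donor bleach both channels are dark, so their pooled median
    estimates the detection background; falls back to ``default`` when no
    usable post-bleach segment exists.
    """
    donor_points = [bp for bp in bleach_points if bp.channel == "donor"]
    if not donor_points:
        return default
    b = donor_points[0].frame
    if len(trace) - b < min_segment:
        return default
    seg = np.concatenate([trace.donor[b:], trace.acceptor[b:]])
    return float(np.median(seg))


def process_trace(trace: IntensityTrace, config: QcConfig | None = None) -> FretTrace:
    """detect_bleach -> background estimate -> compute_fret -> QC filter."""
    config = config or QcConfig()
    points = detect_bleach(trace, window=config.bleach_window, z_threshold=config.bleach_z)
    bg = estimate_background(trace, points, default=config.background)
    fret = compute_fret(trace, floor=config.intensity_floor, background=bg)
    return truncate_and_filter(fret, points, config)


def qc_report(fret_traces: Sequence[FretTrace]) -> dict:
    """Counts of accepted traces and of each rejection reason."""
    report = {"n_traces": len(fret_traces), "n_accepted": 0, "rejections": {}}
    for ft in fret_traces:
        if ft.is_accepted:
            report["n_accepted"] += 1
        else:
            reasons = [f for f in ft.qc_flags if f.startswith("rejected:")] or [
                "rejected:unfiltered"
            ]
            for r in reasons:
                report["rejections"][r] = report["rejections"].get(r, 0) + 1
    return report
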