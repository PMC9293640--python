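"""Microscale thermophoresis (MST) binding analysis.

An MST capillary records the fluorescence of a labeled RNA substrate around
an IR-laser pulse (here 30 s on, 5 s off).  The normalized fluorescence
Fnorm — the hot-window / cold-window ratio in per-mil — changes when protein
binds the substrate, so titrating protein against fixed 20 nM substrate
gives a dose-response curve whose EC50 measures affinity: smaller EC50,
tighter binding.  The curve is fit with a Hill model

    Fnorm(c) = baseline + amplitude * c^h / (EC50^h + c^h)

by multi-start least squares with residual-bootstrap confidence intervals,
and substrates are ranked by ascending EC50 with overlap flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np

__all__ = [
    "MstTrace",
    "BindingCurve",
    "DoseResponseFit",
    "SubstrateRanking",
    "compute_fnorm",
    "hill_curve",
    "simulate_mst_trace",
    "simulate_binding_curve",
    "fit_dose_response",
    "rank_substrates",
]


@dataclass(frozen=True)
class MstTrace:
    """Fluorescence time trace of one capillary.

    The laser is off for ``laser_off_s`` seconds, on for ``laser_on_s``
    seconds, then off again; the thermophoresis signal is read from windows
    just before laser-on (cold) and at the end of laser-on (hot).
    """

    time_s: np.ndarray
    fluorescence: np.ndarray
    ligand_concentration: float
    laser_on_s: float = 30.0
    laser_off_s: float = 5.0
    substrate: str = ""
    protein: str = ""

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or f.shape != t.shape or t.size < 2:
            raise ValueError("time_s and fluorescence must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly ascending")
        if np.any(f < 0):
            raise ValueError("fluorescence must be non-negative")
        if self.laser_off_s + self.laser_on_s > t[-1] + 1e-9:
            raise ValueError("laser windows extend beyond the trace")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "fluorescence", f)

    @property
    def laser_on_start(self) -> float:
        return self.laser_off_s

    @property
    def laser_on_end(self) -> float:
        return self.laser_off_s + self.laser_on_s


def compute_fnorm(
    trace: MstTrace,
    cold_window: tuple[float, float] | None = None,
    hot_window: tuple[float, float] | None = None,
) -> float:
    """Normalized fluorescence in per-mil: 1000 * mean(hot) / mean(cold).

    Defaults follow the vendor-style convention: cold = the 1 s before
    laser-on, hot = the final 1 s of the laser-on period.  The ratio is
    invariant to overall intensity scaling of the trace.
    """
    if cold_window is None:
        cold_window = (trace.laser_on_start - 1.0, trace.laser_on_start)
    if hot_window is None:
        hot_window = (trace.laser_on_end - 1.0, trace.laser_on_end)
    t = trace.time_s
    for name, (lo, hi) in (("cold", cold_window), ("hot", hot_window)):
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
            raise ValueError(f"{name} window [{lo}, {hi}] not within the trace")
    if cold_window[1] > trace.laser_on_start + 1e-9:
        raise ValueError("cold window must end before laser-on")
    cold = trace.fluorescence[(t >= cold_window[0]) & (t <= cold_window[1])]
    hot = trace.fluorescence[(t >= hot_window[0]) & (t <= hot_window[1])]
    if cold.size == 0 or hot.size == 0:
        raise ValueError("empty Fnorm window")
    cold_mean = float(cold.mean())
    if cold_mean == 0:
        raise ValueError("cold-window mean is zero; cannot normalize")
    return 1000.0 * float(hot.mean()) / cold_mean


def simulate_mst_trace(
    ligand_concentration: float,
    plateau: float,
    *,
    tau_s: float = 3.0,
    dt_s: float = 0.1,
    laser_on_s: float = 30.0,
    laser_off_s: float = 5.0,
    post_off_s: float = 5.0,
    f0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    substrate: str = "",
    protein: str = "",
) -> MstTrace:
    """Synthetic capillary trace: exponential depletion to ``plateau``.

    Before laser-on the signal sits at ``f0``; during the pulse it relaxes
    as f0 * (plateau + (1 - plateau) * exp(-(t - t_on)/tau)); after
    laser-off it recovers with the same time constant.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, laser_off_s + laser_on_s + post_off_s + dt_s / 2, dt_s)
    f = np.full_like(t, f0)
    on = (t >= laser_off_s) & (t <= laser_off_s + laser_on_s)
    f[on] = f0 * (plateau + (1.0 - plateau) * np.exp(-(t[on] - laser_off_s) / tau_s))
    after = t > laser_off_s + laser_on_s
    f_end = f0 * (plateau + (1.0 - plateau) * np.exp(-laser_on_s / tau_s))
    f[after] = f0 + (f_end - f0) * np.exp(-(t[after] - laser_off_s - laser_on_s) / tau_s)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, f.size)
    return MstTrace(
        time_s=t,
        fluorescence=np.clip(f, 0.0, None),
        ligand_concentration=ligand_concentration,
        laser_on_s=laser_on_s,
        laser_off_s=laser_off_s,
        substrate=substrate,
        protein=protein,
    )


@dataclass(frozen=True)
class BindingCurve:
    """Fnorm (per-mil) versus ligand concentration (molar)."""

    concentrations: np.ndarray
    fnorm: np.ndarray
    n_replicates: np.ndarray | None = None
    substrate: str = ""
    protein: str = ""

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        f = np.asarray(self.fnorm, dtype=float)
        if c.ndim != 1 or f.shape != c.shape:
            raise ValueError("concentrations and fnorm must be equal-length 1-D arrays")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly ascending")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "fnorm", f)


def hill_curve(concentrations, ec50: float, hill: float, baseline: float, amplitude: float):
    """Hill dose-response: baseline + amplitude * c^h / (EC50^h + c^h)."""
    c = np.asarray(concentrations, dtype=float)
    ch = c**hill
    return baseline + amplitude * ch / (ec50**hill + ch)


def simulate_binding_curve(
    ec50: float,
    *,
    hill: float = 1.0,
    baseline: float = 900.0,
    amplitude: float = 60.0,
    concentrations: np.ndarray | None = None,
    noise_fraction: float = 0.0,
    seed: int | None = 0,
    substrate: str = "",
    protein: str = "",
) -> BindingCurve:
    """Synthetic titration; noise is ``noise_fraction`` of the amplitude."""
    if concentrations is None:
        concentrations = np.logspace(-9.5, -5.5, 12)  # ~0.3 nM - 3 uM
    f = hill_curve(concentrations, ec50, hill, baseline, amplitude)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_fraction * abs(amplitude), f.size)
    return BindingCurve(
        concentrations=np.asarray(concentrations, dtype=float),
        fnorm=f,
        substrate=substrate,
        protein=protein,
    )


@dataclass
class DoseResponseFit:
    """Fitted Hill parameters with bootstrap CIs and diagnostics."""

    ec50: float
    hill: float
    baseline: float
    amplitude: float
    ec50_ci: tuple[float, float]
    rmse: float
    warnings: tuple[str, ...] = ()
    substrate: str = ""
    protein: str = ""

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")
        lo, hi = self.ec50_ci
        if not (lo <= self.ec50 <= hi):
            raise ValueError("EC50 CI must contain the point estimate")


def _hill_residual(params, c, f):
    return hill_curve(c, params["ec50"].value, params["hill"].value,
                      params["baseline"].value, params["amplitude"].value) - f


def _fit_once(c, f, ec50_start, fix_hill):
    params = lmfit.Parameters()
    params.add("ec50", value=ec50_start, min=c.min() / 1e3, max=c.max() * 1e3)
    params.add("hill", value=1.0 if fix_hill is None else fix_hill,
               min=0.3, max=4.0, vary=fix_hill is None)
    params.add("baseline", value=float(f[0]))
    params.add("amplitude", value=float(f[-1] - f[0]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lmfit.minimize(_hill_residual, params, args=(c, f), method="leastsq")


def fit_dose_response(
    curve: BindingCurve,
    *,
    fix_hill: float | None = None,
    n_starts: int = 7,
    n_boot: int = 200,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> DoseResponseFit:
    """Multi-start Hill fit with residual-bootstrap EC50 CI.

    Requires >= 5 concentrations spanning >= 2 decades.  EC50 starting
    values are spread log-uniformly across the tested range; the lowest
    residual sum wins.  Flags: ``no_binding_signal`` when the fitted
    amplitude is within noise, ``ec50_outside_range`` when the estimate
    falls outside the tested concentrations.
    """
    c, f = curve.concentrations, curve.fnorm
    if c.size < 5:
        raise ValueError("need at least 5 concentrations")
    if np.log10(c.max() / c.min()) < 2.0:
        raise ValueError("concentrations must span at least two decades")

    starts = np.logspace(np.log10(c.min()), np.log10(c.max()), n_starts)
    results = []
    for s in starts:
        try:
            results.append(_fit_once(c, f, s, fix_hill))
        except Exception:
            continue
    if not any(r.success for r in results):
        raise RuntimeError(
            "Hill fit failed to converge from every starting point; "
            f"messages: {[getattr(r, 'message', '') for r in results]}"
        )
    best = min((r for r in results if r.success), key=lambda r: float(r.chisqr))
    p = best.params
    resid = _hill_residual(p, c, f)
    rmse = float(np.sqrt(np.mean(resid**2)))

    rng = np.random.default_rng(seed)
    fitted = hill_curve(c, p["ec50"].value, p["hill"].value,
                        p["baseline"].value, p["amplitude"].value)
    boot_ec50 = []
    for _ in range(n_boot):
        fb = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            rb = _fit_once(c, fb, p["ec50"].value, fix_hill)
        except Exception:
            continue
        if rb.success:
            boot_ec50.append(rb.params["ec50"].value)
    alpha = (1.0 - ci_level) / 2.0
    if boot_ec50:
        lo = float(np.quantile(boot_ec50, alpha))
        hi = float(np.quantile(boot_ec50, 1.0 - alpha))
        lo, hi = min(lo, p["ec50"].value), max(hi, p["ec50"].value)
    else:
        lo = hi = p["ec50"].value

    flags = []
    if abs(p["amplitude"].value) <= 2.0 * rmse:
        flags.append("no_binding_signal")
    if not (c.min() <= p["ec50"].value <= c.max()):
        flags.append("ec50_outside_range")
    return DoseResponseFit(
        ec50=float(p["ec50"].value),
        hill=float(p["hill"].value),
        baseline=float(p["baseline"].value),
        amplitude=float(p["amplitude"].value),
        ec50_ci=(lo, hi),
        rmse=rmse,
        warnings=tuple(flags),
        substrate=curve.substrate,
        protein=curve.protein,
    )


@dataclass
class SubstrateRanking:
    """Substrates ordered by ascending EC50 (descending affinity)."""

    order: list[str]
    ec50: dict[str, float]
    indistinguishable_pairs: list[tuple[str, str]]

    def to_records(self) -> list[dict]:
        return [
            {"rank": i + 1, "substrate": name, "ec50": self.ec50[name]}
            for i, name in enumerate(self.order)
        ]


def rank_substrates(fits: Mapping[str, DoseResponseFit]) -> SubstrateRanking:
    """Affinity ranking: ascending EC50, CI-overlap pairs flagged as ties."""
    if len(fits) < 2:
        raise ValueError("need at least two substrates to rank")
    order = sorted(fits, key=lambda k: fits[k].ec50)
    ties = []
    names = list(fits)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            lo_a, hi_a = fits[a].ec50_ci
            lo_b, hi_b = fits[b].ec50_ci
            if lo_a <= hi_b and lo_b <= hi_a:
                ties.append((a, b))
    return SubstrateRanking(
        order=order,
        ec50={k: fits[k].ec50 for k in fits},
        indistinguishable_pairs=ties,
    )
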